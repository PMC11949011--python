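"""Synthetic cohorts with the statistical structure of the ICI liquid-biopsy study.

Generates paired baseline (BL) / on-treatment (OT) data for a cohort of
metastatic urothelial cancer patients treated with checkpoint inhibitors:

* clinical ground truth (clinical-benefit label, PFS, censoring),
* a tracked-variant ctDNA assay (cfDNA, matched WBC, control panel, CNV
  segments, total cfDNA concentration),
* a gene x sample whole-blood RNA count matrix with paired structure.

A single latent responder status drives both PFS and the molecular effects,
so the two modalities are correlated with outcome yet individually noisy.
A configurable fraction of patients is "discordant": their ctDNA ratio or
RNA effect is pushed toward the respective decision cutoff, which is what
gives the downstream multimodal arbitration something to arbitrate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SimConfig",
    "CtdnaAssay",
    "ExpressionData",
    "simulate_cohort",
    "simulate_ctdna_assay",
    "simulate_expression",
    "study_93",
    "write_assay",
    "write_expression",
]

_TIMEPOINTS = ("BL", "OT")
_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults are desk-scale but structurally matched to the study: 93
    patients of whom 42 have clinical benefit, RNA cohorts of 29/29/21,
    ~12.5% of patients with undetectable ctDNA at both timepoints, and
    ~40% of patients whose two modalities disagree near the cutoffs.
    """

    n_patients: int = 93
    cb_fraction: float = 42 / 93
    seed: int = 0
    # expression
    n_genes: int = 2000
    n_signal_genes: int = 50
    signal_log2fc_range: tuple[float, float] = (0.4, 1.1)
    signal_down_fraction: float = 0.2
    nb_dispersion: float = 0.18
    library_size: int = 1_000_000
    paired_effect_sd: float = 0.2
    # ctDNA assay
    n_tracked_variants: int = 10
    mean_depth: int = 5000
    bl_tf_log10_range: tuple[float, float] = (-2.5, -1.0)
    ot_tf_multiplier_cb: float = 0.25
    ot_tf_multiplier_ncb: float = 1.6
    ot_tf_sigma: float = 0.4
    control_noise_vaf: float = 1e-4
    n_controls: int = 22
    chip_fraction: float = 0.1
    undetectable_fraction: float = 0.125
    cfdna_conc_lognormal_params: tuple[float, float] = (2.3, 0.5)
    # clinical
    censor_months: float = 36.0
    responder_pfs_mean: float = 12.0
    nonresponder_pfs_mean: float = 3.0
    # discordance injection
    discordant_ctdna_fraction: float = 0.2
    discordant_rna_fraction: float = 0.2
    rna_discordant_attenuation: float = 0.3

    def validate(self) -> None:
        for name in ("cb_fraction", "control_noise_vaf", "chip_fraction",
                     "undetectable_fraction", "discordant_ctdna_fraction",
                     "discordant_rna_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("n_patients", "n_genes", "n_signal_genes",
                     "n_tracked_variants", "mean_depth", "library_size",
                     "n_controls"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("signal_log2fc_range", "bl_tf_log10_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must be an ordered pair, got ({lo}, {hi})")
        if self.n_signal_genes > self.n_genes:
            raise ValueError("n_signal_genes may not exceed n_genes")
        if self.censor_months <= 0:
            raise ValueError("censor_months must be positive")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        d = yaml.safe_load(Path(path).read_text())
        for k, v in d.items():
            if isinstance(v, list):
                d[k] = tuple(v)
        return cls(**d)


def _rng(seed: int, stream: int) -> np.random.Generator:
    # independent, reproducible streams per generator stage
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(stream + 1)[stream])


def _largest_remainder(total: int, sizes: tuple[int, ...], denom: int) -> list[int]:
    """Apportion ``total`` items over buckets proportional to sizes/denom."""
    exact = [total * s / denom for s in sizes]
    base = [int(np.floor(e)) for e in exact]
    short = total - sum(base)
    order = np.argsort([b - e for b, e in zip(base, exact)])  # largest remainder first
    for j in order[:short]:
        base[j] += 1
    return base


def _truncated_exp_below(rng, mean: float, upper: float, size: int) -> np.ndarray:
    """Exponential(mean) conditioned on being < upper, by inverse CDF."""
    u = rng.uniform(size=size)
    cap = 1.0 - np.exp(-upper / mean)
    return -mean * np.log1p(-u * cap)


def simulate_cohort(
    config: SimConfig,
    cohort_sizes: tuple[int, int, int] = (29, 29, 21),
    exact_n_cb: int | None = None,
) -> pd.DataFrame:
    """Generate the clinical table plus latent simulation flags.

    Returns one row per patient: ``patient_id, cohort, cb, pfs_months,
    event`` (the observable clinical table) and latent columns prefixed
    ``latent_`` (simulation ground truth used by the assay generators and
    by tests, never by the analysis pipeline).

    Clinical benefit (CB) is progression-free survival of at least 6
    months. Responders draw PFS = 6 + Exp(mean 12 mo); non-responders draw
    Exp(mean 3 mo) truncated below 6; everyone is administratively
    censored at ``censor_months``.
    """
    config.validate()
    if sum(cohort_sizes) > config.n_patients:
        raise ValueError(
            f"cohort sizes {cohort_sizes} exceed n_patients={config.n_patients}"
        )
    rng = _rng(config.seed, 0)
    n = config.n_patients

    if exact_n_cb is not None:
        if not 0 <= exact_n_cb <= n:
            raise ValueError("exact_n_cb out of range")
        cb = np.zeros(n, bool)
        cb[: exact_n_cb] = True
        rng.shuffle(cb)
    else:
        cb = rng.uniform(size=n) < config.cb_fraction

    pfs = np.empty(n)
    pfs[cb] = 6.0 + rng.exponential(config.responder_pfs_mean, cb.sum())
    pfs[~cb] = _truncated_exp_below(
        rng, config.nonresponder_pfs_mean, 6.0, (~cb).sum()
    )
    event = np.ones(n, bool)
    over = pfs > config.censor_months
    pfs[over] = config.censor_months
    event[over] = False

    # stratified cohort assignment: spread CB and N-CB proportionally over
    # discovery / test / validation so every cohort holds both classes;
    # patients beyond the cohort sizes stay unassigned (ctDNA-only)
    cohort = np.array([None] * n, object)
    names = ["discovery", "test", "validation"]
    n_assigned = sum(cohort_sizes)
    pool = rng.permutation(n)[:n_assigned] if n_assigned else np.array([], int)
    cb_members = rng.permutation(pool[cb[pool]]) if n_assigned else pool
    ncb_members = rng.permutation(pool[~cb[pool]]) if n_assigned else pool
    cb_quota = (
        _largest_remainder(len(cb_members), cohort_sizes, n_assigned)
        if n_assigned
        else [0, 0, 0]
    )
    start_cb = start_ncb = 0
    for name, size, q_cb in zip(names, cohort_sizes, cb_quota):
        q_cb = min(q_cb, size)
        q_ncb = size - q_cb
        cohort[cb_members[start_cb:start_cb + q_cb]] = name
        cohort[ncb_members[start_ncb:start_ncb + q_ncb]] = name
        start_cb += q_cb
        start_ncb += q_ncb

    # latent discordance / undetectable flags
    u = rng.uniform(size=n)
    ct_disc = u < config.discordant_ctdna_fraction
    rna_disc = (~ct_disc) & (
        u < config.discordant_ctdna_fraction + config.discordant_rna_fraction
    )
    undet = rng.uniform(size=n) < config.undetectable_fraction

    return pd.DataFrame(
        {
            "patient_id": [f"P{i + 1:03d}" for i in range(n)],
            "cohort": cohort,
            "cb": cb,
            "pfs_months": pfs,
            "event": event,
            "latent_ctdna_discordant": ct_disc,
            "latent_rna_discordant": rna_disc,
            "latent_undetectable": undet,
        }
    )


def study_93(seed: int = 0, config: SimConfig | None = None) -> pd.DataFrame:
    """The default study-scale fixture: 93 patients, exactly 42 with CB,
    RNA cohorts of 29/29/21 (the remaining 14 patients are ctDNA-only and
    carry cohort None)."""
    cfg = config or SimConfig(seed=seed)
    cfg = SimConfig(**{**asdict(cfg), "seed": seed, "n_patients": 93})
    return simulate_cohort(cfg, cohort_sizes=(29, 29, 21), exact_n_cb=42)


@dataclass
class CtdnaAssay:
    """Tracked-variant assay tables for a cohort.

    variants: long table over (patient, timepoint/sample_role, locus) with
        columns patient_id, sample_role in {cfdna_bl, cfdna_ot, wbc, control},
        control_id (controls only), chrom, pos, ref, alt, region_id,
        variant_reads, depth, vaf.
    cnv: per patient x timepoint segment table (patient_id, timepoint,
        region_id, relative_coverage, maf).
    cfdna_conc: per patient x timepoint total cfDNA concentration (ng/mL).
    truth: latent per-patient tumor fractions at BL and OT.
    """

    variants: pd.DataFrame
    cnv: pd.DataFrame
    cfdna_conc: pd.DataFrame
    truth: pd.DataFrame


def simulate_ctdna_assay(patients: pd.DataFrame, config: SimConfig) -> CtdnaAssay:
    """Simulate the ctDNA assay for every patient in ``patients``.

    Baseline tumor fraction is log-uniform over ``bl_tf_log10_range``; the
    OT fraction multiplies it by a lognormal factor centered at the
    CB- or N-CB-specific multiplier (or at 1 with tight spread for
    ctDNA-discordant patients). Patients flagged latent_undetectable carry
    TF = 0 at both timepoints. Per-variant VAF is TF * ccf / 2 in
    copy-neutral regions; variant reads are binomial over sequencing depth
    with a background error floor. A chip_fraction subset of tracked
    variants is of hematopoietic origin: present at both timepoints and in
    the matched WBC sample at comparable VAF, independent of tumor burden.
    """
    config.validate()
    rng = _rng(config.seed, 1)
    n = len(patients)

    lo, hi = config.bl_tf_log10_range
    tf_bl = 10.0 ** rng.uniform(lo, hi, n)
    tf_bl[patients["latent_undetectable"].to_numpy()] = 0.0

    mult = np.where(
        patients["cb"].to_numpy(),
        config.ot_tf_multiplier_cb,
        config.ot_tf_multiplier_ncb,
    ).astype(float)
    sigma = np.full(n, config.ot_tf_sigma)
    disc = patients["latent_ctdna_discordant"].to_numpy()
    mult[disc] = 1.0
    sigma[disc] = 0.05
    tf_ot = np.minimum(tf_bl * np.exp(rng.normal(np.log(mult), sigma)), 0.5)
    tf_ot[tf_bl == 0.0] = 0.0

    mu_c, sd_c = config.cfdna_conc_lognormal_params
    conc = np.exp(rng.normal(mu_c, sd_c, (n, 2)))

    n_var = config.n_tracked_variants
    n_chip = int(round(config.chip_fraction * n_var))
    rows: list[pd.DataFrame] = []
    cnv_rows: list[dict] = []
    regions = [f"region_{j + 1}" for j in range(5)]

    def _binom_rows(pid, role, depth_mean, p, loci, control_id=None, size=None):
        m = len(loci)
        depth = rng.poisson(depth_mean, m).clip(min=1)
        reads = rng.binomial(depth, np.clip(p, 0.0, 1.0))
        df = loci.copy()
        df.insert(0, "patient_id", pid)
        df.insert(1, "sample_role", role)
        df["control_id"] = control_id
        df["variant_reads"] = reads
        df["depth"] = depth
        df["vaf"] = reads / depth
        return df

    for i, pid in enumerate(patients["patient_id"]):
        ccf = rng.uniform(0.3, 1.0, n_var)
        is_chip = np.zeros(n_var, bool)
        if n_chip:
            is_chip[rng.choice(n_var, n_chip, replace=False)] = True
        chip_vaf = rng.uniform(0.002, 0.05, n_var)
        loci = pd.DataFrame(
            {
                "chrom": [f"chr{c}" for c in rng.integers(1, 23, n_var)],
                "pos": rng.integers(1, 10**8, n_var),
                "ref": rng.choice(_BASES, n_var),
                "alt": rng.choice(_BASES, n_var),
                "region_id": rng.choice(regions, n_var),
            }
        )
        # tumor variants sit in copy-neutral regions: VAF = TF * ccf / 2
        for role, tf in (("cfdna_bl", tf_bl[i]), ("cfdna_ot", tf_ot[i])):
            p = tf * ccf / 2.0
            p = np.where(is_chip, chip_vaf, p) + config.control_noise_vaf
            rows.append(_binom_rows(pid, role, config.mean_depth, p, loci))
        # matched WBC: chip variants at comparable VAF, others at noise floor
        p_wbc = np.where(
            is_chip, chip_vaf * rng.uniform(0.8, 1.2, n_var), 0.0
        ) + config.control_noise_vaf
        rows.append(_binom_rows(pid, "wbc", config.mean_depth, p_wbc, loci))
        # control cfDNA panel: pure background noise at every tracked locus
        for c in range(config.n_controls):
            rows.append(
                _binom_rows(
                    pid, "control", config.mean_depth,
                    np.full(n_var, config.control_noise_vaf), loci,
                    control_id=f"C{c + 1:02d}",
                )
            )
        for tp, tf in zip(_TIMEPOINTS, (tf_bl[i], tf_ot[i])):
            for region in regions:
                cnv_rows.append(
                    {
                        "patient_id": pid,
                        "timepoint": tp,
                        "region_id": region,
                        "relative_coverage": rng.normal(0.0, 0.02),
                        "maf": 0.5 + abs(rng.normal(0.0, 0.01)),
                    }
                )

    variants = pd.concat(rows, ignore_index=True)
    cnv = pd.DataFrame(cnv_rows)
    conc_df = pd.DataFrame(
        {
            "patient_id": np.repeat(patients["patient_id"].to_numpy(), 2),
            "timepoint": np.tile(_TIMEPOINTS, n),
            "cfdna_conc_ng_per_ml": conc.ravel(),
        }
    )
    truth = pd.DataFrame(
        {"patient_id": patients["patient_id"], "tf_bl": tf_bl, "tf_ot": tf_ot}
    )
    return CtdnaAssay(variants=variants, cnv=cnv, cfdna_conc=conc_df, truth=truth)


@dataclass
class ExpressionData:
    """Gene x sample counts with sample metadata and signal-gene truth."""

    counts: pd.DataFrame  # genes x samples, nonnegative integers
    samples: pd.DataFrame  # sample_id, patient_id, timepoint, group, cohort
    signal: pd.DataFrame  # gene, log2fc (signed), latent truth


def simulate_expression(patients: pd.DataFrame, config: SimConfig) -> ExpressionData:
    """Simulate paired whole-blood RNA counts for the RNA-cohort patients.

    Counts are negative-binomial around lognormal gene baselines with a
    shared patient x gene random effect (the paired structure). For CB
    patients, OT samples shift the signal genes by a log2 fold change
    drawn from ``signal_log2fc_range`` (a ``signal_down_fraction`` minority
    shifted down, emulating the down-regulated myeloid genes); clean N-CB
    patients have no systematic OT shift. RNA-discordant patients of
    either class get the attenuated effect, landing them near the
    classifier's probability cutoff. Signal genes are drawn from the upper
    half of baseline abundance, as befits expressed blood immune genes.
    """
    config.validate()
    rng = _rng(config.seed, 2)
    sub = patients[patients["cohort"].notna()].reset_index(drop=True)
    if sub.empty:
        raise ValueError("no cohort-assigned patients to simulate expression for")

    g = config.n_genes
    genes = np.array([f"G{j + 1:05d}" for j in range(g)])
    abundance = np.exp(rng.normal(0.0, 1.2, g))
    abundance /= abundance.sum()

    upper_half = np.argsort(abundance)[g // 2:]
    signal_idx = rng.choice(upper_half, config.n_signal_genes, replace=False)
    lo, hi = config.signal_log2fc_range
    fc = rng.uniform(lo, hi, config.n_signal_genes)
    down = rng.uniform(size=config.n_signal_genes) < config.signal_down_fraction
    fc[down] *= -1.0

    eff = np.zeros(len(sub))
    cbv = sub["cb"].to_numpy()
    rdisc = sub["latent_rna_discordant"].to_numpy()
    eff[cbv & ~rdisc] = 1.0
    eff[rdisc] = config.rna_discordant_attenuation

    sample_ids, cols, meta = [], [], []
    phi = config.nb_dispersion
    for i, row in sub.iterrows():
        pat_eff = np.exp(rng.normal(0.0, config.paired_effect_sd, g))
        for tp in _TIMEPOINTS:
            lib = np.exp(rng.normal(np.log(config.library_size), 0.1))
            mu = lib * abundance * pat_eff
            if tp == "OT" and eff[i] > 0:
                mu = mu.copy()
                mu[signal_idx] *= 2.0 ** (fc * eff[i])
            lam = rng.gamma(1.0 / phi, mu * phi)
            cols.append(rng.poisson(lam))
            sid = f"{row.patient_id}_{tp}"
            sample_ids.append(sid)
            meta.append(
                {
                    "sample_id": sid,
                    "patient_id": row.patient_id,
                    "timepoint": tp,
                    "group": "CB" if row.cb else "N-CB",
                    "cohort": row.cohort,
                }
            )

    counts = pd.DataFrame(
        np.column_stack(cols), index=genes, columns=sample_ids
    )
    counts.index.name = "gene"
    signal = pd.DataFrame({"gene": genes[signal_idx], "log2fc": fc})
    return ExpressionData(counts=counts, samples=pd.DataFrame(meta), signal=signal)


def write_assay(assay: CtdnaAssay, outdir: str | Path) -> None:
    """Write assay tables as tab-separated files with documented headers."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    assay.variants.to_csv(out / "variants.tsv", sep="\t", index=False)
    assay.cnv.to_csv(out / "cnv_segments.tsv", sep="\t", index=False)
    assay.cfdna_conc.to_csv(out / "cfdna_conc.tsv", sep="\t", index=False)
    assay.truth.to_csv(out / "tf_truth.tsv", sep="\t", index=False)


def write_expression(expr: ExpressionData, outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    expr.counts.to_csv(out / "counts.tsv", sep="\t")
    expr.samples.to_csv(out / "samples.tsv", sep="\t", index=False)
    expr.signal.to_csv(out / "signal_genes.tsv", sep="\t", index=False)
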