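"""ctDNA quantification from tracked-variant sequencing evidence.

Implements the liquid-biopsy quantification chain: variant filtering
(independent and dependent calling against a control cfDNA panel and the
patient-matched WBC sample), CNV classification from relative coverage and
major-allele fraction, tumor-fraction estimation with LOH correction and a
germline-SNP fallback, conversion to ctDNA copies per mL plasma
(concentration x fraction x 303), exact binomial uncertainty limits, and
longitudinal dichotomization of BL -> OT changes into increase vs no
increase (the early-response ctDNA readout: an increase predicts no
clinical benefit).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "COPIES_PER_NG",
    "CtdnaQuant",
    "CtdnaDynamics",
    "filter_independent_variants",
    "dependent_call",
    "classify_cnv",
    "classify_cnv_segments",
    "estimate_tumor_fraction",
    "to_copies_per_ml",
    "quant_uncertainty",
    "dichotomize_dynamics",
    "control_mean_vafs",
    "quantify_timepoint",
    "quantify_cohort",
]

log = logging.getLogger(__name__)

#: haploid genome copies per ng of human DNA, the plasma conversion constant
COPIES_PER_NG = 303.0

MIN_READS_INDEPENDENT = 5
MIN_VAF_INDEPENDENT = 0.001
MIN_READS_DEPENDENT = 3
CONTROL_FOLD = 20.0
WBC_FOLD = 3.0
DEFAULT_CONTROL_FLOOR = 1e-5

_LOCUS_COLS = ["chrom", "pos", "ref", "alt"]


@dataclass
class CtdnaQuant:
    """Per-timepoint ctDNA level with uncertainty bounds."""

    tumor_fraction: float
    tf_lower: float
    tf_upper: float
    cfdna_conc_ng_per_ml: float
    copies_per_ml: float
    copies_lower: float
    copies_upper: float
    detectable: bool
    source: str  # somatic_vaf | germline_maf | none


@dataclass
class CtdnaDynamics:
    """BL -> OT dynamics: ratio, dichotomized category, predicted label."""

    bl: CtdnaQuant
    ot: CtdnaQuant
    ratio: float
    category: str  # increase_or_stable | decrease | undetectable_both
    predicted_label: str  # CB | N-CB


def filter_independent_variants(observations: pd.DataFrame) -> pd.DataFrame:
    """Independent calling: keep variants with >= 5 supporting reads and
    VAF > 0.1%. Zero-depth records are dropped with a logged reason."""
    obs = observations
    bad = obs["depth"] <= 0
    if bad.any():
        for _, r in obs[bad].iterrows():
            log.warning(
                "rejecting zero-depth observation at %s:%s %s>%s",
                r.get("chrom"), r.get("pos"), r.get("ref"), r.get("alt"),
            )
        obs = obs[~bad]
    vaf = obs["variant_reads"] / obs["depth"]
    keep = (obs["variant_reads"] >= MIN_READS_INDEPENDENT) & (vaf > MIN_VAF_INDEPENDENT)
    return obs[keep]


def dependent_call(
    variant_reads: int,
    vaf: float,
    control_vafs,
    wbc_vaf: float | None = None,
    control_floor: float = DEFAULT_CONTROL_FLOOR,
) -> bool:
    """Dependent calling for a variant already detected at the other
    timepoint (or in tumor tissue): >= 3 supporting reads, VAF at least
    20x the mean control-panel VAF for that nucleotide change, and at
    least 3x the patient-matched WBC VAF when available."""
    control_vafs = np.asarray(list(control_vafs), float)
    if control_vafs.size == 0:
        raise ValueError("control_vafs must be nonempty")
    if vaf < 0 or (control_vafs < 0).any() or (wbc_vaf is not None and wbc_vaf < 0):
        raise ValueError("VAFs must be nonnegative")
    ctrl = max(float(control_vafs.mean()), control_floor)
    if variant_reads < MIN_READS_DEPENDENT:
        return False
    if vaf < CONTROL_FOLD * ctrl:
        return False
    if wbc_vaf is not None and vaf < WBC_FOLD * wbc_vaf:
        return False
    return True


def classify_cnv(relative_coverage: float, maf: float) -> str:
    """Classify a segment as loss / gain / neutral.

    Loss: relative coverage <= -0.3, or <= -0.1 with MAF >= 0.6.
    Gain: relative coverage >= 0.3, or >= 0.1 with MAF >= 0.6.
    """
    rc = relative_coverage
    if rc <= -0.3 or (rc <= -0.1 and maf >= 0.6):
        return "loss"
    if rc >= 0.3 or (rc >= 0.1 and maf >= 0.6):
        return "gain"
    return "neutral"


def classify_cnv_segments(cnv: pd.DataFrame) -> pd.DataFrame:
    """Vectorized :func:`classify_cnv` over a segment table."""
    rc = cnv["relative_coverage"].to_numpy(float)
    maf = cnv["maf"].to_numpy(float)
    call = np.where(
        (rc <= -0.3) | ((rc <= -0.1) & (maf >= 0.6)),
        "loss",
        np.where((rc >= 0.3) | ((rc >= 0.1) & (maf >= 0.6)), "gain", "neutral"),
    )
    out = cnv.copy()
    out["call"] = call
    return out


def _tf_from_vaf(vaf: float, region_call: str) -> float:
    """Allele-dosage algebra: TF from the defining somatic VAF.

    Copy-neutral heterozygous variant: VAF = TF/2, so TF = 2 VAF.
    Single-copy loss (variant on the retained copy): VAF = TF/(2-TF),
    so TF = 2 VAF / (1 + VAF).
    """
    if region_call == "loss":
        return min(2.0 * vaf / (1.0 + vaf), 1.0)
    return min(2.0 * vaf, 1.0)


def estimate_tumor_fraction(
    called_variants: pd.DataFrame,
    cnv_calls: pd.DataFrame | None = None,
    germline_snp_mafs_in_loss_regions=None,
) -> tuple[float, str]:
    """Estimate tumor fraction from called somatic variants, with a
    germline-SNP fallback.

    Primary route: the called variant with highest VAF in a region not
    classified as gain; TF = 2v/(1+v) if its region is a loss (LOH
    corrected), else TF = min(2v, 1). Fallback: the major-allele fraction
    m of germline SNPs in a single-copy-loss region gives TF = 2 - 1/m.
    Returns (tf, source) with source in {somatic_vaf, germline_maf, none}.
    """
    region_call: dict[str, str] = {}
    if cnv_calls is not None and len(cnv_calls):
        calls = cnv_calls
        if "call" not in calls.columns:
            calls = classify_cnv_segments(calls)
        region_call = dict(zip(calls["region_id"], calls["call"]))

    if called_variants is not None and len(called_variants):
        cand = called_variants.copy()
        cand["region_call"] = (
            cand["region_id"].map(region_call).fillna("neutral")
            if "region_id" in cand.columns
            else "neutral"
        )
        cand = cand[cand["region_call"] != "gain"]
        if len(cand):
            if "vaf" not in cand.columns:
                cand["vaf"] = cand["variant_reads"] / cand["depth"]
            best = cand.loc[cand["vaf"].idxmax()]
            return _tf_from_vaf(float(best["vaf"]), str(best["region_call"])), "somatic_vaf"

    if germline_snp_mafs_in_loss_regions is not None:
        mafs = np.asarray(list(germline_snp_mafs_in_loss_regions), float)
        mafs = mafs[mafs > 0.5]
        if mafs.size:
            m = float(mafs.max())
            return float(np.clip(2.0 - 1.0 / m, 0.0, 1.0)), "germline_maf"

    return 0.0, "none"


def to_copies_per_ml(tumor_fraction: float, cfdna_conc_ng_per_ml: float) -> float:
    """ctDNA copies per mL plasma: tumor fraction x total cfDNA
    concentration (ng/mL) x 303 haploid copies per ng."""
    if tumor_fraction < 0 or cfdna_conc_ng_per_ml < 0:
        raise ValueError("tumor fraction and cfDNA concentration must be nonnegative")
    return tumor_fraction * cfdna_conc_ng_per_ml * COPIES_PER_NG


def quant_uncertainty(
    variant_reads: int,
    depth: int,
    cfdna_conc_ng_per_ml: float,
    region_call: str = "neutral",
    level: float = 0.95,
) -> tuple[float, float, float, float]:
    """95% Clopper-Pearson limits on the defining variant's VAF, propagated
    through the TF formula and the copies/mL conversion.

    Returns (tf_lower, tf_upper, copies_lower, copies_upper).
    """
    alpha = 1.0 - level
    if variant_reads <= 0:
        v_lo = 0.0
        v_hi = 1.0 - (alpha / 2.0) ** (1.0 / depth) if depth > 0 else 1.0
    else:
        v_lo = stats.beta.ppf(alpha / 2.0, variant_reads, depth - variant_reads + 1)
        v_hi = (
            1.0
            if variant_reads >= depth
            else stats.beta.ppf(1.0 - alpha / 2.0, variant_reads + 1, depth - variant_reads)
        )
    tf_lo = _tf_from_vaf(float(v_lo), region_call)
    tf_hi = _tf_from_vaf(float(v_hi), region_call)
    return (
        tf_lo,
        tf_hi,
        to_copies_per_ml(tf_lo, cfdna_conc_ng_per_ml),
        to_copies_per_ml(tf_hi, cfdna_conc_ng_per_ml),
    )


def dichotomize_dynamics(bl: CtdnaQuant, ot: CtdnaQuant) -> CtdnaDynamics:
    """Dichotomize BL -> OT copies/mL change into increase vs no increase.

    Undetectable at both timepoints -> no increase, predicted CB (low
    ctDNA is prognostically favorable), with ratio defined as 0. Otherwise
    ratio = OT/BL copies (+inf if BL is 0 and OT positive); ratio >= 1 is
    increase-or-stable -> predicted N-CB, ratio < 1 is decrease ->
    predicted CB.
    """
    if not bl.detectable and not ot.detectable:
        return CtdnaDynamics(bl, ot, 0.0, "undetectable_both", "CB")
    if bl.copies_per_ml == 0.0:
        ratio = np.inf if ot.copies_per_ml > 0 else 0.0
    else:
        ratio = ot.copies_per_ml / bl.copies_per_ml
    if ratio >= 1.0:
        return CtdnaDynamics(bl, ot, ratio, "increase_or_stable", "N-CB")
    return CtdnaDynamics(bl, ot, ratio, "decrease", "CB")


def control_mean_vafs(
    control_obs: pd.DataFrame, floor: float = DEFAULT_CONTROL_FLOOR
) -> pd.Series:
    """Mean control-panel VAF per nucleotide change (locus + alt), floored
    to avoid degenerate 20x thresholds when a locus is absent from all
    controls."""
    vaf = control_obs["variant_reads"] / control_obs["depth"]
    means = vaf.groupby([control_obs[c] for c in _LOCUS_COLS]).mean()
    return means.clip(lower=floor)


def _lookup(series: pd.Series, key: tuple, default: float) -> float:
    try:
        return float(series.loc[key])
    except KeyError:
        return default


def quantify_timepoint(
    cfdna_obs: pd.DataFrame,
    other_timepoint_obs: pd.DataFrame | None,
    wbc_obs: pd.DataFrame | None,
    control_obs: pd.DataFrame,
    cnv_segments: pd.DataFrame,
    cfdna_conc_ng_per_ml: float,
    control_floor: float = DEFAULT_CONTROL_FLOOR,
) -> CtdnaQuant:
    """Quantify ctDNA for one timepoint of one patient.

    Somatic calls must pass the independent thresholds (>= 5 reads,
    VAF > 0.1%) plus the control-panel (20x) and matched-WBC (3x) checks
    that stand in for upstream somatic filtering; variants failing the
    independent thresholds but detected at the other timepoint may be
    rescued by dependent calling (>= 3 reads, same 20x / 3x checks).
    Tumor fraction comes from the highest-VAF call outside gain regions
    (LOH-corrected in losses) or from germline MAF in a called loss,
    with exact binomial uncertainty propagated to copies/mL.
    """
    ctrl = control_mean_vafs(control_obs, floor=control_floor)
    wbc = None
    if wbc_obs is not None and len(wbc_obs):
        wv = wbc_obs["variant_reads"] / wbc_obs["depth"]
        wbc = wv.groupby([wbc_obs[c] for c in _LOCUS_COLS]).mean()

    other_keys: set[tuple] = set()
    if other_timepoint_obs is not None and len(other_timepoint_obs):
        detected = filter_independent_variants(other_timepoint_obs)
        other_keys = set(map(tuple, detected[_LOCUS_COLS].itertuples(index=False)))

    calls = []
    obs = cfdna_obs[cfdna_obs["depth"] > 0]
    for _, r in obs.iterrows():
        key = (r["chrom"], r["pos"], r["ref"], r["alt"])
        vaf = r["variant_reads"] / r["depth"]
        ctrl_mean = _lookup(ctrl, key, control_floor)
        wbc_vaf = _lookup(wbc, key, 0.0) if wbc is not None else None
        germline_ok = vaf >= CONTROL_FOLD * ctrl_mean and (
            wbc_vaf is None or vaf >= WBC_FOLD * wbc_vaf
        )
        independent = (
            r["variant_reads"] >= MIN_READS_INDEPENDENT and vaf > MIN_VAF_INDEPENDENT
        )
        dependent = key in other_keys and dependent_call(
            int(r["variant_reads"]), vaf, [ctrl_mean], wbc_vaf,
            control_floor=control_floor,
        )
        if (independent and germline_ok) or dependent:
            calls.append({**r.to_dict(), "vaf": vaf})
    called = pd.DataFrame(calls)

    cnv = classify_cnv_segments(cnv_segments) if len(cnv_segments) else cnv_segments
    germline_mafs = (
        cnv.loc[cnv["call"] == "loss", "maf"].tolist() if len(cnv) else []
    )
    tf, source = estimate_tumor_fraction(called, cnv, germline_mafs)
    detectable = len(called) > 0

    if source == "somatic_vaf":
        best = called.loc[called["vaf"].idxmax()]
        region = "neutral"
        if len(cnv) and "region_id" in called.columns:
            m = dict(zip(cnv["region_id"], cnv["call"]))
            region = m.get(best.get("region_id"), "neutral")
        tf_lo, tf_hi, cp_lo, cp_hi = quant_uncertainty(
            int(best["variant_reads"]), int(best["depth"]),
            cfdna_conc_ng_per_ml, region_call=region,
        )
    else:
        # germline-MAF route and undetectable samples carry no read-level
        # binomial interval; report a degenerate one
        tf_lo = tf_hi = tf
        cp_lo = cp_hi = to_copies_per_ml(tf, cfdna_conc_ng_per_ml)

    return CtdnaQuant(
        tumor_fraction=tf,
        tf_lower=min(tf_lo, tf),
        tf_upper=max(tf_hi, tf),
        cfdna_conc_ng_per_ml=cfdna_conc_ng_per_ml,
        copies_per_ml=to_copies_per_ml(tf, cfdna_conc_ng_per_ml),
        copies_lower=min(cp_lo, to_copies_per_ml(tf, cfdna_conc_ng_per_ml)),
        copies_upper=max(cp_hi, to_copies_per_ml(tf, cfdna_conc_ng_per_ml)),
        detectable=detectable,
        source=source,
    )


def quantify_cohort(assay) -> pd.DataFrame:
    """Run per-patient quantification and dichotomization over a cohort
    assay (a :class:`mmresp.synthetic.CtdnaAssay` or anything with the
    same tables). Returns one row per patient with copies/mL at both
    timepoints, the ratio, category, and predicted label."""
    variants = assay.variants
    conc = assay.cfdna_conc.set_index(["patient_id", "timepoint"])[
        "cfdna_conc_ng_per_ml"
    ]
    rows = []
    for pid, pv in variants.groupby("patient_id", sort=False):
        roles = {role: df for role, df in pv.groupby("sample_role")}
        cnv_pat = assay.cnv[assay.cnv["patient_id"] == pid]
        quants = {}
        for tp, role, other in (
            ("BL", "cfdna_bl", "cfdna_ot"),
            ("OT", "cfdna_ot", "cfdna_bl"),
        ):
            quants[tp] = quantify_timepoint(
                roles.get(role, pv.iloc[0:0]),
                roles.get(other),
                roles.get("wbc"),
                roles.get("control", pv.iloc[0:0]),
                cnv_pat[cnv_pat["timepoint"] == tp],
                float(conc.loc[(pid, tp)]),
            )
        dyn = dichotomize_dynamics(quants["BL"], quants["OT"])
        rows.append(
            {
                "patient_id": pid,
                "tf_bl": quants["BL"].tumor_fraction,
                "tf_ot": quants["OT"].tumor_fraction,
                "copies_bl": quants["BL"].copies_per_ml,
                "copies_ot": quants["OT"].copies_per_ml,
                "detectable_bl": quants["BL"].detectable,
                "detectable_ot": quants["OT"].detectable,
                "ratio": dyn.ratio,
                "category": dyn.category,
                "ctdna_label": dyn.predicted_label,
            }
        )
    return pd.DataFrame(rows)
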