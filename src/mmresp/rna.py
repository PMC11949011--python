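"""Whole-blood RNA-seq analysis: filtering, normalization, differential
expression, set intersection, enrichment, and signature scoring.

The differential-expression machinery is a moderated t pipeline: per-gene
statistics with empirical-Bayes variance shrinkage, where the prior degrees
of freedom and prior variance are fit by method of moments on the log
sample variances, followed by Benjamini-Hochberg adjustment. Three
contrasts cover the study design: paired BL vs OT within the
clinical-benefit group, paired BL vs OT within the no-benefit group, and
unpaired CB vs N-CB at the on-treatment timepoint.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "cpm",
    "filter_genes",
    "transform_counts",
    "tmm_factors",
    "normalized_log_expression",
    "paired_dea",
    "group_dea",
    "deg_set",
    "intersect_deg_sets",
    "signature_score",
    "enrich_hypergeometric",
    "read_gmt",
]

DEG_ADJ_P = 0.05


def cpm(counts: pd.DataFrame, lib_sizes: pd.Series | None = None) -> pd.DataFrame:
    """Counts per million; library sizes default to column sums."""
    lib = counts.sum(axis=0) if lib_sizes is None else lib_sizes
    if (lib <= 0).any():
        bad = lib.index[lib <= 0].tolist()
        raise ValueError(f"zero library size for sample(s): {bad}")
    return counts.div(lib, axis=1) * 1e6


def filter_genes(
    counts: pd.DataFrame, groups: pd.Series | None = None, cv_cutoff: float = 100.0
) -> tuple[pd.DataFrame, dict]:
    """Expression filter: drop genes with CPM < 1 in every sample, then
    genes whose percent coefficient of variation of CPM exceeds
    ``cv_cutoff`` in every condition group (all samples as one group when
    ``groups`` is None). Returns (filtered counts, removal report)."""
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples to filter")
    x = cpm(counts)
    low = (x < 1.0).all(axis=1)
    kept = counts[~low]
    xk = x[~low]

    if groups is None:
        groups = pd.Series("all", index=counts.columns)
    groups = groups.reindex(xk.columns)
    noisy = pd.Series(True, index=xk.index)
    for _, cols in groups.groupby(groups).groups.items():
        sub = xk[list(cols)]
        mean = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=1)
        cv = np.where(mean > 0, 100.0 * sd / mean, np.inf)
        noisy &= pd.Series(cv, index=xk.index) > cv_cutoff
    report = {
        "n_input": counts.shape[0],
        "removed_low_cpm": int(low.sum()),
        "removed_high_cv": int(noisy.sum()),
        "n_kept": int((~noisy).sum()),
    }
    return kept[~noisy], report


def transform_counts(
    counts: pd.DataFrame, lib_sizes: pd.Series | None = None
) -> pd.DataFrame:
    """Stabilized expression values: log2(CPM + 0.5). Monotone in counts
    and finite everywhere, including zeros."""
    return np.log2(cpm(counts, lib_sizes) + 0.5)


def tmm_factors(
    counts: pd.DataFrame, trim_m: float = 0.3, trim_a: float = 0.05
) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors.

    The reference sample is the one whose upper-quartile CPM is closest to
    the mean upper-quartile. Per sample, genes expressed in both sample
    and reference contribute an M-value (log2 ratio of library-normalized
    proportions) and an A-value (average log2 abundance); after trimming
    the most extreme 30% of M and 5% of A, the factor is 2 to the
    precision-weighted mean M. Factors are rescaled to multiply to 1.
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples for TMM")
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("sample with all-zero counts")
    uq = cpm(counts).quantile(0.75, axis=0)
    ref_name = (uq - uq.mean()).abs().idxmin()
    ref = counts[ref_name].to_numpy(float)
    nref = lib[ref_name]

    factors = {}
    for s in counts.columns:
        obs = counts[s].to_numpy(float)
        nobs = lib[s]
        ok = (obs > 0) & (ref > 0)
        if s == ref_name or ok.sum() == 0:
            factors[s] = 1.0
            continue
        o, r = obs[ok], ref[ok]
        m = np.log2((o / nobs) / (r / nref))
        a = 0.5 * np.log2((o / nobs) * (r / nref))
        w = 1.0 / ((nobs - o) / (nobs * o) + (nref - r) / (nref * r))
        lo_m, hi_m = np.quantile(m, [trim_m, 1.0 - trim_m])
        lo_a, hi_a = np.quantile(a, [trim_a, 1.0 - trim_a])
        keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        if keep.sum() == 0 or not np.isfinite(m[keep]).any():
            factors[s] = 1.0
            continue
        factors[s] = 2.0 ** (np.average(m[keep], weights=w[keep]))
    f = pd.Series(factors).reindex(counts.columns)
    return f / np.exp(np.log(f).mean())  # geometric-mean rescale: product 1


def normalized_log_expression(counts: pd.DataFrame) -> pd.DataFrame:
    """log2(CPM + 0.5) on TMM-adjusted effective library sizes."""
    lib = counts.sum(axis=0) * tmm_factors(counts)
    return transform_counts(counts, lib_sizes=lib)


def _trigamma_inverse(x: float) -> float:
    """Invert the trigamma function by Newton iteration (used to fit the
    prior degrees of freedom from the spread of log sample variances)."""
    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-8 * y:
            break
    return float(y)


def _eb_shrink(s2: np.ndarray, df: float) -> tuple[np.ndarray, float, float]:
    """Empirical-Bayes variance shrinkage by method of moments on log
    sample variances. Returns (posterior variances, d0, s0_squared)."""
    s2 = np.asarray(s2, float)
    pos = s2[s2 > 0]
    if pos.size < 2:
        return s2.copy(), np.inf, float(pos.mean()) if pos.size else 0.0
    z = np.log(pos)
    e_z = z.mean()
    var_z = z.var(ddof=1)
    resid = var_z - special.polygamma(1, df / 2.0)
    if resid > 0:
        d0 = 2.0 * _trigamma_inverse(resid)
        log_s0 = e_z - special.polygamma(0, df / 2.0) + np.log(df / 2.0)
        log_s0 += special.polygamma(0, d0 / 2.0) - np.log(d0 / 2.0)
        s0 = np.exp(log_s0)
    else:  # variances more concentrated than chi-square: infinite prior df
        d0 = np.inf
        s0 = np.exp(e_z - special.polygamma(0, df / 2.0) + np.log(df / 2.0))
    if np.isinf(d0):
        post = np.full_like(s2, s0)
    else:
        post = (d0 * s0 + df * s2) / (d0 + df)
    return post, float(d0), float(s0)


def _moderated_result(
    genes, effect: np.ndarray, s2: np.ndarray, df: float, n_eff: float
) -> pd.DataFrame:
    post, d0, _ = _eb_shrink(s2, df)
    se = np.sqrt(post / n_eff)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, effect / se, 0.0)
    total_df = df + d0 if np.isfinite(d0) else np.inf
    if np.isinf(total_df):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), total_df)
    adj = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "gene": genes,
            "log2fc": effect,
            "p_value": p,
            "adj_p": adj,
            "direction": np.where(effect >= 0, "up", "down"),
        }
    )
    return out.sort_values("p_value", kind="mergesort").reset_index(drop=True)


def paired_dea(
    expr: pd.DataFrame, samples: pd.DataFrame, group: str
) -> pd.DataFrame:
    """Paired BL vs OT differential expression within one clinical group.

    ``expr`` is the normalized log2 expression matrix (genes x samples);
    ``samples`` carries sample_id, patient_id, timepoint, group. Per gene,
    OT - BL paired differences feed a moderated paired t statistic.
    """
    meta = samples[samples["group"] == group]
    piv = meta.pivot(index="patient_id", columns="timepoint", values="sample_id")
    piv = piv.dropna()
    if len(piv) < 3:
        raise ValueError(f"need >= 3 complete pairs in group {group}, got {len(piv)}")
    d = expr[piv["OT"]].to_numpy() - expr[piv["BL"]].to_numpy()
    n = d.shape[1]
    mean = d.mean(axis=1)
    s2 = d.var(axis=1, ddof=1)
    return _moderated_result(expr.index.to_numpy(), mean, s2, n - 1.0, float(n))


def group_dea(
    expr: pd.DataFrame,
    samples: pd.DataFrame,
    timepoint: str = "OT",
    groups: tuple[str, str] = ("CB", "N-CB"),
) -> pd.DataFrame:
    """Unpaired CB vs N-CB differential expression at one timepoint, by
    two-sample moderated t with pooled variance."""
    a_ids = samples.loc[
        (samples["timepoint"] == timepoint) & (samples["group"] == groups[0]),
        "sample_id",
    ]
    b_ids = samples.loc[
        (samples["timepoint"] == timepoint) & (samples["group"] == groups[1]),
        "sample_id",
    ]
    na, nb = len(a_ids), len(b_ids)
    if na < 3 or nb < 3:
        raise ValueError(f"need >= 3 samples per group, got {na} and {nb}")
    a = expr[list(a_ids)].to_numpy()
    b = expr[list(b_ids)].to_numpy()
    effect = a.mean(axis=1) - b.mean(axis=1)
    s2 = (
        a.var(axis=1, ddof=1) * (na - 1) + b.var(axis=1, ddof=1) * (nb - 1)
    ) / (na + nb - 2)
    n_eff = 1.0 / (1.0 / na + 1.0 / nb)
    return _moderated_result(
        expr.index.to_numpy(), effect, s2, float(na + nb - 2), n_eff
    )


def deg_set(dea: pd.DataFrame, adj_p: float = DEG_ADJ_P) -> set[str]:
    """Differentially expressed genes at the BH-adjusted threshold."""
    return set(dea.loc[dea["adj_p"] <= adj_p, "gene"])


def intersect_deg_sets(
    deg_cb: set[str],
    deg_ncb: set[str],
    deg_ot: set[str],
    exclude_ncb: bool = True,
) -> dict:
    """All 7 Venn regions of the three DEG sets plus the exported
    signature set: the CB-longitudinal / OT-group intersection, by default
    excluding genes also moved in the N-CB group."""
    a, b, c = set(deg_cb), set(deg_ncb), set(deg_ot)
    regions = {
        "cb_only": a - b - c,
        "ncb_only": b - a - c,
        "ot_only": c - a - b,
        "cb_ncb_only": (a & b) - c,
        "cb_ot_only": (a & c) - b,
        "ncb_ot_only": (b & c) - a,
        "all_three": a & b & c,
    }
    signature = (a & c) - b if exclude_ncb else (a & c)
    return {
        "counts": {k: len(v) for k, v in regions.items()},
        "regions": regions,
        "signature_set": signature,
    }


def signature_score(
    expr: pd.DataFrame,
    samples: pd.DataFrame,
    gene_set,
    timepoint: str = "OT",
) -> tuple[pd.DataFrame, float]:
    """Per-patient mean normalized expression over a gene set at one
    timepoint, with a rank-sum test of the CB vs N-CB score difference.

    Returns (scores frame with patient_id/group/score, Wilcoxon p)."""
    gene_set = list(gene_set)
    if not gene_set:
        raise ValueError("empty gene set")
    missing = [g for g in gene_set if g not in expr.index]
    if missing:
        raise ValueError(f"genes absent from expression matrix: {missing[:5]}")
    meta = samples[samples["timepoint"] == timepoint]
    score = expr.loc[gene_set, meta["sample_id"]].mean(axis=0)
    out = pd.DataFrame(
        {
            "patient_id": meta["patient_id"].to_numpy(),
            "group": meta["group"].to_numpy(),
            "score": score.to_numpy(),
        }
    )
    a = out.loc[out["group"] == "CB", "score"]
    b = out.loc[out["group"] == "N-CB", "score"]
    if len(a) and len(b):
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    else:
        p = np.nan
    return out, p


def enrich_hypergeometric(
    deg_set, gene_universe, pathway_sets: dict[str, set]
) -> pd.DataFrame:
    """Over-representation analysis: one-sided hypergeometric upper-tail p
    per pathway, BH-adjusted across pathways; enriched at adj_p <= 0.05."""
    universe = set(gene_universe)
    if not universe:
        raise ValueError("empty gene universe")
    hits = set(deg_set) & universe
    m = len(universe)
    n_hits = len(hits)
    rows = []
    for name, members in pathway_sets.items():
        path = set(members) & universe
        k = len(path & hits)
        # P(X >= k) for X ~ Hypergeom(M=m, n=len(path), N=n_hits)
        p = float(stats.hypergeom.sf(k - 1, m, len(path), n_hits))
        rows.append(
            {"pathway": name, "set_size": len(path), "overlap": k, "p_value": p}
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["adj_p"] = multipletests(out["p_value"], method="fdr_bh")[1]
        out["enriched"] = out["adj_p"] <= 0.05
        out = out.sort_values("p_value", kind="mergesort").reset_index(drop=True)
    return out


def read_gmt(path: str | Path) -> dict[str, set]:
    """Read gene sets from a GMT file (name, description, members...)."""
    sets: dict[str, set] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        sets[parts[0]] = set(parts[2:])
    return sets
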