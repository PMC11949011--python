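"""Multimodal arbitration between the ctDNA ratio and the RNA classifier.

Each patient carries two standalone predictions: the dichotomized ctDNA
copies/mL ratio (cutoff 1) and the RNA model probability (cutoff 0.55).
Around each cutoff sits an uncertainty band; a value inside its band is
considered unreliable and the other modality's call is used instead. The
precedence rule: ctDNA is the base prediction, adjusted by RNA when the
ratio is in its band; when the RNA probability is in its band the ctDNA
call stands; when both are in their bands the RNA call is prioritized.
Band widths are tuned by grid search on the test cohort against the gain
in sensitivity plus specificity over the standalone RNA model, then frozen
before touching the validation cohort.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from mmresp.survival import confusion_metrics

__all__ = [
    "DEFAULT_CT_GRID",
    "DEFAULT_RNA_GRID",
    "MultimodalConfig",
    "arbitrate",
    "arbitrate_frame",
    "grid_search_bands",
    "apply_multimodal",
]

DEFAULT_CT_GRID = (0.0, 0.25, 0.5, 0.75, 1.0)
DEFAULT_RNA_GRID = (0.0, 0.05, 0.10, 0.15, 0.20)
PROB_CUTOFF = 0.55


@dataclass
class MultimodalConfig:
    """Uncertainty-band half-widths.

    ratio_band_halfwidth d_ct: the ctDNA band is [2^-d, 2^d] around
    ratio 1, symmetric on the log2 scale. prob_band_halfwidth d_rna: the
    RNA band is [0.55 - d, 0.55 + d]. Bands are closed intervals.
    """

    ratio_band_halfwidth: float = 0.0
    prob_band_halfwidth: float = 0.0
    prob_cutoff: float = PROB_CUTOFF

    def __post_init__(self):
        if self.ratio_band_halfwidth < 0:
            raise ValueError("ratio_band_halfwidth must be nonnegative")
        if not 0 <= self.prob_band_halfwidth <= self.prob_cutoff:
            raise ValueError("prob_band_halfwidth must lie in [0, cutoff]")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "ratio_band_halfwidth": self.ratio_band_halfwidth,
                    "prob_band_halfwidth": self.prob_band_halfwidth,
                    "prob_cutoff": self.prob_cutoff,
                },
                indent=1,
            )
        )


def _in_ct_band(ratio: float, d: float) -> bool:
    if ratio is None or not np.isfinite(ratio) or ratio <= 0:
        # undetectable-both (ratio 0) and BL-zero increases (+inf) are
        # unambiguous calls, never in the uncertainty band
        return False
    return 2.0 ** (-d) <= ratio <= 2.0**d


def _in_rna_band(prob: float, d: float, cutoff: float) -> bool:
    return cutoff - d <= prob <= cutoff + d


def arbitrate(
    ratio: float | None,
    rna_prob: float | None,
    rna_label: str | None,
    ctdna_label: str | None,
    config: MultimodalConfig,
) -> str:
    """Arbitrated label for one patient.

    (i) ratio in ct band, probability not in RNA band -> RNA label;
    (ii) probability in RNA band, ratio not in ct band -> ctDNA label;
    (iii) both in bands -> RNA label; (iv) neither in band -> ctDNA label.
    A missing modality falls back to the other modality's label.
    """
    ct_missing = ctdna_label is None or ratio is None or (
        isinstance(ratio, float) and np.isnan(ratio)
    )
    rna_missing = rna_label is None or rna_prob is None or (
        isinstance(rna_prob, float) and np.isnan(rna_prob)
    )
    if ct_missing and rna_missing:
        raise ValueError("both modalities missing")
    if ct_missing:
        return rna_label
    if rna_missing:
        return ctdna_label
    ct_band = _in_ct_band(float(ratio), config.ratio_band_halfwidth)
    rna_band = _in_rna_band(
        float(rna_prob), config.prob_band_halfwidth, config.prob_cutoff
    )
    if ct_band:
        return rna_label  # rules (i) and (iii): RNA prioritized
    if rna_band:
        return ctdna_label  # rule (ii)
    return ctdna_label  # rule (iv): ctDNA is the base prediction


def arbitrate_frame(predictions: pd.DataFrame, config: MultimodalConfig) -> np.ndarray:
    """Vectorized arbitration over a predictions frame with columns
    ratio, rna_prob, rna_label, ctdna_label."""
    return np.array(
        [
            arbitrate(r.ratio, r.rna_prob, r.rna_label, r.ctdna_label, config)
            for r in predictions.itertuples()
        ]
    )


def _sn_sp(labels, truth) -> tuple[float, float]:
    perf = confusion_metrics(labels, truth)
    return perf.sensitivity, perf.specificity


def grid_search_bands(
    predictions: pd.DataFrame,
    truth,
    ct_grid=DEFAULT_CT_GRID,
    rna_grid=DEFAULT_RNA_GRID,
) -> tuple[MultimodalConfig, pd.DataFrame]:
    """Tune band widths on the test cohort.

    Every (d_ct, d_rna) pair is scored by (SN + SP of the multimodal
    labels) minus (SN + SP of the standalone RNA labels), with N-CB as
    the positive class. The winner maximizes this objective; ties prefer
    the smaller d_ct + d_rna, then the smaller d_ct. Returns the chosen
    config and the full grid report.
    """
    ct_grid = list(ct_grid)
    rna_grid = list(rna_grid)
    if not ct_grid or not rna_grid:
        raise ValueError("empty band grid")
    truth = np.asarray(truth)
    truth_lab = np.where(truth.astype(bool), "CB", "N-CB") if truth.dtype == bool else truth
    rna_sn, rna_sp = _sn_sp(predictions["rna_label"].to_numpy(), truth_lab)
    rows = []
    for d_ct in ct_grid:
        for d_rna in rna_grid:
            cfg = MultimodalConfig(d_ct, d_rna)
            labels = arbitrate_frame(predictions, cfg)
            sn, sp = _sn_sp(labels, truth_lab)
            rows.append(
                {
                    "d_ct": d_ct,
                    "d_rna": d_rna,
                    "sensitivity": sn,
                    "specificity": sp,
                    "objective": (sn + sp) - (rna_sn + rna_sp),
                }
            )
    report = pd.DataFrame(rows)
    # tie-breaking: max objective, then min d_ct + d_rna, then min d_ct
    report["_width"] = report["d_ct"] + report["d_rna"]
    best = report.sort_values(
        by=["objective", "_width", "d_ct"],
        ascending=[False, True, True],
        kind="mergesort",
    ).iloc[0]
    report = report.drop(columns="_width")
    return MultimodalConfig(float(best["d_ct"]), float(best["d_rna"])), report


def apply_multimodal(
    config: MultimodalConfig, predictions: pd.DataFrame, truth=None
) -> tuple[np.ndarray, "object | None"]:
    """Apply a frozen config to a cohort's predictions.

    Returns (labels, PerformanceSummary or None when truth is withheld).
    """
    labels = arbitrate_frame(predictions, config)
    perf = None
    if truth is not None:
        truth = np.asarray(truth)
        truth_lab = (
            np.where(truth, "CB", "N-CB") if truth.dtype == bool else truth
        )
        perf = confusion_metrics(labels, truth_lab)
    return labels, perf
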