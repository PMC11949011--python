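#!/usr/bin/env python
"""Tune and validate the multimodal (ctDNA + RNA) arbitration model.

Combines the ctDNA ratio predictions (02) with the RNA model
probabilities (04) on the test cohort, grid-searches the uncertainty-band
widths against the gain over the standalone RNA model, then applies the
frozen bands to the validation cohort and compares all three approaches.
Outputs under results/multimodal/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from mmresp import multimodal, survival

BASE = Path(__file__).resolve().parents[1] / "results"


def _predictions(cohort: str) -> tuple[pd.DataFrame, np.ndarray]:
    rna_preds = pd.read_csv(
        BASE / "rna_model" / f"predictions_{cohort}.tsv", sep="\t"
    )
    ct = pd.read_csv(BASE / "ctdna" / "ctdna_quant.tsv", sep="\t").set_index(
        "patient_id"
    )
    common = [p for p in rna_preds["patient_id"] if p in ct.index]
    rna_preds = rna_preds.set_index("patient_id").loc[common]
    preds = pd.DataFrame(
        {
            "patient_id": common,
            "ratio": ct.loc[common, "ratio"].to_numpy(),
            "ctdna_label": ct.loc[common, "ctdna_label"].to_numpy(),
            "rna_prob": rna_preds["rna_prob"].to_numpy(),
            "rna_label": rna_preds["rna_label"].to_numpy(),
        }
    )
    truth = np.where(ct.loc[common, "cb"], "CB", "N-CB")
    return preds, truth


def main() -> None:
    out = BASE / "multimodal"
    out.mkdir(parents=True, exist_ok=True)

    preds_test, truth_test = _predictions("test")
    discordant = (preds_test["rna_label"] != preds_test["ctdna_label"]).sum()
    print(f"test cohort: {discordant}/{len(preds_test)} discordant predictions")

    cfg, report = multimodal.grid_search_bands(preds_test, truth_test)
    report.to_csv(out / "band_grid.tsv", sep="\t", index=False)
    cfg.to_json(out / "multimodal_config.json")
    print(
        f"tuned bands: ratio half-width {cfg.ratio_band_halfwidth} (log2), "
        f"probability half-width {cfg.prob_band_halfwidth}"
    )

    for cohort in ("test", "validation"):
        preds, truth = _predictions(cohort)
        labels, perf = multimodal.apply_multimodal(cfg, preds, truth)
        rna_perf = survival.confusion_metrics(preds["rna_label"], truth)
        ct_perf = survival.confusion_metrics(preds["ctdna_label"], truth)
        print(
            f"{cohort}: multimodal SN {perf.sensitivity:.2f} / SP "
            f"{perf.specificity:.2f} | RNA {rna_perf.sensitivity:.2f}/"
            f"{rna_perf.specificity:.2f} | ctDNA {ct_perf.sensitivity:.2f}/"
            f"{ct_perf.specificity:.2f} (n={len(preds)})"
        )
        preds["multimodal_label"] = labels
        preds.to_csv(out / f"predictions_{cohort}.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
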