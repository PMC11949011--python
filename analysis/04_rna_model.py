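#!/usr/bin/env python
"""Train, select, and validate the sparse-PLS RNA response model.

Candidate genes come from the discovery-cohort longitudinal CB contrast;
features are per-patient OT - BL expression changes. Repeated 3-fold CV
(10 repeats) over feature counts {10, 15, 20} yields candidate models,
the test cohort picks the winner by AUC + PFS-separation rank, and the
frozen model is evaluated once on the validation cohort.
Outputs under results/rna_model/.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from mmresp import classifier, pipeline, rna, survival

BASE = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main() -> None:
    cohort_dir = BASE / "cohort"
    out = BASE / "rna_model"
    out.mkdir(parents=True, exist_ok=True)

    patients = pd.read_csv(cohort_dir / "patients.tsv", sep="\t").set_index("patient_id")
    counts = pd.read_csv(cohort_dir / "counts.tsv", sep="\t", index_col=0)
    samples = pd.read_csv(cohort_dir / "samples.tsv", sep="\t")
    filtered, _ = rna.filter_genes(
        counts, groups=samples.set_index("sample_id")["group"]
    )
    expr = rna.normalized_log_expression(filtered)

    disc_meta = samples[samples["cohort"] == "discovery"]
    dea = rna.paired_dea(expr, disc_meta, group="CB")
    degs = sorted(rna.deg_set(dea))
    if len(degs) < 30:
        degs = dea["gene"].head(30).tolist()
    print(f"candidate genes from discovery DEA: {len(degs)}")

    X_disc, _ = pipeline.build_change_features(expr, samples, degs, "discovery")
    y_disc = patients.loc[X_disc.index, "cb"].to_numpy()
    plan = classifier.CvPlan(seed=SEED)
    cv = classifier.cross_validate(X_disc, y_disc, plan)
    cv.auc_table.to_csv(out / "cv_auc.tsv", sep="\t", index=False)
    print(cv.auc_table.groupby("k")["cv_auc"].median().rename("median CV AUC"))

    X_test, _ = pipeline.build_change_features(expr, samples, degs, "test")
    info = patients.loc[X_test.index]
    model, selection = classifier.select_best_model(
        cv.candidates, X_test, info["cb"].to_numpy(),
        info["pfs_months"].to_numpy(), info["event"].to_numpy(),
    )
    selection.to_csv(out / "model_selection.tsv", sep="\t", index=False)
    model.to_json(out / "rna_model.json")
    print(f"selected k = {len(model.selected_genes)} genes: {model.selected_genes}")

    for cohort in ("test", "validation"):
        X, _ = pipeline.build_change_features(expr, samples, degs, cohort)
        info = patients.loc[X.index]
        proba = classifier.predict_proba(model, X)
        labels = classifier.classify(model, X)
        truth = np.where(info["cb"], "CB", "N-CB")
        perf = survival.confusion_metrics(labels, truth)
        auc, _ = survival.roc_auc(1.0 - proba, truth == "N-CB", positive=True)
        print(
            f"{cohort}: AUC {auc:.2f}, SN {perf.sensitivity:.2f} / "
            f"SP {perf.specificity:.2f} (n={len(X)})"
        )
        pd.DataFrame(
            {"patient_id": X.index, "rna_prob": proba, "rna_label": labels}
        ).to_csv(out / f"predictions_{cohort}.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
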