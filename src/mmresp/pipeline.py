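"""End-to-end orchestration with strict cohort separation.

Discovery trains; the test cohort selects the RNA model and tunes the
multimodal bands; the validation cohort is evaluated once, with frozen
cutoffs. Validation truth is wrapped in a sealed container that raises
until the evaluation stage explicitly unseals it, so no tuning stage can
read it even by accident.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from mmresp import classifier, ctdna, multimodal, rna, survival, synthetic

__all__ = [
    "LeakageError",
    "SealedLabels",
    "RunConfig",
    "RunResult",
    "build_change_features",
    "run_pipeline",
]


class LeakageError(RuntimeError):
    """Raised when a tuning stage touches frozen validation truth."""


class SealedLabels:
    """Truth labels that cannot be read until unsealed."""

    def __init__(self, values):
        self._values = np.asarray(values)
        self._sealed = True

    def unseal(self, stage: str) -> np.ndarray:
        if stage != "final_evaluation":
            raise LeakageError(
                f"stage {stage!r} attempted to read sealed validation truth"
            )
        self._sealed = False
        return self._values

    @property
    def values(self) -> np.ndarray:
        if self._sealed:
            raise LeakageError("validation truth is sealed until final evaluation")
        return self._values

    def __len__(self) -> int:
        return len(self._values)


@dataclass
class RunConfig:
    """Everything a run needs; study-fixed thresholds are defaults and are
    echoed into the run manifest."""

    sim: synthetic.SimConfig = field(default_factory=synthetic.SimConfig)
    cohort_sizes: tuple[int, int, int] = (29, 29, 21)
    exact_n_cb: int | None = 42
    seed: int = 0
    feature_grid: tuple[int, ...] = (10, 15, 20)
    n_cv_repeats: int = 10
    n_cv_folds: int = 3
    prob_cutoff: float = classifier.DEFAULT_CUTOFF
    ct_band_grid: tuple[float, ...] = multimodal.DEFAULT_CT_GRID
    rna_band_grid: tuple[float, ...] = multimodal.DEFAULT_RNA_GRID
    deg_adj_p: float = rna.DEG_ADJ_P
    min_candidate_features: int = 30
    run_rna: bool = True
    outdir: str | None = None


@dataclass
class RunResult:
    patients: pd.DataFrame
    ctdna_table: pd.DataFrame
    dea_cb: pd.DataFrame | None
    rna_model: classifier.SplsModel | None
    selection_report: pd.DataFrame | None
    mm_config: multimodal.MultimodalConfig | None
    grid_report: pd.DataFrame | None
    metrics: dict
    manifest: dict


def _child_seed(seed: int, stage: int) -> int:
    """Deterministic per-stage child seeds below 2**31."""
    ss = np.random.SeedSequence(seed).spawn(stage + 1)[stage]
    return int(ss.generate_state(1)[0] % (2**31))


def build_change_features(
    expr: pd.DataFrame, samples: pd.DataFrame, genes, cohort: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-patient OT - BL expression change of candidate genes for one
    cohort. Returns (patients x genes feature frame indexed by patient_id,
    the cohort's sample metadata)."""
    meta = samples[samples["cohort"] == cohort]
    piv = meta.pivot(index="patient_id", columns="timepoint", values="sample_id").dropna()
    genes = [g for g in genes if g in expr.index]
    delta = (
        expr.loc[genes, piv["OT"]].to_numpy() - expr.loc[genes, piv["BL"]].to_numpy()
    )
    X = pd.DataFrame(delta.T, index=piv.index, columns=genes)
    return X, meta


def _stratify(patients: pd.DataFrame, labels: np.ndarray, ids) -> dict:
    sub = patients.set_index("patient_id").loc[list(ids)]
    groups = {}
    for lab in ("CB", "N-CB"):
        mask = labels == lab
        groups[lab] = sub[mask]
    if all(len(g) for g in groups.values()):
        fit = survival.logrank_test(
            groups["CB"]["pfs_months"], groups["CB"]["event"],
            groups["N-CB"]["pfs_months"], groups["N-CB"]["event"],
        )
        return {
            "median_pfs_pred_cb": fit.median_pfs["A"],
            "median_pfs_pred_ncb": fit.median_pfs["B"],
            "logrank_p": fit.p_value,
            "hazard_ratio": fit.hazard_ratio,
        }
    return {"logrank_p": np.nan, "hazard_ratio": np.nan}


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the full analysis on a synthetic cohort.

    Stages: simulate -> ctDNA quantification and dichotomization -> RNA
    DEA on discovery -> sparse-PLS cross-validation and candidate fitting
    -> model selection on the test cohort -> multimodal band tuning on the
    test cohort -> frozen evaluation on the validation cohort.
    """
    sim = synthetic.SimConfig(**{**asdict(config.sim), "seed": _child_seed(config.seed, 0)})
    patients = synthetic.simulate_cohort(
        sim, cohort_sizes=config.cohort_sizes, exact_n_cb=config.exact_n_cb
    )
    assay = synthetic.simulate_ctdna_assay(patients, sim)

    ct = ctdna.quantify_cohort(assay)
    ct = ct.merge(patients[["patient_id", "cohort", "cb"]], on="patient_id")
    truth_lab = np.where(ct["cb"], "CB", "N-CB")
    ct_perf = survival.confusion_metrics(ct["ctdna_label"], truth_lab)

    metrics: dict = {
        "n_patients": len(patients),
        "n_cb": int(patients["cb"].sum()),
        "ctdna": {
            "n": len(ct),
            "n_predicted_ncb": int((ct["ctdna_label"] == "N-CB").sum()),
            "n_undetectable_both": int((ct["category"] == "undetectable_both").sum()),
            "sensitivity": ct_perf.sensitivity,
            "specificity": ct_perf.specificity,
        },
    }

    dea_cb = rna_model = selection = mm_cfg = grid_report = None
    if config.run_rna:
        expr_data = synthetic.simulate_expression(patients, sim)
        counts, _ = rna.filter_genes(
            expr_data.counts,
            groups=expr_data.samples.set_index("sample_id")["group"],
        )
        expr = rna.normalized_log_expression(counts)
        samples = expr_data.samples

        disc = samples[samples["cohort"] == "discovery"]
        dea_cb = rna.paired_dea(expr, disc, group="CB")
        degs = sorted(rna.deg_set(dea_cb, adj_p=config.deg_adj_p))
        if len(degs) < config.min_candidate_features:
            # fall back to the top-ranked genes so the classifier always has
            # a candidate list of workable size
            degs = dea_cb["gene"].head(config.min_candidate_features).tolist()
        metrics["rna"] = {"n_candidate_genes": len(degs)}

        pat_idx = patients.set_index("patient_id")
        X_disc, _ = build_change_features(expr, samples, degs, "discovery")
        y_disc = pat_idx.loc[X_disc.index, "cb"].to_numpy()
        plan = classifier.CvPlan(
            n_repeats=config.n_cv_repeats,
            n_folds=config.n_cv_folds,
            seed=_child_seed(config.seed, 1),
            feature_grid=config.feature_grid,
        )
        cv = classifier.cross_validate(X_disc, y_disc, plan)

        X_test, _ = build_change_features(expr, samples, degs, "test")
        test_info = pat_idx.loc[X_test.index]
        rna_model, selection = classifier.select_best_model(
            cv.candidates,
            X_test,
            test_info["cb"].to_numpy(),
            test_info["pfs_months"].to_numpy(),
            test_info["event"].to_numpy(),
        )
        test_proba = classifier.predict_proba(rna_model, X_test)
        test_labels = classifier.classify(rna_model, X_test)
        test_truth = np.where(test_info["cb"], "CB", "N-CB")
        rna_test_perf = survival.confusion_metrics(test_labels, test_truth)
        # N-CB is the reported positive class; its score is 1 - P(CB)
        rna_test_auc, _ = survival.roc_auc(
            1.0 - test_proba, test_truth == "N-CB", positive=True
        )
        metrics["rna"].update(
            {
                "k": len(rna_model.selected_genes),
                "test_auc": rna_test_auc,
                "test_sensitivity": rna_test_perf.sensitivity,
                "test_specificity": rna_test_perf.specificity,
            }
        )

        # multimodal tuning on the test cohort
        ct_idx = ct.set_index("patient_id")
        common = [p for p in X_test.index if p in ct_idx.index]
        preds_test = pd.DataFrame(
            {
                "patient_id": common,
                "ratio": ct_idx.loc[common, "ratio"].to_numpy(),
                "ctdna_label": ct_idx.loc[common, "ctdna_label"].to_numpy(),
                "rna_prob": pd.Series(test_proba, index=X_test.index).loc[common].to_numpy(),
                "rna_label": pd.Series(test_labels, index=X_test.index).loc[common].to_numpy(),
            }
        )
        mm_cfg, grid_report = multimodal.grid_search_bands(
            preds_test,
            np.where(pat_idx.loc[common, "cb"], "CB", "N-CB"),
            ct_grid=config.ct_band_grid,
            rna_grid=config.rna_band_grid,
        )
        mm_test_labels, mm_test_perf = multimodal.apply_multimodal(
            mm_cfg, preds_test, np.where(pat_idx.loc[common, "cb"], "CB", "N-CB")
        )
        metrics["multimodal"] = {
            "d_ct": mm_cfg.ratio_band_halfwidth,
            "d_rna": mm_cfg.prob_band_halfwidth,
            "test_sensitivity": mm_test_perf.sensitivity,
            "test_specificity": mm_test_perf.specificity,
        }

        # frozen validation evaluation: truth sealed until this stage
        X_val, _ = build_change_features(expr, samples, degs, "validation")
        val_truth = SealedLabels(
            np.where(pat_idx.loc[X_val.index, "cb"], "CB", "N-CB")
        )
        val_proba = classifier.predict_proba(rna_model, X_val)
        val_labels = classifier.classify(rna_model, X_val)
        common_v = [p for p in X_val.index if p in ct_idx.index]
        preds_val = pd.DataFrame(
            {
                "patient_id": common_v,
                "ratio": ct_idx.loc[common_v, "ratio"].to_numpy(),
                "ctdna_label": ct_idx.loc[common_v, "ctdna_label"].to_numpy(),
                "rna_prob": pd.Series(val_proba, index=X_val.index).loc[common_v].to_numpy(),
                "rna_label": pd.Series(val_labels, index=X_val.index).loc[common_v].to_numpy(),
            }
        )
        mm_val_labels = multimodal.arbitrate_frame(preds_val, mm_cfg)

        truth_v = val_truth.unseal("final_evaluation")
        truth_v = pd.Series(truth_v, index=X_val.index).loc[common_v].to_numpy()
        rna_val_perf = survival.confusion_metrics(
            preds_val["rna_label"].to_numpy(), truth_v
        )
        ct_val_perf = survival.confusion_metrics(
            preds_val["ctdna_label"].to_numpy(), truth_v
        )
        mm_val_perf = survival.confusion_metrics(mm_val_labels, truth_v)
        val_auc, _ = survival.roc_auc(
            1.0 - preds_val["rna_prob"].to_numpy(), truth_v == "N-CB", positive=True
        )
        metrics["validation"] = {
            "n": len(common_v),
            "rna_auc": val_auc,
            "rna_sensitivity": rna_val_perf.sensitivity,
            "rna_specificity": rna_val_perf.specificity,
            "ctdna_sensitivity": ct_val_perf.sensitivity,
            "ctdna_specificity": ct_val_perf.specificity,
            "mm_sensitivity": mm_val_perf.sensitivity,
            "mm_specificity": mm_val_perf.specificity,
            "mm_survival": _stratify(patients, mm_val_labels, common_v),
        }

    manifest = {
        "package": "mmresp",
        "python": platform.python_version(),
        "seed": config.seed,
        "stage_seeds": {"simulate": _child_seed(config.seed, 0), "cv": _child_seed(config.seed, 1)},
        "parameters": {
            "independent_calling": {"min_reads": 5, "min_vaf": 0.001},
            "dependent_calling": {"min_reads": 3, "control_fold": 20, "wbc_fold": 3},
            "cnv_thresholds": {"loss_rc": -0.3, "loss_rc_maf": [-0.1, 0.6],
                               "gain_rc": 0.3, "gain_rc_maf": [0.1, 0.6]},
            "copies_per_ng": ctdna.COPIES_PER_NG,
            "gene_filter": {"min_cpm": 1, "cv_cutoff": 100},
            "cv": {"repeats": config.n_cv_repeats, "folds": config.n_cv_folds},
            "feature_grid": list(config.feature_grid),
            "prob_cutoff": config.prob_cutoff,
            "ct_band_grid": list(config.ct_band_grid),
            "rna_band_grid": list(config.rna_band_grid),
            "sim": asdict(config.sim),
        },
    }

    result = RunResult(
        patients=patients,
        ctdna_table=ct,
        dea_cb=dea_cb,
        rna_model=rna_model,
        selection_report=selection,
        mm_config=mm_cfg,
        grid_report=grid_report,
        metrics=metrics,
        manifest=manifest,
    )
    if config.outdir:
        _write_outputs(result, Path(config.outdir))
    return result


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if np.isnan(f) else f
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj


def _write_outputs(result: RunResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    files = {}
    result.patients.to_csv(outdir / "patients.tsv", sep="\t", index=False)
    result.ctdna_table.to_csv(outdir / "ctdna_quant.tsv", sep="\t", index=False)
    files["patients.tsv"] = _hash_file(outdir / "patients.tsv")
    files["ctdna_quant.tsv"] = _hash_file(outdir / "ctdna_quant.tsv")
    if result.dea_cb is not None:
        result.dea_cb.to_csv(outdir / "dea_cb_longitudinal.tsv", sep="\t", index=False)
        files["dea_cb_longitudinal.tsv"] = _hash_file(outdir / "dea_cb_longitudinal.tsv")
    if result.rna_model is not None:
        result.rna_model.to_json(outdir / "rna_model.json")
        files["rna_model.json"] = _hash_file(outdir / "rna_model.json")
    if result.grid_report is not None:
        result.grid_report.to_csv(outdir / "band_grid.tsv", sep="\t", index=False)
        files["band_grid.tsv"] = _hash_file(outdir / "band_grid.tsv")
    if result.mm_config is not None:
        result.mm_config.to_json(outdir / "multimodal_config.json")
        files["multimodal_config.json"] = _hash_file(outdir / "multimodal_config.json")
    result.manifest["files"] = files
    (outdir / "metrics.json").write_text(json.dumps(_jsonable(result.metrics), indent=1))
    (outdir / "manifest.json").write_text(json.dumps(_jsonable(result.manifest), indent=1))
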