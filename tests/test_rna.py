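"""RNA expression analysis: filtering, TMM, moderated-t DEA, enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from mmresp import rna


def _counts(matrix, genes=None, samples=None):
    matrix = np.asarray(matrix)
    genes = genes or [f"g{i}" for i in range(matrix.shape[0])]
    samples = samples or [f"s{j}" for j in range(matrix.shape[1])]
    return pd.DataFrame(matrix, index=genes, columns=samples)


class TestFiltering:
    def test_all_zero_gene_removed(self):
        counts = _counts([[0, 0], [10, 20]])
        out, report = rna.filter_genes(counts)
        assert list(out.index) == ["g1"]
        assert report["removed_low_cpm"] == 1

    def test_cpm_rule_hand_computed(self):
        # libraries 1e7 each; CPMs per gene: {0.5,0.5}, {2,2}, {0.9,1.1}
        lib = 10**7
        counts = pd.DataFrame(
            {"s0": [5, 20, 9], "s1": [5, 20, 11]},
            index=["low", "mid", "edge"],
        )
        filler = pd.DataFrame(
            {"s0": [lib - 34], "s1": [lib - 36]}, index=["bulk"]
        )
        counts = pd.concat([counts, filler])
        out, _ = rna.filter_genes(counts)
        assert "low" not in out.index
        assert {"mid", "edge"} <= set(out.index)  # any CPM >= 1 retains

    def test_stable_expressed_gene_retained(self):
        rng = np.random.default_rng(0)
        base = rng.poisson(50, size=(20, 6)) + 1
        counts = _counts(base)
        out, _ = rna.filter_genes(counts)
        assert len(out) == 20

    def test_zero_library_sample_named(self):
        counts = _counts([[0, 5], [0, 7]], samples=["bad", "good"])
        with pytest.raises(ValueError, match="bad"):
            rna.filter_genes(counts)


class TestTransform:
    def test_closed_form_at_zero(self):
        counts = _counts([[0], [10**6]], samples=["s"])
        vals = rna.transform_counts(counts, lib_sizes=pd.Series({"s": 10**6}))
        assert vals.loc["g0", "s"] == pytest.approx(-1.0)  # log2(0.5)

    def test_equal_counts_equal_values(self):
        counts = _counts([[7, 7], [3, 3]])
        vals = rna.transform_counts(counts)
        assert (vals["s0"] == vals["s1"]).all()

    def test_monotone_and_bounded_increment(self):
        rng = np.random.default_rng(1)
        counts = _counts(rng.integers(1, 1000, size=(50, 4)))
        lib = counts.sum(axis=0)
        doubled = counts * 2
        v1 = rna.transform_counts(counts, lib_sizes=lib)
        v2 = rna.transform_counts(doubled, lib_sizes=lib)
        inc = (v2 - v1).to_numpy()
        assert (inc > 0).all() and (inc <= 1.0 + 1e-12).all()


def _tmm_bruteforce(counts: pd.DataFrame) -> pd.Series:
    """Independent loop-wise coding of the trim-and-weight formula."""
    lib = counts.sum(axis=0)
    cpm = counts / lib * 1e6
    uq = cpm.quantile(0.75)
    ref = min(counts.columns, key=lambda s: abs(uq[s] - uq.mean()))
    fac = {}
    for s in counts.columns:
        if s == ref:
            fac[s] = 1.0
            continue
        ms, as_, ws = [], [], []
        for g in counts.index:
            o, r = counts.loc[g, s], counts.loc[g, ref]
            if o > 0 and r > 0:
                po, pr = o / lib[s], r / lib[ref]
                ms.append(np.log2(po / pr))
                as_.append(0.5 * np.log2(po * pr))
                ws.append(
                    1.0 / ((lib[s] - o) / (lib[s] * o) + (lib[ref] - r) / (lib[ref] * r))
                )
        ms, as_, ws = map(np.array, (ms, as_, ws))
        lo_m, hi_m = np.quantile(ms, [0.3, 0.7])
        lo_a, hi_a = np.quantile(as_, [0.05, 0.95])
        keep = (ms >= lo_m) & (ms <= hi_m) & (as_ >= lo_a) & (as_ <= hi_a)
        fac[s] = 2.0 ** (np.sum(ms[keep] * ws[keep]) / np.sum(ws[keep]))
    f = pd.Series(fac).reindex(counts.columns)
    return f / np.exp(np.log(f).mean())


class TestTmm:
    def test_identical_columns_give_unit_factors(self):
        counts = _counts(np.tile([[10], [200], [3000]], (1, 4)))
        f = rna.tmm_factors(counts)
        np.testing.assert_allclose(f, 1.0)

    def test_pure_depth_change_gives_unit_factor(self):
        rng = np.random.default_rng(2)
        col = rng.integers(10, 2000, 100)
        counts = _counts(np.column_stack([col, 2 * col, col]))
        f = rna.tmm_factors(counts)
        np.testing.assert_allclose(f, 1.0, atol=1e-10)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(3)
        mat = rng.integers(5, 500, size=(60, 3))
        mat[0, 1] = 50_000  # one inflated gene pulls that sample's factor
        counts = _counts(mat)
        np.testing.assert_allclose(
            rna.tmm_factors(counts), _tmm_bruteforce(counts), rtol=1e-10
        )

    def test_factors_multiply_to_one(self):
        rng = np.random.default_rng(4)
        counts = _counts(rng.integers(1, 300, size=(80, 5)))
        f = rna.tmm_factors(counts)
        assert np.prod(f) == pytest.approx(1.0)

    def test_all_zero_sample_rejected(self):
        counts = _counts([[0, 5], [0, 5]])
        with pytest.raises(ValueError):
            rna.tmm_factors(counts)


def _make_paired(n_genes=200, n_pairs=10, shift_gene=None, shift=0.0, seed=0):
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n_genes)]
    sample_ids, meta, cols = [], [], []
    for p in range(n_pairs):
        base = rng.normal(8, 1, n_genes)
        for tp in ("BL", "OT"):
            x = base + rng.normal(0, 0.3, n_genes)
            if tp == "OT" and shift_gene is not None:
                x[shift_gene] += shift
            sid = f"p{p}_{tp}"
            cols.append(x)
            sample_ids.append(sid)
            meta.append(
                {"sample_id": sid, "patient_id": f"p{p}", "timepoint": tp,
                 "group": "CB"}
            )
    expr = pd.DataFrame(np.column_stack(cols), index=genes, columns=sample_ids)
    return expr, pd.DataFrame(meta)


class TestPairedDea:
    def test_identical_timepoints_give_null(self):
        expr, meta = _make_paired(n_genes=30, n_pairs=5)
        expr[[c for c in expr.columns if c.endswith("OT")]] = expr[
            [c.replace("OT", "BL") for c in expr.columns if c.endswith("OT")]
        ].to_numpy()
        res = rna.paired_dea(expr, meta, group="CB")
        assert (res["log2fc"] == 0).all()
        assert rna.deg_set(res) == set()

    def test_injected_signal_ranks_first(self):
        expr, meta = _make_paired(shift_gene=7, shift=1.0, seed=1)
        res = rna.paired_dea(expr, meta, group="CB")
        assert res.iloc[0]["gene"] == "g7"
        assert res.iloc[0]["log2fc"] == pytest.approx(1.0, abs=0.3)
        assert res.iloc[0]["adj_p"] <= 0.05

    def test_null_type_one_error_near_nominal(self):
        hits = []
        for seed in range(5):
            expr, meta = _make_paired(n_genes=400, n_pairs=12, seed=seed + 10)
            res = rna.paired_dea(expr, meta, group="CB")
            hits.append((res["p_value"] <= 0.05).mean())
        frac = np.mean(hits)
        # binomial band around 0.05 for 5 x 400 draws
        assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 2000)

    def test_zero_variance_gene_yields_finite_p(self):
        expr, meta = _make_paired(n_genes=20, n_pairs=6, seed=3)
        # constant gene: identical at BL and OT across pairs
        expr.iloc[0, :] = 5.0
        res = rna.paired_dea(expr, meta, group="CB")
        assert np.isfinite(res["p_value"]).all()

    def test_requires_three_pairs(self):
        expr, meta = _make_paired(n_pairs=2)
        with pytest.raises(ValueError):
            rna.paired_dea(expr, meta, group="CB")

    def test_sample_order_invariance(self):
        expr, meta = _make_paired(shift_gene=3, shift=0.8, seed=5)
        res1 = rna.paired_dea(expr, meta, group="CB")
        shuffled = expr[list(reversed(expr.columns))]
        res2 = rna.paired_dea(shuffled, meta, group="CB")
        pd.testing.assert_frame_equal(res1, res2)


class TestGroupDea:
    def test_two_group_contrast_detects_shift(self):
        rng = np.random.default_rng(6)
        genes = [f"g{i}" for i in range(100)]
        meta, cols, ids = [], [], []
        for i in range(16):
            grp = "CB" if i < 8 else "N-CB"
            x = rng.normal(8, 0.4, 100)
            if grp == "CB":
                x[11] += 1.5
            sid = f"s{i}"
            ids.append(sid)
            cols.append(x)
            meta.append({"sample_id": sid, "patient_id": f"p{i}",
                         "timepoint": "OT", "group": grp})
        expr = pd.DataFrame(np.column_stack(cols), index=genes, columns=ids)
        res = rna.group_dea(expr, pd.DataFrame(meta))
        assert res.iloc[0]["gene"] == "g11"
        assert res.iloc[0]["direction"] == "up"

    def test_requires_three_per_group(self):
        expr, meta = _make_paired(n_pairs=4)
        meta["timepoint"] = "OT"
        meta["group"] = ["CB", "CB", "N-CB", "N-CB"] * 2
        meta = meta.iloc[:4]
        with pytest.raises(ValueError):
            rna.group_dea(expr[meta["sample_id"]], meta)


class TestBhAdjustment:
    def test_hand_stepup_on_toy_pvalues(self):
        # BH on (0.01, 0.02, 0.03, 0.04) with m=4: adjusted
        # p_(i) * 4/i then cumulative min from the right -> all 0.04
        adj = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_dea_adjusted_monotone_in_rank(self):
        expr, meta = _make_paired(seed=7)
        res = rna.paired_dea(expr, meta, group="CB")
        assert (res["adj_p"] >= res["p_value"] - 1e-15).all()
        assert (np.diff(res["adj_p"]) >= -1e-12).all()
        assert (res["adj_p"] <= 1.0).all()


class TestIntersections:
    def test_disjoint_sets(self):
        out = rna.intersect_deg_sets({"a"}, {"b"}, {"c"})
        counts = out["counts"]
        assert counts["cb_only"] == counts["ncb_only"] == counts["ot_only"] == 1
        assert counts["all_three"] == 0
        assert out["signature_set"] == set()

    def test_signature_set_excludes_ncb(self):
        out = rna.intersect_deg_sets({"a", "b", "c"}, {"c"}, {"b", "c", "d"})
        assert out["signature_set"] == {"b"}
        out2 = rna.intersect_deg_sets({"a", "b", "c"}, {"c"}, {"b", "c", "d"},
                                      exclude_ncb=False)
        assert out2["signature_set"] == {"b", "c"}

    def test_counts_match_set_oracle(self):
        rng = np.random.default_rng(8)
        univ = [f"g{i}" for i in range(200)]
        a, b, c = (set(rng.choice(univ, 60, replace=False)) for _ in range(3))
        out = rna.intersect_deg_sets(a, b, c)
        assert out["counts"]["all_three"] == len(a & b & c)
        assert out["counts"]["cb_ot_only"] == len((a & c) - b)
        assert sum(out["counts"].values()) == len(a | b | c)


class TestSignatureScore:
    def test_singleton_set_equals_gene_value(self):
        expr, meta = _make_paired(n_genes=10, n_pairs=4)
        meta.loc[meta.index[:4], "group"] = "N-CB"
        scores, _ = rna.signature_score(expr, meta, ["g3"], timepoint="OT")
        ot = meta[meta["timepoint"] == "OT"]
        np.testing.assert_allclose(
            scores["score"], expr.loc["g3", ot["sample_id"]].to_numpy()
        )

    def test_constant_shift_moves_score_linearly(self):
        expr, meta = _make_paired(n_genes=10, n_pairs=4)
        s1, _ = rna.signature_score(expr, meta, ["g1", "g2"])
        s2, _ = rna.signature_score(expr + 3.0, meta, ["g1", "g2"])
        np.testing.assert_allclose(s2["score"], s1["score"] + 3.0)

    def test_upshifted_set_separates_groups(self):
        rng = np.random.default_rng(9)
        genes = [f"g{i}" for i in range(20)]
        meta, cols, ids = [], [], []
        for i in range(24):
            grp = "CB" if i < 12 else "N-CB"
            x = rng.normal(5, 0.5, 20)
            if grp == "CB":
                x[:5] += 1.2
            sid = f"s{i}"
            ids.append(sid)
            cols.append(x)
            meta.append({"sample_id": sid, "patient_id": f"p{i}",
                         "timepoint": "OT", "group": grp})
        expr = pd.DataFrame(np.column_stack(cols), index=genes, columns=ids)
        scores, p = rna.signature_score(expr, pd.DataFrame(meta), genes[:5])
        cb = scores.loc[scores["group"] == "CB", "score"]
        ncb = scores.loc[scores["group"] == "N-CB", "score"]
        assert cb.median() > ncb.median()
        assert p < 0.01

    def test_empty_set_rejected(self):
        expr, meta = _make_paired(n_genes=5, n_pairs=3)
        with pytest.raises(ValueError):
            rna.signature_score(expr, meta, [])


class TestEnrichment:
    def test_exact_combinatorial_example(self):
        # universe 20, pathway 5, DEG set 4, overlap 3:
        # p = (C(5,3)C(15,1) + C(5,4)C(15,0)) / C(20,4) = 155/4845
        universe = [f"g{i}" for i in range(20)]
        pathway = set(universe[:5])
        degs = set(universe[:3]) | {universe[10]}
        res = rna.enrich_hypergeometric(degs, universe, {"pw": pathway})
        assert res.loc[0, "p_value"] == pytest.approx(155 / 4845)

    def test_pathway_equal_to_degs_is_most_enriched(self):
        universe = [f"g{i}" for i in range(50)]
        degs = set(universe[:8])
        paths = {
            "exact": set(universe[:8]),
            "half": set(universe[4:12]),
            "none": set(universe[20:28]),
        }
        res = rna.enrich_hypergeometric(degs, universe, paths).set_index("pathway")
        assert res.loc["exact", "p_value"] == res["p_value"].min()
        assert res.loc["exact", "enriched"]

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            rna.enrich_hypergeometric({"a"}, [], {"pw": {"a"}})


class TestGmt:
    def test_roundtrip(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("pw1\tdesc\tg1\tg2\npw2\tdesc\tg3\n")
        sets = rna.read_gmt(p)
        assert sets == {"pw1": {"g1", "g2"}, "pw2": {"g3"}}
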