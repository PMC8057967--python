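"""RPKM, variable-gene selection, clustering, DEGs, enrichment and HLA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ithpipe import expr_ith, simdata
from ithpipe.expr_ith import (
    ExpressionMatrix,
    cluster_two_groups,
    enrich,
    hla_association,
    identify_degs,
    rpkm,
    select_variable_genes,
)


class TestRpkm:
    def test_textbook_value(self):
        m = ExpressionMatrix(
            values=pd.DataFrame({"S1": [10, 999_990]}, index=["g1", "g2"]),
            lengths=pd.Series([1000, 100_000], index=["g1", "g2"]),
        )
        out = rpkm(m)
        # count 10, length 1 kb, library 1e6 reads -> RPKM 10
        assert out.values.loc["g1", "S1"] == pytest.approx(10.0)
        assert out.value_kind == "rpkm"

    def test_zero_count_zero_rpkm(self):
        m = ExpressionMatrix(
            values=pd.DataFrame({"S1": [0, 100]}, index=["g1", "g2"]),
            lengths=pd.Series([500, 500], index=["g1", "g2"]),
        )
        assert rpkm(m).values.loc["g1", "S1"] == 0.0

    def test_matches_bruteforce_oracle(self, rng):
        counts = pd.DataFrame(
            rng.integers(0, 500, size=(8, 4)),
            index=[f"g{i}" for i in range(8)],
            columns=list("ABCD"),
        )
        lengths = pd.Series(rng.integers(200, 5000, size=8), index=counts.index)
        out = rpkm(ExpressionMatrix(values=counts, lengths=lengths)).values
        for g in counts.index:
            for s in counts.columns:
                expected = counts.loc[g, s] * 1e9 / (lengths[g] * counts[s].sum())
                assert out.loc[g, s] == pytest.approx(expected)

    def test_per_sample_scaling_invariance(self, rng):
        counts = pd.DataFrame(
            rng.integers(1, 500, size=(6, 3)), index=[f"g{i}" for i in range(6)], columns=list("XYZ")
        )
        lengths = pd.Series(rng.integers(200, 5000, size=6), index=counts.index)
        base = rpkm(ExpressionMatrix(values=counts, lengths=lengths)).values
        scaled_counts = counts.copy()
        scaled_counts["Y"] *= 5  # library size scales with the counts
        scaled = rpkm(ExpressionMatrix(values=scaled_counts, lengths=lengths)).values
        pd.testing.assert_series_equal(base["Y"], scaled["Y"])


class TestVariableGenes:
    def test_lowly_expressed_gene_removed(self):
        vals = pd.DataFrame(
            {
                "S1": [2**0.5 - 1, 100],
                "S2": [2**0.5 - 1, 1],
            },
            index=["low", "hi"],
        )
        kept = select_variable_genes(vals, min_mad_log2=0.0)
        assert "low" not in kept.index and "hi" in kept.index

    def test_constant_gene_removed_by_mad(self):
        vals = pd.DataFrame({"S1": [50.0], "S2": [50.0], "S3": [50.0]}, index=["flat"])
        assert len(select_variable_genes(vals)) == 0

    def test_bimodal_gene_kept(self):
        # log2(RPKM+1) = 2,2,5,5 -> mean 3.5, MAD 1.5
        vals = pd.DataFrame([[3.0, 3.0, 31.0, 31.0]], index=["bimodal"], columns=list("ABCD"))
        kept = select_variable_genes(vals)
        assert list(kept.index) == ["bimodal"]

    def test_iid_background_survives_nowhere_at_default_threshold(self, rng):
        lg = rng.normal(5, 0.1, size=(200, 6))
        vals = pd.DataFrame(np.exp2(lg) - 1, index=[f"g{i}" for i in range(200)])
        assert len(select_variable_genes(vals)) == 0


class TestClustering:
    def test_two_samples_split_apart(self):
        vals = pd.DataFrame({"S1": [1.0, 2.0], "S2": [2.0, 1.0]}, index=["g1", "g2"])
        groups, _ = cluster_two_groups(vals)
        assert set(groups) == {0, 1}

    def test_planted_subgroups_recovered(self, clean_cfg):
        expr, truth = simdata.simulate_expression(clean_cfg, [f"S{i}" for i in range(8)])
        rp = rpkm(expr)
        variable = select_variable_genes(rp.values, min_mad_log2=0.5)
        groups, _ = cluster_two_groups(variable)
        want = pd.Series(truth["groups"])
        agree = (groups == want).mean()
        assert agree in (0.0, 1.0)  # exact partition up to label swap

    def test_sample_order_invariance(self, clean_cfg):
        expr, _ = simdata.simulate_expression(clean_cfg, [f"S{i}" for i in range(6)])
        rp = rpkm(expr).values
        variable = select_variable_genes(rp, min_mad_log2=0.5)
        g1, _ = cluster_two_groups(variable)
        perm = list(variable.columns[::-1])
        g2, _ = cluster_two_groups(variable[perm])
        same = (g1 == g2.reindex(g1.index)).mean()
        assert same in (0.0, 1.0)


class TestDegs:
    def _vals(self, a_mean, b_mean):
        return pd.DataFrame(
            {"A1": [a_mean], "A2": [a_mean], "B1": [b_mean], "B2": [b_mean]}, index=["g"]
        )

    def _groups(self):
        return pd.Series({"A1": 0, "A2": 0, "B1": 1, "B2": 1})

    def test_boundary_fold_change_included(self):
        degs = identify_degs(self._vals(10.0, 5.0), self._groups(), eps=0.0)
        assert degs.genes == ["g"] and degs.direction["g"] == "up"

    def test_sub_threshold_fold_change_excluded(self):
        degs = identify_degs(self._vals(10.0, 6.0), self._groups())
        assert degs.genes == []

    def test_swap_symmetry(self, rng):
        vals = pd.DataFrame(
            rng.lognormal(2, 1, size=(50, 4)),
            index=[f"g{i}" for i in range(50)],
            columns=["A1", "A2", "B1", "B2"],
        )
        g = self._groups()
        fwd = identify_degs(vals, g)
        rev = identify_degs(vals, 1 - g)
        assert set(fwd.genes) == set(rev.genes)
        for gene in fwd.genes:
            assert fwd.fold_change[gene] == pytest.approx(1 / rev.fold_change[gene], rel=1e-9)

    def test_planted_deg_recovery(self, clean_cfg):
        expr, truth = simdata.simulate_expression(clean_cfg, [f"S{i}" for i in range(8)])
        rp = rpkm(expr)
        degs = identify_degs(rp.values, pd.Series(truth["groups"]))
        planted = set(truth["deg_genes"])
        found = set(degs.genes)
        assert len(found & planted) >= 0.9 * len(planted)
        background = {g for g in rp.values.index if g.startswith("BG")}
        assert len(found & background) <= 5

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            identify_degs(self._vals(1, 1), pd.Series({"A1": 0, "A2": 0, "B1": 0, "B2": 0}))


class TestEnrichment:
    def test_identical_set_minimal_p(self):
        universe = [f"g{i}" for i in range(50)]
        degs = universe[:10]
        res = enrich(degs, universe, {"hit": degs})
        expected = stats.hypergeom.sf(9, 50, 10, 10)
        assert res.loc[0, "pvalue"] == pytest.approx(expected)
        assert res.loc[0, "pvalue"] < 1e-9

    def test_disjoint_set_p_one(self):
        universe = [f"g{i}" for i in range(50)]
        res = enrich(universe[:10], universe, {"miss": universe[40:]})
        assert res.loc[0, "pvalue"] == pytest.approx(1.0)

    def test_matches_exact_tail_sum_oracle(self, rng):
        universe = [f"g{i}" for i in range(60)]
        for _ in range(10):
            degs = list(rng.choice(universe, size=12, replace=False))
            members = list(rng.choice(universe, size=20, replace=False))
            res = enrich(degs, universe, {"s": members})
            k = len(set(degs) & set(members))
            # direct sum of the hypergeometric pmf over the upper tail
            oracle = sum(
                stats.hypergeom.pmf(x, 60, 20, 12) for x in range(k, min(20, 12) + 1)
            )
            assert res.loc[0, "pvalue"] == pytest.approx(oracle, abs=1e-10)

    def test_bh_adjustment_monotone(self, rng):
        universe = [f"g{i}" for i in range(100)]
        degs = universe[:15]
        sets = {f"s{j}": list(rng.choice(universe, size=20, replace=False)) for j in range(8)}
        res = enrich(degs, universe, sets)
        assert (res["pvalue"].is_monotonic_increasing
                and res["padj"].is_monotonic_increasing)
        assert ((res["padj"] >= res["pvalue"] - 1e-12).all())

    def test_deg_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            enrich(["x"], ["a", "b"], {"s": ["a"]})


class TestHlaAssociation:
    def test_noiseless_linear_map_exact(self):
        cfg = simdata.SimConfig(
            seed=3, expr_noise_sd=0.0, hla_noise_sd=0.0, expr_value_kind="rpkm",
            hla_regulator_slope=1.3,
        )
        expr, truth = simdata.simulate_expression(cfg, [f"S{i}" for i in range(6)])
        assoc = hla_association(expr.values)
        assert len(assoc) == len(truth["regulator_pairs"])
        assert np.allclose(assoc["slope"], 1.3, atol=1e-9)
        assert np.allclose(assoc["r2"], 1.0, atol=1e-12)

    def test_noisy_r2_matches_analytic_expectation(self):
        cfg = simdata.SimConfig(seed=9, hla_noise_sd=0.3, expr_value_kind="rpkm")
        samples = [f"S{i}" for i in range(200)]
        expr, _ = simdata.simulate_expression(cfg, samples)
        assoc = hla_association(expr.values)
        # regulator ~ U(4,6): var 1/3; R2 ≈ var/(var + 0.09) ≈ 0.787
        expected = (1 / 3) / (1 / 3 + 0.09)
        assert assoc["r2"].mean() == pytest.approx(expected, abs=0.1)

    def test_constant_regulator_flagged(self):
        vals = pd.DataFrame(
            {"S1": [4.0, 2.0], "S2": [4.0, 3.0], "S3": [4.0, 1.0]},
            index=["CIITA", "HLA-DRA"],
        )
        with pytest.warns(UserWarning, match="constant"):
            assoc = hla_association(vals)
        assert assoc["r2"].isna().all()

    def test_panel_sizes(self):
        panel = expr_ith.HlaPanel()
        assert len(panel.class_i) == 9 and len(panel.class_ii) == 16


def test_zscore_rows_unit_scale(rng):
    vals = pd.DataFrame(rng.lognormal(2, 1, size=(5, 6)), index=[f"g{i}" for i in range(5)])
    z = expr_ith.zscore_rows(vals)
    assert np.allclose(z.mean(axis=1), 0, atol=1e-12)
    assert np.allclose(z.std(axis=1, ddof=0), 1, atol=1e-12)


def test_counts_tsv_round_trip(tmp_path, clean_cfg):
    expr, _ = simdata.simulate_expression(clean_cfg, [f"S{i}" for i in range(4)])
    path = tmp_path / "counts.tsv"
    expr_ith.write_counts_tsv(expr, path)
    back = expr_ith.read_counts_tsv(path)
    pd.testing.assert_frame_equal(expr.values, back.values, check_dtype=False)
    pd.testing.assert_series_equal(
        expr.lengths, back.lengths, check_dtype=False, check_names=False
    )
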