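import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from irgpi import (
    CohortSpec,
    ValidationError,
    bh_adjust,
    gsea,
    log2fc_ranking,
    mannwhitney_compare,
    simulate_cohort,
    ssgsea_scores,
)
from tests.conftest import monotone_distort_per_sample


@pytest.fixture()
def four_gene_sample():
    return pd.DataFrame({"s1": [4.0, 3.0, 2.0, 1.0]}, index=["A", "B", "C", "D"])


class TestSsgsea:
    def test_top_gene_set_unweighted_es(self, four_gene_sample):
        # P_in jumps to 1 at position 1; P_out climbs 0, 1/3, 2/3, 1
        res = ssgsea_scores(four_gene_sample, {"top": ["A"]}, tau=0.0)
        assert res.scores.loc["top", "s1"] == pytest.approx(2.0)

    def test_bottom_gene_set_mirror_image(self, four_gene_sample):
        res = ssgsea_scores(four_gene_sample, {"bottom": ["D"]}, tau=0.0)
        assert res.scores.loc["bottom", "s1"] == pytest.approx(-2.0)

    def test_rank_only_dependence_under_monotone_transform(self, small_cohort):
        expr, _, _ = small_cohort
        sets = {"S1": list(expr.index[:6]), "S2": list(expr.index[10:18])}
        a = ssgsea_scores(expr, sets, tau=0.25)
        b = ssgsea_scores(monotone_distort_per_sample(expr, seed=8), sets, tau=0.25)
        np.testing.assert_allclose(a.scores.values, b.scores.values, atol=1e-12)

    def test_range_normalisation(self, small_cohort):
        expr, _, _ = small_cohort
        sets = {"S1": list(expr.index[:6]), "S2": list(expr.index[10:18])}
        res = ssgsea_scores(expr, sets)
        spread = res.scores.values.max() - res.scores.values.min()
        assert res.norm_constant == pytest.approx(spread)
        np.testing.assert_allclose(res.nes.values, res.scores.values / spread)
        assert np.abs(res.nes.values).max() <= 1.0 + 1e-12

    def test_zero_overlap_set_excluded_with_warning(self, four_gene_sample):
        with pytest.warns(RuntimeWarning, match="no gene"):
            res = ssgsea_scores(
                four_gene_sample, {"ok": ["A", "B"], "alien": ["ZZ"]}, tau=0.25
            )
        assert list(res.scores.index) == ["ok"]

    def test_planted_immune_signal_detected_at_cohort_scale(self):
        """Positively associated sets score higher in the high-risk half
        (Mann-Whitney p < 0.05 at effect +1.0, n=150)."""
        sets = {"UP": [f"G{i:04d}" for i in range(12, 20)],
                "DOWN": [f"G{i:04d}" for i in range(20, 28)]}
        spec = CohortSpec(
            n_samples=150, n_genes=40, seed=19,
            immune_sets=sets, immune_set_signs={"UP": 1, "DOWN": -1},
        )
        expr, _, truth = simulate_cohort(spec)
        groups = pd.Series(
            np.where(truth["eta"] > truth["eta"].median(), "high", "low"),
            index=expr.columns,
        )
        res = ssgsea_scores(expr, sets)
        comp = mannwhitney_compare(res, groups)
        assert comp.loc["UP", "p"] < 0.05
        assert comp.loc["UP", "mean_high"] > comp.loc["UP", "mean_low"]
        assert comp.loc["DOWN", "mean_high"] < comp.loc["DOWN", "mean_low"]


class TestLog2fcRanking:
    def _expr(self):
        return pd.DataFrame(
            {"h1": [8.0, 5.0, 1.0], "h2": [8.0, 5.0, 1.0],
             "l1": [2.0, 5.0, 4.0], "l2": [2.0, 5.0, 0.0]},
            index=["UPG", "FLATG", "DOWNG"],
        )

    def _groups(self):
        return pd.Series(["high", "high", "low", "low"],
                         index=["h1", "h2", "l1", "l2"])

    def test_fold_change_of_four_is_two(self):
        ranked = log2fc_ranking(self._expr(), self._groups(), pseudocount=0.0)
        assert ranked["UPG"] == pytest.approx(2.0)
        assert ranked["FLATG"] == pytest.approx(0.0)
        assert list(ranked.index) == ["UPG", "FLATG", "DOWNG"]

    def test_zero_denominator_needs_pseudocount(self):
        expr = self._expr()
        expr.loc["DOWNG", ["l1", "l2"]] = 0.0
        with pytest.raises(ValidationError, match="pseudocount"):
            log2fc_ranking(expr, self._groups(), pseudocount=0.0)
        ranked = log2fc_ranking(expr, self._groups(), pseudocount=0.01)
        assert np.isfinite(ranked).all()

    def test_empty_group_rejected(self):
        groups = pd.Series(["high"] * 4, index=self._expr().columns)
        with pytest.raises(ValidationError, match="non-empty"):
            log2fc_ranking(self._expr(), groups)

    def test_ties_break_by_gene_symbol(self):
        expr = pd.DataFrame(
            {"h": [3.0, 3.0], "l": [3.0, 3.0]}, index=["ZGENE", "AGENE"]
        )
        groups = pd.Series(["high", "low"], index=["h", "l"])
        ranked = log2fc_ranking(expr, groups)
        assert list(ranked.index) == ["AGENE", "ZGENE"]


class TestGsea:
    def test_hand_walked_running_sum(self):
        # hits weighted 3/5, 2/5; misses 1/2 each: 0.6, 1.0, 0.5, 0.0
        ranked = pd.Series([3.0, 2.0, 1.0, -1.0], index=["G1", "G2", "G3", "G4"])
        res = gsea(ranked, {"S": ["G1", "G2"]}, n_perm=20, seed=0)
        assert res.table.loc["S", "es"] == pytest.approx(1.0)

    def test_complement_set_scores_negative(self):
        ranked = pd.Series([3.0, 2.0, 1.0, -1.0], index=["G1", "G2", "G3", "G4"])
        res = gsea(ranked, {"C": ["G3", "G4"]}, n_perm=20, seed=0)
        assert res.table.loc["C", "es"] < 0

    def test_top_block_attains_maximal_es_for_its_size(self):
        rng = np.random.default_rng(2)
        scores = pd.Series(np.sort(rng.normal(size=50))[::-1],
                           index=[f"g{i}" for i in range(50)])
        sets = {"topblock": [f"g{i}" for i in range(8)]}
        es_top = gsea(scores, sets, n_perm=10, seed=0).table.loc["topblock", "es"]
        for trial in range(5):
            other = list(rng.choice(scores.index.to_numpy(), 8, replace=False))
            es = gsea(scores, {"o": other}, n_perm=10, seed=0).table.loc["o", "es"]
            assert es <= es_top + 1e-12

    def test_p_value_bounds_and_bh_dominance(self):
        rng = np.random.default_rng(4)
        scores = pd.Series(rng.normal(size=60), index=[f"g{i}" for i in range(60)])
        sets = {f"s{j}": list(rng.choice(scores.index.to_numpy(), 10, replace=False))
                for j in range(5)}
        res = gsea(scores, sets, n_perm=100, seed=1)
        assert (res.table["p"] >= 1.0 / 101).all()
        assert (res.table["p"] <= 1.0).all()
        assert (res.table["p_adj"] >= res.table["p"] - 1e-15).all()

    def test_set_as_large_as_list_rejected(self):
        ranked = pd.Series([2.0, 1.0], index=["A", "B"])
        with pytest.raises(ValidationError, match="as large as"):
            gsea(ranked, {"all": ["A", "B"]}, n_perm=10)

    def test_es_matches_independent_implementation(self):
        """Observed enrichment scores agree with gseapy's preranked GSEA."""
        import gseapy

        rng = np.random.default_rng(0)
        genes = [f"G{i}" for i in range(60)]
        scores = pd.Series(np.sort(rng.normal(size=60))[::-1], index=genes)
        sets = {
            "S1": list(rng.choice(genes, 12, replace=False)),
            "S2": list(rng.choice(genes, 8, replace=False)),
        }
        rnk = scores.reset_index()
        rnk.columns = ["gene", "score"]
        ref = gseapy.prerank(
            rnk=rnk, gene_sets=sets, permutation_num=5, min_size=2,
            max_size=50, seed=1, outdir=None, no_plot=True,
        ).res2d.set_index("Term")["ES"].astype(float)
        mine = gsea(scores, sets, n_perm=5, seed=0).table["es"]
        for name in sets:
            assert mine[name] == pytest.approx(ref[name], abs=1e-9)

    def test_null_calibration_small(self):
        """Nominal p is approximately uniform on null ranked lists."""
        from irgpi.experiments import gsea_null_batch

        out = gsea_null_batch(seed=5, n_lists=20, n_sets_per_list=10, n_perm=100)
        assert 0.02 <= out["rate_p_below_05"] <= 0.09


class TestBhAdjust:
    def test_worked_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])

    def test_single_p_identity(self):
        np.testing.assert_allclose(bh_adjust([0.5]), [0.5])

    def test_capped_at_one(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0]), [1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_order_preserving_and_dominates_raw(self, ps):
        adj = bh_adjust(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-15)
        order = np.argsort(ps)
        assert np.all(np.diff(np.asarray(adj)[order]) >= -1e-15)
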