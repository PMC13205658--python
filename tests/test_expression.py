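import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lncfunnel.expression import (
    CountMatrix,
    TissueProfile,
    bh_adjust,
    ddct_fold_change,
    filter_enriched,
    hypergeom_enrichment,
    nb_wald_test,
    percent_input,
    size_factors,
    tau_specificity,
)
from lncfunnel.synthetic import gen_expression_experiment


def _cm(counts, groups=("a", "a", "b", "b"), biotypes=None):
    counts = np.asarray(counts)
    genes = [f"g{i}" for i in range(counts.shape[0])]
    samples = [f"s{j}" for j in range(counts.shape[1])]
    return CountMatrix(
        genes,
        samples,
        counts,
        dict(zip(samples, groups)),
        biotypes or {},
    )


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        cm = _cm([[10, 10, 10, 10], [5, 5, 5, 5]])
        np.testing.assert_allclose(size_factors(cm), 1.0)

    def test_doubled_column_has_double_factor(self):
        base = np.array([[10, 10], [40, 40], [7, 7]])
        cm = _cm(np.column_stack([base[:, 0], 2 * base[:, 1]]), groups=("a", "a"))
        f = size_factors(cm)
        assert f[1] / f[0] == pytest.approx(2.0)

    def test_median_of_ratios_hand_example(self):
        # 3 genes x 2 samples, all rows [10, 20]: geomean sqrt(200),
        # ratios 10/sqrt(200) = 1/sqrt2 and 20/sqrt(200) = sqrt2
        cm = _cm([[10, 20]] * 3, groups=("a", "a"))
        np.testing.assert_allclose(
            size_factors(cm), [1 / math.sqrt(2), math.sqrt(2)], rtol=1e-12
        )

    def test_no_universally_expressed_gene_errors(self):
        cm = _cm([[0, 5], [5, 0]], groups=("a", "a"))
        with pytest.raises(ValueError, match="filter"):
            size_factors(cm)


class TestBhAdjust:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.04]), [0.04])

    def test_stepup_with_monotone_enforcement(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03] * 3)

    def test_all_ones_stay_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_bounds_and_sorted_monotonicity(self, ps):
        q = bh_adjust(ps)
        assert ((q >= np.asarray(ps) - 1e-12) & (q <= 1.0)).all()
        order = np.argsort(ps)
        assert (np.diff(np.asarray(q)[order]) >= -1e-12).all()


class TestNbWaldTest:
    def test_identical_groups_give_zero_log2fc(self):
        cm = _cm([[7, 7, 7, 7], [30, 30, 30, 30], [2, 9, 2, 9]])
        res = nb_wald_test(cm, "a", "b")
        assert res[0].log2fc == 0.0
        assert res[1].log2fc == 0.0

    def test_single_sample_group_rejected(self):
        cm = _cm([[5, 5, 5]], groups=("a", "a", "b"))
        with pytest.raises(ValueError, match="2 samples"):
            nb_wald_test(cm, "a", "b")

    def test_null_type_one_error_calibrated(self):
        cm, _, _ = gen_expression_experiment(
            n_genes=2000, n_per_group=3, frac_enriched=0.0, seed=101
        )
        res = nb_wald_test(cm, "neun_neg", "neun_pos")
        frac = np.mean([r.p < 0.05 for r in res])
        assert 0.03 <= frac <= 0.07

    def test_planted_log2fc_recovered(self):
        cm, _, truth = gen_expression_experiment(
            n_genes=1000, planted_log2fc=4.0, dispersion=0.05, seed=7
        )
        res = {r.gene_id: r.log2fc for r in nb_wald_test(cm, "neun_neg", "neun_pos")}
        neg_mean = dict(zip(cm.gene_ids, cm.counts[:, :3].mean(axis=1)))
        within = [
            abs(res[g] - 4.0) <= 0.5
            for g in truth.enriched_gene_ids
            if neg_mean[g] >= 100  # counting noise dominates below
        ]
        assert np.mean(within) >= 0.9

    def test_column_scaling_absorbed_by_normalization(self):
        # multiplying one sample's counts by c rescales every normalized
        # count by c^(1/n); the fixed pseudo-mean then perturbs log2FC by
        # at most ~0.5/mu per group, which bounds the comparison here
        cm, _, _ = gen_expression_experiment(n_genes=400, seed=3)
        res0 = {r.gene_id: r.log2fc for r in nb_wald_test(cm, "neun_neg", "neun_pos")}
        scaled = cm.counts.copy()
        scaled[:, 0] *= 3
        cm2 = CountMatrix(
            cm.gene_ids, cm.sample_ids, scaled, cm.group_of, cm.biotype_of
        )
        res1 = {r.gene_id: r.log2fc for r in nb_wald_test(cm2, "neun_neg", "neun_pos")}
        diffs = [abs(res0[g] - res1[g]) for g in res0]
        assert max(diffs) < 0.05


class TestFilterEnriched:
    def _results(self):
        from lncfunnel.expression import DiffResult

        return [
            DiffResult("hit", 100, 3.5, 0.1, 1e-6, 0.01),
            DiffResult("padj_boundary", 100, 3.5, 0.1, 0.04, 0.05),
            DiffResult("fc_boundary", 100, 3.0, 0.1, 1e-6, 0.01),
            DiffResult("coding", 100, 5.0, 0.1, 1e-6, 0.01),
        ]

    def test_strict_thresholds_and_biotype(self):
        biotypes = {
            "hit": "lncRNA",
            "padj_boundary": "lncRNA",
            "fc_boundary": "lncRNA",
            "coding": "protein_coding",
        }
        assert filter_enriched(self._results(), biotypes) == ["hit"]

    def test_planted_recovery_sensitivity_and_fdp(self):
        cm, _, truth = gen_expression_experiment(seed=11)
        res = nb_wald_test(cm, "neun_neg", "neun_pos")
        called = set(filter_enriched(res, cm.biotype_of))
        tp = len(called & truth.enriched_gene_ids)
        assert tp / len(truth.enriched_gene_ids) >= 0.9
        assert (len(called) - tp) / max(len(called), 1) <= 0.1


class TestTau:
    def _profile(self, expr, brain=("t0",)):
        expr = np.atleast_2d(np.asarray(expr, dtype=float))
        tissues = [f"t{i}" for i in range(expr.shape[1])]
        genes = [f"g{i}" for i in range(expr.shape[0])]
        return TissueProfile(genes, tissues, expr, frozenset(brain))

    def test_single_tissue_expression_gives_one(self):
        t = tau_specificity(self._profile([0, 0, 5, 0, 0]))
        assert t["tau"].iloc[0] == pytest.approx(1.0)

    def test_uniform_expression_gives_zero(self):
        t = tau_specificity(self._profile([3, 3, 3, 3]))
        assert t["tau"].iloc[0] == pytest.approx(0.0)

    def test_worked_example(self):
        t = tau_specificity(self._profile([8, 2, 2, 2, 2]))
        assert t["tau"].iloc[0] == pytest.approx(0.75)

    def test_all_zero_gene_flagged_not_enriched(self):
        t = tau_specificity(self._profile([0, 0, 0]))
        assert math.isnan(t["tau"].iloc[0])
        assert not t["brain_enriched"].iloc[0]

    def test_brain_flag_requires_brain_argmax_and_high_tau(self):
        expr = [[9, 0, 0, 0, 0], [0, 9, 0, 0, 0], [5, 4, 4, 4, 4]]
        t = tau_specificity(self._profile(expr, brain=("t0",)))
        assert list(t["brain_enriched"]) == [True, False, False]

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(st.floats(0.01, 1e4), min_size=2, max_size=10),
        st.floats(0.01, 100.0),
    )
    def test_in_unit_interval_and_scale_invariant(self, expr, scale):
        t1 = tau_specificity(self._profile(expr))["tau"].iloc[0]
        t2 = tau_specificity(self._profile([x * scale for x in expr]))["tau"].iloc[0]
        assert 0.0 <= t1 <= 1.0
        assert t1 == pytest.approx(t2, rel=1e-9)


class TestHypergeom:
    def test_exact_value_one_over_252(self):
        universe = {f"u{i}" for i in range(10)}
        annotation = {f"u{i}" for i in range(5)}
        k, p = hypergeom_enrichment(annotation, annotation, universe)
        assert k == 5
        assert p == pytest.approx(1 / 252, abs=1e-12)

    def test_empty_query_gives_one(self):
        universe = {"a", "b", "c"}
        k, p = hypergeom_enrichment(set(), {"a"}, universe)
        assert (k, p) == (0, 1.0)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_enrichment(set(), set(), set())

    def test_matches_enumeration_oracle_on_small_universes(self):
        from itertools import combinations

        rng = np.random.default_rng(5)
        for _ in range(20):
            m = int(rng.integers(2, 12))
            universe = set(range(m))
            ann = set(rng.choice(m, size=int(rng.integers(1, m + 1)), replace=False).tolist())
            nq = int(rng.integers(1, m + 1))
            query = set(rng.choice(m, size=nq, replace=False).tolist())
            k = len(query & ann)
            hits = sum(
                1 for draw in combinations(sorted(universe), nq)
                if len(set(draw) & ann) >= k
            )
            expected = hits / math.comb(m, nq)
            _, p = hypergeom_enrichment(
                {str(q) for q in query},
                {str(a) for a in ann},
                {str(u) for u in universe},
            )
            assert p == pytest.approx(expected, rel=1e-9)


class TestQpcr:
    def _table(self, rows):
        return pd.DataFrame(
            rows, columns=["sample_id", "condition", "ct_target", "ct_reference"]
        )

    def test_equal_cts_give_unit_fold(self):
        t = self._table([("s1", "ctl", 20, 20), ("s2", "trt", 20, 20)])
        fold = ddct_fold_change(t, "trt", "ctl")
        assert fold["s2"] == pytest.approx(1.0)

    def test_worked_folds_half_and_four(self):
        t = self._table(
            [("c1", "ctl", 24, 20), ("down", "trt", 25, 20), ("up", "trt", 22, 20)]
        )
        fold = ddct_fold_change(t, "trt", "ctl")
        assert fold["down"] == pytest.approx(0.5)
        assert fold["up"] == pytest.approx(4.0)

    def test_missing_reference_ct_rejected(self):
        t = self._table([("c1", "ctl", 24, np.nan), ("s", "trt", 22, 20)])
        with pytest.raises(ValueError, match="missing Ct"):
            ddct_fold_change(t, "trt", "ctl")

    def test_percent_input_examples(self):
        assert percent_input(20.0, 20.0, 0.1) == pytest.approx(10.0)
        assert percent_input(20.0 - math.log2(10), 20.0, 0.1) == pytest.approx(100.0)

    def test_percent_input_fraction_validated(self):
        with pytest.raises(ValueError):
            percent_input(20, 20, 0.0)
        with pytest.raises(ValueError):
            percent_input(20, 20, 1.0)
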