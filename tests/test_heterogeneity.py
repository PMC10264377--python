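"""Heterogeneity statistics: GMM, percentiles, subtype calls, bins."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import histomil as hm
from histomil.exceptions import DegenerateDataError


class TestGMM1D:
    def test_planted_mixture_recovered(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(0, 0.1, 500), rng.normal(1, 0.1, 500)])
        fit = hm.fit_gmm_1d(x)
        assert abs(fit.means[0] - 1.0) <= 0.05
        assert abs(fit.means[1] - 0.0) <= 0.05
        assert fit.weights.sum() == pytest.approx(1.0)

    def test_two_point_masses(self):
        fit = hm.fit_gmm_1d(np.array([0.0, 0, 0, 1, 1, 1]))
        np.testing.assert_allclose(fit.means, [1.0, 0.0], atol=1e-6)
        np.testing.assert_allclose(fit.weights, [0.5, 0.5], atol=1e-6)

    def test_loglik_nondecreasing(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            x = rng.normal(size=rng.integers(10, 200)) ** rng.integers(1, 3)
            trace = np.array(hm.fit_gmm_1d(x).loglik_trace)
            assert np.all(np.diff(trace) >= -1e-8)

    def test_responsibilities_rows_sum_to_one(self):
        x = np.random.default_rng(2).normal(size=60)
        fit = hm.fit_gmm_1d(x)
        np.testing.assert_allclose(fit.responsibilities.sum(axis=1), 1.0)

    def test_matches_sklearn_on_well_separated_data(self):
        from sklearn.mixture import GaussianMixture
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(-2, 0.3, 300), rng.normal(2, 0.3, 300)])
        fit = hm.fit_gmm_1d(x)
        sk = GaussianMixture(2, random_state=0).fit(x[:, None])
        sk_means = np.sort(sk.means_.ravel())[::-1]
        np.testing.assert_allclose(fit.means, sk_means, atol=0.05)

    def test_too_few_points_error(self):
        with pytest.raises(ValueError):
            hm.fit_gmm_1d(np.array([1.0, 2.0, 3.0]))

    def test_identical_values_degenerate(self):
        with pytest.raises(DegenerateDataError):
            hm.fit_gmm_1d(np.full(20, 0.7))


class TestPercentileScores:
    def test_linear_interpolation_0_to_100(self):
        b99, c99 = hm.percentile_scores(np.arange(101.0), np.arange(101.0))
        assert b99 == pytest.approx(99.0)

    def test_constant_scores(self):
        b99, _ = hm.percentile_scores(np.full(10, 0.3), np.full(10, 0.3))
        assert b99 == 0.3

    def test_single_tile(self):
        assert hm.percentile_scores([0.8], [0.2]) == (0.8, 0.2)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            hm.percentile_scores([], [])


def archetype_cohort():
    """Constructed 40-patient cohort with unambiguous archetype geometry."""
    blocks = [((0.95, 0.05), "main_basal"), ((0.05, 0.95), "main_classical"),
              ((0.9, 0.9), "hybrid"), ((0.45, 0.5), "intermediary")]
    ids, p99b, p99c, truth = [], [], [], []
    rng = np.random.default_rng(0)
    for (b, c), name in blocks:
        for i in range(10):
            ids.append(f"{name}_{i}")
            p99b.append(b + rng.normal(0, 0.005))
            p99c.append(c + rng.normal(0, 0.005))
            truth.append(name)
    return ids, np.array(p99b), np.array(p99c), truth


class TestCallSubtypes:
    def test_constructed_cohort_fully_recovered(self):
        ids, p99b, p99c, truth = archetype_cohort()
        res = hm.call_subtypes(ids, p99b, p99c)
        assert [c.subtype for c in res.calls] == truth
        cts = res.counts()
        assert cts.tolist() == [10, 10, 10, 10]

    def test_call_fields_consistent(self):
        ids, p99b, p99c, _ = archetype_cohort()
        res = hm.call_subtypes(ids, p99b, p99c)
        for c in res.calls:
            assert c.delta == pytest.approx(abs(c.p99_bas - c.p99_cla))
            assert c.max_level == pytest.approx(max(c.p99_bas, c.p99_cla))
            if c.clear:
                assert c.subtype in ("main_classical", "main_basal")

    def test_partition_exhaustive_and_exclusive(self):
        ids, p99b, p99c, _ = archetype_cohort()
        tab = hm.call_subtypes(ids, p99b, p99c).table
        assert tab["subtype"].isin(hm.heterogeneity.SUBTYPES).all()
        assert len(tab) == len(ids)

    def test_patient_order_invariance(self):
        ids, p99b, p99c, _ = archetype_cohort()
        perm = np.random.default_rng(1).permutation(len(ids))
        res1 = hm.call_subtypes(ids, p99b, p99c)
        res2 = hm.call_subtypes([ids[i] for i in perm], p99b[perm], p99c[perm])
        m1 = {c.patient_id: c.subtype for c in res1.calls}
        m2 = {c.patient_id: c.subtype for c in res2.calls}
        assert m1 == m2

    def test_cohort_duplication_invariance(self):
        ids, p99b, p99c, _ = archetype_cohort()
        res1 = hm.call_subtypes(ids, p99b, p99c)
        ids2 = ids + [f"{i}_dup" for i in ids]
        res2 = hm.call_subtypes(ids2, np.tile(p99b, 2), np.tile(p99c, 2))
        for c1, c2 in zip(res1.calls, res2.calls[: len(ids)]):
            assert c1.subtype == c2.subtype
        assert res2.cutoff == pytest.approx(res1.cutoff, abs=1e-6)

    def test_identical_patients_surface_degenerate_error(self):
        with pytest.raises(DegenerateDataError):
            hm.call_subtypes([f"p{i}" for i in range(10)],
                             np.full(10, 0.5), np.full(10, 0.5))

    def test_small_cohort_rejected(self):
        with pytest.raises(ValueError):
            hm.call_subtypes(["a", "b"], [0.1, 0.9], [0.9, 0.1])

    def test_cutoff_override(self):
        ids, p99b, p99c, _ = archetype_cohort()
        res = hm.call_subtypes(ids, p99b, p99c, cutoff=2.0)
        # nothing can reach a cutoff of 2 -> no hybrids
        assert res.counts()["hybrid"] == 0


class TestClearRNASubtype:
    def test_matches_median_filter_oracle(self):
        rng = np.random.default_rng(0)
        b, c = rng.normal(size=50), rng.normal(size=50)
        clear = hm.clear_rna_subtype(b, c)
        zb = (b - b.mean()) / b.std()
        zc = (c - c.mean()) / c.std()
        d = np.abs(zb - zc)
        np.testing.assert_array_equal(clear, d > np.median(d))

    def test_all_equal_differences_none_clear(self):
        # identical scaled components give d = 0 everywhere; strict ">"
        # above the median means nobody qualifies
        b = np.array([0.0, 1.0, 2.0, 3.0])
        clear = hm.clear_rna_subtype(b, b.copy())
        assert not clear.any()

    def test_at_most_half_clear_even_cohort(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = int(rng.integers(2, 30)) * 2
            clear = hm.clear_rna_subtype(rng.normal(size=n),
                                         rng.normal(size=n))
            assert clear.sum() <= n // 2

    def test_zero_variance_names_component(self):
        with pytest.raises(DegenerateDataError, match="classical"):
            hm.clear_rna_subtype(np.array([1.0, 2.0]), np.array([3.0, 3.0]))


class TestMacroClassicalCall:
    @pytest.mark.parametrize("scores,want", [
        ((0.05, 0.1), "pure"), ((0.05, 0.6), "mixed"), ((0.2,), "mixed"),
        ((0.19999,), "pure")])
    def test_cases(self, scores, want):
        assert hm.macro_classical_call(scores) == want

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=10),
           st.floats(0, 1))
    def test_adding_slide_never_unmixes(self, scores, extra):
        before = hm.macro_classical_call(scores)
        after = hm.macro_classical_call(scores + [extra])
        assert not (before == "mixed" and after == "pure")


class TestBasalFraction:
    def test_bin_edges(self):
        def frac_to_bin(f):
            n = 1000
            scores = np.concatenate([np.ones(int(round(f * n))),
                                     np.zeros(n - int(round(f * n)))])
            return hm.basal_fraction(scores, 0.5)[1]
        assert frac_to_bin(0.03) == "lt5"
        assert frac_to_bin(0.05) == "5to20"
        assert frac_to_bin(0.5) == "gt20"

    def test_none_above_threshold(self):
        frac, b = hm.basal_fraction(np.full(20, 0.1), 0.5)
        assert frac == 0.0 and b == "lt5"

    def test_all_above_threshold(self):
        frac, b = hm.basal_fraction(np.full(20, 0.9), 0.5)
        assert frac == 1.0 and b == "gt20"

    def test_classical_comparison_rule(self):
        b = np.array([0.9, 0.9, 0.9, 0.1])
        c = np.array([0.95, 0.1, 0.1, 0.0])
        frac, _ = hm.basal_fraction(b, 0.5, c)
        assert frac == pytest.approx(0.5)   # first tile loses to classical

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50),
           st.floats(0, 1), st.floats(0, 1))
    def test_non_increasing_in_threshold(self, scores, t1, t2):
        lo, hi = min(t1, t2), max(t1, t2)
        f_lo, _ = hm.basal_fraction(np.array(scores), lo)
        f_hi, _ = hm.basal_fraction(np.array(scores), hi)
        assert f_hi <= f_lo

    def test_cohort_table(self):
        tab = hm.cohort_basal_fractions(
            ["a", "b"], [np.array([0.0, 10.0]), np.array([0.0, 0.0])])
        assert set(tab["patient_id"]) == {"a", "b"}
        assert tab.loc[tab.patient_id == "a", "basal_fraction"].item() == 0.5
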