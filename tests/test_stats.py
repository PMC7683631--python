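"""Separation statistics: tests, ROC/AUC, logistic cutoff, results grid."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from petquant.corrections import correct_cohort
from petquant.kras import assign_labels
from petquant.rc_model import PsfModel, model_rc_curve
from petquant.stats import (
    auc_mann_whitney,
    build_results_grid,
    logistic_cutoff,
    roc,
    t_test,
    t_test_from_summary,
    wilcoxon_rank_sum,
)
from petquant.synth import CohortParams, generate_forward_model, table3_moments


class TestTTest:
    def test_identical_groups_give_p_one(self):
        res = t_test([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        assert res.p_value == 1.0 and res.flagged

    def test_summary_row_reproduces_headline_bound(self):
        # threshold-segmentation fully corrected SUR_MAX cohort moments
        res = t_test_from_summary(3.47, 1.79, 36, 5.23, 1.79, 24)
        assert res.p_value <= 0.001

    def test_pooled_equals_scipy_on_moment_matched_sample(self):
        rng = np.random.default_rng(1)
        for variant in ("student_pooled", "welch"):
            for m0, s0, n0, m1, s1, n1 in [(3.0, 1.0, 12, 4.2, 1.5, 9),
                                           (5.5, 2.0, 36, 5.5, 2.0, 24)]:
                z0 = rng.normal(size=n0)
                z0 = (z0 - z0.mean()) / z0.std(ddof=1)
                z1 = rng.normal(size=n1)
                z1 = (z1 - z1.mean()) / z1.std(ddof=1)
                raw = t_test(m0 + s0 * z0, m1 + s1 * z1, variant)
                summ = t_test_from_summary(m0, s0, n0, m1, s1, n1, variant)
                assert raw.p_value == pytest.approx(summ.p_value, rel=1e-12)

    def test_equal_means_from_summary_give_p_one(self):
        assert t_test_from_summary(4.0, 1.0, 10, 4.0, 2.0, 10).p_value == pytest.approx(1.0)

    def test_permutation_null_p_values_are_uniform(self):
        rng = np.random.default_rng(4)
        pooled = rng.normal(5.0, 1.5, size=24)
        ps = []
        for _ in range(2000):
            perm = rng.permutation(pooled)
            ps.append(t_test(perm[:12], perm[12:]).p_value)
        ps = np.asarray(ps)
        assert abs((ps < 0.05).mean() - 0.05) < 0.02
        assert abs((ps < 0.5).mean() - 0.5) < 0.05

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValueError):
            t_test([1.0], [2.0, 3.0])


class TestWilcoxon:
    def test_identical_groups_flagged_p_one(self):
        res = wilcoxon_rank_sum([3.0, 3.0], [3.0, 3.0])
        assert res.p_value == 1.0 and res.flagged

    def test_matches_exact_enumeration_within_approximation_error(self):
        v0, v1 = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        # exact two-sided p by enumerating all C(6,3) group assignments
        pooled = v0 + v1
        observed = sum(v1)
        more_extreme = 0
        total = 0
        for comb in itertools.combinations(range(6), 3):
            s = sum(pooled[i] for i in comb)
            total += 1
            if abs(s - 10.5) >= abs(observed - 10.5) - 1e-12:
                more_extreme += 1
        exact = more_extreme / total
        assert exact == pytest.approx(0.1)
        approx = wilcoxon_rank_sum(v0, v1).p_value
        assert abs(approx - exact) < 0.025  # continuity-corrected normal approximation

    @settings(deadline=None, max_examples=50)
    @given(st.data())
    def test_invariant_under_monotone_transform(self, data):
        # integer-spaced values stay distinct through the transform, so the
        # rank pattern (and hence the p-value) must be unchanged
        ints = st.lists(st.integers(1, 500), min_size=3, max_size=10, unique=True)
        v0 = np.array(data.draw(ints), dtype=float) * 0.37
        v1 = np.array(data.draw(ints), dtype=float) * 0.37 + 0.11
        p_raw = wilcoxon_rank_sum(v0, v1).p_value
        p_log = wilcoxon_rank_sum(np.log(v0), np.log(v1)).p_value
        assert p_raw == pytest.approx(p_log, rel=1e-9)


class TestRoc:
    def test_perfect_separation(self):
        r = roc([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert r.auc == 1.0

    def test_identical_values_give_half(self):
        assert auc_mann_whitney([2.0, 2.0], [2.0, 2.0]) == 0.5

    def test_interleaved_enumeration(self):
        # pairs: (1,2)+, (1,4)+, (3,2)-, (3,4)+ -> 3/4 concordant
        assert auc_mann_whitney([1.0, 3.0], [2.0, 4.0]) == pytest.approx(0.75)

    def test_complement_symmetry_without_ties(self):
        rng = np.random.default_rng(2)
        v0, v1 = rng.normal(0, 1, 15), rng.normal(1, 1, 11)
        assert auc_mann_whitney(v0, v1) + auc_mann_whitney(v1, v0) == pytest.approx(1.0)

    def test_matches_independent_rank_implementation(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(3)
        v0, v1 = rng.normal(0, 1, 30), rng.normal(0.8, 1.3, 20)
        y = np.r_[np.zeros(30), np.ones(20)]
        assert auc_mann_whitney(v0, v1) == pytest.approx(
            roc_auc_score(y, np.r_[v0, v1]), rel=1e-12
        )

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        v0, v1 = rng.normal(2, 1, 12), rng.normal(3, 1, 10)
        assert auc_mann_whitney(v0, v1) == pytest.approx(
            auc_mann_whitney(np.exp(v0), np.exp(v1)), rel=1e-12
        )

    def test_binormal_convergence(self):
        # empirical AUC converges to Phi(d') for binormal groups; averaging a
        # few n=6000 draws keeps the sampling SE well under the tolerance
        rng = np.random.default_rng(6)
        mu0, mu1, s0, s1 = 0.0, 1.0, 1.0, 1.5
        n = 6000
        estimates = [
            auc_mann_whitney(rng.normal(mu0, s0, n), rng.normal(mu1, s1, n))
            for _ in range(5)
        ]
        analytic = norm.cdf((mu1 - mu0) / np.hypot(s0, s1))
        assert np.mean(estimates) == pytest.approx(analytic, abs=0.01)


def _brute_force_logistic(x, y, span=6.0, stages=4, n_grid=101):
    """Independent ML oracle: nested grid search over (intercept, slope)."""
    b0, b1, h0, h1 = 0.0, 0.0, span, span
    for _ in range(stages):
        g0 = np.linspace(b0 - h0, b0 + h0, n_grid)
        g1 = np.linspace(b1 - h1, b1 + h1, n_grid)
        z = g0[:, None, None] + g1[None, :, None] * x[None, None, :]
        ll = (y * z - np.logaddexp(0.0, z)).sum(axis=-1)
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        b0, b1 = g0[i], g1[j]
        h0 = 4 * (g0[1] - g0[0])
        h1 = 4 * (g1[1] - g1[0])
    return b0, b1


class TestLogisticCutoff:
    def test_coefficients_match_grid_search_oracle(self):
        v0 = np.array([1.0, 2.0, 2.5, 3.1, 3.6])
        v1 = np.array([2.2, 3.0, 3.5, 4.4, 5.0])
        res = logistic_cutoff(v0, v1)
        x = np.r_[v0, v1]
        y = np.r_[np.zeros(5), np.ones(5)]
        b0, b1 = _brute_force_logistic(x, y)
        assert res.intercept == pytest.approx(b0, abs=1e-3)
        assert res.slope == pytest.approx(b1, abs=1e-3)
        assert res.converged

    def test_symmetric_groups_cut_near_zero(self):
        rng = np.random.default_rng(7)
        v0 = rng.normal(-1.0, 1.0, 400)
        v1 = rng.normal(1.0, 1.0, 400)
        res = logistic_cutoff(v0, v1)
        assert abs(res.cutoff) < 0.25
        assert abs(res.p50_crossing) < 0.15

    def test_complete_separation_flagged_with_roc_cutoff(self):
        res = logistic_cutoff([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert not res.converged
        assert res.sensitivity == 1.0 and res.specificity == 1.0
        assert 3.0 < res.cutoff <= 4.0

    def test_youden_point_consistent_with_reported_sens_spec(self):
        rng = np.random.default_rng(8)
        v0 = rng.normal(3.4, 1.7, 36)
        v1 = rng.normal(5.1, 1.7, 24)
        res = logistic_cutoff(v0, v1)
        sens = (v1 >= res.cutoff).mean()
        spec = (v0 < res.cutoff).mean()
        assert res.sensitivity == pytest.approx(sens)
        assert res.specificity == pytest.approx(spec)


@pytest.fixture(scope="module")
def corrected_cohort():
    psf = PsfModel(6.5)
    curves = {s: model_rc_curve(psf, s) for s in ("mean", "peak", "max")}
    coh = generate_forward_model(CohortParams(), curves, seed=13)
    out = correct_cohort(coh, curves)
    labels = assign_labels(out["kras_annotation"].fillna("").tolist())
    return out, labels


class TestResultsGrid:
    def test_grid_covers_all_family_statistic_cells(self, corrected_cohort):
        out, labels = corrected_cohort
        grid = build_results_grid(out, labels)
        assert len(grid) == 18  # 6 families x 3 statistics, one segmentation
        assert ((grid["auc"] >= 0) & (grid["auc"] <= 1)).all()
        assert ((grid["t_p"] > 0) & (grid["t_p"] <= 1)).all()

    def test_grid_is_deterministic(self, corrected_cohort):
        out, labels = corrected_cohort
        a = build_results_grid(out, labels)
        b = build_results_grid(out, labels)
        pd.testing.assert_frame_equal(a, b)

    def test_label_permutation_destroys_separation(self, corrected_cohort):
        out, labels = corrected_cohort
        rng = np.random.default_rng(9)
        aucs = []
        for _ in range(40):
            perm = rng.permutation(labels)
            grid = build_results_grid(out, perm, families=("sur_pvec_time",),
                                      statistics=("max",))
            aucs.append(grid["auc"].iloc[0])
        assert abs(np.mean(aucs) - 0.5) < 0.05

    def test_empty_group_after_filter_is_named(self, corrected_cohort):
        out, labels = corrected_cohort
        subset = np.asarray(labels) == 0  # removes every positive lesion
        with pytest.raises(ValueError, match="no-positives"):
            build_results_grid(out, labels, subset=subset, subset_name="no-positives")


def test_published_moment_rows_give_headline_bounds():
    """Fully corrected SUR rows: pooled and Welch p at the inferred 36/24 split."""
    mom = table3_moments()
    rows = mom[(mom["family"] == "sur_pvec_time") & (mom["statistic"] == "max")]
    assert len(rows) == 2
    for _, r in rows.iterrows():
        for variant in ("student_pooled", "welch"):
            p = t_test_from_summary(
                r["mean_wt"], r["sd_wt"], 36, r["mean_mut"], r["sd_mut"], 24, variant
            ).p_value
            assert p <= 0.001
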