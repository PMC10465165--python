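"""Wasserstein learning ranking: eigenvariate extraction, kernel density
estimation, the W1 metric's analytic cases and properties, and cohort
ranking behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nfdcm.generative_model import RoiTimeSeries
from nfdcm.learning_ranking import (
    kde_density,
    mean_sma_activity,
    principal_eigenvariate,
    rank_cohort,
    wasserstein_1d,
    wasserstein_samples,
)


class TestPrincipalEigenvariate:
    def test_single_voxel_identity(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(1, 50))
        ts = principal_eigenvariate(x)
        centred = x[0] - x[0].mean()
        assert np.corrcoef(ts, centred)[0, 1] == pytest.approx(1.0)
        np.testing.assert_allclose(ts, centred, atol=1e-12)

    def test_rank_one_matrix_recovers_temporal_factor(self):
        rng = np.random.default_rng(1)
        temporal = rng.normal(size=80)
        spatial = rng.uniform(0.5, 2.0, size=30)
        X = np.outer(spatial, temporal) + rng.normal(0, 1e-6, size=(30, 80))
        ts = principal_eigenvariate(X)
        r = abs(np.corrcoef(ts, temporal)[0, 1])
        assert r >= 0.999

    def test_sign_aligned_with_roi_mean(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            X = rng.normal(size=(12, 40))
            ts = principal_eigenvariate(X)
            mean_ts = (X - X.mean(axis=1, keepdims=True)).mean(axis=0)
            assert np.dot(ts, mean_ts) >= 0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="eigenvariate"):
            principal_eigenvariate(np.zeros((5, 20)))


def _run(data, labels=None):
    return RoiTimeSeries(data=data, TR=1.5, condition_labels=labels)


class TestMeanSmaActivity:
    def test_constant_series(self):
        run = _run(np.full((4, 10), 3.0))
        np.testing.assert_array_equal(mean_sma_activity(run), np.full(10, 3.0))

    def test_block_scope_counts(self):
        labels = ["baseline"] * 20 + ["up-regulation"] * 20 + ["baseline"] * 20
        run = _run(np.arange(240).reshape(4, 60).astype(float), labels)
        assert mean_sma_activity(run, "up-regulation").size == 20
        assert mean_sma_activity(run, "baseline").size == 40
        assert mean_sma_activity(run, "all").size == 60

    def test_empty_scope_rejected(self):
        run = _run(np.zeros((4, 5)), ["baseline"] * 5)
        with pytest.raises(ValueError, match="selects no volumes"):
            mean_sma_activity(run, "up-regulation")


class TestKDE:
    def test_standard_normal_density_at_zero(self):
        rng = np.random.default_rng(0)
        d = kde_density(rng.normal(size=10_000))
        at0 = np.interp(0.0, d.grid, d.pdf)
        assert at0 == pytest.approx(1 / np.sqrt(2 * np.pi), rel=0.05)

    def test_grid_integral_normalised(self):
        rng = np.random.default_rng(1)
        d = kde_density(rng.exponential(size=500))
        assert np.trapezoid(d.pdf, d.grid) == pytest.approx(1.0, abs=1e-6)

    def test_degenerate_samples_flagged(self):
        d = kde_density(np.full(10, 2.5))
        assert d.degenerate and d.point == 2.5

    def test_shared_grid_spans_both_sets(self):
        a = np.random.default_rng(2).normal(0, 1, 200)
        b = np.random.default_rng(3).normal(5, 1, 200)
        da = kde_density(a, other=b)
        db = kde_density(b, other=a)
        np.testing.assert_allclose(da.grid, db.grid)
        assert da.grid[0] < a.min() and da.grid[-1] > b.max()


class TestWasserstein:
    def test_identical_distributions_zero(self):
        x = np.random.default_rng(0).normal(size=300)
        d1 = kde_density(x)
        d2 = kde_density(x.copy())
        assert wasserstein_1d(d1, d2) == pytest.approx(0.0, abs=1e-12)

    def test_point_masses_analytic(self):
        a = kde_density(np.full(5, 1.0))
        b = kde_density(np.full(5, 3.5))
        assert wasserstein_1d(a, b) == pytest.approx(2.5)

    def test_shifted_normals_recover_shift(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 10_000)
        y = rng.normal(0.7, 1, 10_000)
        da = kde_density(x, other=y)
        db = kde_density(y, other=x)
        assert wasserstein_1d(da, db) == pytest.approx(0.7, abs=0.05)
        assert wasserstein_samples(x, y) == pytest.approx(0.7, abs=0.05)

    def test_kde_route_agrees_with_raw_samples(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 2000)
        y = rng.gamma(2.0, 1.0, 2000)
        da = kde_density(x, other=y)
        db = kde_density(y, other=x)
        assert wasserstein_1d(da, db) == pytest.approx(
            wasserstein_samples(x, y), abs=0.1
        )

    def test_mismatched_grids_rejected(self):
        a = kde_density(np.random.default_rng(6).normal(size=100))
        b = kde_density(np.random.default_rng(7).normal(10, 1, size=100))
        with pytest.raises(ValueError, match="common grid"):
            wasserstein_1d(a, b)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        mu=st.floats(-3, 3),
        delta=st.floats(-2, 2),
        seed=st.integers(0, 100),
    )
    def test_translation_equivariance(self, mu, delta, seed):
        x = np.random.default_rng(seed).normal(mu, 1, 400)
        y = x + delta
        da = kde_density(x, other=y)
        db = kde_density(y, other=x)
        assert wasserstein_1d(da, db) == pytest.approx(abs(delta), abs=0.05)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 500))
    def test_metric_properties_on_sample_triples(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 2), 300)
        y = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 2), 300)
        z = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 2), 300)
        dxy = wasserstein_samples(x, y)
        dyx = wasserstein_samples(y, x)
        dxz = wasserstein_samples(x, z)
        dzy = wasserstein_samples(z, y)
        assert dxy >= 0
        assert dxy == pytest.approx(dyx, abs=1e-12)
        assert dxy <= dxz + dzy + 1e-9


class TestRankCohort:
    @staticmethod
    def _cohort_runs(shifts, noise=0.3, n_vol=120, seed=0):
        rng = np.random.default_rng(seed)
        base, trans = {}, {}
        for i, delta in enumerate(shifts):
            sid = f"sub-{i:02d}"
            b = rng.normal(0, noise, size=(4, n_vol))
            t = rng.normal(delta, noise, size=(4, n_vol))
            base[sid] = _run(b)
            trans[sid] = _run(t)
        return base, trans

    def test_transfer_copy_of_baseline_is_tie(self):
        base, _ = self._cohort_runs([0.0])
        recs = rank_cohort(base, {k: v for k, v in base.items()})
        assert recs[0].signed_wd == 0.0
        assert recs[0].label == "non_learner"

    def test_shift_increases_signed_wd_proportionally(self):
        base, trans = self._cohort_runs([0.8, 0.0], noise=0.05)
        recs = {r.subject_id: r for r in rank_cohort(base, trans)}
        assert recs["sub-00"].signed_wd == pytest.approx(0.8, abs=0.05)
        assert abs(recs["sub-01"].signed_wd) < 0.1

    def test_ranks_descending_and_order_invariant(self):
        base, trans = self._cohort_runs([1.0, -0.5, 0.2, -1.2])
        recs = rank_cohort(base, trans)
        swd = [r.signed_wd for r in recs]
        assert swd == sorted(swd, reverse=True)
        shuffled_base = dict(reversed(list(base.items())))
        recs2 = rank_cohort(shuffled_base, trans)
        assert [r.subject_id for r in recs] == [r.subject_id for r in recs2]

    def test_sign_rule_vs_median_rule(self):
        base, trans = self._cohort_runs([1.0, 0.6, 0.4, 0.2], noise=0.02)
        sign_labels = {r.subject_id: r.label for r in rank_cohort(base, trans)}
        med_labels = {r.subject_id: r.label for r in rank_cohort(base, trans, rule="median")}
        assert all(lab == "learner" for lab in sign_labels.values())
        assert list(med_labels.values()).count("learner") == 2

    def test_missing_transfer_rejected(self):
        base, trans = self._cohort_runs([0.1, 0.2])
        trans.popitem()
        with pytest.raises(ValueError, match="transfer"):
            rank_cohort(base, trans)

    def test_recovers_simulated_learner_split(self, small_cohort):
        recs = rank_cohort(small_cohort.baseline_runs, small_cohort.transfer_runs)
        labels = small_cohort.labels()
        assert all(r.label == labels[r.subject_id] for r in recs)
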