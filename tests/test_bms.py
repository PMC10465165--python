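"""Random-effects BMS numerics: the Dirichlet fixed point against an
independent reference implementation, exceedance probabilities against the
Beta closed form, omnibus risk, protection, family-size correction and
model averaging."""

import numpy as np
import pytest
from scipy.special import digamma, logsumexp
from scipy.stats import beta as beta_dist

from nfdcm.bms import (
    attach_xp,
    bayesian_omnibus_risk,
    bma,
    exceedance_prob,
    family_inference,
    protected_xp,
    rfx_dirichlet,
)
from nfdcm.inversion import InversionResult
from nfdcm.model_space import FamilyPartition


def reference_rfx(log_ev, alpha0, n_iter=5000):
    """Deliberately slow, loop-based re-implementation of the same
    variational fixed point (the oracle for the vectorised code)."""
    n, K = log_ev.shape
    alpha = np.full(K, alpha0, dtype=float) + n / K
    for _ in range(n_iter):
        u = np.zeros((n, K))
        for i in range(n):
            logu = [
                log_ev[i, k] + digamma(alpha[k]) - digamma(alpha.sum())
                for k in range(K)
            ]
            logu = np.array(logu) - logsumexp(logu)
            u[i] = np.exp(logu)
        new = np.full(K, alpha0, dtype=float)
        for k in range(K):
            for i in range(n):
                new[k] += u[i, k]
        if np.max(np.abs(new - alpha)) < 1e-14:
            alpha = new
            break
        alpha = new
    return alpha


class TestRfxDirichlet:
    def test_matches_independent_reference(self):
        rng = np.random.default_rng(7)
        log_ev = rng.normal(scale=3.0, size=(12, 4))
        fit = rfx_dirichlet(log_ev, 1.0)
        ref = reference_rfx(log_ev, 1.0)
        np.testing.assert_allclose(fit.alpha, ref, atol=1e-6)

    def test_equal_evidence_symmetry(self):
        fit = rfx_dirichlet(np.zeros((6, 2)))
        np.testing.assert_allclose(fit.expected_freq, [0.5, 0.5], atol=1e-12)
        np.testing.assert_allclose(fit.alpha[0], fit.alpha[1])

    def test_single_subject_saturation(self):
        fit = rfx_dirichlet(np.array([[0.0, -100.0]]), alpha0=1.0)
        np.testing.assert_allclose(fit.expected_freq, [2 / 3, 1 / 3], atol=1e-9)

    def test_alpha_bounded_below_by_prior(self):
        rng = np.random.default_rng(1)
        fit = rfx_dirichlet(rng.normal(size=(9, 5)), alpha0=0.7)
        assert np.all(fit.alpha >= 0.7 - 1e-12)

    def test_subject_permutation_invariance(self):
        rng = np.random.default_rng(2)
        log_ev = rng.normal(size=(10, 3))
        a = rfx_dirichlet(log_ev).alpha
        b = rfx_dirichlet(log_ev[rng.permutation(10)]).alpha
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            rfx_dirichlet(np.array([[0.0, np.nan]]))


class TestExceedance:
    def test_exchangeable_pair(self):
        xp = exceedance_prob(np.array([1.0, 1.0]), n_samples=100_000, method="mc", seed=0)
        np.testing.assert_allclose(xp, [0.5, 0.5], atol=0.01)

    def test_dominant_component(self):
        xp = exceedance_prob(np.array([100.0, 1.0]), n_samples=1_000_000, method="mc", seed=1)
        assert abs(xp[0] - 1.0) < 0.001

    def test_k2_sampling_matches_beta_closed_form(self):
        alpha = np.array([3.0, 5.0])
        exact = exceedance_prob(alpha)  # Beta route
        assert exact[0] == pytest.approx(1 - beta_dist.cdf(0.5, 3, 5), abs=1e-12)
        mc = exceedance_prob(alpha, n_samples=1_000_000, method="mc", seed=2)
        assert abs(mc[0] - exact[0]) < 0.005

    def test_monte_carlo_error_scales_as_root_n(self):
        alpha = np.array([2.0, 1.5, 1.0])
        reps = {
            n: np.array(
                [
                    exceedance_prob(alpha, n_samples=n, method="mc", seed=s)[0]
                    for s in range(20)
                ]
            )
            for n in (2000, 32000)
        }
        ratio = reps[2000].std() / reps[32000].std()
        assert 2.0 < ratio < 8.0  # expected 4 = sqrt(16)

    def test_normalisation(self):
        xp = exceedance_prob(np.array([3.0, 2.0, 1.0]), n_samples=50_000, seed=3)
        assert xp.sum() == pytest.approx(1.0, abs=1e-9)


class TestOmnibusRisk:
    def test_uninformative_evidence_favours_null(self):
        assert bayesian_omnibus_risk(np.full((18, 3), 5.0)) > 0.8

    def test_consistent_preference_rejects_null(self):
        lev = np.zeros((18, 3))
        lev[:, 0] = 10.0
        assert bayesian_omnibus_risk(lev) < 0.05

    def test_row_shift_invariance(self):
        rng = np.random.default_rng(0)
        lev = rng.normal(size=(10, 4))
        shifted = lev + rng.normal(size=(10, 1)) * 50
        assert bayesian_omnibus_risk(lev) == pytest.approx(
            bayesian_omnibus_risk(shifted), abs=1e-9
        )


class TestProtectedXP:
    def test_limits(self):
        xp = np.array([0.9, 0.1])
        np.testing.assert_allclose(protected_xp(xp, 0.0), xp)
        np.testing.assert_allclose(protected_xp(xp, 1.0), [0.5, 0.5])
        np.testing.assert_allclose(protected_xp(xp, 0.5), [0.7, 0.3])

    def test_bounds_and_normalisation(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            K = rng.integers(2, 6)
            xp = rng.dirichlet(np.ones(K))
            bor = rng.uniform()
            pxp = protected_xp(xp, bor)
            assert pxp.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all(pxp >= bor / K - 1e-12)
            assert np.all(pxp <= 1 - bor * (K - 1) / K + 1e-12)

    def test_invalid_bor_rejected(self):
        with pytest.raises(ValueError, match="BOR"):
            protected_xp(np.array([0.5, 0.5]), 1.5)


class TestFamilyInference:
    PART = FamilyPartition(
        families={"a": [0, 1, 2], "b": [3, 4, 5, 6, 7], "c": [8, 9, 10]},
        level="second_step",
    )

    def test_size_correction_under_exchangeable_evidence(self):
        rng = np.random.default_rng(0)
        lev = np.tile(rng.normal(size=(12, 1)), (1, 11))  # identical across models
        fam = family_inference(lev, self.PART, n_samples=100_000)
        np.testing.assert_allclose(fam.expected_freq, 1 / 3, atol=1e-9)
        np.testing.assert_allclose(fam.pxp, 1 / 3, atol=0.01)

    def test_concentrated_evidence_identifies_family(self):
        rng = np.random.default_rng(1)
        lev = rng.normal(scale=0.01, size=(12, 11))
        lev[:, 3:8] += 10.0
        fam = family_inference(lev, self.PART, n_samples=100_000)
        assert fam.names[int(np.argmax(fam.pxp))] == "b"
        assert fam.pxp[1] > 0.95

    def test_partition_coverage_enforced(self):
        with pytest.raises(ValueError, match="cover"):
            family_inference(np.zeros((3, 12)), self.PART)

    def test_two_equal_families_symmetric(self):
        part = FamilyPartition(families={"x": [0, 1], "y": [2, 3]}, level="first_step")
        fam = family_inference(np.zeros((8, 4)), part, n_samples=100_000)
        np.testing.assert_allclose(fam.pxp, 0.5, atol=0.01)


def _mock_result(names, values):
    p = len(names)
    return InversionResult(
        posterior_mean=np.array(values, dtype=float),
        posterior_cov=np.eye(p),
        free_energy=0.0,
        fe_trace=[0.0],
        converged=True,
        names=list(names),
    )


class TestBMA:
    def test_single_model_scope_identity(self):
        r = _mock_result(["B[SMA<-F]"], [0.4])
        names, avg, w = bma([r], np.array([-3.0]), scope=[0])
        assert avg[names.index("B[SMA<-F]")] == pytest.approx(0.4)
        np.testing.assert_allclose(w, [1.0])

    def test_absent_parameter_halved_at_equal_evidence(self):
        r1 = _mock_result(["B[SMA<-F]"], [0.5])
        r2 = _mock_result(["B[ACC<-F]"], [0.2])
        names, avg, w = bma([r1, r2], np.array([1.0, 1.0]))
        assert avg[names.index("B[SMA<-F]")] == pytest.approx(0.25)
        assert avg[names.index("B[ACC<-F]")] == pytest.approx(0.1)

    def test_softmax_weights_hand_computed(self):
        rs = [_mock_result(["x"], [1.0]) for _ in range(3)]
        lev = np.array([0.0, -1.0, -2.0])
        _, _, w = bma(rs, lev)
        expected = np.exp(lev) / np.exp(lev).sum()
        np.testing.assert_allclose(w, expected, atol=1e-12)

    def test_empty_scope_rejected(self):
        with pytest.raises(ValueError, match="scope"):
            bma([], np.array([]), scope=[])


def test_attach_xp_roundtrip():
    rng = np.random.default_rng(0)
    lev = rng.normal(size=(8, 3))
    fit = rfx_dirichlet(lev)
    attach_xp(fit, lev, n_samples=50_000, seed=0)
    assert fit.xp is not None and fit.pxp is not None
    np.testing.assert_allclose(fit.pxp, protected_xp(fit.xp, fit.bor), atol=1e-12)
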