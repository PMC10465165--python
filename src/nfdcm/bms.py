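"""Random-effects Bayesian model selection and Bayesian model averaging.

The random-effects (RFX) scheme treats the model identity as a random
variable across subjects: population model frequencies ``r`` follow a
Dirichlet distribution whose concentrations are estimated from the
subjects' log evidences by a variational fixed point.  From the fitted
Dirichlet we report

* expected model frequencies ``alpha / sum(alpha)``,
* exceedance probabilities ``xp`` — the probability that a model (or
  family) is the most frequent in the population,
* the Bayesian omnibus risk ``BOR`` — the posterior probability of the
  null hypothesis that all frequencies are equal, and
* protected exceedance probabilities ``pxp = xp (1 - BOR) + BOR / K``.

Family-level inference pools models sharing a structural feature.  To
keep families comparable regardless of how many models they contain, the
within-family prior is uniform conditional on the family and each family
receives equal prior mass (the per-model prior concentration is
``1 / family size``).

Bayesian model averaging summarises each subject's parameters as the
posterior-model-probability-weighted average of the per-model posterior
means (uniform model prior within the averaging scope; a parameter absent
from a model contributes zero with full weight).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import betainc, digamma, gammaln, logsumexp

from .model_space import FamilyPartition

__all__ = [
    "BMSResult",
    "BMAResult",
    "rfx_dirichlet",
    "exceedance_prob",
    "bayesian_omnibus_risk",
    "protected_xp",
    "family_inference",
    "bma",
]


@dataclass
class BMSResult:
    """Dirichlet posterior summary over models or families."""

    alpha: np.ndarray
    expected_freq: np.ndarray
    xp: np.ndarray | None
    bor: float | None
    pxp: np.ndarray | None
    level: str = "model"  # "model" | "family"
    names: list[str] | None = None
    responsibilities: np.ndarray | None = None  # subjects x K
    free_energy_rfx: float | None = None
    free_energy_null: float | None = None

    def to_dict(self) -> dict:
        d = {
            "level": self.level,
            "names": self.names,
            "alpha": self.alpha.tolist(),
            "expected_freq": self.expected_freq.tolist(),
            "bor": self.bor,
        }
        for key in ("xp", "pxp"):
            v = getattr(self, key)
            d[key] = None if v is None else v.tolist()
        return d


@dataclass
class BMAResult:
    """Per-subject Bayesian-model-averaged parameters."""

    names: list[str]
    averaged: dict[str, np.ndarray]  # subject -> parameter vector
    weights: dict[str, np.ndarray]  # subject -> model weights
    scope: str = "all-models"

    def table(self):
        import pandas as pd

        return pd.DataFrame.from_dict(
            {s: dict(zip(self.names, v)) for s, v in self.averaged.items()}, orient="index"
        )


def _check_log_ev(log_ev: np.ndarray) -> np.ndarray:
    log_ev = np.asarray(log_ev, dtype=float)
    if log_ev.ndim != 2:
        raise ValueError("log evidence must be subjects x models")
    if not np.all(np.isfinite(log_ev)):
        raise ValueError("log evidence contains non-finite entries")
    return log_ev


def rfx_dirichlet(
    log_ev: np.ndarray,
    alpha0: float | np.ndarray = 1.0,
    max_iter: int = 500,
    tol: float = 1e-10,
) -> BMSResult:
    """Variational Dirichlet update for RFX model frequencies.

    Iterates subject responsibilities
    ``u_nk ∝ exp(log_ev_nk + psi(alpha_k) - psi(sum alpha))`` and
    ``alpha = alpha0 + sum_n u_nk`` to convergence.
    """
    log_ev = _check_log_ev(log_ev)
    n, K = log_ev.shape
    if K < 2:
        raise ValueError("need at least two models")
    alpha0 = np.broadcast_to(np.asarray(alpha0, dtype=float), (K,)).copy()
    if np.any(alpha0 <= 0):
        raise ValueError("alpha0 must be positive")
    alpha = alpha0.copy() + n / K
    u = np.full((n, K), 1.0 / K)
    for _ in range(max_iter):
        logu = log_ev + digamma(alpha)[None, :] - digamma(alpha.sum())
        logu -= logsumexp(logu, axis=1, keepdims=True)
        u = np.exp(logu)
        alpha_new = alpha0 + u.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new
    expected = alpha / alpha.sum()
    f1 = _rfx_free_energy(log_ev, alpha0, alpha, u)
    return BMSResult(
        alpha=alpha,
        expected_freq=expected,
        xp=None,
        bor=None,
        pxp=None,
        level="model",
        responsibilities=u,
        free_energy_rfx=f1,
    )


def _rfx_free_energy(
    log_ev: np.ndarray, alpha0: np.ndarray, alpha: np.ndarray, u: np.ndarray
) -> float:
    """Variational free energy of the Dirichlet RFX model at (alpha, u)."""
    elogr = digamma(alpha) - digamma(alpha.sum())
    data_term = float(np.sum(u * log_ev))
    assign_term = float(np.sum(u * elogr[None, :]))
    entropy_u = -float(np.sum(u[u > 0] * np.log(u[u > 0])))
    lnB = lambda a: float(np.sum(gammaln(a)) - gammaln(np.sum(a)))
    prior_term = -lnB(alpha0) + float(np.sum((alpha0 - 1) * elogr))
    q_term = -lnB(alpha) + float(np.sum((alpha - 1) * elogr))
    return data_term + assign_term + entropy_u + prior_term - q_term


def exceedance_prob(
    alpha: np.ndarray,
    n_samples: int = 1_000_000,
    seed: int | np.random.Generator = 0,
    method: str = "auto",
) -> np.ndarray:
    """P(frequency_k is the largest) under Dir(alpha).

    For K = 2 the exact Beta closed form is used (``method="auto"``);
    otherwise Dirichlet Monte Carlo with ``n_samples`` draws (ties, a
    probability-zero event, go to the first index).  ``method="mc"``
    forces sampling even for K = 2.
    """
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= 0):
        raise ValueError("alpha must be positive")
    K = alpha.size
    if K == 2 and method == "auto":
        # P(r1 > 0.5) under Beta(a1, a2) = 1 - I_{0.5}(a1, a2)
        p1 = 1.0 - betainc(alpha[0], alpha[1], 0.5)
        return np.array([p1, 1.0 - p1])
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    xp = np.zeros(K)
    chunk = 200_000
    remaining = int(n_samples)
    while remaining > 0:
        m = min(chunk, remaining)
        draws = rng.dirichlet(alpha, size=m)
        winners = np.argmax(draws, axis=1)
        xp += np.bincount(winners, minlength=K)
        remaining -= m
    return xp / n_samples


def bayesian_omnibus_risk(log_ev: np.ndarray, alpha0: float | np.ndarray = 1.0) -> float:
    """Posterior probability of the null (all model frequencies equal).

    Compares the free energy of the RFX model against the evidence of the
    fixed-uniform-frequency null; invariant to adding a constant to each
    subject's row.
    """
    log_ev = _check_log_ev(log_ev)
    n, K = log_ev.shape
    res = rfx_dirichlet(log_ev, alpha0)
    f1 = res.free_energy_rfx
    # null: each subject's model drawn from the fixed uniform frequency
    alpha0v = np.broadcast_to(np.asarray(alpha0, dtype=float), (K,))
    w0 = alpha0v / alpha0v.sum()
    f0 = float(np.sum(logsumexp(log_ev + np.log(w0)[None, :], axis=1)))
    return float(1.0 / (1.0 + np.exp(f1 - f0)))


def protected_xp(xp: np.ndarray, bor: float, K: int | None = None) -> np.ndarray:
    """pxp_k = xp_k (1 - BOR) + BOR / K."""
    xp = np.asarray(xp, dtype=float)
    if not 0.0 <= bor <= 1.0:
        raise ValueError("BOR must lie in [0, 1]")
    K = K or xp.size
    return xp * (1.0 - bor) + bor / K


def attach_xp(
    result: BMSResult,
    log_ev: np.ndarray | None = None,
    n_samples: int = 1_000_000,
    seed: int = 0,
    bor: float | None = None,
) -> BMSResult:
    """Fill in xp, BOR and pxp on an existing Dirichlet fit."""
    result.xp = exceedance_prob(result.alpha, n_samples=n_samples, seed=seed)
    if bor is None:
        if log_ev is None:
            raise ValueError("need log_ev (or an explicit bor) to compute BOR")
        bor = bayesian_omnibus_risk(log_ev)
    result.bor = float(bor)
    result.pxp = protected_xp(result.xp, result.bor)
    return result


def family_inference(
    log_ev: np.ndarray,
    partition: FamilyPartition,
    alpha0: float = 1.0,
    n_samples: int = 1_000_000,
    seed: int = 0,
) -> BMSResult:
    """Family-level RFX with family-size correction.

    The within-family model prior is uniform conditional on the family,
    so each subject's family evidence is the average of its member
    evidences, ``log mean_k exp(log_ev_nk)``; the Dirichlet RFX scheme
    then runs over families with a symmetric prior (equal prior mass per
    family regardless of size).  Under exchangeable evidence the expected
    family frequencies are uniform, not proportional to family size.
    """
    log_ev = _check_log_ev(log_ev)
    n, K = log_ev.shape
    if partition.n_models != K:
        raise ValueError("partition does not cover the model space")
    fam_names = list(partition.families.keys())
    fam_lev = np.column_stack(
        [
            logsumexp(log_ev[:, partition.families[f]], axis=1)
            - np.log(len(partition.families[f]))
            for f in fam_names
        ]
    )
    fit = rfx_dirichlet(fam_lev, alpha0)
    xp = exceedance_prob(fit.alpha, n_samples=n_samples, seed=seed)
    bor = bayesian_omnibus_risk(fam_lev, alpha0)
    pxp = protected_xp(xp, bor)
    return BMSResult(
        alpha=fit.alpha,
        expected_freq=fit.expected_freq,
        xp=xp,
        bor=bor,
        pxp=pxp,
        level="family",
        names=fam_names,
        responsibilities=fit.responsibilities,
        free_energy_rfx=fit.free_energy_rfx,
    )


def bma(
    inversion_results: list,
    log_ev_row: np.ndarray,
    scope: list[int] | None = None,
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Bayesian model average for one subject.

    Parameters are matched by name across models; a parameter absent from
    a model is treated as 0 with zero variance.  Weights are the softmax
    of the free energies over the scope (uniform model prior).

    Returns (parameter names, averaged vector, weights over scope).
    """
    log_ev_row = np.asarray(log_ev_row, dtype=float)
    if scope is None:
        scope = list(range(len(inversion_results)))
    if len(scope) == 0:
        raise ValueError("empty BMA scope")
    names: list[str] = []
    for i in scope:
        for nm in inversion_results[i].names:
            if nm not in names and not nm.startswith("conf"):
                names.append(nm)
    w = np.exp(log_ev_row[scope] - logsumexp(log_ev_row[scope]))
    avg = np.zeros(len(names))
    for wi, i in zip(w, scope):
        res = inversion_results[i]
        for j, nm in enumerate(names):
            if nm in res.names:
                avg[j] += wi * res[nm]
    return names, avg, w


def bma_cohort(
    results: dict[tuple[str, str], object],
    log_ev,
    model_names: list[str],
    scope: list[int] | None = None,
) -> BMAResult:
    """BMA for every subject in a log-evidence table (rows = subjects)."""
    averaged: dict[str, np.ndarray] = {}
    weights: dict[str, np.ndarray] = {}
    names_out: list[str] = []
    for subject in log_ev.index:
        row = log_ev.loc[subject].to_numpy()
        res_list = [results[(subject, mn)] for mn in model_names]
        names, avg, w = bma(res_list, row, scope)
        names_out = names
        averaged[subject] = avg
        weights[subject] = w
    return BMAResult(
        names=names_out,
        averaged=averaged,
        weights=weights,
        scope="all-models" if scope is None else f"models {scope}",
    )
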