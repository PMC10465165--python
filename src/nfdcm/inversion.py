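"""Variational-Laplace model inversion and free-energy evidence.

The observation model is ``y = g(theta) + X_c beta + eps`` with
``eps ~ N(0, exp(-lambda) I)``: ``g`` is the deterministic DCM forward
model, ``X_c`` run-indicator / low-order cosine confounds, and ``lambda``
a single shared log precision.  A Gaussian fixed-form posterior
``q(theta) = N(m, S)`` is optimised by Gauss-Newton ascent on the
variational free energy

    F = E_q[log p(y | theta, lambda)] - KL(q(theta) || p(theta))
        - KL(q(lambda) || p(lambda)),

with Levenberg-Marquardt damping: a step that would decrease F is
rejected and retried with stronger damping, so the trace of accepted
free energies is non-decreasing.  On a linear forward model with fixed
noise precision the scheme is conjugate and F equals the analytic log
evidence at convergence.

The estimator is deterministic: initialisation at the prior mean, no
random restarts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .generative_model import (
    DEFAULT_BINS_PER_TR,
    HemoParams,
    InputSet,
    RoiTimeSeries,
    SELF_INHIBITION,
    integrate_batch,
)
from .model_space import ModelSpec
from .regions import REGION_LABELS

logger = logging.getLogger(__name__)

__all__ = [
    "PriorSpec",
    "InversionResult",
    "InversionConfig",
    "default_priors",
    "concatenate_runs",
    "concatenate_inputs",
    "inputs_from_labels",
    "variational_laplace",
    "invert",
    "log_evidence_matrix",
]

LOG2PI = math.log(2.0 * math.pi)


@dataclass
class PriorSpec:
    """Gaussian priors over the free parameters.

    The vector covers, in order: free A entries, free B entries, free C
    entries, optional per-region hemodynamic log-deviations, and finally
    the noise log precision ``lambda``.  Fixed parameters (the diagonal
    self-inhibitions) are excluded rather than carried with zero variance.
    """

    names: list[str]
    mean: np.ndarray
    var: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.var = np.asarray(self.var, dtype=float)
        if not (len(self.names) == self.mean.size == self.var.size):
            raise ValueError("names, mean and var must have equal length")
        if np.any(self.var <= 0):
            raise ValueError("prior variances must be strictly positive")

    @property
    def lambda_index(self) -> int:
        return self.names.index("lambda")

    def theta_slice(self) -> tuple[np.ndarray, np.ndarray, list[str]]:
        i = self.lambda_index
        keep = [j for j in range(len(self.names)) if j != i]
        return self.mean[keep], self.var[keep], [self.names[j] for j in keep]


# default prior variances (conventional shrinkage scale for 1/s couplings)
_VAR_A = 1.0 / 64.0
_VAR_B = 1.0 / 16.0
_VAR_C = 1.0 / 4.0
_VAR_HEMO = 0.0025  # log-scaling deviations on kappa, tau
_LAMBDA_MEAN = 2.0
_VAR_LAMBDA = 16.0


def default_priors(spec: ModelSpec, include_hemo: bool = True) -> PriorSpec:
    """Shrinkage priors for one model: N(0, 1/64) on free A entries,
    N(0, 1/16) on B, N(0, 1/4) on C, tight N(0, 0.05^2) log-deviations on
    per-region kappa/tau when ``include_hemo``, and N(2, 16) on the noise
    log precision."""
    names: list[str] = []
    R = spec.n_regions
    off = ~np.eye(R, dtype=bool)
    lab = REGION_LABELS
    var: list[float] = []
    for t in range(R):
        for s in range(R):
            if spec.a_mask[t, s] and off[t, s]:
                names.append(f"A[{lab[t]}<-{lab[s]}]")
                var.append(_VAR_A)
    for t in range(R):
        for s in range(R):
            if spec.b_masks[0][t, s]:
                names.append(f"B[{lab[t]}<-{lab[s]}]")
                var.append(_VAR_B)
    for r in range(R):
        for u in range(spec.c_mask.shape[1]):
            if spec.c_mask[r, u]:
                names.append(f"C[{lab[r]}]")
                var.append(_VAR_C)
    if include_hemo:
        for kind in ("kappa", "tau"):
            for r in range(R):
                names.append(f"hemo_log{kind}[{lab[r]}]")
                var.append(_VAR_HEMO)
    names.append("lambda")
    var.append(_VAR_LAMBDA)
    mean = np.zeros(len(names))
    mean[-1] = _LAMBDA_MEAN
    return PriorSpec(names=names, mean=mean, var=np.array(var))


@dataclass
class InversionResult:
    """Posterior summary and free-energy bound for one subject x model."""

    posterior_mean: np.ndarray
    posterior_cov: np.ndarray
    free_energy: float
    fe_trace: list[float]
    converged: bool
    names: list[str]
    predicted: np.ndarray | None = None
    residuals: np.ndarray | None = None
    noise_log_precision: float = 0.0

    def __getitem__(self, name: str) -> float:
        return float(self.posterior_mean[self.names.index(name)])

    def sd(self, name: str) -> float:
        i = self.names.index(name)
        return float(np.sqrt(self.posterior_cov[i, i]))

    def to_dict(self) -> dict:
        return {
            "names": self.names,
            "posterior_mean": self.posterior_mean.tolist(),
            "posterior_marginal_var": np.diag(self.posterior_cov).tolist(),
            "free_energy": self.free_energy,
            "fe_trace": list(self.fe_trace),
            "converged": self.converged,
            "noise_log_precision": self.noise_log_precision,
        }


@dataclass
class InversionConfig:
    """Numerical settings of the Gauss-Newton variational scheme."""

    max_iter: int = 128
    tol: float = 0.01  # nats; |dF| below this counts toward convergence
    n_consecutive: int = 3
    max_step_retries: int = 8
    bins_per_tr: int = DEFAULT_BINS_PER_TR
    include_hemo: bool = True
    estimate_lambda: bool = True
    cosine_order: int = 0  # per-run cosine drift confounds
    confound_prior_var: float = 1.0  # run offsets are O(1) in percent units
    fd_step_scale: float = 1e-3  # FD step = scale * prior SD, clipped
    fd_central: bool = False  # central differences (2x forward cost)
    n_runs: int | None = None  # subset of training runs (scaled-down analyses)


# ---------------------------------------------------------------------------
# run concatenation
# ---------------------------------------------------------------------------

def concatenate_runs(
    runs: list[RoiTimeSeries],
) -> tuple[RoiTimeSeries, np.ndarray]:
    """Time-wise concatenation plus per-run indicator confounds.

    The indicator regressors absorb inter-run baseline offsets so model
    evidence is not driven by them.  A single run passes through with one
    constant confound.
    """
    if not runs:
        raise ValueError("no runs to concatenate")
    TR = runs[0].TR
    for r in runs[1:]:
        if abs(r.TR - TR) > 1e-9:
            raise ValueError("runs disagree on TR")
        if r.regions.labels != runs[0].regions.labels:
            raise ValueError("runs disagree on region order")
    data = np.concatenate([r.data for r in runs], axis=1)
    labels = None
    if all(r.condition_labels is not None for r in runs):
        labels = [lab for r in runs for lab in r.condition_labels]
    total = data.shape[1]
    confounds = np.zeros((total, len(runs)))
    t0 = 0
    for i, r in enumerate(runs):
        confounds[t0 : t0 + r.n_volumes, i] = 1.0
        t0 += r.n_volumes
    out = RoiTimeSeries(
        data=data,
        TR=TR,
        run_id="+".join(r.run_id for r in runs),
        condition_labels=labels,
        regions=runs[0].regions,
    )
    return out, confounds


def concatenate_inputs(inputs: list[InputSet]) -> InputSet:
    """Concatenate per-run input box-cars with matching offsets."""
    TR = inputs[0].TR
    bpt = inputs[0].bins_per_tr
    for x in inputs[1:]:
        if abs(x.TR - TR) > 1e-9 or x.bins_per_tr != bpt:
            raise ValueError("inputs disagree on TR or micro-time resolution")
    n_vol = sum(x.n_volumes for x in inputs)
    dt = TR / bpt
    times = (np.arange(n_vol * bpt) + 0.5) * dt
    return InputSet(
        times=times,
        u_drive=np.concatenate([x.u_drive for x in inputs]),
        u_mod=np.concatenate([x.u_mod for x in inputs]),
        TR=TR,
        n_volumes=n_vol,
    )


def inputs_from_labels(
    run: RoiTimeSeries, bins_per_tr: int = DEFAULT_BINS_PER_TR, drive_on: bool = True
) -> InputSet:
    """Rebuild box-car inputs from a run's per-volume condition labels."""
    if run.condition_labels is None:
        raise ValueError("run carries no condition labels")
    up = np.array([lab == "up-regulation" for lab in run.condition_labels], dtype=float)
    u_vol = np.repeat(up, bins_per_tr)
    dt = run.TR / bins_per_tr
    times = (np.arange(u_vol.size) + 0.5) * dt
    # the feedback display is on for the whole run (static in baselines)
    return InputSet(
        times=times,
        u_drive=np.ones_like(u_vol) if drive_on else np.zeros_like(u_vol),
        u_mod=u_vol,
        TR=run.TR,
        n_volumes=run.n_volumes,
    )


def _cosine_confounds(n_volumes_per_run: list[int], order: int) -> np.ndarray:
    """Per-run discrete cosine drift regressors (order columns per run)."""
    total = sum(n_volumes_per_run)
    cols = []
    t0 = 0
    for n in n_volumes_per_run:
        t = (np.arange(n) + 0.5) / n
        for k in range(1, order + 1):
            col = np.zeros(total)
            col[t0 : t0 + n] = np.cos(np.pi * k * t)
            cols.append(col)
        t0 += n
    return np.stack(cols, axis=1) if cols else np.zeros((total, 0))


# ---------------------------------------------------------------------------
# variational Laplace core
# ---------------------------------------------------------------------------

@dataclass
class _VLState:
    m: np.ndarray
    lam: float
    F: float
    S: np.ndarray


def _free_energy(
    e: np.ndarray,
    JtJ: np.ndarray,
    S: np.ndarray,
    m: np.ndarray,
    m0: np.ndarray,
    pi0: np.ndarray,
    lam: float,
    lam0: float,
    lam_var: float,
    estimate_lambda: bool,
) -> float:
    N = e.size
    p = m.size
    tr_SJtJ = float(np.sum(S * JtJ))
    elik = -0.5 * math.exp(lam) * (float(e @ e) + tr_SJtJ) + 0.5 * N * lam - 0.5 * N * LOG2PI
    dm = m - m0
    sign, logdet_S = np.linalg.slogdet(S)
    if sign <= 0:
        return -np.inf
    logdet_S0 = float(np.sum(-np.log(pi0)))
    kl_theta = 0.5 * (
        float(dm @ (pi0 * dm)) + float(np.sum(np.diag(S) * pi0)) - p + logdet_S0 - logdet_S
    )
    kl_lam = 0.0
    if estimate_lambda:
        E = float(e @ e) + tr_SJtJ
        s_lam = 1.0 / (0.5 * E * math.exp(lam) + 1.0 / lam_var)
        kl_lam = 0.5 * (
            (lam - lam0) ** 2 / lam_var + s_lam / lam_var - 1.0 + math.log(lam_var / s_lam)
        )
    return elik - kl_theta - kl_lam


def _update_lambda(
    e: np.ndarray,
    JtJ: np.ndarray,
    pi0: np.ndarray,
    lam: float,
    lam0: float,
    lam_var: float,
) -> float:
    """Newton ascent of F in the noise log precision (1-D, monotone)."""
    N = e.size
    ete = float(e @ e)
    for _ in range(16):
        P = math.exp(lam) * JtJ + np.diag(pi0)
        S = np.linalg.inv(P)
        E = ete + float(np.sum(S * JtJ))
        grad = -0.5 * E * math.exp(lam) + 0.5 * N - (lam - lam0) / lam_var
        hess = -0.5 * E * math.exp(lam) - 1.0 / lam_var
        step = np.clip(-grad / hess, -2.0, 2.0)
        lam += step
        if abs(step) < 1e-6:
            break
    return float(lam)


def variational_laplace(
    y: np.ndarray,
    predict,
    prior_mean: np.ndarray,
    prior_var: np.ndarray,
    lam0: float = _LAMBDA_MEAN,
    lam_var: float = _VAR_LAMBDA,
    estimate_lambda: bool = True,
    config: InversionConfig | None = None,
    names: list[str] | None = None,
) -> InversionResult:
    """Gauss-Newton ascent on the variational free energy.

    ``predict(m) -> (g, J)`` returns the forward prediction and its
    Jacobian at ``m``.  Accepted steps never decrease F; a proposed step
    that would is retried with stronger Levenberg-Marquardt damping and
    the scheme stops (flagged unconverged only if the tolerance was never
    met) when no admissible step remains.
    """
    cfg = config or InversionConfig()
    y = np.asarray(y, dtype=float).ravel()
    m = np.asarray(prior_mean, dtype=float).copy()
    m0 = m.copy()
    pi0 = 1.0 / np.asarray(prior_var, dtype=float)
    lam = float(lam0)
    p = m.size

    g, J = predict(m)
    if not np.all(np.isfinite(g)):
        raise FloatingPointError("forward model returned non-finite prediction at the prior mean")
    e = y - g
    JtJ = J.T @ J
    if estimate_lambda:
        lam = _update_lambda(e, JtJ, pi0, lam, lam0, lam_var)
    P = math.exp(lam) * JtJ + np.diag(pi0)
    S = np.linalg.inv(P)
    F = _free_energy(e, JtJ, S, m, m0, pi0, lam, lam0, lam_var, estimate_lambda)
    fe_trace = [F]
    nu = 1e-6  # LM damping
    converged = False
    n_small = 0

    for it in range(cfg.max_iter):
        accepted = False
        for _ in range(cfg.max_step_retries):
            P = math.exp(lam) * JtJ + np.diag(pi0)
            Pd = P + nu * np.diag(np.diag(P))
            rhs = math.exp(lam) * (J.T @ e) - pi0 * (m - m0)
            try:
                dm = np.linalg.solve(Pd, rhs)
            except np.linalg.LinAlgError as exc:  # pragma: no cover
                raise FloatingPointError(f"singular curvature at iteration {it}") from exc
            m_new = m + dm
            try:
                g_new, J_new = predict(m_new)
            except FloatingPointError:
                nu = max(nu, 1e-4) * 8.0
                continue
            if not np.all(np.isfinite(g_new)):
                nu = max(nu, 1e-4) * 8.0
                continue
            e_new = y - g_new
            JtJ_new = J_new.T @ J_new
            lam_new = (
                _update_lambda(e_new, JtJ_new, pi0, lam, lam0, lam_var)
                if estimate_lambda
                else lam
            )
            P_new = math.exp(lam_new) * JtJ_new + np.diag(pi0)
            S_new = np.linalg.inv(P_new)
            F_new = _free_energy(
                e_new, JtJ_new, S_new, m_new, m0, pi0, lam_new, lam0, lam_var, estimate_lambda
            )
            if np.isfinite(F_new) and F_new >= F - 1e-9:
                dF = F_new - F
                m, e, J, JtJ, lam, S, F = m_new, e_new, J_new, JtJ_new, lam_new, S_new, F_new
                fe_trace.append(F)
                nu = max(nu / 2.0, 1e-8)
                accepted = True
                n_small = n_small + 1 if dF < cfg.tol else 0
                break
            nu = max(nu, 1e-4) * 8.0
        if not accepted:
            # no admissible uphill step left: treat as converged at optimum
            converged = True
            break
        if n_small >= cfg.n_consecutive:
            converged = True
            break

    return InversionResult(
        posterior_mean=m,
        posterior_cov=S,
        free_energy=F,
        fe_trace=fe_trace,
        converged=converged,
        names=names or [f"theta{i}" for i in range(p)],
        predicted=y - e,
        residuals=e,
        noise_log_precision=lam,
    )


# ---------------------------------------------------------------------------
# DCM predictor (batched finite-difference Jacobian)
# ---------------------------------------------------------------------------

class _DCMPredictor:
    """Maps the free-parameter vector to concatenated BOLD predictions.

    The Jacobian is obtained by one-sided finite differences evaluated in
    a single batched integration (one batch element per perturbed
    parameter); confound regressors enter linearly with analytic Jacobian
    columns.
    """

    def __init__(
        self,
        spec: ModelSpec,
        theta_names: list[str],
        theta_var: np.ndarray,
        inputs: InputSet | list[InputSet],
        confounds: np.ndarray,
        hemo: HemoParams,
        fd_step_scale: float = 1e-3,
        fd_central: bool = False,
    ):
        self.fd_central = fd_central
        self.spec = spec
        # each run is integrated from rest independently; a concatenated
        # recording is passed as a list of per-run input sets
        self.inputs = [inputs] if isinstance(inputs, InputSet) else list(inputs)
        self.hemo = hemo
        self.R = spec.n_regions
        self.n_conf = confounds.shape[1]
        self.names = theta_names
        self.n_dcm = len(theta_names)
        self.fd_steps = np.clip(fd_step_scale * np.sqrt(theta_var), 1e-5, 1e-2)
        # kron structure: one beta per (region, confound column)
        T = confounds.shape[0]
        self.Xc = np.zeros((self.R * T, self.R * self.n_conf))
        for r in range(self.R):
            self.Xc[r * T : (r + 1) * T, r * self.n_conf : (r + 1) * self.n_conf] = confounds
        # index maps
        self._a_idx, self._b_idx, self._c_idx, self._hk_idx, self._ht_idx = [], [], [], [], []
        for i, nm in enumerate(theta_names):
            if nm.startswith("A["):
                self._a_idx.append(i)
            elif nm.startswith("B["):
                self._b_idx.append(i)
            elif nm.startswith("C["):
                self._c_idx.append(i)
            elif nm.startswith("hemo_logkappa"):
                self._hk_idx.append(i)
            elif nm.startswith("hemo_logtau"):
                self._ht_idx.append(i)
        off = ~np.eye(self.R, dtype=bool)
        self._a_pos = np.argwhere(spec.a_mask & off)
        self._b_pos = np.argwhere(spec.b_masks[0])
        self._c_pos = np.argwhere(spec.c_mask[:, 0])

    @property
    def n_free(self) -> int:
        return self.n_dcm + self.R * self.n_conf

    def _unpack(self, theta: np.ndarray):
        A = np.zeros((self.R, self.R))
        np.fill_diagonal(A, SELF_INHIBITION)
        for i, (t, s) in zip(self._a_idx, self._a_pos):
            A[t, s] = theta[i]
        Bm = np.zeros((self.R, self.R))
        for i, (t, s) in zip(self._b_idx, self._b_pos):
            Bm[t, s] = theta[i]
        c = np.zeros(self.R)
        for i, (r,) in zip(self._c_idx, self._c_pos):
            c[r] = theta[i]
        kappa = np.full(self.R, self.hemo.kappa)
        tau = np.full(self.R, self.hemo.tau)
        for j, i in enumerate(self._hk_idx):
            kappa[j] = self.hemo.kappa * math.exp(theta[i])
        for j, i in enumerate(self._ht_idx):
            tau[j] = self.hemo.tau * math.exp(theta[i])
        return A, Bm, c, kappa, tau

    def _forward_batch(self, thetas: np.ndarray) -> np.ndarray:
        B_ = thetas.shape[0]
        M0 = np.empty((B_, self.R, self.R))
        M1 = np.empty((B_, self.R, self.R))
        cb = np.empty((B_, self.R))
        kb = np.empty((B_, self.R))
        gb = np.full((B_, self.R), self.hemo.gamma)
        tb = np.empty((B_, self.R))
        for b in range(B_):
            A, Bm, c, kappa, tau = self._unpack(thetas[b])
            M0[b] = A
            M1[b] = A + Bm
            cb[b] = c
            kb[b] = kappa
            tb[b] = tau
        segments = []
        for seg in self.inputs:
            y, bad = integrate_batch(M0, M1, cb, seg, kb, gb, tb, self.hemo)
            if np.any(bad[:, 0] >= 0):
                raise FloatingPointError("hemodynamic state left the positive orthant")
            segments.append(y)
        y = np.concatenate(segments, axis=1)
        # (B, n_vol, R) -> (B, R * n_vol), region-major
        return y.transpose(0, 2, 1).reshape(B_, -1)

    def __call__(self, m: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        theta = m[: self.n_dcm]
        beta = m[self.n_dcm :]
        if self.fd_central:
            batch = np.tile(theta, (2 * self.n_dcm + 1, 1))
            for i in range(self.n_dcm):
                batch[1 + 2 * i, i] += self.fd_steps[i]
                batch[2 + 2 * i, i] -= self.fd_steps[i]
            ys = self._forward_batch(batch)
            g = ys[0] + self.Xc @ beta
            J = np.empty((g.size, self.n_free))
            for i in range(self.n_dcm):
                J[:, i] = (ys[1 + 2 * i] - ys[2 + 2 * i]) / (2 * self.fd_steps[i])
        else:
            batch = np.tile(theta, (self.n_dcm + 1, 1))
            for i in range(self.n_dcm):
                batch[i + 1, i] += self.fd_steps[i]
            ys = self._forward_batch(batch)
            g = ys[0] + self.Xc @ beta
            J = np.empty((g.size, self.n_free))
            for i in range(self.n_dcm):
                J[:, i] = (ys[i + 1] - ys[0]) / self.fd_steps[i]
        J[:, self.n_dcm :] = self.Xc
        return g, J


def invert(
    data: RoiTimeSeries,
    spec: ModelSpec,
    priors: PriorSpec | None = None,
    config: InversionConfig | None = None,
    inputs: InputSet | list[InputSet] | None = None,
    confounds: np.ndarray | None = None,
) -> InversionResult:
    """Invert one model on one subject's (possibly concatenated) data.

    For concatenated recordings pass one :class:`InputSet` per run; each
    run is then predicted from the resting state independently, matching
    how separate acquisitions start from rest.
    """
    cfg = config or InversionConfig()
    if priors is None:
        priors = default_priors(spec, include_hemo=cfg.include_hemo)
    if inputs is None:
        inputs = inputs_from_labels(data, bins_per_tr=cfg.bins_per_tr)
    if not np.all(np.isfinite(data.data)):
        raise ValueError("data contains non-finite values")
    if confounds is None:
        confounds = np.ones((data.n_volumes, 1))
    if confounds.shape[0] != data.n_volumes:
        raise ValueError("confound rows must match volume count")

    theta_mean, theta_var, theta_names = priors.theta_slice()
    lam_i = priors.lambda_index
    predictor = _DCMPredictor(
        spec,
        theta_names,
        theta_var,
        inputs,
        confounds,
        HemoParams(),
        fd_step_scale=cfg.fd_step_scale,
        fd_central=cfg.fd_central,
    )
    n_beta = predictor.n_free - predictor.n_dcm
    full_mean = np.concatenate([theta_mean, np.zeros(n_beta)])
    full_var = np.concatenate([theta_var, np.full(n_beta, cfg.confound_prior_var)])
    full_names = theta_names + [f"conf{j}" for j in range(n_beta)]
    y = data.data.reshape(-1)  # region-major
    res = variational_laplace(
        y,
        predictor,
        full_mean,
        full_var,
        lam0=priors.mean[lam_i],
        lam_var=priors.var[lam_i],
        estimate_lambda=cfg.estimate_lambda,
        config=cfg,
        names=full_names,
    )
    g, _ = predictor(res.posterior_mean)
    res.predicted = g.reshape(data.data.shape)
    res.residuals = data.data - res.predicted
    return res


def log_evidence_matrix(
    cohort,
    model_space: list[ModelSpec],
    config: InversionConfig | None = None,
) -> pd.DataFrame:
    """Free energy of every model for every subject (subjects x models).

    Training runs are concatenated per subject (optionally only the first
    ``config.n_runs`` for scaled-down analyses).  A failed inversion is
    recorded as NaN with a log entry; a subject failing on every model
    raises.
    """
    cfg = config or InversionConfig()
    rows = {}
    results: dict[tuple[str, str], InversionResult] = {}
    for subj in cohort.subjects:
        runs = cohort.training_runs[subj.subject_id]
        if cfg.n_runs is not None:
            runs = runs[: cfg.n_runs]
        data, confounds = concatenate_runs(runs)
        if cfg.cosine_order > 0:
            cos = _cosine_confounds([r.n_volumes for r in runs], cfg.cosine_order)
            confounds = np.concatenate([confounds, cos], axis=1)
        inputs = [inputs_from_labels(r, bins_per_tr=cfg.bins_per_tr) for r in runs]
        row = {}
        for mi, spec in enumerate(model_space):
            try:
                res = invert(data, spec, config=cfg, inputs=inputs, confounds=confounds)
                row[spec.name] = res.free_energy
                results[(subj.subject_id, spec.name)] = res
            except (FloatingPointError, np.linalg.LinAlgError) as exc:
                logger.warning(
                    "inversion failed for %s model %s: %s", subj.subject_id, spec.name, exc
                )
                row[spec.name] = np.nan
        if all(np.isnan(v) for v in row.values()):
            raise RuntimeError(f"all models failed for subject {subj.subject_id}")
        rows[subj.subject_id] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.attrs["results"] = results
    return df
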