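"""Deterministic forward model: bilinear neuronal dynamics + balloon cascade.

The neuronal model is a one-state bilinear ODE over the four regions,

.. math::

    \\dot x = (A + u_{mod} B)\\, x + C\\, u_{drive}

where ``A`` is baseline effective connectivity (1/s), ``B`` the modulation
of connectivity by the up-regulation condition, and ``C`` the gain of the
visual-feedback driving input.  Self connections (the diagonal of ``A``)
are fixed at -0.5 1/s and never estimated, which guarantees a stable
resting point.

Neuronal activity drives a balloon–Windkessel hemodynamic cascade per
region (vasodilatory signal s, inflow f, volume v, deoxyhemoglobin q)
whose output is the classical BOLD observation equation in percent signal
change.  The cascade is integrated with a fixed-step RK4 scheme on a
micro-time grid of ``bins_per_tr`` bins per repetition time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._integrator import bold_from_state, rk4_bold_batch
from .regions import DEFAULT_REGIONS, REGION_LABELS, RegionSet

__all__ = [
    "HemoParams",
    "DCMParameters",
    "InputSet",
    "RoiTimeSeries",
    "neuronal_drift",
    "hemodynamic_drift",
    "bold_observation",
    "integrate_dcm",
    "integrate_batch",
    "bold_coefficients",
    "DEFAULT_TR",
    "DEFAULT_BINS_PER_TR",
    "SELF_INHIBITION",
    "UnstableModelWarning",
]

#: Repetition time in seconds (two volumes span the 3-s reward display).
DEFAULT_TR = 1.5
#: Micro-time bins per TR for the fixed-step integrator.
DEFAULT_BINS_PER_TR = 16
#: Fixed within-region self-inhibition, 1/s.
SELF_INHIBITION = -0.5


class UnstableModelWarning(UserWarning):
    """Raised when the (modulated) coupling matrix has an unstable mode."""


class NumericalIntegrationError(RuntimeError):
    """Hemodynamic state left the positive orthant during integration."""


@dataclass(frozen=True)
class HemoParams:
    """Balloon–Windkessel constants (standard DCM defaults).

    kappa : signal decay rate, 1/s
    gamma : autoregulatory feedback rate, 1/s
    tau   : mean transit time, s
    alpha : vessel stiffness exponent (Grubb), in (0, 1)
    E0    : resting oxygen extraction fraction, in (0, 1)
    V0    : resting venous blood volume fraction
    """

    kappa: float = 0.64
    gamma: float = 0.32
    tau: float = 2.0
    alpha: float = 0.32
    E0: float = 0.4
    V0: float = 0.04

    def __post_init__(self) -> None:
        for name in ("kappa", "gamma", "tau", "V0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"hemodynamic constant {name} must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.E0 < 1:
            raise ValueError("E0 must lie in (0, 1)")


def bold_coefficients(hemo: HemoParams) -> tuple[float, float, float]:
    """Classical (non-revised) balloon observation coefficients.

    k1 = 7 E0, k2 = 2, k3 = 2 E0 - 0.2.  This is the single place the
    constants are defined.
    """
    return 7.0 * hemo.E0, 2.0, 2.0 * hemo.E0 - 0.2


@dataclass
class DCMParameters:
    """Full parameter set of the generative model.

    A : (R, R) baseline coupling, 1/s; diagonal strictly negative.
    B : (n_mod, R, R) modulatory coupling per modulatory input, 1/s.
    C : (R, n_drive) driving-input gains.
    hemo : shared hemodynamic constants; per-region multiplicative
        deviations may be supplied via ``hemo_scale`` (rows kappa, tau).
    noise_log_precision : log precision of the additive observation noise.
    """

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    hemo: HemoParams = field(default_factory=HemoParams)
    hemo_scale: np.ndarray | None = None  # (2, R): exp-scalings of kappa, tau
    noise_log_precision: float = 0.0
    regions: RegionSet = field(default_factory=lambda: DEFAULT_REGIONS)

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        self.C = np.asarray(self.C, dtype=float)
        R = self.regions.n_regions
        if self.A.shape != (R, R):
            raise ValueError(f"A must be {R}x{R}, got {self.A.shape}")
        if self.B.ndim == 2:
            self.B = self.B[None, :, :]
        if self.B.shape[1:] != (R, R):
            raise ValueError(f"each B must be {R}x{R}, got {self.B.shape}")
        if self.C.ndim == 1:
            self.C = self.C[:, None]
        if self.C.shape[0] != R:
            raise ValueError(f"C must have {R} rows, got {self.C.shape}")
        if np.any(np.diag(self.A) >= 0):
            raise ValueError("diagonal of A (self-inhibition) must be strictly negative")

    @property
    def n_regions(self) -> int:
        return self.A.shape[0]

    def kappa_tau_vectors(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-region kappa and tau after applying hemo_scale deviations."""
        R = self.n_regions
        kappa = np.full(R, self.hemo.kappa)
        tau = np.full(R, self.hemo.tau)
        if self.hemo_scale is not None:
            hs = np.asarray(self.hemo_scale, dtype=float)
            kappa = kappa * np.exp(hs[0])
            tau = tau * np.exp(hs[1])
        return kappa, tau

    def conforms_to(self, a_mask: np.ndarray, b_masks: np.ndarray, c_mask: np.ndarray) -> bool:
        """True when every nonzero entry lies inside the given masks."""
        off = ~np.eye(self.n_regions, dtype=bool)
        if np.any((self.A != 0) & off & ~a_mask.astype(bool)):
            return False
        bm = np.asarray(b_masks, dtype=bool)
        if bm.ndim == 2:
            bm = bm[None]
        if np.any((self.B != 0) & ~bm):
            return False
        if np.any((self.C != 0) & ~np.asarray(c_mask, dtype=bool).reshape(self.C.shape)):
            return False
        return True


@dataclass
class InputSet:
    """Experimental inputs resolved onto the integrator's micro-time grid.

    ``u_drive`` carries the visual-feedback box-car, ``u_mod`` the
    up-regulation box-car; both are binary per micro-time bin.
    """

    times: np.ndarray
    u_drive: np.ndarray
    u_mod: np.ndarray
    TR: float
    n_volumes: int

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.u_drive = np.asarray(self.u_drive, dtype=float)
        self.u_mod = np.asarray(self.u_mod, dtype=float)
        T = self.times.size
        if self.u_drive.size != T or self.u_mod.size != T:
            raise ValueError("times, u_drive and u_mod must have equal length")
        if T % self.n_volumes != 0:
            raise ValueError("micro-time bins must divide n_volumes evenly")
        for u in (self.u_drive, self.u_mod):
            if not np.all(np.isin(u, (0.0, 1.0))):
                raise ValueError("inputs must be binary box-cars")

    @property
    def bins_per_tr(self) -> int:
        return self.times.size // self.n_volumes

    @property
    def dt(self) -> float:
        return self.TR / self.bins_per_tr

    @classmethod
    def from_events(
        cls,
        events: pd.DataFrame,
        TR: float = DEFAULT_TR,
        n_volumes: int | None = None,
        bins_per_tr: int = DEFAULT_BINS_PER_TR,
        drive_conditions: tuple[str, ...] | str = "sustained",
        mod_conditions: tuple[str, ...] = ("up-regulation",),
    ) -> "InputSet":
        """Build box-car inputs from a BIDS-style events table.

        ``events`` needs columns onset, duration, trial_type.  The
        modulatory input follows the up-regulation blocks.  The driving
        (visual feedback display) input is by default ``"sustained"`` — on
        from the first block onset to the end of the run, since the
        display is present during baselines too, merely static.  Pass a
        tuple of condition names to restrict the drive to those blocks, or
        ``()`` to silence it (transfer runs).
        """
        for col in ("onset", "duration", "trial_type"):
            if col not in events.columns:
                raise ValueError(f"events table missing column '{col}'")
        end = float((events["onset"] + events["duration"]).max())
        if n_volumes is None:
            n_volumes = int(np.ceil(end / TR))
        T = n_volumes * bins_per_tr
        dt = TR / bins_per_tr
        times = (np.arange(T) + 0.5) * dt
        u_drive = np.zeros(T)
        u_mod = np.zeros(T)
        sustained = drive_conditions == "sustained"
        for _, row in events.iterrows():
            on, dur, cond = float(row["onset"]), float(row["duration"]), row["trial_type"]
            mask = (times >= on) & (times < on + dur)
            if sustained or cond in drive_conditions:
                u_drive[mask] = 1.0
            if cond in mod_conditions:
                u_mod[mask] = 1.0
        return cls(times=times, u_drive=u_drive, u_mod=u_mod, TR=TR, n_volumes=n_volumes)


@dataclass
class RoiTimeSeries:
    """Region-by-volume BOLD matrix with acquisition metadata."""

    data: np.ndarray  # (R, n_volumes), percent signal change
    TR: float
    run_id: str = "run-01"
    condition_labels: list[str] | None = None
    regions: RegionSet = field(default_factory=lambda: DEFAULT_REGIONS)
    stable: bool = True

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (regions x volumes)")
        if self.data.shape[0] != self.regions.n_regions:
            raise ValueError("row count must match the region set")
        if np.any(~np.isfinite(self.data)):
            raise ValueError("BOLD data contains non-finite values")
        if self.condition_labels is not None and len(self.condition_labels) != self.n_volumes:
            raise ValueError("one condition label per volume required")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[1]

    def region(self, label: str) -> np.ndarray:
        return self.data[self.regions.index(label)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.data.T, columns=list(self.regions.labels))
        if self.condition_labels is not None:
            df["condition"] = list(self.condition_labels)
        df.insert(0, "volume", np.arange(self.n_volumes))
        return df


# ---------------------------------------------------------------------------
# drift / observation primitives (reference implementations)
# ---------------------------------------------------------------------------

def neuronal_drift(
    x: np.ndarray, u_drive: float, u_mod: float, params: DCMParameters
) -> np.ndarray:
    """dx/dt = (A + u_mod B) x + C u_drive, units 1/s."""
    x = np.asarray(x, dtype=float)
    if x.shape != (params.n_regions,):
        raise ValueError(
            f"state has {x.shape} elements but A is {params.A.shape}"
        )
    M = params.A + u_mod * params.B[0]
    return M @ x + params.C[:, 0] * u_drive


def hemodynamic_drift(
    h: np.ndarray, z: np.ndarray, params: DCMParameters
) -> np.ndarray:
    """Balloon–Windkessel state derivative.

    ``h`` is (R, 4) with columns (s, f, v, q); ``z`` the neuronal activity.
    """
    h = np.atleast_2d(np.asarray(h, dtype=float))
    z = np.atleast_1d(np.asarray(z, dtype=float))
    s, f, v, q = h[:, 0], h[:, 1], h[:, 2], h[:, 3]
    if np.any(f <= 0) or np.any(v <= 0) or np.any(q <= 0):
        r = int(np.argmax((f <= 0) | (v <= 0) | (q <= 0)))
        raise NumericalIntegrationError(
            f"non-positive hemodynamic state in region {REGION_LABELS[r]}"
        )
    kappa, tau = params.kappa_tau_vectors()
    gamma = np.full_like(kappa, params.hemo.gamma)
    ia = 1.0 / params.hemo.alpha
    E0 = params.hemo.E0
    vflow = v**ia
    ds = z - kappa * s - gamma * (f - 1.0)
    df = s
    dv = (f - vflow) / tau
    dq = (f * (1.0 - (1.0 - E0) ** (1.0 / f)) / E0 - vflow * q / v) / tau
    return np.stack([ds, df, dv, dq], axis=1)


def bold_observation(h: np.ndarray, params: DCMParameters) -> np.ndarray:
    """BOLD percent signal change from hemodynamic state (R, 4)."""
    h = np.atleast_2d(np.asarray(h, dtype=float))
    v, q = h[:, 2], h[:, 3]
    if np.any(v <= 0) or np.any(q <= 0):
        raise NumericalIntegrationError("non-positive volume or deoxyhemoglobin")
    k1, k2, k3 = bold_coefficients(params.hemo)
    return np.array(
        [bold_from_state(v[r], q[r], params.hemo.V0, k1, k2, k3) for r in range(len(v))]
    )


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def _hemo_arrays(params: DCMParameters) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    kappa, tau = params.kappa_tau_vectors()
    gamma = np.full_like(kappa, params.hemo.gamma)
    return kappa, gamma, tau


def integrate_batch(
    M0: np.ndarray,
    M1: np.ndarray,
    c: np.ndarray,
    inputs: InputSet,
    kappa: np.ndarray,
    gamma: np.ndarray,
    tau: np.ndarray,
    hemo: HemoParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Low-level batched integration; see :func:`rk4_bold_batch`."""
    k1, k2, k3 = bold_coefficients(hemo)
    return rk4_bold_batch(
        np.ascontiguousarray(M0),
        np.ascontiguousarray(M1),
        np.ascontiguousarray(c),
        inputs.u_drive,
        inputs.u_mod,
        np.ascontiguousarray(kappa),
        np.ascontiguousarray(gamma),
        np.ascontiguousarray(tau),
        1.0 / hemo.alpha,
        hemo.E0,
        hemo.V0,
        k1,
        k2,
        k3,
        inputs.dt,
        inputs.bins_per_tr,
    )


def integrate_dcm(
    spec,
    params: DCMParameters,
    inputs: InputSet,
    run_id: str = "run-01",
    condition_labels: list[str] | None = None,
) -> RoiTimeSeries:
    """Noise-free BOLD time series for one run.

    ``spec`` may be None (parameters taken as-is) or a ModelSpec whose
    masks the parameters must conform to.  An unstable coupling matrix
    (eigenvalue with positive real part, with or without modulation)
    triggers :class:`UnstableModelWarning` and flags the output.
    """
    if spec is not None and not params.conforms_to(spec.a_mask, spec.b_masks, spec.c_mask):
        raise ValueError("parameters have nonzero entries outside the model-spec masks")
    M0 = params.A
    M1 = params.A + params.B[0]
    stable = True
    for M in (M0, M1):
        if np.max(np.linalg.eigvals(M).real) > 0:
            stable = False
            warnings.warn(
                "coupling matrix has an unstable mode; output flagged",
                UnstableModelWarning,
                stacklevel=2,
            )
    kappa, gamma, tau = _hemo_arrays(params)
    y, bad = integrate_batch(
        M0[None], M1[None], params.C[:, 0][None], inputs, kappa[None], gamma[None], tau[None], params.hemo
    )
    if bad[0, 0] >= 0:
        raise NumericalIntegrationError(
            f"hemodynamic state became non-positive in region "
            f"{REGION_LABELS[bad[0, 1]]} at volume {bad[0, 0]}"
        )
    return RoiTimeSeries(
        data=y[0].T,
        TR=inputs.TR,
        run_id=run_id,
        condition_labels=condition_labels,
        stable=stable,
    )
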