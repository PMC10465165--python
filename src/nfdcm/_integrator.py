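"""Fixed-step RK4 integration kernels for the bilinear DCM cascade.

The kernels are compiled with numba and operate on a *batch* of parameter
sets simultaneously; finite-difference Jacobians in the estimator reuse the
same kernel with one batch element per perturbed parameter, which keeps the
per-iteration cost close to a single forward integration.

State layout per region: ``[x, s, f, v, q]`` — neuronal activity, the
vasodilatory signal, normalised blood inflow, volume, and deoxyhemoglobin
content.  Inflow, volume and deoxyhemoglobin rest at 1; a value ≤ 0 during
integration is a numerical failure and is reported via the ``bad`` output
(first offending volume index and region, -1 when the run is clean).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["rk4_bold_batch", "bold_from_state"]

_NSTATE = 5  # x, s, f, v, q


@njit(cache=True, fastmath=True)
def _drift(state, M, c, ud, kappa, gamma, tau, ialpha, E0, out):
    """Time derivative of the stacked neuronal + hemodynamic state.

    state : (R, 5) current state
    M     : (R, R) effective coupling (A or A + B, chosen by the caller)
    c     : (R,)  driving gains, scaled into the neuronal drift by ``ud``
    """
    R = state.shape[0]
    for r in range(R):
        acc = c[r] * ud
        for j in range(R):
            acc += M[r, j] * state[j, 0]
        out[r, 0] = acc
    for r in range(R):
        x = state[r, 0]
        s = state[r, 1]
        f = state[r, 2]
        v = state[r, 3]
        q = state[r, 4]
        out[r, 1] = x - kappa[r] * s - gamma[r] * (f - 1.0)
        out[r, 2] = s
        vflow = v ** ialpha
        out[r, 3] = (f - vflow) / tau[r]
        # oxygen extraction: E(f) = 1 - (1 - E0)^(1/f)
        ex = 1.0 - (1.0 - E0) ** (1.0 / f)
        out[r, 4] = (f * ex / E0 - vflow * q / v) / tau[r]


@njit(cache=True, fastmath=True)
def bold_from_state(v, q, V0, k1, k2, k3):
    """Classical balloon observation equation, percent signal change."""
    return 100.0 * V0 * (k1 * (1.0 - q) + k2 * (1.0 - q / v) + k3 * (1.0 - v))


@njit(cache=True)
def rk4_bold_batch(
    M0, M1, c, u_drive, u_mod, kappa, gamma, tau, ialpha, E0, V0, k1, k2, k3, dt, spv
):
    """Integrate the DCM cascade for a batch of parameter sets.

    Parameters
    ----------
    M0, M1 : (B, R, R)
        Coupling under modulation off (``A``) and on (``A + B``); the
        modulatory input is a box-car so only these two matrices occur.
    c : (B, R)
        Driving-input gain vector (``C`` column for the single drive).
    u_drive, u_mod : (T,)
        Inputs on the micro-time grid, ``T = n_volumes * spv``.
    kappa, gamma, tau : (B, R)
        Per-region hemodynamic rate constants.
    dt : micro-time step in seconds; spv : micro-time bins per volume.

    Returns
    -------
    y : (B, n_volumes, R) BOLD percent signal change sampled at the end of
        each volume.
    bad : (B, 2) int32, first (volume, region) with a non-positive
        hemodynamic state, or (-1, -1).
    """
    B = c.shape[0]
    R = c.shape[1]
    T = u_drive.shape[0]
    n_vol = T // spv
    y = np.zeros((B, n_vol, R))
    bad = np.full((B, 2), -1, dtype=np.int32)

    for b in range(B):
        state = np.zeros((R, _NSTATE))
        for r in range(R):
            state[r, 2] = 1.0
            state[r, 3] = 1.0
            state[r, 4] = 1.0
        k1s = np.empty((R, _NSTATE))
        k2s = np.empty((R, _NSTATE))
        k3s = np.empty((R, _NSTATE))
        k4s = np.empty((R, _NSTATE))
        tmp = np.empty((R, _NSTATE))
        failed = False
        t = 0
        for vlm in range(n_vol):
            for _ in range(spv):
                ud = u_drive[t]
                um = u_mod[t]
                M = M1[b] if um > 0.5 else M0[b]
                _drift(state, M, c[b], ud, kappa[b], gamma[b], tau[b], ialpha, E0, k1s)
                for r in range(R):
                    for i in range(_NSTATE):
                        tmp[r, i] = state[r, i] + 0.5 * dt * k1s[r, i]
                _drift(tmp, M, c[b], ud, kappa[b], gamma[b], tau[b], ialpha, E0, k2s)
                for r in range(R):
                    for i in range(_NSTATE):
                        tmp[r, i] = state[r, i] + 0.5 * dt * k2s[r, i]
                _drift(tmp, M, c[b], ud, kappa[b], gamma[b], tau[b], ialpha, E0, k3s)
                for r in range(R):
                    for i in range(_NSTATE):
                        tmp[r, i] = state[r, i] + dt * k3s[r, i]
                _drift(tmp, M, c[b], ud, kappa[b], gamma[b], tau[b], ialpha, E0, k4s)
                for r in range(R):
                    for i in range(_NSTATE):
                        state[r, i] += (dt / 6.0) * (
                            k1s[r, i] + 2.0 * k2s[r, i] + 2.0 * k3s[r, i] + k4s[r, i]
                        )
                for r in range(R):
                    if state[r, 2] <= 0.0 or state[r, 3] <= 0.0 or state[r, 4] <= 0.0:
                        bad[b, 0] = vlm
                        bad[b, 1] = r
                        failed = True
                t += 1
                if failed:
                    break
            if failed:
                for vv in range(vlm, n_vol):
                    for r in range(R):
                        y[b, vv, r] = np.nan
                break
            for r in range(R):
                y[b, vlm, r] = bold_from_state(state[r, 3], state[r, 4], V0, k1, k2, k3)
    return y, bad
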