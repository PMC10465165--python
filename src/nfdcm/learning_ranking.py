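"""Wasserstein-distance learning ranking.

Learning is quantified per subject as the 1-Wasserstein distance between
the distribution of SMA BOLD values in the initial-baseline run and in
the post-training transfer run, signed by the direction of the mean
change: positive = up-regulation achieved (learner), negative =
reduced activity (non-learner).  Densities are estimated with a Gaussian
kernel (Scott's bandwidth) on a shared grid and the distance computed
from the integrated absolute CDF difference; a raw-sample estimator is
available and agrees within grid tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "Density",
    "WDRecord",
    "principal_eigenvariate",
    "mean_sma_activity",
    "kde_density",
    "wasserstein_1d",
    "wasserstein_samples",
    "rank_cohort",
]


def principal_eigenvariate(voxel_ts: np.ndarray) -> np.ndarray:
    """Summary time series of a multi-voxel ROI.

    First right singular vector of the row-centred voxels x volumes
    matrix, scaled to the ROI's root-mean-square amplitude and
    sign-aligned with the ROI mean time series.
    """
    X = np.asarray(voxel_ts, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1 or X.shape[1] < 2:
        raise ValueError("need a voxels x volumes matrix with >= 2 volumes")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in voxel data")
    Xc = X - X.mean(axis=1, keepdims=True)
    if np.allclose(Xc, 0):
        raise ValueError("all-zero (constant) voxel matrix has no eigenvariate")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    ts = s[0] * Vt[0] / np.sqrt(X.shape[0])
    mean_ts = Xc.mean(axis=0)
    if np.dot(ts, mean_ts) < 0:
        ts = -ts
    return ts


def mean_sma_activity(run, scope: str = "all") -> np.ndarray:
    """Per-volume SMA samples for the selected scope.

    scope: "all" (whole run), "baseline" or "up-regulation" (volumes in
    those blocks).  These samples form the empirical distribution whose
    density is estimated downstream.
    """
    sma = run.region("SMA")
    if scope == "all":
        out = sma
    else:
        if run.condition_labels is None:
            raise ValueError("run has no condition labels; cannot scope by block")
        mask = np.array([lab == scope for lab in run.condition_labels])
        out = sma[mask]
    if out.size == 0:
        raise ValueError(f"scope {scope!r} selects no volumes")
    return np.asarray(out, dtype=float)


@dataclass
class Density:
    """KDE evaluated on a grid, or a degenerate point mass."""

    grid: np.ndarray | None
    pdf: np.ndarray | None
    degenerate: bool = False
    point: float | None = None

    def cdf(self) -> np.ndarray:
        from scipy.integrate import cumulative_trapezoid

        c = cumulative_trapezoid(self.pdf, self.grid, initial=0.0)
        return c / c[-1]


def _scott_bandwidth(samples: np.ndarray) -> float:
    return float(samples.std(ddof=1) * samples.size ** (-1.0 / 5.0))


def kde_density(
    samples: np.ndarray,
    bandwidth_rule: str = "scott",
    grid: np.ndarray | None = None,
    other: np.ndarray | None = None,
    n_grid: int = 1024,
) -> Density:
    """Gaussian KDE on a shared grid.

    The grid spans both ``samples`` and ``other`` (the comparison set)
    plus three bandwidths on each side, so two densities built with the
    same arguments share support.  Zero-spread samples yield a degenerate
    point mass handled analytically downstream.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two samples")
    if np.ptp(x) == 0:
        return Density(grid=None, pdf=None, degenerate=True, point=float(x[0]))
    if bandwidth_rule != "scott":
        raise ValueError(f"unknown bandwidth rule {bandwidth_rule!r}")
    if grid is None:
        pool = x if other is None else np.concatenate([x, np.asarray(other, dtype=float)])
        bw = _scott_bandwidth(x)
        if other is not None and np.ptp(other) > 0:
            bw = max(bw, _scott_bandwidth(np.asarray(other, dtype=float)))
        lo, hi = pool.min() - 3 * bw, pool.max() + 3 * bw
        grid = np.linspace(lo, hi, n_grid)
    kde = stats.gaussian_kde(x, bw_method="scott")
    pdf = kde(grid)
    area = np.trapezoid(pdf, grid)
    pdf = pdf / area
    return Density(grid=grid, pdf=pdf)


def wasserstein_1d(dist_a: Density, dist_b: Density) -> float:
    """1-Wasserstein distance between two densities on a common grid.

    W1 = integral of |CDF_a - CDF_b|; symmetric, nonnegative, zero iff
    the distributions coincide on the grid.  Degenerate point masses are
    handled analytically (|mu_a - mu_b| when both are points).
    """
    if dist_a.degenerate and dist_b.degenerate:
        return abs(dist_a.point - dist_b.point)
    if dist_a.degenerate or dist_b.degenerate:
        pt = dist_a.point if dist_a.degenerate else dist_b.point
        d = dist_b if dist_a.degenerate else dist_a
        cdf = d.cdf()
        step = np.where(d.grid >= pt, 1.0, 0.0)
        return float(np.trapezoid(np.abs(cdf - step), d.grid))
    if dist_a.grid.shape != dist_b.grid.shape or not np.allclose(dist_a.grid, dist_b.grid):
        raise ValueError("densities must share a common grid")
    return float(np.trapezoid(np.abs(dist_a.cdf() - dist_b.cdf()), dist_a.grid))


def wasserstein_samples(a: np.ndarray, b: np.ndarray) -> float:
    """Raw-sample W1 (independent estimator; agrees with the KDE route
    within grid tolerance)."""
    return float(stats.wasserstein_distance(np.asarray(a), np.asarray(b)))


@dataclass
class WDRecord:
    """Signed Wasserstein learning score for one subject."""

    subject_id: str
    wd: float
    sign: int
    signed_wd: float
    rank: int
    label: str


def rank_cohort(
    baseline_runs: dict,
    transfer_runs: dict,
    rule: str = "sign",
    scope: str = "all",
) -> list[WDRecord]:
    """Rank subjects by signed Wasserstein distance baseline -> transfer.

    signed_wd = sign(mean_transfer - mean_baseline) * W1; rank descending.
    Label rules: "sign" (learner iff signed_wd > 0; ties are
    non-learners) or "median" (upper half by signed_wd).
    """
    if rule not in ("sign", "median"):
        raise ValueError(f"unknown label rule {rule!r}")
    subjects = sorted(baseline_runs.keys())
    for s in subjects:
        if s not in transfer_runs:
            raise ValueError(f"subject {s} is missing a transfer run")
    records = []
    for s in subjects:
        base = mean_sma_activity(baseline_runs[s], scope=scope)
        trans = mean_sma_activity(transfer_runs[s], scope=scope)
        da = kde_density(base, other=trans)
        db = kde_density(trans, other=base)
        wd = wasserstein_1d(da, db)
        delta = float(trans.mean() - base.mean())
        sign = 1 if delta > 0 else (-1 if delta < 0 else 0)
        records.append((s, wd, sign, sign * wd))
    order = np.argsort([-r[3] for r in records], kind="stable")
    out: list[WDRecord] = []
    signed = np.array([r[3] for r in records])
    median = float(np.median(signed))
    for rank, i in enumerate(order, start=1):
        s, wd, sign, swd = records[i]
        if rule == "sign":
            label = "learner" if swd > 0 else "non_learner"
        else:
            label = "learner" if swd > median else "non_learner"
        out.append(
            WDRecord(subject_id=s, wd=wd, sign=sign, signed_wd=swd, rank=rank, label=label)
        )
    return out
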