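"""Learner vs non-learner comparison of modulatory (B) parameters.

Subjects' Bayesian-model-averaged modulation strengths are compared
between groups with a two-sample pooled-variance t-test per connection,
Bonferroni-corrected over the number of modulatory connections tested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["GroupComparison", "two_sample_ttest", "bonferroni_correct", "compare_groups"]


@dataclass
class GroupComparison:
    """Per-connection group test results, sorted by significance then |t|."""

    table: pd.DataFrame  # connection, mean_a, mean_b, t, p, significant
    m: int
    alpha: float

    def significant_connections(self) -> list[str]:
        return list(self.table.loc[self.table["significant"], "connection"])

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "n_tests": self.m,
            "results": self.table.to_dict(orient="records"),
        }


def two_sample_ttest(values_a, values_b, welch: bool = False) -> tuple[float, float]:
    """Two-sided two-sample t-test (pooled variance unless ``welch``).

    Degenerate zero-variance input: equal means give (0, 1) by
    convention; unequal means are an error.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite values in groups")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if np.isclose(a.mean(), b.mean()):
            return 0.0, 1.0
        raise ValueError("zero pooled variance with unequal means")
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def bonferroni_correct(pvals, alpha: float = 0.05) -> np.ndarray:
    """flag_i = p_i < alpha / m with m = len(pvals)."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    return p < alpha / p.size


def compare_groups(
    bma_table: pd.DataFrame,
    labels: dict[str, str],
    alpha: float = 0.05,
    parameter_prefix: str = "B[",
    welch: bool = False,
) -> GroupComparison:
    """Group comparison over the modulatory parameters of a BMA table.

    ``bma_table`` has one row per subject and one column per parameter
    (as produced by :meth:`nfdcm.bms.BMAResult.table`); only columns
    starting with ``parameter_prefix`` are tested (the modulatory
    effects).  Bonferroni correction uses the number of tested
    connections.
    """
    for sid in bma_table.index:
        if sid not in labels:
            raise ValueError(f"subject {sid} has no group label")
    learners = [s for s in bma_table.index if labels[s] == "learner"]
    non_learners = [s for s in bma_table.index if labels[s] == "non_learner"]
    if len(learners) < 2 or len(non_learners) < 2:
        raise ValueError("each group needs at least two subjects")
    cols = [c for c in bma_table.columns if c.startswith(parameter_prefix)]
    if not cols:
        raise ValueError(f"no parameters matching prefix {parameter_prefix!r}")
    rows = []
    for c in cols:
        va = bma_table.loc[learners, c].to_numpy()
        vb = bma_table.loc[non_learners, c].to_numpy()
        t, p = two_sample_ttest(va, vb, welch=welch)
        rows.append(
            {
                "connection": c,
                "mean_learner": float(va.mean()),
                "mean_non_learner": float(vb.mean()),
                "t": t,
                "p": p,
            }
        )
    table = pd.DataFrame(rows)
    table["significant"] = bonferroni_correct(table["p"].to_numpy(), alpha)
    table = table.sort_values(
        by=["significant", "t"], key=lambda s: s.abs() if s.name == "t" else s, ascending=False
    ).reset_index(drop=True)
    return GroupComparison(table=table, m=len(cols), alpha=alpha)
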