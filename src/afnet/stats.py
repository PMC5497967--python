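"""Paired comparison of density-resolved network-parameter curves.

Each subject contributes one curve per metric (metric value as a
function of connection density).  Conditions (e.g. baseline vs
post-ablation) are compared with a Wilcoxon signed-rank test — exact
null distribution for n <= 25 pairs, tie-corrected normal approximation
above — both per density point and pooled on the per-subject
density-averaged metric.  The pooled test is the headline number; no
multiple-testing correction is applied by default (a Benjamini-Hochberg
option exists behind a flag).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


class DegenerateTestError(ValueError):
    """All paired differences are zero; the signed-rank test is undefined."""


# --------------------------------------------------------------------------
# Wilcoxon signed-rank


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p by dynamic programming over signed rank sums.

    Ranks may be half-integers (average ties), so sums are doubled to
    index an integer DP table.  Equivalent to enumerating all 2^n sign
    assignments, in O(n * n^2) instead of O(2^n).
    """
    r2 = np.round(2 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(round(2 * w_plus))
    p_le = counts[: w2 + 1].sum()
    p_ge = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_signed_rank(differences) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped (Wilcoxon convention); ties in |d| get
    average ranks.  Returns (W+, two-sided p): exact distribution for
    n <= 25 remaining pairs, tie-corrected normal approximation above.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise DegenerateTestError("all paired differences are zero")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= 25:
        return w_plus, _exact_signed_rank_p(ranks, w_plus)
    mu = n * (n + 1) / 4.0
    # tie correction on the variance
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum()) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    z = (w_plus - mu) / np.sqrt(var)
    return w_plus, float(min(1.0, 2.0 * sps.norm.sf(abs(z))))


# --------------------------------------------------------------------------
# subject curves


@dataclass
class SubjectCurve:
    """One subject's metric-vs-density curve under one condition."""

    subject_id: str
    condition: str
    metric: str
    densities: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.densities = np.asarray(self.densities, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.densities.shape != self.values.shape:
            raise ValueError("densities and values must align")


def _common_grid(curves: list[SubjectCurve]) -> np.ndarray:
    grid = curves[0].densities
    for c in curves[1:]:
        if not np.array_equal(c.densities, grid):
            raise ValueError("all curves must share one density grid")
    return grid


def summarize_group(curves: list[SubjectCurve], ci: float = 0.95) -> pd.DataFrame:
    """Mean and t-distribution CI per density point across subjects.

    Returns a tidy frame (density, mean, ci_low, ci_high, n).  With a
    single subject the mean is returned and the CI columns are NaN.
    """
    if not curves:
        raise ValueError("need at least one curve")
    grid = _common_grid(curves)
    stack = np.stack([c.values for c in curves])
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    if n >= 2:
        sem = stack.std(axis=0, ddof=1) / np.sqrt(n)
        t_crit = sps.t.ppf(0.5 + ci / 2.0, df=n - 1)
        lo, hi = mean - t_crit * sem, mean + t_crit * sem
    else:
        warnings.warn("single subject; CI undefined", stacklevel=2)
        lo = hi = np.full_like(mean, np.nan)
    return pd.DataFrame(
        {"density": grid, "mean": mean, "ci_low": lo, "ci_high": hi, "n": n}
    )


@dataclass
class PairedComparison:
    """Per-density and pooled Wilcoxon comparison of two conditions."""

    metric: str
    densities: np.ndarray
    p_per_density: np.ndarray
    pooled_statistic: float
    pooled_p: float
    n_pairs: int
    significant: bool
    alpha: float = 0.05
    summary_a: pd.DataFrame | None = field(default=None, repr=False)
    summary_b: pd.DataFrame | None = field(default=None, repr=False)
    p_adjusted: np.ndarray | None = None


def compare_conditions(
    a: list[SubjectCurve],
    b: list[SubjectCurve],
    *,
    paired: bool = True,
    alpha: float = 0.05,
    adjust: bool = False,
) -> PairedComparison:
    """Compare a metric between two conditions across the density grid.

    Paired mode matches curves by subject id and runs the signed-rank
    test per density plus pooled on each subject's density-averaged
    value (the headline p).  Degenerate points (all differences zero,
    e.g. a self-comparison) report p = 1.  ``adjust`` applies
    Benjamini-Hochberg across the per-density p-values.
    """
    if not a or not b:
        raise ValueError("both condition groups must be non-empty")
    metric = a[0].metric
    grid = _common_grid(a + b)
    if paired:
        by_id_a = {c.subject_id: c for c in a}
        by_id_b = {c.subject_id: c for c in b}
        common = sorted(set(by_id_a) & set(by_id_b))
        if not common:
            raise ValueError("paired comparison requires overlapping subject ids")
        va = np.stack([by_id_a[s].values for s in common])
        vb = np.stack([by_id_b[s].values for s in common])
        diffs = vb - va

        def _test(x: np.ndarray) -> float:
            try:
                return wilcoxon_signed_rank(x)[1]
            except DegenerateTestError:
                return 1.0

        p_density = np.array([_test(diffs[:, j]) for j in range(diffs.shape[1])])
        pooled_diff = diffs.mean(axis=1)
        try:
            pooled_stat, pooled_p = wilcoxon_signed_rank(pooled_diff)
        except DegenerateTestError:
            pooled_stat, pooled_p = float("nan"), 1.0
        n_pairs = len(common)
    else:
        va = np.stack([c.values for c in a])
        vb = np.stack([c.values for c in b])
        p_density = np.array([
            sps.mannwhitneyu(va[:, j], vb[:, j], alternative="two-sided").pvalue
            for j in range(len(grid))
        ])
        res = sps.mannwhitneyu(va.mean(axis=1), vb.mean(axis=1),
                               alternative="two-sided")
        pooled_stat, pooled_p = float(res.statistic), float(res.pvalue)
        n_pairs = min(len(a), len(b))

    p_adj = sps.false_discovery_control(p_density) if adjust else None
    return PairedComparison(
        metric=metric,
        densities=grid,
        p_per_density=p_density,
        pooled_statistic=float(pooled_stat),
        pooled_p=float(pooled_p),
        n_pairs=n_pairs,
        significant=bool(pooled_p < alpha),
        alpha=alpha,
        summary_a=summarize_group(a) if len(a) > 1 else None,
        summary_b=summarize_group(b) if len(b) > 1 else None,
        p_adjusted=p_adj,
    )


def curves_from_sweep(
    subject_id: str, condition: str, sweep: list
) -> dict[str, SubjectCurve]:
    """Convert one density_sweep result into per-metric SubjectCurves."""
    rows = [(d, m) for d, m in sweep if m is not None]
    if not rows:
        raise ValueError("sweep produced no valid metric rows")
    densities = np.array([d for d, _ in rows])
    out: dict[str, SubjectCurve] = {}
    for name in rows[0][1].as_dict():
        if name == "density":
            continue
        vals = np.array([m.as_dict()[name] for _, m in rows])
        out[name] = SubjectCurve(subject_id, condition, name, densities, vals)
    return out
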