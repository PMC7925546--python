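"""Statistical machinery: goodness of fit, bootstrap tests, correlations,
rank-binned trends and two-group region comparisons.

The bootstrap test follows the one-sided resampling recipe used throughout
the analysis: draw N samples with replacement, recompute the statistic, repeat
B times, count the K replicates that satisfy the tested direction, and report
p = 1 - K/B.  Two-sided p-values are the doubled smaller one-sided p capped
at 1 (the one-sided recipe is the primitive).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


# --------------------------------------------------------------------------
# goodness of fit
# --------------------------------------------------------------------------

def goodness_of_fit(data: np.ndarray, model: np.ndarray) -> float:
    """1 - SS_res / SS_tot of a model against data.

    Equals 1 for a perfect fit and can be arbitrarily negative for a fit
    worse than the data mean.  Raises for constant data (total sum of
    squares 0), where the quantity is undefined.
    """
    data = np.asarray(data, dtype=float).ravel()
    model = np.asarray(model, dtype=float).ravel()
    if data.shape != model.shape:
        raise ValueError("data and model must have the same number of points")
    ss_tot = float(np.sum((data - data.mean()) ** 2))
    if ss_tot == 0.0:
        raise ZeroDivisionError("goodness of fit undefined for constant data")
    ss_res = float(np.sum((data - model) ** 2))
    return 1.0 - ss_res / ss_tot


# --------------------------------------------------------------------------
# bootstrap
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BootstrapResult:
    estimate: float
    p: float
    B: int
    seed: int
    statistic: str
    direction: str

    @property
    def significant(self) -> bool:
        return self.p < 0.05


def _replicate_statistic(sample: np.ndarray, idx: np.ndarray, statistic: str) -> np.ndarray:
    if statistic == "mean":
        return sample[idx].mean(axis=1)
    # correlation: sample is (n, 2); resample rows, Pearson r per replicate
    x = sample[idx, 0]
    y = sample[idx, 1]
    xm = x - x.mean(axis=1, keepdims=True)
    ym = y - y.mean(axis=1, keepdims=True)
    denom = np.sqrt((xm**2).sum(axis=1) * (ym**2).sum(axis=1))
    if np.any(denom == 0):
        raise ValueError("degenerate bootstrap replicate: zero variance")
    return (xm * ym).sum(axis=1) / denom


def bootstrap_test(
    sample: np.ndarray,
    statistic: str = "mean",
    direction: str = "greater",
    reference: float = 0.0,
    B: int = 1000,
    seed: int = 0,
) -> BootstrapResult:
    """One-sided (or doubled two-sided) resampling test of a statistic.

    Parameters
    ----------
    sample:
        1-D values for ``statistic='mean'``; an (n, 2) array of paired values
        for ``statistic='correlation'``.
    direction:
        'greater' / 'less' test whether the statistic exceeds / falls below
        ``reference``; 'two-sided' doubles the smaller one-sided p.
    """
    sample = np.asarray(sample, dtype=float)
    if statistic not in ("mean", "correlation"):
        raise ValueError(f"unknown statistic {statistic!r}")
    if statistic == "correlation":
        if sample.ndim != 2 or sample.shape[1] != 2:
            raise ValueError("correlation statistic needs an (n, 2) sample")
        if np.ptp(sample[:, 0]) == 0 or np.ptp(sample[:, 1]) == 0:
            raise ValueError("degenerate sample: zero variance")
    else:
        sample = sample.ravel()
    n = sample.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")
    if B < 1:
        raise ValueError("B must be >= 1")

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(B, n))
    reps = _replicate_statistic(sample, idx, statistic)

    if statistic == "mean":
        estimate = float(sample.mean())
    else:
        estimate = float(np.corrcoef(sample[:, 0], sample[:, 1])[0, 1])

    k_greater = int(np.sum(reps > reference))
    k_less = int(np.sum(reps < reference))
    if direction == "greater":
        p = 1.0 - k_greater / B
    elif direction == "less":
        p = 1.0 - k_less / B
    elif direction == "two-sided":
        p = min(1.0, 2.0 * min(1.0 - k_greater / B, 1.0 - k_less / B))
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return BootstrapResult(estimate=estimate, p=float(p), B=B, seed=seed,
                           statistic=statistic, direction=direction)


# --------------------------------------------------------------------------
# correlation with regression-line summary
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationResult:
    coefficient: float
    p: float
    method: str
    slope: float
    intercept: float


def correlate(x: np.ndarray, y: np.ndarray, method: str = "pearson") -> CorrelationResult:
    """Pearson or Spearman correlation plus a least-squares line for plotting."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must be equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y")
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    slope, intercept = np.polyfit(x, y, 1)
    return CorrelationResult(float(r), float(p), method, float(slope), float(intercept))


def robust_regression_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Huber-loss robust regression line (slope, intercept)."""
    import statsmodels.api as sm

    x = np.asarray(x, dtype=float).ravel()
    exog = sm.add_constant(x)
    fit = sm.RLM(np.asarray(y, dtype=float).ravel(), exog,
                 M=sm.robust.norms.HuberT()).fit()
    return float(fit.params[1]), float(fit.params[0])


# --------------------------------------------------------------------------
# rank-binned trend
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BinnedTrend:
    group_edges: np.ndarray          # index boundaries into the rank order
    group_means: np.ndarray
    group_stds: np.ndarray
    group_x_means: np.ndarray
    correlation: float               # Spearman rho of the raw x, y
    p: float
    n_groups: int = field(default=6)


def binned_trend(x: np.ndarray, y: np.ndarray, n_groups: int = 6) -> BinnedTrend:
    """Split sites into near-equal groups by the rank of x; per-group mean/std of y.

    The first (n mod n_groups) groups take the extra element; ties in x are
    broken by stable sort order, so the split is deterministic.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = x.size
    if y.size != n:
        raise ValueError("x and y must have the same length")
    if n < n_groups:
        raise ValueError("need at least as many points as groups")
    order = np.argsort(x, kind="stable")
    base, extra = divmod(n, n_groups)
    sizes = np.full(n_groups, base, dtype=int)
    sizes[:extra] += 1
    edges = np.concatenate([[0], np.cumsum(sizes)])
    means = np.empty(n_groups)
    stds = np.empty(n_groups)
    x_means = np.empty(n_groups)
    for g in range(n_groups):
        sel = order[edges[g]:edges[g + 1]]
        means[g] = y[sel].mean()
        stds[g] = y[sel].std(ddof=1) if sel.size > 1 else 0.0
        x_means[g] = x[sel].mean()
    if np.ptp(y) == 0:
        raise ValueError("y is constant; rank correlation undefined")
    rho, p = sps.spearmanr(x, y)
    return BinnedTrend(group_edges=edges, group_means=means, group_stds=stds,
                       group_x_means=x_means, correlation=float(rho), p=float(p),
                       n_groups=n_groups)


# --------------------------------------------------------------------------
# two-group (region) comparison
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupComparison:
    group_means: dict
    group_stds: dict
    t_statistic: float
    p: float
    distance_correlation: CorrelationResult | None


def group_compare(values, group_labels, covariate=None) -> GroupComparison:
    """Compare a statistic between two labelled groups (e.g. cortical areas).

    Reports per-group mean +/- sd and a two-sample t-test; when a signed
    covariate (distance to the group border) is supplied, also its Spearman
    correlation with the statistic.
    """
    values = np.asarray(values, dtype=float).ravel()
    labels = np.asarray(group_labels).ravel()
    uniq = pd.unique(labels)
    if len(uniq) != 2:
        raise ValueError("group_compare needs exactly two groups")
    a = values[labels == uniq[0]]
    b = values[labels == uniq[1]]
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    t, p = sps.ttest_ind(a, b)
    corr = None
    if covariate is not None:
        corr = correlate(np.asarray(covariate, dtype=float), values, method="spearman")
    return GroupComparison(
        group_means={uniq[0]: float(a.mean()), uniq[1]: float(b.mean())},
        group_stds={uniq[0]: float(a.std(ddof=1)), uniq[1]: float(b.std(ddof=1))},
        t_statistic=float(t), p=float(p), distance_correlation=corr,
    )
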