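"""Response matrices and the cross-orientation interaction index.

A response matrix M1(c1, c2) holds the trial-averaged response of one signal
(low-gamma power, high-gamma power, or MUA) over the full plaid contrast
grid.  The additive prediction matrix

    M2(c1, c2) = M1(c1, 0) + M1(0, c2) - M1(0, 0)

is what the plaid response would be if the two component gratings combined
linearly (the Methods form; a variant without the -M1(0,0) term, as printed
in one figure caption, is selectable).  The interaction index

    index = 2 * (sum M1 - sum M2) / (sum M1 + sum M2)

with both sums over the plaid-only block (c1 > 0, c2 > 0), is negative when
the plaid response falls short of the additive prediction
(cross-orientation suppression) and positive for facilitation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import ContrastGrid
from .stats import goodness_of_fit


@dataclass
class ResponseMatrix:
    """Trial-mean responses on the plaid contrast grid, rows indexing c1."""

    values: np.ndarray
    grid: ContrastGrid
    signal: str = "MUA"
    trials: np.ndarray | None = None   # (n_trials, n, n) replicate values
    normalized: bool = False
    ground_truth: object | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.grid.n
        if self.values.shape != (n, n):
            raise ValueError(f"values must be {n}x{n} for this grid")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("response matrix contains non-finite values")
        if self.trials is not None:
            self.trials = np.asarray(self.trials, dtype=float)
            if self.trials.shape[1:] != (n, n):
                raise ValueError("trials must be (n_trials, n, n)")

    @property
    def n_trials(self) -> int:
        return 0 if self.trials is None else self.trials.shape[0]

    def normalized_copy(self) -> "ResponseMatrix":
        """Divide all cells (and trials) by the maximum cell value."""
        peak = self.values.max()
        if peak <= 0:
            raise ValueError("cannot normalize a matrix with non-positive maximum")
        trials = None if self.trials is None else self.trials / peak
        return ResponseMatrix(self.values / peak, self.grid, self.signal,
                              trials=trials, normalized=True,
                              ground_truth=self.ground_truth)


def build_matrix(trials: np.ndarray, grid: ContrastGrid, signal: str = "MUA",
                 normalize: bool = False) -> ResponseMatrix:
    """Average per-condition replicates into a response matrix.

    ``trials`` is (n_trials, n, n) with at least one trial per condition
    (NaN marks a missing replicate; a condition that is all-NaN is an error).
    """
    trials = np.asarray(trials, dtype=float)
    n = grid.n
    if trials.ndim != 3 or trials.shape[1:] != (n, n):
        raise ValueError(f"trials must be (n_trials, {n}, {n})")
    counts = np.sum(np.isfinite(trials), axis=0)
    if np.any(counts == 0):
        c1, c2 = grid.pairs()
        missing = [(float(a), float(b))
                   for a, b in zip(c1[counts == 0], c2[counts == 0])]
        raise ValueError(f"conditions with no trials: {missing}")
    values = np.nanmean(trials, axis=0)
    mat = ResponseMatrix(values, grid, signal=signal, trials=trials)
    return mat.normalized_copy() if normalize else mat


@dataclass(frozen=True)
class InteractionResult:
    index: float
    prediction: np.ndarray            # full additive-prediction matrix M2
    p: float | None = None            # bootstrap p for index < 0, if requested
    variant: str = "methods"


def additive_prediction(values: np.ndarray, variant: str = "methods") -> np.ndarray:
    """Additive prediction M2 from the single-grating margins of M1."""
    values = np.asarray(values, dtype=float)
    row0 = values[:, 0][:, None]      # M1(c1, 0)
    col0 = values[0, :][None, :]      # M1(0, c2)
    if variant == "methods":
        return row0 + col0 - values[0, 0]
    if variant == "caption":
        return row0 + col0
    raise ValueError(f"unknown prediction variant {variant!r}")


def interaction_index(matrix: ResponseMatrix, variant: str = "methods",
                      bootstrap_B: int = 0, seed: int = 0) -> InteractionResult:
    """Cross-orientation interaction index of one response matrix.

    Optionally attaches a one-sided bootstrap p for index < 0, resampling
    trials within each condition (requires per-trial replicates).
    """
    m1 = matrix.values
    m2 = additive_prediction(m1, variant)
    idx = _index_from(m1, m2)

    p = None
    if bootstrap_B > 0:
        if matrix.trials is None:
            raise ValueError("bootstrap over trials requires per-trial replicates")
        rng = np.random.default_rng(seed)
        nt = matrix.trials.shape[0]
        k = 0
        for _ in range(bootstrap_B):
            pick = rng.integers(0, nt, size=nt)
            vals = matrix.trials[pick].mean(axis=0)
            rep = _index_from(vals, additive_prediction(vals, variant))
            k += rep < 0.0
        p = 1.0 - k / bootstrap_B
    return InteractionResult(index=idx, prediction=m2, p=p, variant=variant)


def _index_from(m1: np.ndarray, m2: np.ndarray) -> float:
    s1 = float(m1[1:, 1:].sum())
    s2 = float(m2[1:, 1:].sum())
    if s1 + s2 == 0:
        raise ZeroDivisionError("interaction index undefined: sums cancel")
    return 2.0 * (s1 - s2) / (s1 + s2)


@dataclass(frozen=True)
class LinearPrediction:
    fitted: np.ndarray
    residual: np.ndarray
    gof: float
    slope: float
    intercept: float


def linear_predict_pattern(source: ResponseMatrix,
                           target: ResponseMatrix) -> LinearPrediction:
    """Affine least-squares prediction of one signal's pattern from another's.

    Fits target ~ slope * source + intercept over all grid cells; the
    goodness of fit quantifies how much of the target pattern the source
    pattern explains (used to compare gamma patterns against MUA patterns).
    """
    if source.grid.levels != target.grid.levels:
        raise ValueError("matrices must share the contrast grid")
    x = source.values.ravel()
    y = target.values.ravel()
    if np.ptp(y) == 0:
        raise ZeroDivisionError("constant target: goodness of fit undefined")
    slope, intercept = np.polyfit(x, y, 1)
    fitted = slope * source.values + intercept
    gof = goodness_of_fit(target.values, fitted)
    return LinearPrediction(fitted=fitted, residual=target.values - fitted,
                            gof=gof, slope=float(slope), intercept=float(intercept))
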