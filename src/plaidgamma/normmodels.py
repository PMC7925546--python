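"""Divisive-normalization models for plaid response matrices.

Three model variants describe the response R(c1, c2) of a site to a plaid
whose component gratings have contrasts c1, c2 (fractions):

M0 (the modified normalization model, the primary variant)::

    R1 = Rmax * c1^m1 / (c50^m2 + (c1 + c2)^m2)
    R2 = Rmax * c2^m1 / (c50^m2 + (c1 + c2)^m2)

M1 (single exponent n, mask weight k in the pool)::

    R1 = Rmax * c1^n / (c50^n + c1^n + (k*c2)^n)
    R2 = Rmax * c2^n / (c50^n + (k*c1)^n + c2^n)

M2 (separate exponents, per-component pool)::

    R1 = Rmax * c1^m1 / (c50^m2 + c1^m2 + c2^m2)
    R2 = Rmax * c2^m1 / (c50^m2 + c1^m2 + c2^m2)

In every variant the recorded response is the orientation-weighted sum

    R = b * R1 + (1 - b) * R2 + R0

with b in [0, 1] the weight of the first component and R0 >= 0 an offset,
included uniformly across variants so the comparison is not confounded by
offset handling.  The key derived quantity for M0/M2 is m1 - m2: when the
denominator exponent m2 outgrows the numerator exponent m1 the model's
plaid responses are suppressed relative to the additive prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .interaction import ResponseMatrix
from .stats import goodness_of_fit

MODEL_IDS = ("M0", "M1", "M2")

#: free parameters per variant, in vector order
PARAM_NAMES: dict[str, tuple[str, ...]] = {
    "M0": ("Rmax", "c50", "m1", "m2", "b", "R0"),
    "M1": ("Rmax", "c50", "n", "k", "b", "R0"),
    "M2": ("Rmax", "c50", "m1", "m2", "b", "R0"),
}


def evaluate_model(model_id: str, params: dict, c1, c2) -> np.ndarray:
    """Evaluate one normalization-model variant at contrast pairs (c1, c2)."""
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model {model_id!r}")
    c1 = np.asarray(c1, dtype=float)
    c2 = np.asarray(c2, dtype=float)
    rmax, c50, b, r0 = (params["Rmax"], params["c50"], params["b"], params["R0"])
    if model_id == "M1":
        n, k = params["n"], params["k"]
        r1 = rmax * c1**n / (c50**n + c1**n + (k * c2) ** n)
        r2 = rmax * c2**n / (c50**n + (k * c1) ** n + c2**n)
    else:
        m1, m2 = params["m1"], params["m2"]
        if model_id == "M0":
            pool = c50**m2 + (c1 + c2) ** m2
            r1 = rmax * c1**m1 / pool
            r2 = rmax * c2**m1 / pool
        else:  # M2
            pool = c50**m2 + c1**m2 + c2**m2
            r1 = rmax * c1**m1 / pool
            r2 = rmax * c2**m1 / pool
    return b * r1 + (1.0 - b) * r2 + r0


@dataclass(frozen=True)
class NormalizationFit:
    model_id: str
    params: dict
    gof: float
    converged: bool
    weakly_identified: bool = False

    @property
    def m_diff(self) -> float | None:
        """m1 - m2 (M0/M2 only)."""
        if self.model_id == "M1" or not self.converged:
            return None
        return float(self.params["m1"] - self.params["m2"])

    def predict(self, grid) -> np.ndarray:
        c1, c2 = grid.pairs()
        return evaluate_model(self.model_id, self.params, c1, c2)


def default_bounds(model_id: str, data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Box bounds for the fit, scaled to the data range."""
    dmax = float(np.max(data))
    dmin = float(np.min(data))
    scale = dmax if dmax > 0 else 1.0
    common_lo = {"Rmax": 1e-6 * scale, "c50": 1e-3, "b": 0.0, "R0": 0.0}
    common_hi = {"Rmax": 10.0 * scale, "c50": 2.0, "b": 1.0,
                 "R0": max(dmin, 0.0) + 1e-3 * scale}
    exp_lo, exp_hi = 0.1, 8.0
    lo, hi = [], []
    for name in PARAM_NAMES[model_id]:
        if name in common_lo:
            lo.append(common_lo[name]); hi.append(common_hi[name])
        elif name == "k":
            lo.append(0.0); hi.append(4.0)
        else:  # m1, m2, n
            lo.append(exp_lo); hi.append(exp_hi)
    return np.asarray(lo), np.asarray(hi)


def _data_driven_start(model_id: str, matrix: ResponseMatrix,
                       lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    vals = matrix.values
    dmax, dmin = float(vals.max()), float(vals.min())
    # which component drives the site harder decides the starting b
    s1 = vals[1:, 0].sum()   # responses to grating 1 alone
    s2 = vals[0, 1:].sum()   # responses to grating 2 alone
    b0 = s1 / (s1 + s2) if (s1 + s2) > 0 else 0.5
    start = {"Rmax": max(dmax - dmin, 1e-3), "c50": 0.2, "b": b0,
             "R0": max(dmin, 0.0), "m1": 2.0, "m2": 2.0, "n": 2.0, "k": 1.0}
    x0 = np.array([start[name] for name in PARAM_NAMES[model_id]])
    return np.clip(x0, lo, hi)


def fit_model(matrix: ResponseMatrix, model_id: str = "M0",
              bounds: tuple[np.ndarray, np.ndarray] | None = None,
              n_restarts: int = 40, seed: int = 0) -> NormalizationFit:
    """Bounded least-squares fit of one model variant to a response matrix.

    Runs one data-driven start plus ``n_restarts`` Latin-hypercube starts
    within the bounds and keeps the best solution; goodness of fit is
    1 - SS_res/SS_tot over all grid cells.  A constant matrix (undefined
    goodness of fit) or failure of every start yields ``converged=False``.
    """
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model {model_id!r}")
    names = PARAM_NAMES[model_id]
    c1, c2 = matrix.grid.pairs()
    data = matrix.values.ravel()
    if np.ptp(data) == 0:
        return NormalizationFit(model_id, {}, np.nan, converged=False)

    lo, hi = default_bounds(model_id, data) if bounds is None else bounds

    def residuals(x: np.ndarray) -> np.ndarray:
        p = dict(zip(names, x))
        return evaluate_model(model_id, p, c1, c2).ravel() - data

    starts = [_data_driven_start(model_id, matrix, lo, hi)]
    if n_restarts > 0:
        sampler = qmc.LatinHypercube(d=len(names), seed=seed)
        starts.extend(lo + sampler.random(n_restarts) * (hi - lo))

    best, best_cost = None, np.inf
    for x0 in starts:
        try:
            sol = least_squares(residuals, x0, bounds=(lo, hi), method="trf",
                                xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except Exception:
            continue
        if sol.cost < best_cost:
            best, best_cost = sol, sol.cost
    if best is None:
        return NormalizationFit(model_id, {}, np.nan, converged=False)

    params = dict(zip(names, (float(v) for v in best.x)))
    model = evaluate_model(model_id, params, c1, c2).ravel()
    gof = goodness_of_fit(data, model)
    weak = params["b"] < 0.02 or params["b"] > 0.98
    return NormalizationFit(model_id, params, gof, converged=True,
                            weakly_identified=weak)


def compare_parameters(fits_by_signal: dict[str, list[NormalizationFit]]):
    """Cross-signal parameter comparison: means, correlations, m1-m2 signs.

    Takes matched per-site fit lists keyed by signal name and returns a dict
    with per-signal summaries (mean/sd per parameter, fraction of sites with
    m1 - m2 > 0) and pairwise Pearson correlations of each parameter across
    signals (skipped for pairs with < 3 matched converged sites).
    """
    import pandas as pd

    from .stats import correlate

    frames = {}
    for signal, fits in fits_by_signal.items():
        rows = []
        for f in fits:
            row = {"converged": f.converged}
            row.update(f.params)
            if f.m_diff is not None:
                row["m_diff"] = f.m_diff
            rows.append(row)
        frames[signal] = pd.DataFrame(rows)

    summary = {}
    for signal, df in frames.items():
        ok = df[df["converged"]]
        stats_ = {}
        for col in ok.columns:
            if col == "converged":
                continue
            stats_[col] = (float(ok[col].mean()), float(ok[col].std(ddof=1)))
        entry = {"params": stats_, "n": int(len(ok))}
        if "m_diff" in ok:
            entry["m_diff_positive_fraction"] = float((ok["m_diff"] > 0).mean())
        summary[signal] = entry

    signals = list(fits_by_signal)
    correlations = {}
    for i, a in enumerate(signals):
        for b in signals[i + 1:]:
            mask = frames[a]["converged"].to_numpy() & frames[b]["converged"].to_numpy()
            if mask.sum() < 3:
                continue
            pair = {}
            for col in frames[a].columns:
                if col == "converged" or col not in frames[b]:
                    continue
                x = frames[a].loc[mask, col].to_numpy()
                y = frames[b].loc[mask, col].to_numpy()
                try:
                    res = correlate(x, y)
                except ValueError:
                    continue
                pair[col] = (res.coefficient, res.p)
            correlations[(a, b)] = pair
    return {"summary": summary, "correlations": correlations, "tables": frames}
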