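"""Site-selection criteria: good MUA, good gamma, all signals good.

A site's MUA is "good" when its stimulus-epoch variability clearly exceeds
the pre-stimulus variability (SNR = std ratio > 2.5 in at least one
condition) and its single-grating contrast response is well described by a
saturating contrast-response function

    R(c) = Rmax * c^n1 / (c50^n2 + c^n2) + R0        (goodness of fit > 0.6).

A site's gamma is "good" when (1) some 30-98 Hz bin of the stimulus spectrum
exceeds the blank spectrum by z > 1.96, (2) the parametric spectrum fit has
goodness of fit > 0.8, (3) the fitted narrow-band weight under stimulus is
more than twice the blank weight in at least one condition, and (4) the
contrast-response screen passes for a gamma signal.  "All good" is the
conjunction.  All thresholds are configuration with these values as
defaults.

The contrast-response screen is applied to both single-grating axes (the
c2 = 0 and c1 = 0 margins) and passes when either axis fits well: a site
tuned orthogonally to grating 1 should not be discarded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .grids import ContrastGrid
from .interaction import ResponseMatrix
from .spectra import fit_spectrum, gamma_snr, gamma_zscore
from .stats import goodness_of_fit


@dataclass(frozen=True)
class SelectionThresholds:
    mua_snr: float = 2.5
    zscore: float = 1.96
    spectrum_gof: float = 0.8
    gamma_snr: float = 2.0
    pattern_gof: float = 0.6


# --------------------------------------------------------------------------
# MUA signal-to-noise
# --------------------------------------------------------------------------

def mua_snr(stim_trace: np.ndarray, prestim_trace: np.ndarray) -> float:
    """Std of the stimulus-epoch MUA over std of the pre-stimulus MUA."""
    stim = np.asarray(stim_trace, dtype=float).ravel()
    pre = np.asarray(prestim_trace, dtype=float).ravel()
    if stim.size == 0 or pre.size == 0:
        raise ValueError("both epochs must be non-empty")
    denom = pre.std(ddof=1) if pre.size > 1 else 0.0
    if denom == 0:
        raise ZeroDivisionError("zero pre-stimulus variance: SNR undefined")
    return float(stim.std(ddof=1) / denom)


# --------------------------------------------------------------------------
# contrast-response screen
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ContrastResponseFit:
    Rmax: float
    c50: float
    n1: float
    n2: float
    R0: float
    gof: float
    converged: bool

    def predict(self, c) -> np.ndarray:
        c = np.asarray(c, dtype=float)
        return (self.Rmax * c**self.n1 / (self.c50**self.n2 + c**self.n2)
                + self.R0)


def _crf(x: np.ndarray, c: np.ndarray) -> np.ndarray:
    rmax, c50, n1, n2, r0 = x
    return rmax * c**n1 / (c50**n2 + c**n2) + r0


def fit_contrast_response(responses: np.ndarray, grid: ContrastGrid,
                          n_restarts: int = 15, seed: int = 0,
                          ) -> ContrastResponseFit:
    """Fit the saturating contrast-response function to one single-grating series.

    ``responses`` is either a length-n vector of per-contrast means or an
    (n_trials, n) array of replicates (averaged here).  Constant responses
    leave the goodness of fit undefined and are reported as a failed fit.
    """
    r = np.asarray(responses, dtype=float)
    if r.ndim == 2:
        r = r.mean(axis=0)
    c = grid.as_array()
    if r.shape != c.shape:
        raise ValueError("responses must match the contrast grid")
    if np.ptp(r) == 0:
        return ContrastResponseFit(np.nan, np.nan, np.nan, np.nan, np.nan,
                                   np.nan, converged=False)
    span = float(r.max() - r.min())
    lo = np.array([1e-6 * max(span, 1e-9), 1e-3, 0.1, 0.1, 0.0])
    hi = np.array([10.0 * max(r.max(), span), 2.0, 8.0, 8.0,
                   max(float(r.min()), 0.0) + 1e-3 * max(span, 1e-9)])
    x_guess = np.clip(np.array([span, 0.2, 2.0, 2.0, max(float(r.min()), 0.0)]),
                      lo, hi)
    starts = [x_guess]
    if n_restarts > 0:
        sampler = qmc.LatinHypercube(d=5, seed=seed)
        starts.extend(lo + sampler.random(n_restarts) * (hi - lo))
    best, best_cost = None, np.inf
    for x0 in starts:
        try:
            sol = least_squares(lambda x: _crf(x, c) - r, x0, bounds=(lo, hi),
                                method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except Exception:
            continue
        if sol.cost < best_cost:
            best, best_cost = sol, sol.cost
    if best is None:
        return ContrastResponseFit(np.nan, np.nan, np.nan, np.nan, np.nan,
                                   np.nan, converged=False)
    gof = goodness_of_fit(r, _crf(best.x, c))
    return ContrastResponseFit(*(float(v) for v in best.x), gof=gof,
                               converged=True)


def pattern_screen(matrix: ResponseMatrix, threshold: float = 0.6,
                   n_restarts: int = 15, seed: int = 0) -> tuple[bool, float]:
    """Contrast-response screen on both single-grating axes of a matrix.

    Passes when at least one axis fits with goodness of fit above the
    threshold; returns (passed, best axis goodness of fit).
    """
    best = -np.inf
    series = (matrix.values[:, 0], matrix.values[0, :])   # c2 = 0 and c1 = 0
    for i, resp in enumerate(series):
        fit = fit_contrast_response(resp, matrix.grid,
                                    n_restarts=n_restarts, seed=seed + i)
        if fit.converged and np.isfinite(fit.gof):
            best = max(best, fit.gof)
    return bool(best > threshold), float(best)


# --------------------------------------------------------------------------
# full selection pipeline
# --------------------------------------------------------------------------

@dataclass
class SiteSelection:
    site_id: str
    mua_snr: float | None
    gamma_significant: bool | None
    spectrum_gof_ok: bool | None
    gamma_snr_ok: bool | None
    pattern_gof_mua: float | None
    pattern_gof_gamma: float | None
    good_mua: bool | None
    good_gamma: bool | None
    all_good: bool | None
    evaluable: bool = True


def select_sites(population, thresholds: SelectionThresholds | None = None,
                 spectrum_restarts: int = 6, pattern_restarts: int = 10,
                 seed: int = 0):
    """Label every site of a population as good-MUA / good-gamma / all-good.

    Sites missing a required signal (spectra or MUA epochs) are marked not
    evaluable and excluded from that label's denominator.  Returns a list of
    per-site :class:`SiteSelection` records and a summary dict with counts
    and percentages.
    """
    th = thresholds or SelectionThresholds()
    records = []
    for i, site in enumerate(population.sites):
        rec = SiteSelection(site_id=site.site_id, mua_snr=None,
                            gamma_significant=None, spectrum_gof_ok=None,
                            gamma_snr_ok=None, pattern_gof_mua=None,
                            pattern_gof_gamma=None, good_mua=None,
                            good_gamma=None, all_good=None)
        has_mua = site.mua_prestim is not None and site.mua_stim
        has_gamma = site.stim_spectra is not None and site.blank_spectra is not None
        if not (has_mua or has_gamma):
            rec.evaluable = False
            records.append(rec)
            continue

        if has_mua:
            try:
                rec.mua_snr = max(mua_snr(v, site.mua_prestim)
                                  for v in site.mua_stim.values())
            except ZeroDivisionError:
                warnings.warn(f"{site.site_id}: zero pre-stimulus variance",
                              RuntimeWarning)
                has_mua = False
        if has_mua:
            ok, gof = pattern_screen(site.matrices["MUA"], th.pattern_gof,
                                     n_restarts=pattern_restarts, seed=seed + 2 * i)
            rec.pattern_gof_mua = gof
            rec.good_mua = (rec.mua_snr > th.mua_snr) and ok

        if has_gamma:
            z = gamma_zscore(site.stim_spectra, site.blank_spectra,
                             threshold=th.zscore)
            rec.gamma_significant = z.significant
            stim_fit = fit_spectrum(site.stim_spectra.mean(),
                                    site.stim_spectra.freqs,
                                    n_restarts=spectrum_restarts, seed=seed + i)
            blank_fit = fit_spectrum(site.blank_spectra.mean(),
                                     site.blank_spectra.freqs,
                                     n_restarts=spectrum_restarts,
                                     seed=seed + i + 1)
            rec.spectrum_gof_ok = bool(stim_fit.converged
                                       and stim_fit.gof > th.spectrum_gof)
            if stim_fit.converged and blank_fit.converged:
                rec.gamma_snr_ok = gamma_snr(stim_fit, blank_fit).passes(th.gamma_snr)
            else:
                rec.gamma_snr_ok = False
            gamma_ok = (rec.gamma_significant and rec.spectrum_gof_ok
                        and rec.gamma_snr_ok)
            best = -np.inf
            for j, sig in enumerate(("LG", "HG")):
                _, gof = pattern_screen(site.matrices[sig], th.pattern_gof,
                                        n_restarts=pattern_restarts,
                                        seed=seed + 3 * i + j)
                best = max(best, gof)
            rec.pattern_gof_gamma = best
            rec.good_gamma = bool(gamma_ok and best > th.pattern_gof)

        if rec.good_mua is not None and rec.good_gamma is not None:
            rec.all_good = rec.good_mua and rec.good_gamma
        records.append(rec)

    summary = {}
    for label in ("good_mua", "good_gamma", "all_good"):
        evaluated = [getattr(r, label) for r in records
                     if getattr(r, label) is not None]
        count = int(sum(evaluated))
        summary[label] = {
            "count": count, "n_evaluated": len(evaluated),
            "percent": 100.0 * count / len(evaluated) if evaluated else np.nan,
        }
    return records, summary
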