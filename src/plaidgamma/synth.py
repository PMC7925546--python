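"""Synthetic electrophysiology data with known ground truth.

Three generators mirror the statistical structure the analysis assumes:

* trial-resolved LFP power spectra — the parametric spectrum model
  (power-law baseline plus two narrow-band gamma Gaussians) with
  multiplicative scaled chi-square noise, the sampling distribution of a
  multitaper estimate with ``dof = 2 x tapers`` degrees of freedom;
* 7x7 plaid response matrices — a normalization-model variant evaluated on
  the contrast grid with constant-CV Gaussian trial noise truncated at zero;
* site populations — heterogeneous per-signal model parameters for LG, HG
  and MUA with covariates (per-signal SNR, Delta SF, Delta Ori, distance to
  an area border) and an optional monotone coupling between Delta SF and the
  high-gamma m1 - m2, carrying full ground truth for recovery tests.

Every generator takes an explicit seed; there is no global random state.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

from .grids import ContrastGrid
from .interaction import ResponseMatrix
from .normmodels import MODEL_IDS, PARAM_NAMES, evaluate_model
from .spectra import SpectrumSet, spectrum_model

SIGNALS = ("LG", "HG", "MUA")


def default_freq_grid(fmax: float = 250.0, df: float = 0.5) -> np.ndarray:
    """0-250 Hz at 0.5 Hz: a 2 s window sampled at 500 Hz."""
    return np.arange(0.0, fmax + df / 2, df)


# --------------------------------------------------------------------------
# spectra
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SpectrumGroundTruth:
    """True parameters of one site's spectrum plus the spectral noise dof."""

    wb: float = 1500.0
    f0: float = 3.0
    n0: float = 1.8
    b0: float = 15.0
    k0: float = 0.3
    wg1: float = 6.0
    u1: float = 50.0
    sigma1: float = 4.0
    wg2: float = 3.0
    u2: float = 80.0
    sigma2: float = 5.0
    dof: int = 10          # 2 x number of tapers

    def __post_init__(self) -> None:
        if not (30.0 <= self.u1 < self.u2 <= 100.0):
            raise ValueError("need 30 <= u1 < u2 <= 100 Hz")
        if self.sigma1 <= 0 or self.sigma2 <= 0:
            raise ValueError("bandwidths must be positive")
        if min(self.wb, self.wg1, self.wg2) < 0:
            raise ValueError("weights must be non-negative")
        if self.dof < 2:
            raise ValueError("spectral dof must be >= 2")

    def as_params(self) -> dict:
        return {"wb": self.wb, "f0": self.f0, "n0": self.n0, "b0": self.b0,
                "k0": self.k0, "wg1": self.wg1, "u1": self.u1,
                "sigma1": self.sigma1, "wg2": self.wg2, "u2": self.u2,
                "sigma2": self.sigma2}

    def analytic(self, freqs: np.ndarray) -> np.ndarray:
        return spectrum_model(self.as_params(), freqs)


def generate_spectrum(gt: SpectrumGroundTruth, freq_grid: np.ndarray,
                      n_trials: int, seed: int,
                      site_id: str = "", condition=(0.45, 0.0)) -> SpectrumSet:
    """Per-trial spectra whose expectation is the analytic model spectrum.

    Each trial/bin gets an independent multiplicative chi-square(dof)/dof
    factor (mean 1), the noise of a dof/2-taper multitaper estimate.
    """
    freqs = np.asarray(freq_grid, dtype=float)
    if freqs.ndim != 1 or np.any(np.diff(freqs) <= 0):
        raise ValueError("freq_grid must be strictly increasing")
    mean = gt.analytic(freqs)
    if np.any(mean <= 0):
        raise ValueError("invalid ground truth: non-positive spectrum on the grid")
    rng = np.random.default_rng(seed)
    noise = rng.chisquare(gt.dof, size=(n_trials, freqs.size)) / gt.dof
    return SpectrumSet(freqs=freqs, trials=mean[None, :] * noise,
                       site_id=site_id, condition=condition)


# --------------------------------------------------------------------------
# response matrices
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MatrixGroundTruth:
    """True normalization-model parameters behind one response matrix."""

    model_id: str = "M0"
    Rmax: float = 1.0
    c50: float = 0.2
    m1: float = 2.0
    m2: float = 2.0
    n: float = 2.0
    k: float = 1.0
    b: float = 0.5
    R0: float = 0.0
    noise_cv: float = 0.1
    n_trials: int = 10

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise ValueError(f"unknown model {self.model_id!r}")
        if not 0.0 <= self.b <= 1.0:
            raise ValueError("b must lie in [0, 1]")
        if self.c50 <= 0 or min(self.m1, self.m2, self.n) <= 0:
            raise ValueError("c50 and exponents must be positive")
        if self.noise_cv < 0 or self.n_trials < 1:
            raise ValueError("noise_cv must be >= 0 and n_trials >= 1")

    def as_params(self) -> dict:
        return {name: getattr(self, name) for name in PARAM_NAMES[self.model_id]}

    @property
    def m_diff(self) -> float:
        return self.m1 - self.m2


def generate_response_matrix(gt: MatrixGroundTruth, grid: ContrastGrid,
                             seed: int, signal: str = "MUA") -> ResponseMatrix:
    """Noisy trial replicates around the model's noiseless response surface.

    Trials are mean * (1 + noise_cv * standard-normal), clipped at zero; the
    cell values are the trial means and the ground truth rides along.
    """
    c1, c2 = grid.pairs()
    mean = evaluate_model(gt.model_id, gt.as_params(), c1, c2)
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal(size=(gt.n_trials,) + mean.shape)
    trials = np.clip(mean[None] * (1.0 + gt.noise_cv * eps), 0.0, None)
    return ResponseMatrix(trials.mean(axis=0), grid, signal=signal,
                          trials=trials, ground_truth=gt)


# --------------------------------------------------------------------------
# site populations
# --------------------------------------------------------------------------

#: per-signal uniform parameter ranges for the M0 draws; the exponent ranges
#: are set so that m1 - m2 is positive for nearly all MUA sites (~95%) but
#: negative for a sizeable minority of gamma sites (~35% LG, ~44% HG),
#: matching the qualitative dichotomy the analysis is built to detect
DEFAULT_PARAMETER_DISTRIBUTIONS: dict = {
    "LG": {"Rmax": (0.5, 2.0), "c50": (0.1, 0.7), "m1": (1.4, 2.6),
           "m2": (0.2, 3.0), "b": (0.1, 0.9), "R0": (0.0, 0.1)},
    "HG": {"Rmax": (0.5, 2.0), "c50": (0.1, 0.7), "m1": (1.2, 3.0),
           "m2": (0.2, 3.6), "b": (0.1, 0.9), "R0": (0.0, 0.1)},
    "MUA": {"Rmax": (0.5, 2.0), "c50": (0.03, 0.3), "m1": (0.8, 2.4),
            "m2": (0.3, 1.2), "b": (0.1, 0.9), "R0": (0.0, 0.1)},
}

#: monotone coupling between the Delta SF covariate and high-gamma m2:
#: strength > 0 lowers m2 (raises m1 - m2) for sites whose preferred spatial
#: frequency is below the stimulus SF, the direction seen in real data
DEFAULT_COVARIATE_MODEL: dict = {
    "signal": "HG", "covariate": "delta_sf", "strength": 0.0, "gain": 2.0,
}


@dataclass
class Site:
    site_id: str
    animal: str
    covariates: dict
    matrices: dict                       # signal -> ResponseMatrix
    ground_truth: dict                   # signal -> MatrixGroundTruth
    gamma_bearing: bool = True
    spiking: bool = True
    stim_spectra: SpectrumSet | None = None
    blank_spectra: SpectrumSet | None = None
    spectrum_truth: SpectrumGroundTruth | None = None
    mua_prestim: np.ndarray | None = None
    mua_stim: dict | None = None         # condition -> epoch values


@dataclass
class SitePopulation:
    sites: list
    grid: ContrastGrid
    seed: int

    def __len__(self) -> int:
        return len(self.sites)

    def to_frame(self):
        """Covariates and ground-truth m1 - m2 per site as a DataFrame."""
        import pandas as pd

        rows = []
        for s in self.sites:
            row = {"site_id": s.site_id, "animal": s.animal,
                   "gamma_bearing": s.gamma_bearing, "spiking": s.spiking}
            row.update(s.covariates)
            for sig, gt in s.ground_truth.items():
                row[f"m_diff_{sig}"] = gt.m_diff
            rows.append(row)
        return pd.DataFrame(rows)


def _draw_params(rng: np.random.Generator, ranges: dict) -> dict:
    out = {}
    for name, spec in ranges.items():
        lo, hi = spec
        if not np.isfinite([lo, hi]).all() or hi < lo:
            raise ValueError(f"malformed range for parameter {name!r}: {spec}")
        out[name] = float(rng.uniform(lo, hi))
    return out


def generate_site_population(
    n_sites: int,
    parameter_distributions: dict | None = None,
    covariate_model: dict | None = None,
    seed: int = 0,
    noise_cv: float = 0.1,
    n_trials: int = 10,
    gamma_fraction: float = 1.0,
    spiking_fraction: float = 1.0,
    with_spectra: bool = False,
    spectrum_trials: int = 10,
    gamma_strength: float = 6.0,
    spiking_depth: float = 4.0,
    grid: ContrastGrid | None = None,
) -> SitePopulation:
    """A heterogeneous population of synthetic recording sites.

    Each site carries LG/HG/MUA response matrices generated from model M0
    with per-signal parameter draws, covariates, and (optionally) stimulus
    and blank spectra plus MUA epoch values so the full selection pipeline
    can run.  ``gamma_fraction`` / ``spiking_fraction`` set the designed
    share of gamma-bearing / stimulus-driven sites: a gamma-bearing site's
    stimulus spectrum carries narrow-band bumps ``gamma_strength`` times the
    local baseline power (four times its blank weight), while a non-bearing
    site's stimulus spectrum equals its blank spectrum; a spiking site's
    stimulus-epoch MUA has ``spiking_depth`` times the pre-stimulus standard
    deviation.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    dists = copy.deepcopy(DEFAULT_PARAMETER_DISTRIBUTIONS)
    if parameter_distributions:
        for sig, ranges in parameter_distributions.items():
            if sig not in dists:
                raise ValueError(f"unknown signal {sig!r} in distributions")
            dists[sig].update(ranges)
    cov_model = dict(DEFAULT_COVARIATE_MODEL)
    if covariate_model:
        unknown = set(covariate_model) - set(cov_model)
        if unknown:
            raise ValueError(f"unknown covariate-model keys: {sorted(unknown)}")
        cov_model.update(covariate_model)

    rng = np.random.default_rng(seed)
    grid = grid or ContrastGrid()
    animals = ["A", "B", "C", "D", "E"]
    sites = []
    for i in range(n_sites):
        covs = {
            "delta_sf": float(rng.uniform(-1.0, 1.0)),   # log2 stim/preferred SF
            "delta_ori": float(rng.uniform(0.0, 45.0)),  # degrees
            "distance": float(rng.uniform(-1.5, 2.5)),   # mm, negative = A17
        }
        gamma_bearing = bool(rng.random() < gamma_fraction)
        spiking = bool(rng.random() < spiking_fraction)

        truths, matrices = {}, {}
        for sig in SIGNALS:
            params = _draw_params(rng, dists[sig])
            if sig == cov_model["signal"] and cov_model["strength"] != 0.0:
                lo, hi = dists[sig]["m2"]
                shift = cov_model["strength"] * cov_model["gain"] * covs[cov_model["covariate"]]
                params["m2"] = float(np.clip(params["m2"] - shift, 0.15, 7.5))
            gt = MatrixGroundTruth(model_id="M0", noise_cv=noise_cv,
                                   n_trials=n_trials, **params)
            truths[sig] = gt
            matrices[sig] = generate_response_matrix(
                gt, grid, seed=int(rng.integers(2**31)), signal=sig)
            covs[f"snr_{sig}"] = float(rng.uniform(2.0, 8.0))

        site = Site(site_id=f"site{i:03d}", animal=animals[i % len(animals)],
                    covariates=covs, matrices=matrices, ground_truth=truths,
                    gamma_bearing=gamma_bearing, spiking=spiking)

        if with_spectra:
            _attach_signals(site, rng, spectrum_trials, gamma_strength,
                            spiking_depth)
        sites.append(site)
    return SitePopulation(sites=sites, grid=grid, seed=seed)


def _attach_signals(site: Site, rng: np.random.Generator,
                    spectrum_trials: int, gamma_strength: float,
                    spiking_depth: float) -> None:
    """Stimulus/blank spectra and MUA epochs consistent with the site flags."""
    freqs = default_freq_grid()
    u1 = float(rng.uniform(46.0, 54.0))
    u2 = float(rng.uniform(76.0, 84.0))
    base = SpectrumGroundTruth(u1=u1, u2=u2, wg1=0.0, wg2=0.0)
    local = base.analytic(np.array([u1, u2]))          # baseline power at the peaks
    if site.gamma_bearing:
        wg_stim = gamma_strength * local
        wg_blank = wg_stim / 4.0                        # stimulus/blank ratio 4
    else:
        wg_blank = 1.2 * local                          # weak spontaneous bumps
        wg_stim = wg_blank                              # no stimulus gating
    blank_gt = replace(base, wg1=float(wg_blank[0]), wg2=float(wg_blank[1]))
    stim_gt = replace(base, wg1=float(wg_stim[0]), wg2=float(wg_stim[1]))
    site.spectrum_truth = stim_gt
    site.blank_spectra = generate_spectrum(
        blank_gt, freqs, spectrum_trials, seed=int(rng.integers(2**31)),
        site_id=site.site_id, condition=(0.0, 0.0))
    site.stim_spectra = generate_spectrum(
        stim_gt, freqs, spectrum_trials, seed=int(rng.integers(2**31)),
        site_id=site.site_id, condition=(0.45, 0.0))

    n_epoch = 30
    base_sd = 1.0
    site.mua_prestim = 5.0 + base_sd * rng.standard_normal(n_epoch)
    depth = spiking_depth if site.spiking else 1.0
    site.mua_stim = {
        (0.45, 0.0): 8.0 + depth * base_sd * rng.standard_normal(n_epoch)
    }
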