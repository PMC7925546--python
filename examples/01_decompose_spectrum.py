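"""Decompose an LFP power spectrum into a power-law baseline plus two
narrow-band gamma bumps.

Builds a noisy trial-averaged spectrum from a known ground truth (gammas at
50 and 80 Hz, multitaper-style chi-square noise) and recovers the eleven
model parameters by bounded least squares on log power.
"""

import numpy as np

from plaidgamma import SpectrumGroundTruth, fit_spectrum, generate_spectrum
from plaidgamma.synth import default_freq_grid

gt = SpectrumGroundTruth(wg1=6.0, u1=50.0, sigma1=4.0,
                         wg2=3.0, u2=80.0, sigma2=5.0, dof=10)
freqs = default_freq_grid()
spectra = generate_spectrum(gt, freqs, n_trials=10, seed=1)

fit = fit_spectrum(spectra.mean(), freqs, n_restarts=8, seed=0)

print(f"goodness of fit (raw power): {fit.gof:.3f}")
print(f"low-gamma peak : fitted u1 = {fit.params['u1']:6.2f} Hz (true {gt.u1})")
print(f"high-gamma peak: fitted u2 = {fit.params['u2']:6.2f} Hz (true {gt.u2})")
print(f"narrow-band weights: wg1 = {fit.params['wg1']:.2f} (true {gt.wg1}), "
      f"wg2 = {fit.params['wg2']:.2f} (true {gt.wg2})")
print(f"baseline exponent n0 = {fit.params['n0']:.2f} (true {gt.n0})")
print()
print("The two u values are the narrow-band gamma peak frequencies; the wg")
print("weights are the oscillation powers riding on the 1/f-like baseline.")
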