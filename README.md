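# plaidgamma

Analysis tools for cortical responses to **plaid stimuli** — pairs of
orthogonal drifting gratings with independently varying contrasts (c1, c2)
— as recorded with multi-electrode arrays in visual cortex.  The package is
aimed at systems neuroscientists who want to quantify how narrow-band gamma
oscillations in the local field potential (LFP) and multi-unit spiking
activity (MUA) combine, compete and normalize when two gratings are
superimposed, and to validate every stage of that analysis on synthetic
data with known ground truth.

## What it computes

**Spectrum decomposition.**  Trial-averaged LFP power spectra (multitaper,
time-bandwidth 3, 5 tapers, stimulus epoch 0.3–2.0 s) are decomposed into a
power-law baseline plus two narrow-band gamma bumps:

```
P(f) = wb·F(f) + wg1·G(f|u1,σ1) + wg2·G(f|u2,σ2) + k0
F(f) = 1 / (|f−f0|^n0 + b0^n0)          G(f|u,σ) = exp(−(f−u)²/2σ²)
```

with the low-gamma peak u1 and high-gamma peak u2 constrained to disjoint
bands (defaults 30–70 and 70–100 Hz).

**Site selection.**  Good-MUA sites need a stimulus/pre-stimulus SNR > 2.5;
good-gamma sites need a stimulus-vs-blank z-score > 1.96 somewhere in
30–98 Hz, spectrum-fit goodness of fit > 0.8 and Gamma SNR (stimulus wg /
blank wg) > 2; both additionally need a single-grating contrast response
well fit (gof > 0.6) by `R(c) = Rmax·c^n1/(c50^n2+c^n2) + R0`.

**Interaction index.**  For a 7×7 response matrix M1(c1,c2), the additive
prediction is `M2(c1,c2) = M1(c1,0) + M1(0,c2) − M1(0,0)` and

```
index = 2·(ΣM1 − ΣM2) / (ΣM1 + ΣM2)       (sums over c1>0, c2>0)
```

Negative values mean cross-orientation suppression; −2/3 corresponds to a
plaid block at exactly half its additive prediction.

**Normalization models.**  Three divisive-normalization variants are fitted
to each matrix; the primary one (M0) is

```
R1 = Rmax·c1^m1 / (c50^m2 + (c1+c2)^m2)     (R2 symmetric in c2)
R  = b·R1 + (1−b)·R2 + R0
```

The derived quantity m1 − m2 summarizes whether the divisive pool outgrows
the stimulus drive; its sign pattern across signals (almost always positive
for MUA, frequently negative for gamma) is the package's headline
population statistic.

**Statistics.**  One-sided resampling tests with p = 1 − K/B (B = 1000
default), Pearson/Spearman correlations with regression-line summaries,
rank-based six-group binned trends, and two-group (cortical area A17 vs
A18) comparisons.

## Worked example

`python examples/03_fit_normalization_models.py` fits all three model
variants to a matrix generated from M0 with 10% trial noise:

```
ground truth: c50=0.25, m1=2.0, m2=1.4, b=0.65, m1-m2=+0.60
M0: gof = 0.9951  (c50=0.233, m1=1.97, m2=1.40, b=0.64, m1-m2=+0.57)
M1: gof = 0.9859
M2: gof = 0.9918  (c50=0.056, m1=2.21, m2=1.34, b=0.63, m1-m2=+0.87)
```

The matched variant M0 recovers the generating parameters (m1 − m2 within
0.03 of truth) and explains the most variance; the mismatched pool
structures lose accuracy.  The other scripts in `examples/` walk through
spectrum decomposition, the interaction index, the selection pipeline and
the population-level m1 − m2 dichotomy.

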