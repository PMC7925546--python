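"""Population-level comparison of m1 - m2 across signals, with the
bootstrap, rank-binned trend and region-comparison machinery.

Re-estimates the normalization model per site and signal, then asks: is the
interaction structure of spiking (MUA) different from high gamma?  Under the
default population design, almost every MUA site has m1 - m2 > 0 while a
sizeable minority of high-gamma sites is negative; a Delta-SF coupling adds
a monotone trend for high gamma.
"""

import numpy as np

from plaidgamma import (binned_trend, bootstrap_test, fit_model,
                        generate_site_population, group_compare)

pop = generate_site_population(n_sites=60, seed=5,
                               covariate_model={"strength": 0.8})

m_diff = {}
for sig in ("MUA", "HG"):
    m_diff[sig] = np.array([
        fit_model(site.matrices[sig], "M0", n_restarts=8, seed=i).m_diff
        for i, site in enumerate(pop.sites)])
    frac_pos = float(np.mean(m_diff[sig] > 0))
    boot = bootstrap_test(m_diff[sig], "mean", "greater", B=1000, seed=0)
    print(f"{sig}: mean m1-m2 = {boot.estimate:+.2f}, "
          f"{100*frac_pos:.0f}% of sites positive, "
          f"bootstrap p(mean>0) = {boot.p:.3f}")

delta_sf = np.array([s.covariates["delta_sf"] for s in pop.sites])
trend = binned_trend(delta_sf, m_diff["HG"], n_groups=6)
print(f"\nHG m1-m2 vs Delta SF: Spearman rho = {trend.correlation:+.2f} "
      f"(p = {trend.p:.3g})")
print("six-group means:", np.round(trend.group_means, 2))

distance = np.array([s.covariates["distance"] for s in pop.sites])
region = np.where(distance < 0, "A17", "A18")
cmp_ = group_compare(m_diff["HG"], region, covariate=distance)
print(f"\nA17 vs A18 (HG m1-m2): means "
      f"{cmp_.group_means['A17']:+.2f} / {cmp_.group_means['A18']:+.2f}, "
      f"t-test p = {cmp_.p:.3f}")
print()
print("The MUA/HG sign split is the signature dichotomy; the binned trend")
print("shows the designed monotone coupling between Delta SF and HG m1-m2.")
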