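"""Pool per-cohort estimates and quantify the smoking-attributable COPD
burden with a targeted-cessation impact table."""

import numpy as np

from copdprs import attributable_risk, meta_ess_auc, meta_fixed_iv, meta_random_dl, targeted_impact

# per-cohort log-ORs per SD and their SEs (as a meta-analysis would receive)
log_ors = [0.55, 0.62, 0.48, 0.70]
ses = [0.08, 0.10, 0.12, 0.09]
fixed = meta_fixed_iv(log_ors, ses)
random = meta_random_dl(log_ors, ses)
print(f"fixed-effects pooled OR per SD: {np.exp(fixed.estimate):.2f} "
      f"(I2={fixed.I2:.0f}%, Q={fixed.Q:.2f})")
print(f"random-effects pooled OR per SD: {np.exp(random.estimate):.2f} (tau2={random.tau2:.4f})")

ess = meta_ess_auc([0.66, 0.69, 0.64], [3065, 1713, 371], [2110, 147, 429])
print(f"ESS-weighted mean AUC: {ess.estimate:.3f}")

# smoking dichotomized at 20 pack-years in one cohort
rng = np.random.default_rng(6)
exposure = rng.random(4000) < 0.45
outcome = rng.binomial(1, np.where(exposure, 0.25, 0.08)).astype(float)
d = attributable_risk(exposure, outcome)
print(f"RR {d.rr:.2f}; AR% {d.ar_pct:.1f}; PAR% {d.par_pct:.1f}")

deciles = rng.integers(1, 11, 4000)
imp = targeted_impact(deciles, exposure, outcome, strata={"top_decile": [10], "bottom_decile": [1]})
for row in imp.impact.itertuples(index=False):
    print(f"cessation in {row.stratum}: {row.reduction_pct_of_cases:.1f}% of all cases removed")
# AR% is the excess risk among the exposed; PAR% the population share of cases
# attributable to exposure; the impact table assumes complete cessation efficacy.
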