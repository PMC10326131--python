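"""Trivariate Bayesian regression on a synthetic cohort with known truth.

A cohort of 78 subjects (two configurations each) is generated from the
linear model (log eccentricity, area/1000, semi-minor axis) ~ age + gender
+ configuration with correlated errors, then refitted by the conjugate
Gibbs sampler.  A covariate is "significant" for an outcome when 0 falls
outside the 0.95 highest-posterior-density interval of its coefficient.
"""

import warnings

from skinaniso import CohortGenConfig, McmcSettings, fit_mvreg, generate_outcomes, significance_table

cfg = CohortGenConfig(rng_seed=11)
data = generate_outcomes(cfg)  # 156 rows with known true coefficients

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    post = fit_mvreg(data, McmcSettings(n_chains=4, n_iter=2000, seed=1))

table = significance_table(post)
print(table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print("\ntrue coefficient matrix (rows: outcomes; cols: age, gender, config):")
print(cfg.coefficients)
print(
    "\nEach posterior mean should sit near its true value. Strong effects "
    "(e.g. age on log eccentricity, truth 0.007 over an age range of 90 "
    "years) are flagged significant; the weak gender effect on log "
    "eccentricity (truth 0.032) sits close to the 0.95-HPDI boundary and "
    "its flag varies between cohort realisations."
)
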