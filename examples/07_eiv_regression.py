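"""Bayesian errors-in-variables regression of benchmark doses on predicted
TTR binding energies - the quantitative test of the adverse outcome pathway."""

from ttraop.eiv import AOPDataPoint, fit_eiv
from ttraop.synth import GeneratorSpec, gen_aop_dataset

df, truth = gen_aop_dataset(GeneratorSpec(seed=5))
points = [AOPDataPoint(str(r["compound"]), r["x_obs"], r["sx"],
                       r["y_obs"], r["sy"]) for _, r in df.iterrows()]

res = fit_eiv(points, n_draws=4000, warmup=1000, seed=5)
print(f"slope     = {res.slope:.2f} uM per kcal/mol "
      f"(95% CI {res.slope_ci[0]:.2f}, {res.slope_ci[1]:.2f}); "
      f"planted truth {truth['slope']}")
print(f"intercept = {res.intercept:.1f} uM "
      f"(95% CI {res.intercept_ci[0]:.1f}, {res.intercept_ci[1]:.1f})")
print(f"Bayes R2  = {res.bayes_r2:.2f}, RMSE = {res.rmse:.1f} uM, "
      f"valid = {res.valid}")
# A credibly positive slope means weaker TTR binders (less negative energy)
# need higher serum levels to depress T4 - evidence that T4 displacement
# from transthyretin is the rate-controlling step of the pathway.
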