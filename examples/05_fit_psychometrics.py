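"""Fit the probit pipeline to a simulated study and report PSE/JND.

Ordinal responses are expanded into cumulative binomial observations, fitted
first with a pooled probit regression and then with the mixed-effects probit
(orientation dummies, per-participant random coefficients, Laplace maximum
likelihood).  Per-orientation PSE and JND carry delta-method 95% confidence
intervals.
"""

import plmotion as plm

table = plm.simulate_experiment(plm.ObserverModel(), seed=42)
cdf = plm.build_cdf_observations(table)

print("pooled probit per orientation:")
for c in ("0", "90", "180"):
    fit = plm.fit_probit(cdf[cdf["condition"] == c])
    print(f"  {c:>3} deg: beta0 {fit.beta0:7.3f}, beta1 {fit.beta1:6.3f}, "
          f"PSE {fit.pse:6.2f}, JND {fit.jnd:5.2f}, deviance {fit.deviance:7.1f}")

print()
print("mixed-effects probit (reference 0 deg):")
fit = plm.fit_mixed_probit(cdf)
print(fit.wald().to_string(float_format=lambda v: f"{v:9.4f}"))
print()
print(plm.report_table(fit).to_string(index=False, float_format="%.3f"))
print()
print("The PSE column is the profile index perceived as most uniform (10 = the")
print("pendular 1g profile); the JND is the precision of that judgment in")
print("index units.  Compare the estimates with the generative values")
print("(10.08/9.15/8.66 and 0.94/1.38/1.09).")
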