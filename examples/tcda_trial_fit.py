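"""Fit the temporal CDA model to a simulated three-arm combination trial.

Builds a synthetic trial in which the latent per-patient survival times
under the two monotherapies have a known Spearman correlation (0.4), then
fits the model by grid search and attaches a bootstrap confidence
interval.  The fitted correlation should track the generating one, and
the goodness-of-fit p-value should be large (the combination really does
follow correlated independent action here).
"""

import dataclasses

from cdaction import (
    HillParams,
    SynthSpec,
    bootstrap_rho_ci,
    fit_tcda,
    gen_trialset,
)

spec = SynthSpec(
    hill_A=HillParams(k=5.0, n=1.5, drug_label="drug A"),   # median PFS ~5 months
    hill_B=HillParams(k=8.0, n=2.0, drug_label="drug B"),   # median PFS ~8 months
    rho_true=0.4,
    n_units=2000,       # patients per simulated arm
    seed=42,
)
trial = gen_trialset(spec)

fit = fit_tcda(trial)
ci = bootstrap_rho_ci(trial, n_boot=1000, seed=0)
fit = dataclasses.replace(fit, ci=ci)

print(f"generating Spearman correlation: {spec.rho_true:+.2f}")
print(f"fitted correlation rho_hat:      {fit.rho_hat:+.3f}")
print(f"95% bootstrap CI:                [{ci[0]:+.3f}, {ci[1]:+.3f}]")
print(f"fit RMSE (survival fraction):    {fit.rmse:.4f}")
print(f"KS goodness-of-fit p-value:      {fit.gof_p:.3f}")
print()
print("rho_hat near the generating value with the CI covering it, a small")
print("RMSE and a large p-value mean the combination curve is explained by")
print("the two monotherapies plus one rank correlation - no synergy needed.")
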