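"""Pair latent survival times at a target Spearman correlation, two ways.

Samples two monotherapy cohorts, pairs them with the coin (mixture) and
window-swap constructions at the same target correlation, and shows that
the implied combination survival curves agree even though the joint
distributions are quite different - the basis for trusting the fitted
correlation regardless of how nature actually couples the two responses.
"""

import numpy as np

from cdaction import (
    SurvivalTable,
    correlate_pairs_coin,
    correlate_pairs_window,
    sample_survival_times,
    tcda_survival,
)
from cdaction.joint_sim import empirical_survival

rho = 0.25
t = np.arange(0.0, 30.0 + 1e-9, 0.1)
arm_A = SurvivalTable(t, np.exp(-t / 8.0), label="A")
arm_B = SurvivalTable(t, 1.0 / (1.0 + (t / 9.0) ** 2), label="B")

t_A = np.sort(sample_survival_times(arm_A, 8000, seed=1))
t_B = np.sort(sample_survival_times(arm_B, 8000, seed=2))

coin = correlate_pairs_coin(t_A, t_B, rho, seed=3)
wswp = correlate_pairs_window(t_A, t_B, rho, tol=0.01, seed=3)

curve = {}
for pairs in (coin, wswp):
    t_AB = np.maximum(pairs.t_A, pairs.t_B)
    curve[pairs.method] = empirical_survival(t_AB, t).survival
    print(f"{pairs.method:12s} achieved Spearman = {pairs.achieved_rho:+.4f} "
          f"(target {rho:+.2f})")

closed_form = tcda_survival(arm_A.survival, arm_B.survival, rho)
gap_methods = np.max(np.abs(curve["coin"] - curve["window_swap"]))
gap_formula = np.max(np.abs(curve["coin"] - closed_form))
print(f"sup-norm gap between the two methods' combination curves: {gap_methods:.3f}")
print(f"sup-norm gap between coin simulation and the closed form:  {gap_formula:.3f}")
print()
print("Both pairings hit the target correlation while preserving each")
print("monotherapy's marginal distribution, and the resulting combination")
print("curves are nearly identical: the model depends on the correlation,")
print("not on the fine structure of the joint distribution.")
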