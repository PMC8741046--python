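"""Analytic evaluation statistics on published-style inputs.

These quantities depend only on printed summary numbers, so they can be
recomputed exactly: the normal-approximation Z for a Mann-Whitney U of 120
at group sizes 19 vs 30, Fisher-z confidence intervals for correlations of
0.70 and 0.075 at n = 19, and the Hanley-McNeil interval for an AUC of 0.79
with 19 patients vs 30 controls.
"""

from erpmarker import auc_ci_hanley, fisher_ci, mann_whitney_z_from_u

z, p = mann_whitney_z_from_u(120.0, m=19, n=30)
print(f"U = 120 (19 vs 30)       -> Z = {z:.2f}, two-tailed p = {p:.1g}")

lo, hi = fisher_ci(0.70, n=19)
print(f"r = 0.70  at n = 19      -> 95% CI ({lo:.2f}, {hi:.2f})")

lo, hi = fisher_ci(0.075, n=19)
print(f"r = 0.075 at n = 19      -> 95% CI ({lo:.2f}, {hi:.2f})")

lo, hi = auc_ci_hanley(0.79, n_pos=19, n_neg=30)
print(f"AUC = 0.79 (19 vs 30)    -> 95% CI ({lo:.2f}, {hi:.2f})")

print("\nA |Z| above 1.96 rejects equal score distributions at the 5% level;")
print("a correlation CI covering 0 (the 0.075 case) means no linear relation")
print("is detectable at that sample size.")
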