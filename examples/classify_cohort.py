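"""Full neuromarker pipeline on a study-sized synthetic cohort.

Simulates 30 controls + 19 early-stage + 12 established patients at reduced
trial counts, engineers the parcel and variability features against a
separate normative template pool, runs feature-selection +
logistic-regression 10-fold cross-validation, and prints the classification
summary: AUC with its 95% confidence interval, the sensitivity/specificity
of the above-chance cutoff, and the most important marker features.
"""

from erpmarker import PipelineConfig, run_pipeline

config = PipelineConfig(n_hc=30, n_espd=19, n_established=12, seed=1,
                        trial_scale=0.3)
report = run_pipeline(config)

roc = report["roc"]
mw = report["group_separation"]
print(f"features engineered : {report['manifest']['n_features']}")
print(f"features in marker  : {report['manifest']['n_selected_features']}")
print(f"cross-validated AUC : {roc['auc']:.2f} "
      f"(95% CI {roc['ci95'][0]:.2f}, {roc['ci95'][1]:.2f})")
print(f"sensitivity/specificity at cutoff: "
      f"{roc['sensitivity']:.2f} / {roc['specificity']:.2f}")
print(f"group separation    : U = {mw['u']:.0f}, Z = {mw['z']:.2f}, "
      f"p = {mw['p']:.2g}")
if "mupdrs_correlation" in report:
    mc = report["mupdrs_correlation"]
    print(f"marker vs mUPDRS    : r = {mc['statistic']:.2f} "
          f"(95% CI {mc['ci95'][0]:.2f}, {mc['ci95'][1]:.2f})")
print("\ntop-5 marker features by weight:")
for name, weight in list(report["importance"].items())[:5]:
    print(f"  {weight:.3f}  {name}")
print("\nAn AUC well above 0.5 with planted-effect features on top shows the")
print("pipeline recovering the group differences built into the cohort.")
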