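"""Case-control detection under a shifted test campaign: augmentation no-harm.

Binary ridge-logistic classifiers are trained on experimental subsamples of
varying size, and on augmented cohorts seeded by the same subsamples; both
are evaluated by AUC on a held-out test set measured under a different
instrument state.
"""

from codi import case_control_config, make_case_control, run_case_control

scenario = make_case_control(case_control_config(rng_seed=0), 110, 110)
report = run_case_control(scenario, n_per_seed=100,
                          training_sizes=[25, 50, 100, 200],
                          repeats=3, rng_seed=5)

print("training size | experimental AUC | augmented AUC")
for size, e, c in zip(report.extras["training_sizes"],
                      report.extras["mean_auc_experimental"],
                      report.extras["mean_auc_codi"]):
    print(f"{size:13d} | {e:16.3f} | {c:13.3f}")
print("-> augmentation helps most when experimental training data are "
      "scarce, and never falls meaningfully below the experimental-only "
      "classifier: including it is a safe default.")
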