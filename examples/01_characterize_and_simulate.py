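"""Characterize calibration variability and simulate an augmented cohort.

Builds a small synthetic study, turns its QC measurements into a
mean-centered difference set, injects that variability into one seed
spectrum, and compares the simulated cohort's per-channel spread against
the closed-form spread the source should inject.
"""

import numpy as np

from codi import (
    SimulationConfig, VariabilitySource, differences_mean_centered,
    generate_cohort, make_population, scenario_config, std_profile,
)

scenario = make_population(scenario_config(n_individuals=8, rng_seed=0))

qc = differences_mean_centered(scenario.calib_qc, "qc_drift")
source = VariabilitySource(qc, scale=1.0)
print(f"QC calibration set: {qc.m} mean-centered difference vectors "
      f"over {qc.axis.n_channels} channels")

seed = scenario.train.select([0])
cohort = generate_cohort(SimulationConfig(seed, [source], n_per_seed=5000,
                                          rng_seed=1))
print(f"simulated cohort: {cohort.n} measurements around one seed spectrum")

emp = std_profile(cohort)
closed = source.injected_std()
rel = np.abs(emp - closed)[closed > 1e-6] / closed[closed > 1e-6]
print(f"median relative gap between empirical and closed-form per-channel "
      f"std: {np.median(rel):.3f}")
print("-> the Gaussian-scaled aggregation reproduces the calibration "
      "set's variability structure around the seed.")
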