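"""Cross-year train/test: calibrate on one year, validate on the other.

Generates a small two-year synthetic trial (noisy observations, a cold
October in 2022), tunes each genotype on 2021 and evaluates on 2022 and
vice versa, plus a combined-years run.  Test RRMSE exceeding train RRMSE is
the expected generalization gap: each genotype is tuned on very few series.
"""

import sorgsim as ss

design = ss.TrialDesign(n_genotypes=4, n_blocks=1, obs_noise_cv=0.15,
                        rng_seed=11)
weather = {
    2021: ss.generate_weather(2021, seed=12),
    2022: ss.generate_weather(2022, seed=13,
                              anomalies={"cold_october": True}),
}
genotypes = ss.sample_genotypes(4, seed=14, spread=0.5)
observations, _ = ss.generate_trial(design, genotypes, weather)

config = ss.CalibrationConfig(max_iter=60, sensitivity_refresh=0, rng_seed=15)
report = ss.train_test_experiment(observations, weather, config)

print(report.per_genotype.to_string(index=False,
                                    float_format=lambda v: f"{v:.3f}"))
print()
print(report.summary.to_string(index=False,
                               float_format=lambda v: f"{v:.3f}"))
print("\ntrain/test RRMSE are fractions (0.15 = 15%); on average the "
      "held-out year is harder than the training year.")
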