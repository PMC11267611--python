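"""Fit LFER sensitivities by OLS and check parameter recovery on synthetic data.

Generates a small dataset with known alpha, beta and intercept, adds Gaussian
noise to the barriers, and refits -- mirroring how the sensitivities of a real
reaction class are extracted from computed activation/reaction enthalpies.
"""

from strainlfer import GeneratorSpec, compare_models, fit_lfer, generate, summary_table

truth = GeneratorSpec(alpha=0.5, beta=-10.0, intercept=40.0, n=12,
                      noise_sigma=2.0, seed=7)
table = generate(truth)

fit = fit_lfer(table.records, descriptor="n3")
print(f"true   : alpha=0.50 beta=-10.0 intercept=40.0")
print(f"fitted : alpha={fit.params.alpha:.2f} beta={fit.params.beta:.1f} "
      f"intercept={fit.params.intercept:.1f}")
print(f"R2 = {fit.r_squared:.3f}, RMSE = {fit.rmse:.2f} kcal/mol over {fit.n_records} records\n")

# Compare against the driving-force-only (BEP) model on identical records:
results = compare_models(table.records, descriptors=("none", "n3"))
print(summary_table(results).to_string(index=False))

# The descriptor model recovers the generating parameters within noise and
# clearly outperforms BEP whenever delocalization varies across the set.
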