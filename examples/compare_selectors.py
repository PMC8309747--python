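"""Compare wavelength selectors through a shared ridge regressor.

Each selector picks channels on the calibration set only; a multi-output
ridge then predicts N and OM jointly from the selected channels. The single
R^2/RMSE per row pools both targets after standardizing them to unit SD on
the calibration set.
"""

from nirstack import (
    GAConfig,
    GeneratorConfig,
    PSOConfig,
    build_fsgc,
    compare_feature_selectors,
    generate_dataset,
)

dataset, _ = generate_dataset(GeneratorConfig.reduced(seed=0))
rows = compare_feature_selectors(
    dataset,
    ["none", "lasso", "ga", "pso-svm", "pso-fsgc"],
    seed=0,
    fsgc=build_fsgc(internal_folds=3),
    pso_config=PSOConfig(n_particles=30, n_iterations=6, seed=0, fitness_folds=3),
    ga_config=GAConfig(population=30, generations=6, seed=0),
)
print(f"{'selector':<12}{'n_sel':>6}{'R2c':>9}{'RMSEC':>9}{'R2p':>9}{'RMSEP':>9}")
for r in rows:
    print(f"{r.selector:<12}{r.n_selected:>6}{r.r2c:>9.4f}{r.rmsec:>9.4f}{r.r2p:>9.4f}{r.rmsep:>9.4f}")
print("\nWrapper selectors (pso-fsgc, pso-svm, ga) trade a compact subset "
      "against classifier accuracy; lasso penalizes coefficients directly. "
      "'none' keeps all channels as the no-selection reference.")
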