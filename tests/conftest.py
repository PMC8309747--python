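"""Shared fixtures: small handmade datasets and the synthetic presets.

Expensive artifacts (the 8-channel exhaustive-search fitness cache, the
reduced preset) are session-scoped so every test reuses one computation.
"""

import numpy as np
import pytest

import nirstack as ns


@pytest.fixture()
def toy_dataset():
    """Four spectra, two samples x two replicates, 5-channel grid."""
    grid = ns.WavelengthGrid(np.array([400.0, 500.0, 600.0, 700.0, 800.0]))
    rng = np.random.default_rng(42)
    refl = 0.4 + 0.05 * rng.standard_normal((4, 5))
    return ns.SpectraDataset(
        grid=grid,
        reflectance=refl,
        variety=[1, 1, 2, 2],
        sample_id=[1, 1, 2, 2],
        replicate_id=[1, 2, 1, 2],
        nitrogen=[1.5, 1.5, 2.0, 2.0],
        organic_matter=[50.0, 50.0, 40.0, 40.0],
    )


@pytest.fixture(scope="session")
def reduced_dataset():
    """The 64-channel fast benchmark (90 spectra) plus its truth mask."""
    dataset, truth = ns.generate_dataset(ns.GeneratorConfig.reduced(seed=0))
    return dataset, truth


@pytest.fixture(scope="session")
def tiny_problem():
    """8-channel standardized dataset with the default stacked-classifier
    wrapper fitness (5 CV folds).

    The fitness is memoized with a fixed seed, so the exhaustive oracle over
    all 255 subsets is computed once per session and every swarm/GA run
    afterwards hits the cache."""
    dataset, truth = ns.generate_dataset(ns.GeneratorConfig.tiny(seed=0))
    dataset = ns.savgol_smooth(dataset, window=5)
    scaler = ns.standardize_fit(dataset)
    dataset = ns.standardize_apply(scaler, dataset)
    fitness = ns.make_subset_fitness(dataset, ns.build_fsgc(), alpha=0.5, folds=5, seed=0)
    oracle_mask = ns.exhaustive_best_subset(dataset, fitness)
    oracle_fitness = fitness(oracle_mask, dataset)
    return {
        "dataset": dataset,
        "truth": truth,
        "fitness": fitness,
        "oracle_mask": oracle_mask,
        "oracle_fitness": oracle_fitness,
    }
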