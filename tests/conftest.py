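"""Shared fixtures: the standard synthetic benchmark and its fits.

The benchmark conditions are 2 runs × 20 proteins × 10 temperatures
(37–67 °C), noise sd 0.05, 20% of proteins corrupted by within-protein
scrambling — the generator defaults.  The expensive posterior fits are
session-scoped so every test that needs them shares one computation.
"""

import numpy as np
import pandas as pd
import pytest

from bayesmelt import (
    HierarchicalMeltingModel,
    SeparateCurveFit,
    SimulationConfig,
    simulate,
)

BENCHMARK_SEED = 1


@pytest.fixture(scope="session")
def benchmark_dataset():
    return simulate(SimulationConfig(seed=BENCHMARK_SEED))


@pytest.fixture(scope="session")
def truth_indexed(benchmark_dataset):
    return benchmark_dataset.truth.set_index(["run_name", "protein_id"])


@pytest.fixture(scope="session")
def nuts_fit(benchmark_dataset):
    model = HierarchicalMeltingModel(
        method="nuts", warmup=600, n_draws=600, random_state=BENCHMARK_SEED
    )
    return model.fit(benchmark_dataset.table)


@pytest.fixture(scope="session")
def advi_fit(benchmark_dataset):
    model = HierarchicalMeltingModel(
        method="advi", advi_steps=30_000, n_draws=600, random_state=BENCHMARK_SEED
    )
    return model.fit(benchmark_dataset.table)


@pytest.fixture(scope="session")
def mle_fit(benchmark_dataset):
    return SeparateCurveFit().fit(benchmark_dataset.table)


@pytest.fixture(scope="session")
def tm_summary_with_truth(nuts_fit, truth_indexed):
    s = nuts_fit.tm_summary().set_index(["run_name", "protein_id"])
    return s.join(truth_indexed[["tm", "corrupted"]])


@pytest.fixture
def tiny_table():
    """Three noiseless proteins in one run, enough to exercise plumbing."""
    ds = simulate(
        SimulationConfig(
            n_runs=1,
            proteins_per_run=3,
            noise_sd=0.0,
            corrupt_fraction=0.0,
            seed=3,
        )
    )
    return ds.table
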