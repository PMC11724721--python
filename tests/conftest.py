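"""Shared fixtures: one default simulation and its imputation per session."""

import logging
import warnings

import numpy as np
import pytest

import spvapa as sv

logging.getLogger("spvapa").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_sim() -> sv.SimResult:
    """Reference synthetic dataset: 2000 genes (500 APA), 300 cells, 3 types."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sv.simulate(sv.SimConfig())


@pytest.fixture(scope="session")
def default_imputed(default_sim) -> sv.ImputationResult:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sv.iterate_impute(default_sim.phi, default_sim.expr)


@pytest.fixture(scope="session")
def small_sim() -> sv.SimResult:
    """Cheap dataset for tests that refit models repeatedly."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sv.simulate(sv.SimConfig(n_cells=120, n_genes=400, n_apa_genes=100))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
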