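"""Shared fixtures: small proteomes and cached full-size fits.

The default simulated experiment (200 proteins, 5 naive + 6 immune
mice, 2 replicate chip pairs) is fitted once per seed and shared across
integration tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import episcope as ep
from episcope.arrays import ProteinRecord, build_library


@pytest.fixture(scope="session")
def small_proteome() -> list[ProteinRecord]:
    rng = np.random.default_rng(42)
    aa = list("ACDEFGHIKLMNPQRSTVWY")
    records = []
    for i, (length, reviewed) in enumerate(
        [(40, True), (57, True), (33, False), (16, True), (90, False)]
    ):
        seq = "".join(rng.choice(aa, size=length))
        records.append(
            ProteinRecord(accession=f"P{i:03d}", sequence=seq, reviewed=reviewed)
        )
    return records


@pytest.fixture(scope="session")
def small_library(small_proteome):
    return build_library(small_proteome)


@pytest.fixture(scope="session")
def fitted_by_seed():
    """Fit the default simulated experiment once per seed, lazily."""
    cache: dict[int, tuple] = {}

    def get(seed: int):
        if seed not in cache:
            config = ep.SimulationConfig(seed=seed)
            library, matrix, sheet, truth = ep.simulate_dataset(config)
            results = ep.HeronModel(matrix, sheet, library).fit()
            cache[seed] = (config, library, matrix, sheet, truth, results)
        return cache[seed]

    return get


@pytest.fixture(scope="session")
def fitted_default(fitted_by_seed):
    """The seed-1 default experiment and its fitted results."""
    return fitted_by_seed(1)
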