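"""Shared fixtures.

The expensive session fixtures build the full default cohort (n = 117) the
acceptance checks need; unit tests use small grids so the bulk of the suite
runs in seconds.
"""

from __future__ import annotations

import numpy as np
import pytest
from dataclasses import replace

import rtplaneval as rp
from rtplaneval.cohort import generate_case
from rtplaneval.pipeline import case_row
import pandas as pd

#: Master seed for every fixture cohort in the suite.
SUITE_SEED = 0


@pytest.fixture
def small_grid():
    """Anisotropic toy grid for metric oracles."""
    return rp.VoxelGrid((12, 12, 12), (1.0, 2.0, 3.0))


@pytest.fixture
def unit_grid():
    return rp.VoxelGrid((10, 10, 10), (1.0, 1.0, 1.0))


@pytest.fixture(scope="session")
def default_grid():
    return rp.VoxelGrid((64, 64, 96), (2.5, 2.5, 2.5))


@pytest.fixture(scope="session")
def anatomy(default_grid):
    return rp.synthesize_anatomy(default_grid, [SUITE_SEED, 0])


def _stream_table(config: rp.CohortConfig) -> pd.DataFrame:
    rows = [case_row(generate_case(config, i)) for i in range(config.n_cases)]
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def default_config():
    return rp.CohortConfig(n_cases=117, seed=SUITE_SEED)


@pytest.fixture(scope="session")
def default_table(default_config):
    """Cohort table of the full default cohort (n = 117)."""
    return _stream_table(default_config)


@pytest.fixture(scope="session")
def truncated_table(default_config):
    """Same cohort conditions but every case SI-truncated."""
    cfg = replace(default_config, p_si_truncated=1.0, p_asymmetric=0.0)
    return _stream_table(cfg)


@pytest.fixture(scope="session")
def small_cohort():
    """A 6-case cohort with volumes kept in memory (for pipeline tests)."""
    return rp.generate_cohort(rp.CohortConfig(n_cases=6, seed=SUITE_SEED))


def random_blob(rng: np.random.Generator, shape) -> np.ndarray:
    """Random connected-ish nonempty mask for property tests."""
    m = rng.random(shape) < 0.2
    from scipy import ndimage

    m = ndimage.binary_dilation(m, iterations=1)
    if not m.any():
        m[tuple(d // 2 for d in shape)] = True
    return m
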