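"""Shared fixtures.

The full-size phantom and its noise-free synthesis are expensive (the MT
Bloch integration dominates), so they are built once per session and shared
by the denoising-statistics and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from cordqmri.forward import synthesize_dataset
from cordqmri.phantom import build_phantom, generate_geometry
from cordqmri.protocol import default_protocol

BASE_SEED = 1


@pytest.fixture(scope="session")
def protocol():
    return default_protocol()


@pytest.fixture(scope="session")
def phantom():
    """Full 40-slice phantom at default geometry."""
    return build_phantom(generate_geometry(seed=BASE_SEED), seed=BASE_SEED)


@pytest.fixture(scope="session")
def clean_dataset(phantom, protocol):
    """Noise-free 131-measurement dataset for the full phantom."""
    return synthesize_dataset(phantom, protocol)


@pytest.fixture(scope="session")
def small_phantom():
    """A 4-slice phantom for cheap smoke tests."""
    return build_phantom(generate_geometry(nslices=4, seed=BASE_SEED),
                         seed=BASE_SEED)


@pytest.fixture
def rng():
    return np.random.default_rng(BASE_SEED)
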