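"""Shared fixtures.

Pattern-level fixtures simulate at a coarser grid than the package default
(64x64x16 PET voxels at 8x8x10 mm) so the full 48-reconstruction grid and
multi-seed repeats stay fast; the phantom geometry in millimetres is
identical at every grid.
"""

from __future__ import annotations

import numpy as np
import pytest

import petac

SMALL_SHAPE = (64, 64, 16)
SMALL_SPACING = (8.0, 8.0, 10.0)
N_PATTERN_SEEDS = 5


@pytest.fixture(scope="session")
def small_spec():
    return petac.default_phantom(shape=SMALL_SHAPE, spacing_mm=SMALL_SPACING)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return petac.build_phantom(small_spec)


@pytest.fixture(scope="session")
def pattern_bundles(small_spec):
    """Full-grid study bundles for several seeds (the Monte-Carlo ensemble)."""
    return [petac.generate_study(spec=small_spec, seed=seed)
            for seed in range(N_PATTERN_SEEDS)]


@pytest.fixture(scope="session")
def small_bundle(pattern_bundles):
    return pattern_bundles[0]


@pytest.fixture(scope="session")
def default_spec():
    return petac.default_phantom()
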