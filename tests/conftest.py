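"""Shared fixtures: toy natives, noisy libraries and fitted potentials."""

import numpy as np
import pytest

from fraglib.potentials import build_all_potentials
from fraglib.synthetic import (
    LibrarySpec,
    make_toy_native,
    make_worked_example,
    sample_fragment_library,
)


@pytest.fixture(scope="session")
def helix_native():
    """20-residue all-helix native built from canonical torsions (seed 42)."""
    return make_toy_native([("H", 20)], seed=42)


@pytest.fixture(scope="session")
def worked_example():
    """The package's deterministic worked example: (native, library, truth)."""
    return make_worked_example()


@pytest.fixture(scope="session")
def helix_potentials(worked_example):
    """Per-position wGMM potential sets fitted on the worked-example library."""
    _, lib, _ = worked_example
    return build_all_potentials(lib, seed=1)


@pytest.fixture(scope="session")
def mixed_native():
    """Small helix-coil-strand native for mixed-topology tests."""
    return make_toy_native([("H", 8), ("C", 3), ("E", 6)], seed=3)


@pytest.fixture()
def small_library(mixed_native):
    """Noisy library around the mixed native, 4 fragments per position."""
    spec = LibrarySpec(n_frags_per_pos=4, length_range=(7, 9),
                       angle_noise_sd=8.0, pred_rmsd_noise_sd=0.3, seed=11)
    lib, truth = sample_fragment_library(mixed_native, spec)
    return lib, truth


@pytest.fixture()
def rng():
    """Fresh deterministic generator per test (keeps tests order-independent)."""
    return np.random.default_rng(2024)
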