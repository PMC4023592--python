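from __future__ import annotations

import numpy as np
import pytest

from cslmine.fsalign import AlignParams
from cslmine.simdata import SimConfig, make_panel


@pytest.fixture(scope="session")
def params() -> AlignParams:
    return AlignParams()


@pytest.fixture(scope="session")
def small_sim() -> SimConfig:
    """Desk-scale study conditions for fast unit tests."""
    return SimConfig(
        n_families=3,
        n_species=2,
        protein_length=150,
        read_length=200,
        coverage=5.0,
        n_decoys=50,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_panel(small_sim):
    panel, ancestors = make_panel(small_sim)
    return panel, ancestors


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, length))


def random_protein(rng: np.random.Generator, length: int) -> str:
    aas = "ARNDCQEGHILKMFPSTWYV"
    return "".join(aas[i] for i in rng.integers(0, 20, length))
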