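import numpy as np
import pytest

from chelafix.mbar import solve_mbar
from chelafix.synthetic_data import (
    SurrogateSpec,
    default_state_chain,
    quadrature_free_energies,
    sample_surrogate_ensemble,
    toy_ligand_complex,
)


@pytest.fixture(scope="session")
def surrogate_spec():
    return SurrogateSpec()


@pytest.fixture(scope="session")
def small_archive(surrogate_spec):
    """Small replica-exchange archive on the full 21+2-state chain."""
    states = default_state_chain(surrogate_spec)
    return sample_surrogate_ensemble(surrogate_spec, states, 1500, seed=7,
                                     thin=10)


@pytest.fixture(scope="session")
def small_archive_quadrature(surrogate_spec, small_archive):
    return quadrature_free_energies(surrogate_spec, small_archive.states)


@pytest.fixture(scope="session")
def small_mbar(small_archive):
    return solve_mbar(small_archive.matrix())


@pytest.fixture
def toy_complexes():
    return {mode: toy_ligand_complex(mode)
            for mode in ("A", "B", "G", "AB", "AG", "BG", "ABG")}


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
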