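import numpy as np
import pytest

from pepsa.dynamics import PRE_SA_MINIMIZATION, minimize_positions
from pepsa.forcefield import EnergyModel, EnergySystem, load_parameters, neutralize_charges
from pepsa.pepbuild import build_peptide
from pepsa.structure import assign_mobility, cap_termini
from pepsa.synthetic import ToyComplexSpec, make_toy_complex


@pytest.fixture(scope="session")
def params():
    return load_parameters()


@pytest.fixture(scope="session")
def capped_peptide(params):
    """Free (no scaffold) capped phosphopeptide, all atoms mobile."""
    pep = build_peptide(["PTR", "GLU", "GLU", "ILE"])
    pep = cap_termini(pep)
    pep = assign_mobility(pep, "all-free")
    return neutralize_charges(pep, params)


@pytest.fixture(scope="session")
def toy():
    return make_toy_complex(ToyComplexSpec())


@pytest.fixture(scope="session")
def toy_system(toy):
    return EnergySystem(toy.model, toy.params)


@pytest.fixture(scope="session")
def toy_minimized(toy):
    """Toy complex minimized from the extended start, with a no-cutoff system
    (whole complex inside the interaction range) for conservation tests."""
    system = EnergySystem(toy.model, toy.params, energy_model=EnergyModel(cutoff=100.0))
    x0, _ = minimize_positions(system, toy.extended_coords, PRE_SA_MINIMIZATION)
    return system, x0


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
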