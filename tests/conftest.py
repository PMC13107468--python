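"""Shared fixtures: converged monomer SCFs reused across the suite."""

import numpy as np
import pytest

from pistack.fixtures import fixture
from pistack.orbital_analysis import classify_orbitals, fix_phases
from pistack.scf import run_rhf


@pytest.fixture(scope="session")
def he_scf():
    return run_rhf(fixture("he2").molecule, "sto-3g")


@pytest.fixture(scope="session")
def h2_scf():
    return run_rhf(fixture("h2_dimer").molecule, "sto-3g")


@pytest.fixture(scope="session")
def ethylene_scf():
    return run_rhf(fixture("ethylene_dimer").molecule, "sto-3g")


@pytest.fixture(scope="session")
def benzene_scf():
    return run_rhf(fixture("benzene").molecule, "sto-3g")


@pytest.fixture(scope="session")
def benzene_labels(benzene_scf):
    return fix_phases(classify_orbitals(benzene_scf))


@pytest.fixture(scope="session")
def ethylene_labels(ethylene_scf):
    return fix_phases(classify_orbitals(ethylene_scf))
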