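"""Shared fixtures: everything is generated programmatically at test time."""

from __future__ import annotations

import numpy as np
import pytest

from substrate_graft import (
    FixtureSpec,
    Selector,
    identify_components,
    make_ideal_nucleotide,
    make_toy_complex,
    select_atoms,
)


@pytest.fixture(scope="session")
def default_spec() -> FixtureSpec:
    return FixtureSpec()


@pytest.fixture(scope="session")
def toy_complex(default_spec):
    return make_toy_complex(default_spec)


@pytest.fixture()
def toy_protein(toy_complex):
    return select_atoms(toy_complex, Selector(category="polymer"))


@pytest.fixture(scope="session")
def toy_components(toy_complex):
    return identify_components(toy_complex)


@pytest.fixture(scope="session")
def atp_analog():
    return make_ideal_nucleotide("ATP", P=162.0, chi=-120.0, analog=True)


@pytest.fixture(scope="session")
def adp_analog():
    return make_ideal_nucleotide("ADP", P=162.0, chi=-120.0, analog=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
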