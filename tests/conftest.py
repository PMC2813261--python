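"""Shared fixtures: parsed example compounds, rule/cofactor tables, and a
seeded random-molecule generator used by the property tests."""

from __future__ import annotations

import random

import pytest

from ecassign import chemio, classify, fixtures
from ecassign.chemio import Atom, Bond, Molecule
from ecassign.coding import default_catalog
from ecassign.pairing import KnownPairTable


@pytest.fixture(scope="session")
def mol():
    """Parse a named compound fixture into a Molecule."""

    def _mol(name: str) -> Molecule:
        return chemio.parse_molfile(fixtures.make_fixture(name))

    return _mol


@pytest.fixture(scope="session")
def reaction():
    def _reaction(name: str) -> chemio.Reaction:
        return chemio.parse_manifest(fixtures.make_fixture(name))

    return _reaction


@pytest.fixture(scope="session")
def rules() -> classify.RuleSet:
    return classify.load_rules()


@pytest.fixture(scope="session")
def pair_table() -> KnownPairTable:
    return KnownPairTable.load()


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


# ---------------------------------------------------------------------------
# random molecule generation (valence-respecting connected graphs)

_ELEMENTS = ["C", "C", "C", "C", "N", "O", "O", "S", "P"]
_VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2, "P": 3}


def random_molecule(rng: random.Random, max_atoms: int = 8) -> Molecule:
    """A random connected molecule with plausible valences.

    Grows a spanning tree atom by atom, occasionally upgrading bonds to
    double/triple where both partners have spare valence, and sometimes
    closing one extra ring.  Implicit hydrogens fill the remainder.
    """
    n = rng.randint(1, max_atoms)
    elements = [rng.choice(_ELEMENTS) for _ in range(n)]
    free = [_VALENCE[e] for e in elements]
    bonds: list[Bond] = []
    for i in range(1, n):
        partners = [j for j in range(i) if free[j] >= 1]
        if not partners:
            partners = list(range(i))
        j = rng.choice(partners)
        order = 1
        if free[i] >= 2 and free[j] >= 2 and rng.random() < 0.25:
            order = 2 if rng.random() < 0.8 else 3
            order = min(order, free[i], free[j])
        bonds.append(Bond(i, j, order))
        free[i] -= order
        free[j] -= order
    if n >= 4 and rng.random() < 0.3:
        cands = [(a, b) for a in range(n) for b in range(a + 2, n)
                 if free[a] >= 1 and free[b] >= 1
                 and not any({bd.a, bd.b} == {a, b} for bd in bonds)]
        if cands:
            a, b = rng.choice(cands)
            bonds.append(Bond(a, b, 1))
            free[a] -= 1
            free[b] -= 1
    m = Molecule(name=f"rand{n}", atoms=[Atom(e) for e in elements], bonds=bonds)
    return chemio.assign_implicit_hydrogens(m)


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20100129)


@pytest.fixture(scope="session")
def make_random_molecule():
    return random_molecule
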