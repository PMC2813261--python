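"""Molecule/reaction parsing, hydrogen assignment and canonical keys."""

import random

import networkx as nx
import pytest

from ecassign import chemio, fixtures
from ecassign.chemio import MolParseError, canonical_key, parse_manifest, parse_molfile
from ecassign.pairing import KnownPairTable

BAD_BOND_MOL = """\
bad
  ecassign

  1  1  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
M  END
"""


class TestParseMolfile:
    def test_methane_single_carbon(self, mol):
        m = mol("methane")
        assert m.num_heavy == 1
        assert m.atoms[0].element == "C"
        assert m.atoms[0].formal_charge == 0
        assert m.atoms[0].h_count == 4

    def test_ammonium_charge_from_chg_property(self, mol):
        m = mol("ammonium")
        assert m.atoms[0].element == "N"
        assert m.atoms[0].formal_charge == 1
        assert m.atoms[0].h_count == 4

    def test_bond_to_nonexistent_atom_rejected(self):
        with pytest.raises(MolParseError, match="outside"):
            parse_molfile(BAD_BOND_MOL)

    def test_malformed_counts_line_rejected(self):
        with pytest.raises(MolParseError, match="counts"):
            parse_molfile("name\n\n\nxx broken\nM  END\n")

    def test_v3000_rejected(self):
        text = "name\n\n\n  0  0  0  0  0  0  0  0  0  0999 V3000\n"
        with pytest.raises(MolParseError, match="V3000"):
            parse_molfile(text)

    def test_proton_is_zero_heavy_species(self, mol):
        m = mol("hydron")
        assert m.num_heavy == 0
        assert m.free_h == 1
        assert m.free_charge == 1


class TestImplicitHydrogens:
    @pytest.mark.parametrize(
        "name, index, expected_h",
        [
            ("methane", 0, 4),        # bare C
            ("ammonium", 0, 4),       # N with +1 charge
            ("formaldehyde", 0, 2),   # C double-bonded to one O
            ("ethanol", 2, 1),        # hydroxyl O
            ("phosphate", 1, 0),      # hypervalent P floors at zero
            ("glutathione", 6, 1),    # amide N keeps one H
        ],
    )
    def test_h_counts(self, mol, name, index, expected_h):
        assert mol(name).atoms[index].h_count == expected_h

    def test_hydrogen_conservation_on_balanced_reactions(self, reaction):
        """Per-element heavy atoms and total hydrogens balance across sides."""
        balanced = [
            "indolelactate_dh", "alcohol_dh", "arsenate_reductase",
            "udp_murnac_dh", "pyridoxal_dh", "sterol_demethylase",
            "trimethylamine_dh", "choline_oxidase", "fumarate_hydratase",
            "atp_hydrolysis",
        ]
        from collections import Counter

        def census(mols):
            elements = Counter()
            nh = 0
            for m in mols:
                elements.update(a.element for a in m.atoms)
                nh += sum(a.h_count for a in m.atoms) + m.free_h
            return elements, nh

        for name in balanced:
            r = reaction(name)
            (es, hs), (ep, hp) = census(r.substrates), census(r.products)
            assert es == ep, name
            assert hs == hp, name


class TestRoundTrip:
    @pytest.mark.parametrize(
        "name", ["methane", "ammonium", "acetic_acid", "phenol",
                 "arsenate", "fumarate", "trimethylamine"],
    )
    def test_parse_write_parse_isomorphic(self, mol, name):
        m1 = mol(name)
        m2 = parse_molfile(chemio.write_molfile(m1))

        def graph(m):
            g = nx.Graph()
            for i, a in enumerate(m.atoms):
                g.add_node(i, element=a.element, charge=a.formal_charge,
                           h=a.h_count)
            for bd in m.bonds:
                g.add_edge(bd.a, bd.b, order=bd.order)
            return g

        assert nx.is_isomorphic(
            graph(m1), graph(m2),
            node_match=lambda x, y: x == y,
            edge_match=lambda x, y: x == y,
        )


class TestCanonicalKey:
    @pytest.mark.parametrize("name", ["acetic_acid", "phenol", "nad_plus",
                                      "glutathione", "atp"])
    def test_invariant_under_atom_permutation(self, mol, name):
        m = mol(name)
        ref = canonical_key(m)
        rng = random.Random(42)
        shuffles = 100 if m.num_heavy <= 12 else 10
        for _ in range(shuffles):
            perm = list(range(m.num_heavy))
            rng.shuffle(perm)
            assert canonical_key(m.permuted(perm)) == ref

    def test_distinct_structures_distinct_keys(self, mol):
        assert canonical_key(mol("nad_plus")) != canonical_key(mol("nadh"))
        assert canonical_key(mol("ethanol")) != canonical_key(mol("acetaldehyde"))

    def test_water_key_matches_cofactor_table(self, mol, pair_table):
        stored = dict(pair_table.ubiquitous)["H2O"]
        assert canonical_key(mol("water")) == stored

    def test_rdkit_backend_agrees_on_permutation_invariance(self, mol):
        """Independent cross-check: the InChIKey backend must also see the
        permuted copies as one compound."""
        pytest.importorskip("rdkit")
        m = mol("acetic_acid")
        perm = [3, 1, 0, 2]
        assert (canonical_key(m, backend="rdkit")
                == canonical_key(m.permuted(perm), backend="rdkit"))


class TestReactions:
    def test_manifest_expands_stoichiometry(self):
        text = """
        substrates:
          - {mol: "fixture:water", count: 2}
        products:
          - fixture:oxygen
        """
        r = parse_manifest(text)
        assert len(r.substrates) == 2
        assert all(m.name == "water" for m in r.substrates)

    def test_empty_side_rejected(self):
        with pytest.raises(MolParseError, match="both sides"):
            parse_manifest("substrates: []\nproducts: [fixture:water]\n")

    def test_worked_example_has_five_participants(self, reaction):
        r = reaction("indolelactate_dh")
        assert len(r.substrates) + len(r.products) == 5
        assert r.assigned_ec == "1.1.1.110"

    def test_rxn_format_roundtrip(self, mol):
        blocks = [fixtures.make_fixture(n)
                  for n in ("ethanol", "nad_plus", "acetaldehyde", "nadh")]
        text = "$RXN\nalcohol_dh\n\n\n  2  2\n" + "".join(
            "$MOL\n" + b for b in blocks)
        r = chemio.parse_rxn(text)
        assert len(r.substrates) == 2
        assert len(r.products) == 2
        assert r.substrates[0].num_heavy == mol("ethanol").num_heavy
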