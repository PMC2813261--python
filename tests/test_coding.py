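"""Atom/bond coding operators, group perception and structural motifs."""

import random
from collections import Counter

import pytest

from ecassign import chemio
from ecassign.chemio import Atom, Bond, Molecule, element_class
from ecassign.coding import (
    FIELD_OFFSET,
    AtomCodingError,
    atom_code,
    bond_codes,
    detect_functional_groups,
    detect_structures,
    load_group_catalog,
    type_multiset,
)

# the three published reference operators
TABLE2 = {
    "methane": "C00000040000000000000000000000",
    "formaldehyde": "C00001020000000000000000000000",
    "ammonium": "N00000040000000000000000000001",
}


def oracle_atom_code(m: Molecule, i: int) -> str:
    """Independent brute-force recount of neighbours by class and order."""
    counts: Counter = Counter()
    for bd in m.bonds:
        if i in (bd.a, bd.b):
            other = bd.b if bd.a == i else bd.a
            counts[(element_class(m.atoms[other].element), bd.order)] += 1
    parts = []
    for cls in ("C", "O", "H", "N", "S", "P", "R", "As", "M", "X"):
        if cls == "H":
            parts.append(str(m.atoms[i].h_count))
            continue
        parts.append("".join(str(counts[(cls, o)]) for o in (1, 2, 3)))
    q = m.atoms[i].formal_charge
    glyph = str(q) if q >= 0 else "abcdefghi"[-q - 1]
    return element_class(m.atoms[i].element) + "".join(parts) + glyph


class TestAtomCode:
    @pytest.mark.parametrize("name, expected", sorted(TABLE2.items()))
    def test_reference_operators(self, mol, name, expected):
        assert atom_code(mol(name), 0) == expected

    def test_negative_charge_letter_glyph(self):
        m = chemio.assign_implicit_hydrogens(
            Molecule("acetate-O", atoms=[Atom("O", formal_charge=-1)]))
        assert atom_code(m, 0).endswith("a")

    def test_slot_overflow_is_an_error(self):
        atoms = [Atom("S")] + [Atom("F") for _ in range(10)]
        bonds = [Bond(0, i + 1, 1) for i in range(10)]
        m = Molecule("overflow", atoms=atoms, bonds=bonds)
        with pytest.raises(AtomCodingError, match="at most 9"):
            atom_code(m, 0)

    def test_digit_sum_equals_degree_plus_hydrogens(self, mol):
        """Layout conservation across a spread of fixture molecules."""
        for name in ("acetic_acid", "nad_plus", "glutathione", "atp",
                     "arsenate", "heme_ox"):
            m = mol(name)
            for i in range(m.num_heavy):
                body = atom_code(m, i)[len(element_class(m.atoms[i].element)):-1]
                assert sum(int(c) for c in body) == (
                    len(m.neighbors(i)) + m.atoms[i].h_count)

    def test_agrees_with_bruteforce_oracle(self, mol, rng, make_random_molecule):
        fixture_names = ["methane", "formaldehyde", "ammonium", "ethanol",
                         "acetic_acid", "phenol", "arsenate", "fumarate"]
        mols = [mol(n) for n in fixture_names]
        mols += [make_random_molecule(rng) for _ in range(200)]
        for m in mols:
            for i in range(m.num_heavy):
                assert atom_code(m, i) == oracle_atom_code(m, i), m.name


class TestBondCodes:
    @pytest.mark.parametrize(
        "name, expected",
        [
            ("ethane", {"C-C": 1}),
            ("dinitrogen", {"N#N": 1}),
            ("ethene", {"C=C": 1}),
            ("arsenate", {"As-O": 3, "As=O": 1}),
        ],
    )
    def test_reference_bond_codes(self, mol, name, expected):
        assert dict(bond_codes(mol(name))) == expected

    def test_symbols_canonically_ordered(self, mol):
        for code in bond_codes(mol("glutathione")):
            left, right = code[0], code[-1]
            # single-letter classes only here; left never sorts after right
            assert left <= right


class TestTypeMultiset:
    def test_methane(self, mol):
        assert dict(type_multiset(mol("methane"))) == {TABLE2["methane"]: 1}

    def test_ethane_hand_derived(self, mol):
        # each carbon: one single-bonded C neighbour + 3 H
        assert dict(type_multiset(mol("ethane"))) == {
            "C10000030000000000000000000000": 2,
            "C-C": 1,
        }

    def test_proton_empty(self, mol):
        assert type_multiset(mol("hydron")) == Counter()

    def test_invariant_under_atom_permutation(self, mol):
        rng = random.Random(7)
        for name in ("acetic_acid", "indol3yl_lactate", "pyridoxal"):
            m = mol(name)
            ref = type_multiset(m)
            for _ in range(25):
                perm = list(range(m.num_heavy))
                rng.shuffle(perm)
                assert type_multiset(m.permuted(perm)) == ref


class TestGroupDetection:
    def test_acetic_acid_has_one_carboxylic_acid(self, mol, catalog):
        matches = detect_functional_groups(mol("acetic_acid"), catalog)
        ca = [g for g in matches if g.code == "CA"]
        assert len(ca) == 1
        assert len(ca[0].atom_indices) == 3  # C + both oxygens

    def test_methane_matches_nothing(self, mol, catalog):
        assert detect_functional_groups(mol("methane"), catalog) == []

    def test_worked_substrate_groups(self, mol, catalog):
        codes = {g.code for g in
                 detect_functional_groups(mol("indol3yl_lactate"), catalog)}
        assert {"A1", "CA"} <= codes
        codes_p = {g.code for g in
                   detect_functional_groups(mol("indol3yl_pyruvate"), catalog)}
        assert {"K", "CA"} <= codes_p

    @pytest.mark.parametrize(
        "name, code",
        [("ethanol", "A1"), ("acetaldehyde", "AL"), ("trimethylamine", "AM3"),
         ("dimethylamine", "AM2"), ("glutathione", "TH"), ("atp", "PO"),
         ("hydroxybenzofuranone", "ES")],
    )
    def test_catalog_coverage(self, mol, catalog, name, code):
        assert code in {g.code for g in
                        detect_functional_groups(mol(name), catalog)}

    def test_antimonotonic_under_atom_deletion(self, mol, catalog):
        """Removing a matched atom removes that match."""
        m = mol("ethanol")
        assert any(g.code == "A1"
                   for g in detect_functional_groups(m, catalog))
        no_o = Molecule("ethyl", atoms=[Atom("C"), Atom("C")],
                        bonds=[Bond(0, 1, 1)])
        chemio.assign_implicit_hydrogens(no_o)
        assert not any(g.code == "A1"
                       for g in detect_functional_groups(no_o, catalog))

    def test_custom_catalog_file_roundtrip(self, tmp_path):
        path = tmp_path / "groups.yaml"
        path.write_text(
            "groups:\n"
            "  - code: CA\n"
            "    atoms:\n"
            "      - operator: \"C00011000000000000000000000000\"\n"
            "        wildcards: [C, R]\n"
            "      - operator: \"O10000010000000000000000000000\"\n"
            "    adjacency: [[0, 1]]\n"
        )
        cat = load_group_catalog(path)
        assert len(cat) == 1 and cat[0].patterns[0].symbol == "C"


class TestStructureDetection:
    def test_phenol_yes_cyclohexanol_no(self, mol):
        assert {s.code for s in detect_structures(mol("phenol"))} == {"PHE"}
        assert detect_structures(mol("cyclohexanol")) == []

    def test_heme_redox_states(self, mol):
        assert {s.code for s in detect_structures(mol("heme_ox"))} == {"HEM", "CYO"}
        assert {s.code for s in detect_structures(mol("heme_red"))} == {"HEM", "CYR"}

    def test_flavin_redox_states(self, mol):
        assert {s.code for s in detect_structures(mol("lumiflavin"))} == {"FLO"}
        assert {s.code for s in detect_structures(mol("lumiflavin_red"))} == {"FLR"}

    def test_iron_sulfur_cluster_charge_rule(self):
        def cluster(fe_charge: int) -> Molecule:
            atoms = [Atom("Fe", formal_charge=fe_charge),
                     Atom("Fe", formal_charge=fe_charge), Atom("S"), Atom("S")]
            bonds = [Bond(0, 2, 1), Bond(2, 1, 1), Bond(1, 3, 1), Bond(3, 0, 1)]
            return chemio.assign_implicit_hydrogens(
                Molecule("fes", atoms=atoms, bonds=bonds))

        assert {s.code for s in detect_structures(cluster(3))} == {"ISO"}
        assert {s.code for s in detect_structures(cluster(2))} == {"ISR"}
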