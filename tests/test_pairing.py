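"""Tanimoto coefficient, cofactor-pair removal and greedy pairing."""

import itertools
from collections import Counter

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecassign import chemio, fixtures
from ecassign.coding import type_multiset
from ecassign.pairing import (
    KnownPairTable,
    ReducedReaction,
    pair_reactants,
    remove_known_pairs,
    tanimoto,
)

multisets = st.dictionaries(
    st.sampled_from("abcdefgh"), st.integers(min_value=1, max_value=5),
    max_size=8,
).map(Counter)


class TestTanimoto:
    @pytest.mark.parametrize("name", ["methane", "nad_plus", "glutathione"])
    def test_self_similarity_is_one(self, mol, name):
        ms = type_multiset(mol(name))
        assert tanimoto(ms, ms) == 1.0

    def test_token_disjoint_is_zero(self, mol):
        assert tanimoto(type_multiset(mol("methane")),
                        type_multiset(mol("dinitrogen"))) == 0.0

    def test_ethane_vs_ethene_zero(self, mol):
        # no token occurs with equal nonzero multiplicity in both
        assert tanimoto(type_multiset(mol("ethane")),
                        type_multiset(mol("ethene"))) == 0.0

    def test_empty_cases(self):
        assert tanimoto(Counter(), Counter()) == 1.0
        assert tanimoto(Counter(), Counter({"x": 1})) == 0.0

    @settings(derandomize=True, max_examples=300)
    @given(s=multisets, p=multisets)
    def test_symmetry_and_partition(self, s, p):
        """T is symmetric and a/b/c partition the token union."""
        assert tanimoto(s, p) == tanimoto(p, s)
        union = set(s) | set(p)
        a = sum(1 for t in union if s.get(t, 0) == p.get(t, 0))
        b = sum(1 for t in union if s.get(t, 0) > p.get(t, 0))
        c = sum(1 for t in union if s.get(t, 0) < p.get(t, 0))
        assert a + b + c == len(union)
        if union:
            assert tanimoto(s, p) == pytest.approx(a / (a + b + c))

    def test_bounded_on_random_molecules(self, rng, make_random_molecule):
        for _ in range(200):
            s = type_multiset(make_random_molecule(rng))
            p = type_multiset(make_random_molecule(rng))
            assert 0.0 <= tanimoto(s, p) <= 1.0


class TestRemoveKnownPairs:
    def test_worked_example_removals(self, reaction, pair_table):
        red = remove_known_pairs(reaction("indolelactate_dh"), pair_table)
        assert red.removed_classes == {"NAD_REDOX"}
        assert [m.name for m in red.substrates] == ["indol3yl_lactate"]
        assert [m.name for m in red.products] == ["indol3yl_pyruvate"]
        assert ("UBIQUITOUS", ("hydron",)) in red.removed

    def test_no_table_hits_leaves_reaction_intact(self, reaction, pair_table):
        r = reaction("fumarate_hydratase")
        red = remove_known_pairs(r, pair_table)
        assert [m.name for m in red.substrates] == ["malate"]
        # water removed only as a ubiquitous single, never as a pair
        assert red.removed_classes == set()

    def test_o2_h2o2_pair_class(self, reaction, pair_table):
        red = remove_known_pairs(reaction("choline_oxidase"), pair_table)
        assert "O2_H2O2" in red.removed_classes

    def test_disabled_water_ammonia_row_never_fires(self, pair_table):
        text = """
        substrates: [fixture:water, fixture:methane]
        products: [fixture:ammonia, fixture:methane]
        """
        red = remove_known_pairs(chemio.parse_manifest(text), pair_table)
        assert "H2O_NH3" not in red.removed_classes

    def test_removed_plus_remaining_partition_participants(
            self, reaction, pair_table):
        for name in fixtures.REACTIONS:
            r = reaction(name)
            red = remove_known_pairs(r, pair_table)
            n_removed = sum(len(names) for _, names in red.removed)
            assert n_removed + len(red.substrates) + len(red.products) == (
                len(r.substrates) + len(r.products))


class TestPairReactants:
    def test_single_pair_regardless_of_similarity(self, mol):
        red = ReducedReaction([mol("methane")], [mol("dinitrogen")], [])
        pairs, unpaired = pair_reactants(red)
        assert len(pairs) == 1 and unpaired == []
        assert pairs[0].similarity == 0.0

    def test_dominant_diagonal_two_by_two(self, mol):
        # ethanol/ethanol and methane/methane dominate the cross terms
        red = ReducedReaction(
            [mol("ethanol"), mol("methane")],
            [mol("methane"), mol("ethanol")], [])
        pairs, _ = pair_reactants(red)
        matched = {(p.substrate.name, p.product.name) for p in pairs}
        assert matched == {("ethanol", "ethanol"), ("methane", "methane")}
        assert all(p.similarity == 1.0 for p in pairs)

    def test_unequal_cardinality_leaves_unpaired(self, mol):
        red = ReducedReaction([mol("ethanol"), mol("methane")],
                              [mol("acetaldehyde")], [])
        pairs, unpaired = pair_reactants(red)
        assert len(pairs) == 1
        assert [(side, m.name) for side, m in unpaired] == [("S", "methane")]

    def test_similarities_descending(self, reaction, pair_table):
        red = remove_known_pairs(reaction("sterol_demethylase"), pair_table)
        pairs, _ = pair_reactants(red)
        sims = [p.similarity for p in pairs]
        assert sims == sorted(sims, reverse=True)

    def test_greedy_close_to_exhaustive_on_small_reactions(
            self, rng, make_random_molecule):
        """Greedy matching is the specified behaviour; on random <=3x3
        reactions compare its total similarity with the exhaustive optimum
        and log (not fail) genuine disagreements."""
        disagreements = 0
        for _ in range(60):
            ns, np_ = rng.randint(1, 3), rng.randint(1, 3)
            subs = [make_random_molecule(rng) for _ in range(ns)]
            prods = [make_random_molecule(rng) for _ in range(np_)]
            pairs, unpaired = pair_reactants(ReducedReaction(subs, prods, []))
            assert len(pairs) == min(ns, np_)
            assert len(unpaired) == abs(ns - np_)
            greedy_total = sum(p.similarity for p in pairs)
            k = min(ns, np_)
            sims = [[tanimoto(type_multiset(s), type_multiset(p))
                     for p in prods] for s in subs]
            best = max(
                sum(sims[i][j] for i, j in zip(rows, cols))
                for rows in itertools.permutations(range(ns), k)
                for cols in itertools.permutations(range(np_), k)
            )
            assert greedy_total <= best + 1e-12
            if best - greedy_total > 1e-12:
                disagreements += 1
        # greedy is near-optimal on dominant-diagonal chemistry; a handful
        # of synthetic disagreements is expected and acceptable
        assert disagreements < 60
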