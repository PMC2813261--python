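"""Cofactor-pair removal and Tanimoto-ordered substrate/product pairing.

Recurring cofactor couples (NAD+/NADH, NADP+/NADPH, O2/H2O2, oxidized/
reduced glutathione, 2-oxoglutarate/succinate, ...) take part in a large
fraction of enzyme-catalysed reactions without carrying the reaction's
classifying chemistry, so they are identified by canonical compound key
and removed before pairing, as are ubiquitous single species (H+, water,
free phosphate).  The remaining substrates and products are then paired
one-to-one, most similar first, using the Tanimoto coefficient over
atom-type/bond-type multisets.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .chemio import Molecule, Reaction, canonical_key
from .coding import type_multiset

__all__ = [
    "tanimoto",
    "KnownPair",
    "KnownPairTable",
    "ReducedReaction",
    "ReactantPair",
    "remove_known_pairs",
    "pair_reactants",
]


def tanimoto(s: Counter, p: Counter) -> float:
    """Tanimoto coefficient between two type multisets.

    Over the union of type tokens, ``a`` counts tokens occurring with the
    same frequency in both molecules, ``b`` tokens more frequent in the
    substrate (including those absent from the product) and ``c`` tokens
    more frequent in the product; T = a / (a + b + c).  The coefficient is
    1 for identical and 0 for token-disjoint molecules; two empty
    multisets (e.g. H+ vs H+) count as identical.
    """
    tokens = set(s) | set(p)
    if not tokens:
        return 1.0
    a = b = c = 0
    for t in tokens:
        ns, np_ = s.get(t, 0), p.get(t, 0)
        if ns == np_:
            a += 1
        elif ns > np_:
            b += 1
        else:
            c += 1
    return a / (a + b + c)


@dataclass(frozen=True)
class KnownPair:
    pair_class: str
    substrate_name: str
    substrate_key: str
    product_name: str
    product_key: str
    enabled: bool = True


@dataclass
class KnownPairTable:
    pairs: list[KnownPair] = field(default_factory=list)
    ubiquitous: list[tuple[str, str]] = field(default_factory=list)  # (name, key)

    @classmethod
    def load(cls, path: str | Path | None = None) -> "KnownPairTable":
        if path is None:
            text = resources.files("ecassign").joinpath(
                "data/cofactors.yaml").read_text()
        else:
            text = Path(path).read_text()
        doc = yaml.safe_load(text)
        pairs = [
            KnownPair(
                pair_class=rec["class"],
                substrate_name=rec["substrate"]["name"],
                substrate_key=rec["substrate"]["key"],
                product_name=rec["product"]["name"],
                product_key=rec["product"]["key"],
                enabled=bool(rec.get("enabled", True)),
            )
            for rec in doc.get("pairs", [])
        ]
        ubiq = [(rec["name"], rec["key"]) for rec in doc.get("ubiquitous", [])]
        return cls(pairs=pairs, ubiquitous=ubiq)


@dataclass
class ReducedReaction:
    substrates: list[Molecule]
    products: list[Molecule]
    removed: list[tuple[str, tuple[str, ...]]]  # (class or UBIQUITOUS, names)

    @property
    def removed_classes(self) -> frozenset[str]:
        return frozenset(cls for cls, _ in self.removed if cls != "UBIQUITOUS")


@dataclass
class ReactantPair:
    substrate: Molecule
    product: Molecule
    similarity: float


def remove_known_pairs(r: Reaction, table: KnownPairTable) -> ReducedReaction:
    """Strip known cofactor pairs and ubiquitous single species.

    Pairs are consumed first (each table entry at most once per
    stoichiometric instance, in table order), then ubiquitous species are
    removed from both sides individually.  Every removal is recorded for
    provenance; nothing is ever removed from one side alone as part of a
    pair.
    """
    subs = [(m, canonical_key(m)) for m in r.substrates]
    prods = [(m, canonical_key(m)) for m in r.products]
    removed: list[tuple[str, tuple[str, ...]]] = []

    for pair in table.pairs:
        if not pair.enabled:
            continue
        while True:
            si = next((i for i, (_, k) in enumerate(subs)
                       if k == pair.substrate_key), None)
            pi = next((i for i, (_, k) in enumerate(prods)
                       if k == pair.product_key), None)
            if si is None or pi is None:
                break
            removed.append((pair.pair_class,
                            (subs[si][0].name, prods[pi][0].name)))
            del subs[si]
            del prods[pi]

    ubiq_keys = {k: name for name, k in table.ubiquitous}
    for side in (subs, prods):
        for i in reversed(range(len(side))):
            k = side[i][1]
            if k in ubiq_keys:
                removed.append(("UBIQUITOUS", (side[i][0].name,)))
                del side[i]

    return ReducedReaction(
        substrates=[m for m, _ in subs],
        products=[m for m, _ in prods],
        removed=removed,
    )


def pair_reactants(
    r: ReducedReaction,
) -> tuple[list[ReactantPair], list[tuple[str, Molecule]]]:
    """Greedy one-to-one assignment by descending Tanimoto similarity.

    All substrate x product similarities are computed, then pairs are
    consumed most-similar-first; ties break on the lexicographic canonical
    keys of the two molecules so the result is independent of input
    ordering.  With unequal side cardinalities the leftovers are returned
    as ('S'/'P', molecule) entries.
    """
    subs = list(r.substrates)
    prods = list(r.products)
    sub_ms = [type_multiset(m) for m in subs]
    prod_ms = [type_multiset(m) for m in prods]
    sub_keys = [canonical_key(m) for m in subs]
    prod_keys = [canonical_key(m) for m in prods]

    edges = sorted(
        (
            (-tanimoto(sub_ms[i], prod_ms[j]), sub_keys[i], prod_keys[j], i, j)
            for i in range(len(subs))
            for j in range(len(prods))
        ),
    )
    used_s: set[int] = set()
    used_p: set[int] = set()
    pairs: list[ReactantPair] = []
    for neg_sim, _, _, i, j in edges:
        if i in used_s or j in used_p:
            continue
        used_s.add(i)
        used_p.add(j)
        pairs.append(ReactantPair(subs[i], prods[j], -neg_sim))
    unpaired = [("S", subs[i]) for i in sorted(set(range(len(subs))) - used_s)]
    unpaired += [("P", prods[j]) for j in sorted(set(range(len(prods))) - used_p)]
    return pairs, unpaired
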