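"""Difference-key generation: the type-level fingerprint of a reaction.

For each reactant pair the two molecules are compared level by level —
structural motifs first, then functional groups, then bonds, then atoms —
and only the surplus types on either side survive.  Atoms consumed by a
matched group or motif, and bonds running entirely inside one match, are
masked from the lower levels so that e.g. an alcohol-to-ketone change is
reported once as S:A1 / P:K rather than additionally as hydroxyl-bond and
oxygen-atom noise.  Equal counts cancel in a single running ledger across
all pairs of the reaction; unpaired molecules contribute their full token
sets.  The rendered key is canonical: codes ASCII-sorted within each
side, counts as a ``*n`` suffix, sides joined by ``|``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .chemio import Molecule
from .coding import (
    GroupDef,
    atom_code,
    bond_codes_with_atoms,
    default_catalog,
    detect_functional_groups,
    detect_structures,
)
from .pairing import ReactantPair

__all__ = [
    "SideTaggedCode",
    "DifferenceKey",
    "molecule_tokens",
    "pair_difference",
    "build_difference_key",
]


@dataclass(frozen=True)
class SideTaggedCode:
    side: str  # 'S' or 'P'
    code: str
    count: int


@dataclass(frozen=True)
class DifferenceKey:
    entries: tuple[SideTaggedCode, ...]

    @property
    def side(self) -> dict[str, Counter]:
        out = {"S": Counter(), "P": Counter()}
        for e in self.entries:
            out[e.side][e.code] += e.count
        return out

    @property
    def rendered(self) -> str:
        sides = self.side
        if not sides["S"] and not sides["P"]:
            return ""

        def fmt(counter: Counter) -> str:
            return ",".join(
                code if n == 1 else f"{code}*{n}"
                for code, n in sorted(counter.items())
            )

        return f"S:{fmt(sides['S'])}|P:{fmt(sides['P'])}"


def molecule_tokens(m: Molecule, catalog: list[GroupDef] | None = None) -> Counter:
    """All countable types of one molecule with masking applied.

    Returns one Counter mixing motif codes, group codes, bond codes and
    atom coding operators (the four namespaces cannot collide: motif and
    group codes are short uppercase mnemonics, bond codes contain a bond
    glyph, atom operators are 30+ characters long).
    """
    catalog = catalog if catalog is not None else default_catalog()
    tokens: Counter = Counter()

    motifs = detect_structures(m)
    motif_atoms = frozenset(i for s in motifs for i in s.atom_indices)
    groups = detect_functional_groups(m, catalog, masked=motif_atoms)

    match_sets = [set(s.atom_indices) for s in motifs]
    match_sets += [set(g.atom_indices) for g in groups]
    consumed = set().union(*match_sets) if match_sets else set()

    for s in motifs:
        tokens[s.code] += 1
    for g in groups:
        tokens[g.code] += 1
    for code, (a, b) in bond_codes_with_atoms(m):
        if any(a in ms and b in ms for ms in match_sets):
            continue  # bond consumed inside a single match
        tokens[code] += 1
    for i in range(m.num_heavy):
        if i not in consumed:
            tokens[atom_code(m, i)] += 1
    return tokens


def pair_difference(
    p: ReactantPair, catalog: list[GroupDef] | None = None
) -> list[SideTaggedCode]:
    """Surplus types of one substrate/product pair after cancellation."""
    s_tok = molecule_tokens(p.substrate, catalog)
    p_tok = molecule_tokens(p.product, catalog)
    out = [SideTaggedCode("S", code, n) for code, n in sorted((s_tok - p_tok).items())]
    out += [SideTaggedCode("P", code, n) for code, n in sorted((p_tok - s_tok).items())]
    return out


def build_difference_key(
    pairs: list[ReactantPair],
    unpaired: list[tuple[str, Molecule]] = (),
    catalog: list[GroupDef] | None = None,
) -> DifferenceKey:
    """Accumulate per-pair differences into the reaction's difference key.

    Types matched on opposite sides cancel globally (running ledger across
    pairs, which also removes e.g. a group handed from one pair's
    substrate to another pair's product); the ledger is rendered
    canonically, so the key is byte-identical for any participant
    ordering.
    """
    ledger_s: Counter = Counter()
    ledger_p: Counter = Counter()
    for pair in pairs:
        for e in pair_difference(pair, catalog):
            (ledger_s if e.side == "S" else ledger_p)[e.code] += e.count
        # cancel cross-side equal counts after every comparison step
        common = ledger_s & ledger_p
        ledger_s -= common
        ledger_p -= common
    for side, mol in unpaired:
        tok = molecule_tokens(mol, catalog)
        (ledger_s if side == "S" else ledger_p).update(tok)
    common = ledger_s & ledger_p
    ledger_s -= common
    ledger_p -= common
    entries = tuple(
        [SideTaggedCode("S", c, n) for c, n in sorted(ledger_s.items())]
        + [SideTaggedCode("P", c, n) for c, n in sorted(ledger_p.items())]
    )
    return DifferenceKey(entries=entries)
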