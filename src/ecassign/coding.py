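"""Fixed-layout coding of atoms, bonds, functional groups and motifs.

Every heavy atom of a compound is rendered as a coding operator: the
element symbol followed by 29 character slots laid out as ::

    CCC OOO H NNN SSS PPP RRR AsAsAs MMM XXX c

Within each three-character element field the positions count neighbours
connected by a single, double and triple bond respectively; hydrogen gets
a single slot because it only forms single bonds, and the final character
encodes the formal charge ('0'-'9' for 0..+9, 'a'-'i' for -1..-9).  A
methane carbon therefore codes as ``C00000040000000000000000000000``.

Bonds are coded as ``A-B`` / ``A=B`` / ``A#B`` with the two class symbols
in lexicographic order; bonds to hydrogen are never emitted because
hydrogens live in the H slot of the atom operator.

Functional groups are perceived by conjunctions of operator patterns on
adjacent atoms (no SMARTS engine): a group definition is a list of
patterns, each the literal operator string of the idealized atom with
selected element fields wildcarded, plus adjacency constraints.  Complex
structural motifs (heme, cytochromes, iron-sulfur clusters, flavins,
phenols) are perceived on top of ring perception (smallest set of
smallest rings).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import networkx as nx
import yaml

from .chemio import Molecule, element_class

__all__ = [
    "AtomCodingError",
    "atom_code",
    "bond_codes",
    "bond_codes_with_atoms",
    "default_catalog",
    "type_multiset",
    "OperatorPattern",
    "GroupDef",
    "GroupMatch",
    "StructureMatch",
    "load_group_catalog",
    "detect_functional_groups",
    "detect_structures",
    "sssr",
]

# slot offsets of each element-class field inside the 29-character layout
FIELD_OFFSET = {"C": 0, "O": 3, "H": 6, "N": 7, "S": 10,
                "P": 13, "R": 16, "As": 19, "M": 22, "X": 25}
CHARGE_SLOT = 28
N_SLOTS = 29

_BOND_GLYPH = {1: "-", 2: "=", 3: "#"}


class AtomCodingError(ValueError):
    pass


def _charge_glyph(charge: int, where: str) -> str:
    if 0 <= charge <= 9:
        return str(charge)
    if -9 <= charge <= -1:
        return chr(ord("a") + (-charge) - 1)
    raise AtomCodingError(f"{where}: charge {charge} outside the codable range")


def atom_code(m: Molecule, i: int) -> str:
    """Render the coding operator for atom ``i`` of ``m``.

    Implicit hydrogens must already be assigned.  Any neighbour-count slot
    exceeding 9 is an error rather than a saturation: a silently capped
    digit would corrupt every downstream frequency comparison.
    """
    atom = m.atoms[i]
    slots = [0] * N_SLOTS
    for j, order in m.neighbors(i):
        cls = element_class(m.atoms[j].element)
        off = FIELD_OFFSET[cls]
        if cls == "H":  # explicit H never survives parsing, but be safe
            slots[off] += 1
        else:
            slots[off + order - 1] += 1
    slots[FIELD_OFFSET["H"]] += atom.h_count
    for k in range(N_SLOTS - 1):
        if slots[k] > 9:
            raise AtomCodingError(
                f"{m.name}: atom {i} ({atom.element}) has {slots[k]} "
                "same-class neighbours; the layout holds at most 9")
    symbol = element_class(atom.element)
    body = "".join(str(v) for v in slots[:-1])
    return symbol + body + _charge_glyph(atom.formal_charge, m.name)


def bond_codes(m: Molecule) -> Counter:
    """Multiset of bond codes (one per heavy-atom bond)."""
    out: Counter = Counter()
    for bd in m.bonds:
        a = element_class(m.atoms[bd.a].element)
        b = element_class(m.atoms[bd.b].element)
        left, right = sorted((a, b))
        out[f"{left}{_BOND_GLYPH[bd.order]}{right}"] += 1
    return out


def bond_codes_with_atoms(m: Molecule) -> list[tuple[str, tuple[int, int]]]:
    """Bond codes paired with their endpoint atom indices (for masking)."""
    out = []
    for bd in m.bonds:
        a = element_class(m.atoms[bd.a].element)
        b = element_class(m.atoms[bd.b].element)
        left, right = sorted((a, b))
        out.append((f"{left}{_BOND_GLYPH[bd.order]}{right}", (bd.a, bd.b)))
    return out


def type_multiset(m: Molecule) -> Counter:
    """Atom-type and bond-type tokens with multiplicities.

    This is the object the Tanimoto coefficient compares; a zero-heavy-atom
    species (H+) yields an empty multiset.
    """
    out: Counter = Counter()
    for i in range(m.num_heavy):
        out[atom_code(m, i)] += 1
    out.update(bond_codes(m))
    return out


# ---------------------------------------------------------------------------
# functional group perception


@dataclass(frozen=True)
class OperatorPattern:
    """One atom pattern of a group definition.

    ``operator`` is the literal coding-operator string of the idealized
    atom; ``wildcard_fields`` names element fields whose three slots are
    ignored during matching (where the generic definition allows arbitrary
    attachment); ``at_least`` maps a field name to a minimum count summed
    over that field's slots (e.g. H >= 1 for the alcohol carbon).
    """

    operator: str
    wildcard_fields: tuple[str, ...] = ()
    at_least: tuple[tuple[str, int], ...] = ()

    def __post_init__(self):
        sym = self.operator[:-N_SLOTS]
        if not sym or len(self.operator) != len(sym) + N_SLOTS:
            raise ValueError(f"pattern operator has wrong layout: {self.operator!r}")

    @property
    def symbol(self) -> str:
        return self.operator[:-N_SLOTS]

    def matches(self, code: str) -> bool:
        sym = self.symbol
        if not code.startswith(sym) or len(code) != len(sym) + N_SLOTS:
            return False
        body = code[len(sym):]
        ref = self.operator[len(sym):]
        skip: set[int] = set()
        for f in self.wildcard_fields:
            off = FIELD_OFFSET[f]
            width = 1 if f == "H" else 3
            skip.update(range(off, off + width))
        for f, minimum in self.at_least:
            off = FIELD_OFFSET[f]
            width = 1 if f == "H" else 3
            skip.update(range(off, off + width))
            got = sum(int(body[k]) for k in range(off, off + width))
            if got < minimum:
                return False
        return all(body[k] == ref[k] for k in range(N_SLOTS) if k not in skip)


@dataclass(frozen=True)
class GroupDef:
    code: str
    name: str
    patterns: tuple[OperatorPattern, ...]
    adjacency: tuple[tuple[int, int], ...]  # indices into patterns


@dataclass(frozen=True)
class GroupMatch:
    code: str
    atom_indices: tuple[int, ...]


@dataclass(frozen=True)
class StructureMatch:
    code: str
    atom_indices: tuple[int, ...]


def load_group_catalog(path: str | Path | None = None) -> list[GroupDef]:
    """Load the functional-group catalog (shipped YAML by default)."""
    if path is None:
        text = resources.files("ecassign").joinpath("data/groups.yaml").read_text()
    else:
        text = Path(path).read_text()
    doc = yaml.safe_load(text)
    out = []
    for rec in doc["groups"]:
        patterns = tuple(
            OperatorPattern(
                operator=p["operator"],
                wildcard_fields=tuple(p.get("wildcards", ())),
                at_least=tuple(sorted((p.get("at_least") or {}).items())),
            )
            for p in rec["atoms"]
        )
        adjacency = tuple((int(a), int(b)) for a, b in rec.get("adjacency", ()))
        for a, b in adjacency:
            if not (0 <= a < len(patterns) and 0 <= b < len(patterns)):
                raise ValueError(f"group {rec['code']}: adjacency out of range")
        out.append(GroupDef(code=rec["code"], name=rec.get("name", rec["code"]),
                            patterns=patterns, adjacency=adjacency))
    return out


_DEFAULT_CATALOG: list[GroupDef] | None = None


def default_catalog() -> list[GroupDef]:
    global _DEFAULT_CATALOG
    if _DEFAULT_CATALOG is None:
        _DEFAULT_CATALOG = load_group_catalog()
    return _DEFAULT_CATALOG


def detect_functional_groups(
    m: Molecule,
    catalog: list[GroupDef] | None = None,
    masked: frozenset[int] | set[int] = frozenset(),
) -> list[GroupMatch]:
    """Match every catalog group against the molecule.

    ``masked`` atoms (typically those consumed by a structural motif) are
    invisible to group matching.  Within one group code an atom serves at
    most one match; candidate matches are consumed in deterministic
    ascending atom-index order so results are permutation-stable as
    multisets.
    """
    catalog = catalog if catalog is not None else default_catalog()
    codes = [atom_code(m, i) for i in range(m.num_heavy)]
    adj = {i: {j for j, _ in m.neighbors(i)} for i in range(m.num_heavy)}
    out: list[GroupMatch] = []
    for gd in catalog:
        candidates = _enumerate_matches(gd, codes, adj, masked)
        used: set[int] = set()
        for match in sorted(candidates):
            if not used.intersection(match):
                used.update(match)
                out.append(GroupMatch(code=gd.code, atom_indices=match))
    return out


def _enumerate_matches(gd, codes, adj, masked) -> set[tuple[int, ...]]:
    n = len(codes)
    per_pattern = []
    for pat in gd.patterns:
        hits = [i for i in range(n) if i not in masked and pat.matches(codes[i])]
        if not hits:
            return set()
        per_pattern.append(hits)
    found: set[tuple[int, ...]] = set()

    def backtrack(k: int, chosen: list[int]) -> None:
        if k == len(per_pattern):
            found.add(tuple(sorted(chosen)))
            return
        for i in per_pattern[k]:
            if i in chosen:
                continue
            ok = True
            for a, b in gd.adjacency:
                if a == k and b < k:
                    ok = ok and (chosen[b] in adj[i])
                elif b == k and a < k:
                    ok = ok and (chosen[a] in adj[i])
            if ok:
                chosen.append(i)
                backtrack(k + 1, chosen)
                chosen.pop()

    backtrack(0, [])
    return found


# ---------------------------------------------------------------------------
# ring perception and structural motifs


def sssr(m: Molecule) -> list[tuple[int, ...]]:
    """Smallest set of smallest rings on the heavy graph.

    Computed as a minimum cycle basis; rings are returned as sorted atom
    tuples ordered by (size, atom-index sum, tuple) so ties break
    deterministically.
    """
    g = nx.Graph()
    g.add_nodes_from(range(m.num_heavy))
    for bd in m.bonds:
        g.add_edge(bd.a, bd.b)
    rings = [tuple(sorted(c)) for c in nx.minimum_cycle_basis(g)]
    rings.sort(key=lambda r: (len(r), sum(r), r))
    return rings


def _ring_bond_orders(m: Molecule, ring: tuple[int, ...]) -> list[int]:
    rset = set(ring)
    return [bd.order for bd in m.bonds if bd.a in rset and bd.b in rset]


def detect_structures(m: Molecule) -> list[StructureMatch]:
    """Perceive complex structural motifs.

    HEM    four 5-membered N-heterocycles whose nitrogens share a central
           iron; CYO/CYR additionally report the cytochrome redox state
           from the iron formal charge (+3 oxidized, +2 reduced).
    ISO/ISR  an iron-sulfur cluster (connected Fe/S subgraph with at least
           two irons and two bridging sulfurs); reduced only when every
           iron is Fe2+ or lower.
    FLO/FLR  an isoalloxazine (flavin) tricycle; oxidized when a nitrogen
           of the central ring carries a double bond.
    PHE    a benzene carbocycle bearing at least one hydroxyl.
    """
    out: list[StructureMatch] = []
    rings = sssr(m)
    elems = [a.element for a in m.atoms]

    # --- heme / cytochrome
    five_n_rings = [r for r in rings if len(r) == 5
                    and sum(elems[i] == "N" for i in r) == 1]
    for fe in [i for i, e in enumerate(elems) if e == "Fe"]:
        fe_n = {j for j, _ in m.neighbors(fe) if elems[j] == "N"}
        pyrroles = [r for r in five_n_rings
                    if any(i in fe_n and elems[i] == "N" for i in r)]
        if len(pyrroles) >= 4:
            consumed = tuple(sorted({fe, *[i for r in pyrroles[:4] for i in r]}))
            out.append(StructureMatch("HEM", consumed))
            state = "CYO" if m.atoms[fe].formal_charge >= 3 else "CYR"
            out.append(StructureMatch(state, consumed))

    # --- iron-sulfur clusters
    fes_nodes = [i for i, e in enumerate(elems) if e in ("Fe", "S")]
    g = nx.Graph()
    g.add_nodes_from(fes_nodes)
    for bd in m.bonds:
        if bd.a in g and bd.b in g:
            g.add_edge(bd.a, bd.b)
    for comp in nx.connected_components(g):
        irons = [i for i in comp if elems[i] == "Fe"]
        sulfurs = [i for i in comp if elems[i] == "S"]
        if len(irons) >= 2 and len(sulfurs) >= 2:
            reduced = all(m.atoms[i].formal_charge <= 2 for i in irons)
            out.append(StructureMatch("ISR" if reduced else "ISO",
                                      tuple(sorted(comp))))

    # --- flavin (isoalloxazine)
    out.extend(_detect_flavin(m, rings, elems))

    # --- phenol
    hydroxyl_o = {
        i for i, a in enumerate(m.atoms)
        if a.element == "O" and a.h_count == 1 and a.formal_charge == 0
        and len(m.neighbors(i)) == 1
    }
    claimed = {i for s in out for i in s.atom_indices}
    for r in rings:
        if len(r) != 6 or any(elems[i] != "C" for i in r):
            continue
        if sorted(_ring_bond_orders(m, r)) != [1, 1, 1, 2, 2, 2]:
            continue
        if set(r) & claimed:
            continue
        ohs = sorted(
            j for i in r for j, order in m.neighbors(i)
            if j in hydroxyl_o and order == 1
        )
        if ohs:
            out.append(StructureMatch("PHE", tuple(sorted({*r, *ohs}))))

    out.sort(key=lambda s: (s.code, s.atom_indices))
    return out


def _detect_flavin(m, rings, elems) -> list[StructureMatch]:
    six = [r for r in rings if len(r) == 6]
    out = []
    for mid in six:
        mid_set = set(mid)
        mid_n = [i for i in mid if elems[i] == "N"]
        if len(mid_n) != 2:
            continue
        fused = [r for r in six if r != mid and len(mid_set & set(r)) == 2]
        benzo = [r for r in fused if all(elems[i] == "C" for i in r)]
        pyrimidine = []
        for r in fused:
            ring_n = [i for i in r if elems[i] == "N"]
            carbonyl_o = [
                j for i in r for j, order in m.neighbors(i)
                if order == 2 and elems[j] == "O" and j not in r
            ]
            if len(ring_n) == 2 and len(carbonyl_o) >= 2:
                pyrimidine.append((r, carbonyl_o))
        if not benzo or not pyrimidine:
            continue
        ring, oxo = pyrimidine[0]
        consumed = tuple(sorted({*mid, *benzo[0], *ring, *oxo}))
        oxidized = any(
            order == 2
            for i in mid_n
            for _, order in m.neighbors(i)
        )
        out.append(StructureMatch("FLO" if oxidized else "FLR", consumed))
        break  # one flavin core per molecule is enough for this catalog
    return out
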