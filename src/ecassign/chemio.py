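"""Reading and validating compound and reaction structure files.

Compounds arrive as MDL MOL V2000 connection tables, reactions either as
MDL RXN files or as YAML manifests that list substrate/product MOL sources
with stoichiometric multiplicities.  Parsing produces a plain labelled
graph of heavy atoms (element, formal charge, hydrogen count) and typed
bonds; coordinates and stereochemistry are ignored throughout because the
downstream coding scheme is constitution-only.

Hydrogens never survive as graph nodes: explicit hydrogen atoms are folded
into the ``h_count`` of their heavy neighbour, and the remaining valence
deficit is filled with implicit hydrogens from a standard valence table.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace

log = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Bond",
    "Molecule",
    "Reaction",
    "MolParseError",
    "parse_molfile",
    "write_molfile",
    "parse_rxn",
    "parse_manifest",
    "assign_implicit_hydrogens",
    "canonical_key",
    "element_class",
]


class MolParseError(ValueError):
    """Raised for malformed MOL/RXN/manifest input; carries a line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


# ---------------------------------------------------------------------------
# element classes

#: elements with a dedicated neighbour field in the atom coding layout
CORE_ELEMENTS = {"C", "O", "N", "S", "P", "As"}

HALOGENS = {"F", "Cl", "Br", "I", "At"}

# s/d/f blocks plus the post-transition metals Al, Ga, In, Tl, Sn, Pb, Bi
METALS = {
    "Li", "Na", "K", "Rb", "Cs", "Fr", "Be", "Mg", "Ca", "Sr", "Ba", "Ra",
    "Sc", "Ti", "V", "Cr", "Mn", "Fe", "Co", "Ni", "Cu", "Zn",
    "Y", "Zr", "Nb", "Mo", "Tc", "Ru", "Rh", "Pd", "Ag", "Cd",
    "Hf", "Ta", "W", "Re", "Os", "Ir", "Pt", "Au", "Hg",
    "La", "Ce", "Pr", "Nd", "Pm", "Sm", "Eu", "Gd", "Tb", "Dy", "Ho",
    "Er", "Tm", "Yb", "Lu",
    "Ac", "Th", "Pa", "U", "Np", "Pu", "Am", "Cm", "Bk", "Cf", "Es",
    "Fm", "Md", "No", "Lr",
    "Rf", "Db", "Sg", "Bh", "Hs", "Mt",
    "Al", "Ga", "In", "Tl", "Sn", "Pb", "Bi",
}

#: MOL-file pseudo-atom spellings that map straight to the "any rest" class
PSEUDO_REST = {"R", "R#", "A", "*", "Q", "L", "LP"}

_warned_rest: set[str] = set()


def element_class(symbol: str) -> str:
    """Map an element symbol to its coding class.

    C, O, N, S, P and As keep their own symbol; hydrogens are ``H``; any
    metal becomes ``M``, any halogen ``X``; everything else (Se, B, Si,
    pseudo-atoms, ...) collapses to the rest class ``R``.
    """
    if symbol in CORE_ELEMENTS or symbol == "H":
        return symbol
    if symbol in METALS:
        return "M"
    if symbol in HALOGENS:
        return "X"
    if symbol not in PSEUDO_REST and symbol not in _warned_rest:
        _warned_rest.add(symbol)
        log.warning("element %s has no coding slot; treating as rest class R", symbol)
    return "R"


# default valences used to fill implicit hydrogens on H-suppressed input
_DEFAULT_VALENCE = {
    "C": 4, "N": 3, "O": 2, "S": 2, "P": 3, "As": 3, "B": 3, "Si": 4,
}


def _target_valence(element: str, charge: int) -> int:
    if element in HALOGENS:
        return max(0, 1 + charge)
    base = _DEFAULT_VALENCE.get(element)
    if base is None:  # metals, pseudo-atoms: no implicit hydrogens
        return 0
    if element == "C" or element == "Si":
        return max(0, base - abs(charge))
    # N/P/As gain a bond when protonated, O/S lose one when deprotonated
    return max(0, base + charge)


# ---------------------------------------------------------------------------
# data model


@dataclass
class Atom:
    element: str
    formal_charge: int = 0
    h_count: int = 0


@dataclass(frozen=True)
class Bond:
    a: int
    b: int
    order: int  # 1, 2 or 3; aromatic order 4 never survives parsing


@dataclass
class Molecule:
    """Labelled heavy-atom graph for one reaction participant.

    ``free_h``/``free_charge`` carry hydrogens that have no heavy atom to
    attach to (the proton H+ and molecular hydrogen are legal reaction
    participants with an empty heavy graph).
    """

    name: str
    atoms: list[Atom] = field(default_factory=list)
    bonds: list[Bond] = field(default_factory=list)
    source: str = ""
    free_h: int = 0
    free_charge: int = 0

    def __post_init__(self) -> None:
        n = len(self.atoms)
        seen: set[tuple[int, int]] = set()
        for bd in self.bonds:
            if bd.a == bd.b or not (0 <= bd.a < n) or not (0 <= bd.b < n):
                raise MolParseError(
                    f"{self.name}: bond ({bd.a + 1},{bd.b + 1}) references a "
                    f"nonexistent or identical atom (molecule has {n} atoms)"
                )
            key = (min(bd.a, bd.b), max(bd.a, bd.b))
            if key in seen:
                raise MolParseError(f"{self.name}: duplicate bond {key}")
            seen.add(key)

    def neighbors(self, i: int) -> list[tuple[int, int]]:
        """(neighbor index, bond order) pairs for atom ``i``."""
        out = []
        for bd in self.bonds:
            if bd.a == i:
                out.append((bd.b, bd.order))
            elif bd.b == i:
                out.append((bd.a, bd.order))
        return out

    @property
    def num_heavy(self) -> int:
        return len(self.atoms)

    def permuted(self, perm: list[int]) -> "Molecule":
        """Return the same graph with atoms reordered by ``perm``.

        ``perm[new_index] = old_index``; used by permutation-invariance tests.
        """
        inv = {old: new for new, old in enumerate(perm)}
        return Molecule(
            name=self.name,
            atoms=[replace(self.atoms[old]) for old in perm],
            bonds=[Bond(inv[bd.a], inv[bd.b], bd.order) for bd in self.bonds],
            source=self.source,
            free_h=self.free_h,
            free_charge=self.free_charge,
        )


@dataclass
class Reaction:
    substrates: list[Molecule]
    products: list[Molecule]
    assigned_ec: str | None = None
    name: str = ""
    partials: list["Reaction"] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.substrates or not self.products:
            raise MolParseError("reaction must have both sides")

    def reversed(self) -> "Reaction":
        return Reaction(
            substrates=list(self.products),
            products=list(self.substrates),
            assigned_ec=self.assigned_ec,
            name=self.name,
            partials=self.partials,
        )


# ---------------------------------------------------------------------------
# MOL V2000


def parse_molfile(text: str, name: str | None = None, source: str = "") -> Molecule:
    """Parse an MDL MOL V2000 connection table.

    Aromatic (type 4) bonds are kekulized through RDKit when it is
    importable; otherwise they are rejected with an instruction to supply
    kekulized input.  ``M  CHG`` properties take precedence over the
    atom-block charge column.  Explicit hydrogens are folded into their
    heavy neighbour and implicit hydrogens assigned from default valences.
    """
    lines = text.splitlines()
    if len(lines) < 4:
        raise MolParseError("molfile shorter than header + counts line", len(lines))
    header_name = lines[0].strip()
    counts = lines[3]
    if "V3000" in counts:
        raise MolParseError("V3000 connection tables are not supported; "
                            "convert to V2000", 4)
    try:
        natoms = int(counts[0:3])
        nbonds = int(counts[3:6])
    except (ValueError, IndexError):
        raise MolParseError(f"malformed counts line {counts!r}", 4) from None
    if len(lines) < 4 + natoms + nbonds:
        raise MolParseError(
            f"counts line promises {natoms} atoms / {nbonds} bonds but the "
            f"file has only {len(lines) - 4} block lines", 4)

    atoms: list[tuple[str, int]] = []  # (symbol, atom-block charge)
    for i in range(natoms):
        ln = lines[4 + i]
        if len(ln) < 34:
            raise MolParseError(f"atom line too short: {ln!r}", 5 + i)
        sym = ln[31:34].strip()
        if sym in PSEUDO_REST:
            sym = "R"
        try:
            ccode = int(ln[36:39]) if len(ln) >= 39 and ln[36:39].strip() else 0
        except ValueError:
            raise MolParseError(f"bad charge field in {ln!r}", 5 + i) from None
        # MDL charge codes: 1..3 = +3..+1, 5..7 = -1..-3, 4 = radical
        charge = {0: 0, 1: 3, 2: 2, 3: 1, 4: 0, 5: -1, 6: -2, 7: -3}.get(ccode, 0)
        atoms.append((sym, charge))

    bonds: list[tuple[int, int, int]] = []
    aromatic = False
    for i in range(nbonds):
        ln = lines[4 + natoms + i]
        lineno = 5 + natoms + i
        try:
            a = int(ln[0:3])
            b = int(ln[3:6])
            order = int(ln[6:9])
        except (ValueError, IndexError):
            raise MolParseError(f"malformed bond line {ln!r}", lineno) from None
        if a < 1 or b < 1 or a > natoms or b > natoms or a == b:
            raise MolParseError(
                f"bond references atom outside 1..{natoms}: {ln!r}", lineno)
        if order == 4:
            aromatic = True
        elif order not in (1, 2, 3):
            raise MolParseError(f"unsupported bond type {order}", lineno)
        bonds.append((a - 1, b - 1, order))

    # property block: M CHG overrides every atom-block charge
    chg_overrides: dict[int, int] = {}
    has_chg = False
    for j, ln in enumerate(lines[4 + natoms + nbonds:]):
        if ln.startswith("M  CHG"):
            has_chg = True
            try:
                nn = int(ln[6:9])
                for k in range(nn):
                    idx = int(ln[9 + 8 * k: 13 + 8 * k])
                    val = int(ln[13 + 8 * k: 17 + 8 * k])
                    chg_overrides[idx - 1] = val
            except (ValueError, IndexError):
                raise MolParseError(f"malformed M  CHG line {ln!r}",
                                    5 + natoms + nbonds + j) from None
        elif ln.startswith("M  END"):
            break
    if has_chg:
        atoms = [(sym, 0) for sym, _ in atoms]
        for idx, val in chg_overrides.items():
            if idx >= natoms:
                raise MolParseError(f"M  CHG references atom {idx + 1}")
            atoms[idx] = (atoms[idx][0], val)

    if aromatic:
        bonds = _kekulize(text, bonds)

    mol_name = name or header_name or "unnamed"
    mol = _build_heavy_graph(mol_name, atoms, bonds, source)
    return assign_implicit_hydrogens(mol)


def _kekulize(text: str, bonds: list[tuple[int, int, int]]) -> list[tuple[int, int, int]]:
    """Resolve aromatic (type 4) bonds to alternating single/double orders."""
    try:
        from rdkit import Chem
    except ImportError:
        raise MolParseError(
            "aromatic (type 4) bonds present and RDKit is not installed; "
            "supply a kekulized connection table") from None
    rd = Chem.MolFromMolBlock(text, sanitize=True, removeHs=False)
    if rd is None:
        raise MolParseError("RDKit could not sanitize/kekulize the aromatic system")
    Chem.Kekulize(rd, clearAromaticFlags=True)
    out = []
    for bd in rd.GetBonds():
        order = int(bd.GetBondTypeAsDouble())
        out.append((bd.GetBeginAtomIdx(), bd.GetEndAtomIdx(), order))
    return out


def _build_heavy_graph(name, atoms, bonds, source) -> Molecule:
    """Drop explicit hydrogens, folding them into heavy-atom H counts."""
    heavy_idx: dict[int, int] = {}
    heavy_atoms: list[Atom] = []
    explicit_h: dict[int, int] = {}
    free_h = 0
    free_charge = 0
    for i, (sym, chg) in enumerate(atoms):
        if sym == "H" or sym == "D" or sym == "T":
            continue
        heavy_idx[i] = len(heavy_atoms)
        heavy_atoms.append(Atom(element=sym, formal_charge=chg))
    heavy_bonds: list[Bond] = []
    for a, b, order in bonds:
        a_h = atoms[a][0] in ("H", "D", "T")
        b_h = atoms[b][0] in ("H", "D", "T")
        if a_h and b_h:
            free_h += 2
            continue
        if a_h or b_h:
            heavy = heavy_idx[b if a_h else a]
            explicit_h[heavy] = explicit_h.get(heavy, 0) + 1
            continue
        heavy_bonds.append(Bond(heavy_idx[a], heavy_idx[b], order))
    bonded_h = {i for a, b, _ in bonds for i in (a, b)}
    for i, (sym, chg) in enumerate(atoms):
        if sym in ("H", "D", "T"):
            free_charge += chg
            if i not in bonded_h:
                free_h += 1
    for heavy, nh in explicit_h.items():
        heavy_atoms[heavy].h_count = nh
    return Molecule(name=name, atoms=heavy_atoms, bonds=heavy_bonds,
                    source=source, free_h=free_h, free_charge=free_charge)


def assign_implicit_hydrogens(m: Molecule) -> Molecule:
    """Fill each atom's ``h_count`` up to its charge-adjusted default valence.

    Atoms that already carry explicit hydrogens (folded in at parse time)
    keep them; the implicit complement only tops up the difference between
    the valence target and the total bond order sum.  Overflow (more bonds
    than the valence allows, e.g. hypervalent P in a fully drawn phosphate)
    logs nothing alarming and leaves zero implicit hydrogens.
    """
    for i, atom in enumerate(m.atoms):
        order_sum = sum(order for _, order in m.neighbors(i)) + atom.h_count
        target = _target_valence(atom.element, atom.formal_charge)
        implicit = target - order_sum
        if implicit > 0:
            atom.h_count += implicit
        elif implicit < 0 and target > 0:
            log.debug("%s: atom %d (%s) exceeds default valence (%d > %d)",
                      m.name, i, atom.element, order_sum, target)
    return m


def write_molfile(m: Molecule) -> str:
    """Serialize a Molecule back to a (coordinate-free) MOL V2000 block."""
    lines = [m.name, "  ecassign", "", f"{len(m.atoms):3d}{len(m.bonds):3d}"
             "  0  0  0  0  0  0  0  0999 V2000"]
    for atom in m.atoms:
        lines.append(f"    0.0000    0.0000    0.0000 {atom.element:<3s}"
                     "0  0  0  0  0  0  0  0  0  0  0  0")
    for bd in m.bonds:
        lines.append(f"{bd.a + 1:3d}{bd.b + 1:3d}{bd.order:3d}  0")
    charged = [(i + 1, a.formal_charge) for i, a in enumerate(m.atoms)
               if a.formal_charge]
    for i, chg in charged:
        lines.append(f"M  CHG  1{i:4d}{chg:4d}")
    lines.append("M  END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# reactions


def parse_rxn(text: str, name: str | None = None) -> Reaction:
    """Parse an MDL RXN (V2000) file into a Reaction."""
    lines = text.splitlines()
    if not lines or not lines[0].startswith("$RXN"):
        raise MolParseError("missing $RXN header", 1)
    counts = lines[4]
    try:
        nsub = int(counts[0:3])
        nprod = int(counts[3:6])
    except (ValueError, IndexError):
        raise MolParseError(f"malformed RXN counts line {counts!r}", 5) from None
    blocks: list[str] = []
    current: list[str] | None = None
    for ln in lines[5:]:
        if ln.startswith("$MOL"):
            if current is not None:
                blocks.append("\n".join(current))
            current = []
        elif current is not None:
            current.append(ln)
    if current is not None:
        blocks.append("\n".join(current))
    if len(blocks) != nsub + nprod:
        raise MolParseError(
            f"RXN promises {nsub}+{nprod} molecules, found {len(blocks)}")
    mols = [parse_molfile(b, source="rxn") for b in blocks]
    return Reaction(substrates=mols[:nsub], products=mols[nsub:],
                    name=name or lines[1].strip() or "rxn")


def _default_resolver(ref: str) -> str:
    if ref.startswith("fixture:"):
        from . import fixtures
        return fixtures.make_fixture(ref[len("fixture:"):])
    from pathlib import Path
    return Path(ref).read_text()


def parse_manifest(text: str, resolver=None) -> Reaction:
    """Parse a YAML reaction manifest.

    Grammar::

        name: indolelactate_dh          # optional
        ec: "1.1.1.110"                 # optional assigned EC for audit mode
        substrates:
          - {mol: "fixture:nad_plus", count: 1}
          - "path/to/compound.mol"      # shorthand for count 1
        products: [...]
        partials:                       # optional partial reactions
          - {substrates: [...], products: [...]}

    ``mol`` references are resolved through ``resolver`` (default: the
    ``fixture:`` registry, else a filesystem path).  A coefficient
    ``count: n`` expands into n molecule instances before pairing.
    """
    import yaml

    resolver = resolver or _default_resolver
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise MolParseError("manifest must be a YAML mapping")

    def side(key: str) -> list[Molecule]:
        out = []
        for entry in doc.get(key) or []:
            if isinstance(entry, str):
                ref, count = entry, 1
            else:
                ref, count = entry["mol"], int(entry.get("count", 1))
            if count < 1:
                raise MolParseError(f"multiplicity must be >= 1, got {count}")
            mol = parse_molfile(resolver(ref), source=ref)
            out.extend([mol] + [mol.permuted(list(range(mol.num_heavy)))
                                for _ in range(count - 1)])
        return out

    partials = []
    for p in doc.get("partials") or []:
        sub = [parse_molfile(resolver(r if isinstance(r, str) else r["mol"]),
                             source=str(r)) for r in p["substrates"]]
        prod = [parse_molfile(resolver(r if isinstance(r, str) else r["mol"]),
                              source=str(r)) for r in p["products"]]
        partials.append(Reaction(substrates=sub, products=prod,
                                 name=str(doc.get("name", "")) + ".partial"))
    return Reaction(
        substrates=side("substrates"),
        products=side("products"),
        assigned_ec=doc.get("ec"),
        name=str(doc.get("name") or "reaction"),
        partials=partials,
    )


# ---------------------------------------------------------------------------
# canonical compound keys


def canonical_key(m: Molecule, backend: str = "builtin") -> str:
    """Structure key, identical for identical constitutions.

    The builtin backend canonicalizes the heavy graph by iterative
    neighbourhood refinement with deterministic tie splitting, then hashes
    the relabelled atom and edge lists (charges, hydrogen counts and bond
    orders included).  With ``backend='rdkit'`` an InChIKey is produced
    instead; a cofactor table must store keys from the backend it is used
    with.
    """
    if backend == "rdkit":
        from rdkit import Chem
        rd = Chem.MolFromMolBlock(write_molfile(m), sanitize=False)
        Chem.SanitizeMol(rd, Chem.SanitizeFlags.SANITIZE_FINDRADICALS
                         | Chem.SanitizeFlags.SANITIZE_SETCONJUGATION)
        return Chem.MolToInchiKey(rd)
    ranks = _canonical_ranks(m)
    order = sorted(range(len(m.atoms)), key=lambda i: ranks[i])
    pos = {old: new for new, old in enumerate(order)}
    atom_part = ";".join(
        f"{m.atoms[i].element},{m.atoms[i].formal_charge},{m.atoms[i].h_count}"
        for i in order)
    edges = sorted((min(pos[bd.a], pos[bd.b]), max(pos[bd.a], pos[bd.b]), bd.order)
                   for bd in m.bonds)
    edge_part = ";".join(f"{a}-{b}:{o}" for a, b, o in edges)
    payload = f"{atom_part}|{edge_part}|H{m.free_h}|Q{m.free_charge}"
    digest = hashlib.sha256(payload.encode()).hexdigest()[:16]
    formula = _formula(m)
    return f"v1-{formula}-{digest}"


def _formula(m: Molecule) -> str:
    from collections import Counter
    counts = Counter(a.element for a in m.atoms)
    nh = sum(a.h_count for a in m.atoms) + m.free_h
    parts = []
    for el in sorted(counts, key=lambda e: (e != "C", e)):
        parts.append(el + (str(counts[el]) if counts[el] > 1 else ""))
    if nh:
        parts.insert(1 if counts.get("C") else 0, "H" + (str(nh) if nh > 1 else ""))
    return "".join(parts) or "nil"


def _refine(m: Molecule, labels: list[int]) -> list[int]:
    n = len(labels)
    nbrs = [m.neighbors(i) for i in range(n)]
    while True:
        sig = [
            (labels[i], tuple(sorted((order, labels[j]) for j, order in nbrs[i])))
            for i in range(n)
        ]
        ranking = {s: r for r, s in enumerate(sorted(set(sig)))}
        new = [ranking[s] for s in sig]
        if new == labels:
            return new
        labels = new


def _canonical_ranks(m: Molecule) -> list[int]:
    n = len(m.atoms)
    init_sig = [
        (a.element, a.formal_charge, a.h_count,
         tuple(sorted(o for _, o in m.neighbors(i))))
        for i, a in enumerate(m.atoms)
    ]
    ranking = {s: r for r, s in enumerate(sorted(set(init_sig)))}
    labels = _refine(m, [ranking[s] for s in init_sig])

    best: tuple | None = None
    best_labels: list[int] | None = None

    def serialize(lab: list[int]) -> tuple:
        order = sorted(range(n), key=lambda i: lab[i])
        pos = {old: new for new, old in enumerate(order)}
        atoms = tuple((m.atoms[i].element, m.atoms[i].formal_charge,
                       m.atoms[i].h_count) for i in order)
        edges = tuple(sorted((min(pos[bd.a], pos[bd.b]),
                              max(pos[bd.a], pos[bd.b]), bd.order)
                             for bd in m.bonds))
        return (atoms, edges)

    def descend(lab: list[int]) -> None:
        nonlocal best, best_labels
        cells: dict[int, list[int]] = {}
        for i, v in enumerate(lab):
            cells.setdefault(v, []).append(i)
        tied = sorted(v for v, members in cells.items() if len(members) > 1)
        if not tied:
            s = serialize(lab)
            if best is None or s < best:
                best, best_labels = s, lab
            return
        cell = cells[tied[0]]
        for atom in cell:
            forced = list(lab)
            forced[atom] = -1  # split this atom off, then re-refine
            descend(_refine(m, forced))

    descend(labels)
    assert best_labels is not None
    # ranks must be a permutation of 0..n-1
    order = sorted(range(n), key=lambda i: best_labels[i])
    ranks = [0] * n
    for r, i in enumerate(order):
        ranks[i] = r
    return ranks
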