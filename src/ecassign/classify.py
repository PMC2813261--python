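"""Rule lookup from difference keys to EC sub-subclasses, with audit mode.

A classification rule names an EC sub-subclass and the evidence required
to claim it: the cofactor pair class that must have been removed (the
acceptor context, e.g. an NAD(P)+ couple for 1.1.1), minimum counts of
substrate-side and product-side codes in the difference key, and
optionally forbidden codes.  A sub-subclass may own several rules — one
per characteristic difference key.  The shipped rule file is a
demonstration set covering the sub-subclasses exercised by the bundled
reaction fixtures; the YAML format, not the rule content, is the
contract, and users extend it freely.

Audit mode compares the computed candidates with a database-assigned EC
number and sorts every reaction into one of nine consistency categories
(agreement, reversed direction, ambiguous, wrong sub-subclass,
multi-reaction enzyme, unclear, near-duplicate sub-subclasses, no fit,
duplicate assignment of one reaction to several sub-subclasses).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .chemio import Reaction
from .coding import GroupDef, default_catalog
from .diffkey import DifferenceKey, build_difference_key
from .pairing import KnownPairTable, pair_reactants, remove_known_pairs

__all__ = [
    "CATEGORIES",
    "ClassificationRule",
    "RuleSet",
    "RuleLoadError",
    "ClassificationResult",
    "load_rules",
    "match_rules",
    "classify_reaction",
    "audit",
]

#: the nine audit categories, in report order
CATEGORIES = (
    "MATCH",
    "REVERSED",
    "AMBIGUOUS",
    "MISMATCH",
    "MULTI_REACTION",
    "UNCLEAR",
    "SIMILAR_CLASSES",
    "NO_MATCH",
    "DUPLICATE_ASSIGNMENT",
)

_EC_PREFIX = re.compile(r"^(\d+)\.(\d+)\.(\d+)")


class RuleLoadError(ValueError):
    pass


@dataclass(frozen=True)
class ClassificationRule:
    rule_id: str
    sub_subclass: str
    description: str = ""
    pair_classes: tuple[str, ...] = ()  # empty = no acceptor-context gate
    required_s: tuple[tuple[str, int], ...] = ()
    required_p: tuple[tuple[str, int], ...] = ()
    forbidden: tuple[str, ...] = ()
    similar_to: tuple[str, ...] = ()  # near-duplicate sub-subclasses
    non_standard: bool = False

    def matches(self, key: DifferenceKey, ctx: frozenset[str]) -> bool:
        if self.pair_classes and not any(pc in ctx for pc in self.pair_classes):
            return False
        sides = key.side
        for code, minimum in self.required_s:
            if sides["S"].get(code, 0) < minimum:
                return False
        for code, minimum in self.required_p:
            if sides["P"].get(code, 0) < minimum:
                return False
        for code in self.forbidden:
            if sides["S"].get(code, 0) or sides["P"].get(code, 0):
                return False
        return True


@dataclass
class RuleSet:
    rules: list[ClassificationRule]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for r in self.rules:
            if r.rule_id in seen:
                raise RuleLoadError(f"duplicate rule id {r.rule_id!r}")
            seen.add(r.rule_id)
            if not _EC_PREFIX.fullmatch(r.sub_subclass):
                raise RuleLoadError(
                    f"rule {r.rule_id}: sub_subclass {r.sub_subclass!r} is not "
                    "of the form class.subclass.sub-subclass")
            if not (r.required_s or r.required_p):
                raise RuleLoadError(
                    f"rule {r.rule_id}: at least one S/P requirement is needed")

    def similar_pairs(self) -> set[frozenset[str]]:
        out: set[frozenset[str]] = set()
        for r in self.rules:
            for other in r.similar_to:
                out.add(frozenset({r.sub_subclass, other}))
        return out


def load_rules(path: str | Path | None = None) -> RuleSet:
    if path is None:
        text = resources.files("ecassign").joinpath("data/rules.yaml").read_text()
    else:
        text = Path(path).read_text()
    doc = yaml.safe_load(text) or {}
    rules = []
    for rec in doc.get("rules", []):
        try:
            rules.append(ClassificationRule(
                rule_id=str(rec["id"]),
                sub_subclass=str(rec["sub_subclass"]),
                description=rec.get("description", ""),
                pair_classes=tuple(rec.get("pair_classes", ())),
                required_s=tuple(sorted((rec.get("required_s") or {}).items())),
                required_p=tuple(sorted((rec.get("required_p") or {}).items())),
                forbidden=tuple(rec.get("forbidden", ())),
                similar_to=tuple(str(s) for s in rec.get("similar_to", ())),
                non_standard=bool(rec.get("non_standard", False)),
            ))
        except KeyError as exc:
            raise RuleLoadError(f"rule record missing field {exc}: {rec!r}") from None
    return RuleSet(rules=rules)


def match_rules(
    key: DifferenceKey, ctx: frozenset[str], rs: RuleSet
) -> list[ClassificationRule]:
    """All rules whose requirements the key and context satisfy."""
    return [r for r in rs.rules if r.matches(key, ctx)]


@dataclass
class ClassificationResult:
    reaction: str
    candidates: list[str]  # deduplicated, sorted sub-subclasses
    matched_rules: list[str]
    direction: str  # 'forward' or 'reversed'
    category: str
    difference_key: str
    removed: list[tuple[str, tuple[str, ...]]]
    assigned_ec: str | None = None
    all_matched_non_standard: bool = False
    partial_candidates: list[list[str]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "reaction": self.reaction,
            "assigned_ec": self.assigned_ec,
            "candidates": self.candidates,
            "matched_rules": self.matched_rules,
            "direction": self.direction,
            "category": self.category,
            "difference_key": self.difference_key,
            "removed": [
                {"class": cls, "molecules": list(names)}
                for cls, names in self.removed
            ],
        }


def _run_pipeline(r: Reaction, table: KnownPairTable, catalog):
    reduced = remove_known_pairs(r, table)
    pairs, unpaired = pair_reactants(reduced)
    key = build_difference_key(pairs, unpaired, catalog)
    return reduced, key


def classify_reaction(
    r: Reaction,
    rs: RuleSet,
    table: KnownPairTable | None = None,
    catalog: list[GroupDef] | None = None,
) -> ClassificationResult:
    """Classify one reaction to candidate EC sub-subclasses.

    The forward direction is tried first; if no rule matches, the
    reaction is reversed and rematched, and a success there is reported
    with direction 'reversed'.  Outside audit mode the category is simply
    MATCH / AMBIGUOUS / NO_MATCH by candidate count.
    """
    table = table if table is not None else KnownPairTable.load()
    catalog = catalog if catalog is not None else default_catalog()

    reduced, key = _run_pipeline(r, table, catalog)
    matched = match_rules(key, reduced.removed_classes, rs)
    direction = "forward"
    if not matched:
        reduced_rev, key_rev = _run_pipeline(r.reversed(), table, catalog)
        matched_rev = match_rules(key_rev, reduced_rev.removed_classes, rs)
        if matched_rev:
            reduced, key, matched = reduced_rev, key_rev, matched_rev
            direction = "reversed"

    candidates = sorted({m.sub_subclass for m in matched})
    partial_candidates = []
    for part in r.partials:
        pres = classify_reaction(part, rs, table, catalog)
        partial_candidates.append(pres.candidates)

    category = ("NO_MATCH" if not candidates
                else "MATCH" if len(candidates) == 1 else "AMBIGUOUS")
    return ClassificationResult(
        reaction=r.name,
        candidates=candidates,
        matched_rules=sorted(m.rule_id for m in matched),
        direction=direction,
        category=category,
        difference_key=key.rendered,
        removed=reduced.removed,
        assigned_ec=r.assigned_ec,
        all_matched_non_standard=bool(matched) and all(m.non_standard
                                                       for m in matched),
        partial_candidates=partial_candidates,
    )


def ec_prefix(ec: str) -> str:
    m = _EC_PREFIX.match(ec)
    if not m:
        raise ValueError(f"cannot extract sub-subclass prefix from EC {ec!r}")
    return ".".join(m.groups())


def audit(
    res: ClassificationResult,
    rs: RuleSet,
    duplicates: dict[str, set[str]] | None = None,
) -> str:
    """Assign one of the nine consistency categories to an audited result.

    ``duplicates`` maps a rendered difference key to the set of assigned
    sub-subclass prefixes observed for it across the whole audited set;
    when one key carries more than one distinct assignment the reaction's
    classification is not determined by its chemistry alone and every
    involved row is tagged DUPLICATE_ASSIGNMENT.
    """
    if res.assigned_ec is None:
        raise ValueError("audit requires an assigned EC number")
    assigned = ec_prefix(res.assigned_ec)
    duplicates = duplicates or {}

    if len(duplicates.get(res.difference_key, set())) > 1:
        return "DUPLICATE_ASSIGNMENT"
    if res.partial_candidates and any(
        cands and assigned not in cands for cands in res.partial_candidates
    ):
        return "MULTI_REACTION"
    if not res.candidates:
        return "NO_MATCH"
    if res.all_matched_non_standard:
        return "UNCLEAR"
    if assigned in res.candidates:
        if res.direction == "reversed":
            return "REVERSED"
        if len(res.candidates) == 1:
            return "MATCH"
        others = set(res.candidates) - {assigned}
        similar = rs.similar_pairs()
        if all(frozenset({assigned, o}) in similar for o in others):
            return "SIMILAR_CLASSES"
        return "AMBIGUOUS"
    return "MISMATCH"
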