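"""Command-line interface and audit-report rendering.

Subcommands: ``encode`` (print a compound's coding operators, bond codes,
groups and motifs), ``classify`` (JSON classification of one reaction),
``audit`` (consistency report over a reaction panel) and ``fixtures``
(inspect/write the bundled examples).  Exit codes: 0 success, 2 input
error, 3 rule-file error.
"""

from __future__ import annotations

import csv
import io
import json
import logging
import sys
from collections import Counter
from pathlib import Path

import click
import yaml

from . import fixtures as fx
from .chemio import MolParseError, Reaction, parse_manifest, parse_molfile, parse_rxn
from .classify import (
    CATEGORIES,
    ClassificationResult,
    RuleLoadError,
    RuleSet,
    audit as audit_result,
    classify_reaction,
    ec_prefix,
    load_rules,
)
from .coding import (
    atom_code,
    bond_codes,
    detect_functional_groups,
    detect_structures,
    load_group_catalog,
)
from .pairing import KnownPairTable

log = logging.getLogger(__name__)

EXIT_INPUT_ERROR = 2
EXIT_RULE_ERROR = 3


def _read_source(ref: str) -> str:
    if ref.startswith("fixture:"):
        try:
            return fx.make_fixture(ref[len("fixture:"):])
        except KeyError as exc:
            raise MolParseError(str(exc)) from None
    return Path(ref).read_text()


def _load_reaction(ref: str) -> Reaction:
    text = _read_source(ref)
    if text.startswith("$RXN"):
        return parse_rxn(text)
    return parse_manifest(text)


def _load_rules_or_exit(path: str | None) -> RuleSet:
    try:
        return load_rules(path)
    except (RuleLoadError, OSError, yaml.YAMLError) as exc:
        click.echo(f"rule file error: {exc}", err=True)
        sys.exit(EXIT_RULE_ERROR)


@click.group()
@click.option("-v", "--verbose", is_flag=True, help="debug-level logging")
def main(verbose: bool) -> None:
    """Assign enzyme-catalysed reactions to EC sub-subclasses."""
    logging.basicConfig(
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(levelname)s %(name)s: %(message)s",
    )


@main.command()
@click.argument("source")
@click.option("--groups", "groups_path", default=None,
              help="alternative functional-group catalog")
def encode(source: str, groups_path: str | None) -> None:
    """Print atom codes, bond codes, groups and motifs of one compound.

    SOURCE is a MOL file path or a fixture reference (fixture:NAME).
    """
    try:
        mol = parse_molfile(_read_source(source))
        catalog = load_group_catalog(groups_path)
    except (MolParseError, OSError) as exc:
        click.echo(f"input error: {exc}", err=True)
        sys.exit(EXIT_INPUT_ERROR)
    for i in range(mol.num_heavy):
        click.echo(f"atom {i + 1:3d} {atom_code(mol, i)}")
    for code, n in sorted(bond_codes(mol).items()):
        click.echo(f"bond      {code} x{n}")
    motifs = detect_structures(mol)
    masked = frozenset(i for s in motifs for i in s.atom_indices)
    for s in motifs:
        click.echo(f"motif     {s.code} atoms={','.join(str(a + 1) for a in s.atom_indices)}")
    for g in detect_functional_groups(mol, catalog, masked=masked):
        click.echo(f"group     {g.code} atoms={','.join(str(a + 1) for a in g.atom_indices)}")


@main.command("classify")
@click.argument("reaction")
@click.option("--rules", "rules_path", default=None, help="rule file (YAML)")
@click.option("--cofactors", "cofactors_path", default=None,
              help="known-pair table (YAML)")
def classify_cmd(reaction: str, rules_path: str | None,
                 cofactors_path: str | None) -> None:
    """Classify one reaction (manifest/RXN path or fixture:NAME) to JSON."""
    rs = _load_rules_or_exit(rules_path)
    try:
        rxn = _load_reaction(reaction)
        table = KnownPairTable.load(cofactors_path)
    except (MolParseError, OSError, KeyError, yaml.YAMLError) as exc:
        click.echo(f"input error: {exc}", err=True)
        sys.exit(EXIT_INPUT_ERROR)
    res = classify_reaction(rxn, rs, table)
    click.echo(json.dumps(res.to_dict(), indent=2))


def run_audit(panel_text: str, rs: RuleSet,
              table: KnownPairTable) -> tuple[list[ClassificationResult], Counter]:
    """Classify and audit every reaction of a panel.

    The panel is a YAML mapping with a ``reactions`` list; entries are
    manifest references or ``{manifest: ref, ec: override}`` mappings.
    Returns per-reaction results (category already assigned) and the
    category summary in report order.
    """
    doc = yaml.safe_load(panel_text) or {}
    entries = doc.get("reactions") or []
    results: list[ClassificationResult] = []
    for entry in entries:
        if isinstance(entry, str):
            ref, ec_override = entry, None
        else:
            ref, ec_override = entry["manifest"], entry.get("ec")
        rxn = _load_reaction(ref)
        if ec_override:
            rxn.assigned_ec = ec_override
        if rxn.assigned_ec is None:
            raise MolParseError(f"audit requires an assigned EC ({ref})")
        results.append(classify_reaction(rxn, rs, table))

    # one difference key carrying >1 distinct assigned sub-subclass marks
    # every involved row as a duplicate assignment
    duplicates: dict[str, set[str]] = {}
    for res in results:
        duplicates.setdefault(res.difference_key, set()).add(
            ec_prefix(res.assigned_ec))
    for res in results:
        res.category = audit_result(res, rs, duplicates)
    summary = Counter({cat: 0 for cat in CATEGORIES})
    summary.update(res.category for res in results)
    return results, summary


def report_tsv(results: list[ClassificationResult]) -> str:
    buf = io.StringIO()
    w = csv.writer(buf, delimiter="\t", lineterminator="\n")
    w.writerow(["reaction", "assigned_ec", "candidates", "direction",
                "category", "difference_key", "removed_pairs"])
    for r in results:
        w.writerow([
            r.reaction,
            r.assigned_ec or "",
            ";".join(r.candidates),
            r.direction,
            r.category,
            r.difference_key,
            ";".join(f"{cls}({'+'.join(names)})" for cls, names in r.removed),
        ])
    return buf.getvalue()


def report_json(results: list[ClassificationResult], summary: Counter) -> str:
    return json.dumps(
        {
            "rows": [r.to_dict() for r in results],
            "summary": {cat: summary.get(cat, 0) for cat in CATEGORIES},
        },
        indent=2,
    )


@main.command("audit")
@click.argument("panel")
@click.option("--rules", "rules_path", default=None, help="rule file (YAML)")
@click.option("--cofactors", "cofactors_path", default=None)
@click.option("--tsv", "tsv_path", default=None, help="write TSV report here")
@click.option("--json", "json_path", default=None, help="write JSON report here")
def audit_cmd(panel: str, rules_path: str | None, cofactors_path: str | None,
              tsv_path: str | None, json_path: str | None) -> None:
    """Audit a panel of reactions with assigned EC numbers.

    PANEL is a YAML file (or fixture:panel) listing reaction manifests.
    """
    rs = _load_rules_or_exit(rules_path)
    try:
        text = _read_source(panel)
        table = KnownPairTable.load(cofactors_path)
        results, summary = run_audit(text, rs, table)
    except (MolParseError, OSError, KeyError, yaml.YAMLError, ValueError) as exc:
        click.echo(f"input error: {exc}", err=True)
        sys.exit(EXIT_INPUT_ERROR)
    if tsv_path:
        Path(tsv_path).write_text(report_tsv(results))
    if json_path:
        Path(json_path).write_text(report_json(results, summary))
    for r in results:
        log.info("stage=audit reaction=%s category=%s candidates=%s",
                 r.reaction, r.category, ",".join(r.candidates) or "-")
    click.echo(report_tsv(results), nl=False)
    click.echo("---")
    for cat in CATEGORIES:
        click.echo(f"{cat}\t{summary.get(cat, 0)}")


@main.group("fixtures")
def fixtures_group() -> None:
    """Inspect or export the bundled example compounds and reactions."""


@fixtures_group.command("list")
def fixtures_list() -> None:
    reg = fx.list_fixtures()
    for kind, names in reg.items():
        for n in names:
            click.echo(f"{kind[:-1]}\t{n}")


@fixtures_group.command("write")
@click.argument("name")
@click.option("-o", "--outdir", default=".", help="output directory")
def fixtures_write(name: str, outdir: str) -> None:
    try:
        text = fx.make_fixture(name)
    except KeyError as exc:
        click.echo(f"input error: {exc}", err=True)
        sys.exit(EXIT_INPUT_ERROR)
    suffix = ".mol" if name in fx.COMPOUNDS else ".yaml"
    path = Path(outdir) / f"{name}{suffix}"
    path.write_text(text)
    click.echo(str(path))


if __name__ == "__main__":
    main()
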