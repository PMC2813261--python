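"""Registry of example compounds and reactions.

Every fixture is generated deterministically in memory — identical name,
identical bytes — so tests and demonstrations need no external data.
Compounds are kekulized MOL V2000 blocks; reactions are YAML manifests
whose ``mol`` references point back into this registry.  Several large
metabolites (the UDP-N-acetylmuramate pair, the sterol substrate of the
14-demethylase) are represented by synthetic truncations of the reacting
substructure; their names carry a ``_frag`` suffix or the manifest says
so explicitly.
"""

from __future__ import annotations

from textwrap import dedent

from ._molblocks import MOLBLOCKS
from .chemio import Atom, Bond, Molecule, write_molfile

__all__ = ["make_fixture", "list_fixtures", "COMPOUNDS", "REACTIONS"]

# a proton: one hydrogen, charge +1, no heavy atoms
_HYDRON = """\
hydron
  ecassign

  1  0  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
M  CHG  1   1   1
M  END
"""


def _porphine_iron(charge: int) -> str:
    """Synthetic heme-core fixture: four pyrrole rings around an iron.

    A stylized porphyrin — four 5-membered N-heterocycles whose nitrogens
    all bind one central Fe, rings joined by methine bridges.  Bond orders
    are idealized (two double bonds per pyrrole); the fixture exists to
    exercise heme/cytochrome motif perception, not to model a real
    protoporphyrin IX.
    """
    atoms = [Atom("Fe", formal_charge=charge)]
    bonds = []
    ring_alpha: list[tuple[int, int]] = []  # (first alpha C, last alpha C)
    for _ in range(4):
        base = len(atoms)
        # N, Ca1, Cb1, Cb2, Ca2
        atoms += [Atom("N"), Atom("C"), Atom("C"), Atom("C"), Atom("C")]
        bonds += [
            Bond(base, base + 1, 1),      # N-Ca1
            Bond(base + 1, base + 2, 2),  # Ca1=Cb1
            Bond(base + 2, base + 3, 1),  # Cb1-Cb2
            Bond(base + 3, base + 4, 2),  # Cb2=Ca2
            Bond(base + 4, base, 1),      # Ca2-N
            Bond(0, base, 1),             # Fe-N
        ]
        ring_alpha.append((base + 1, base + 4))
    for i in range(4):
        bridge = len(atoms)
        atoms.append(Atom("C"))
        bonds.append(Bond(ring_alpha[i][1], bridge, 1))
        bonds.append(Bond(bridge, ring_alpha[(i + 1) % 4][0], 1))
    name = "heme_ox" if charge >= 3 else "heme_red"
    mol = Molecule(name=name, atoms=atoms, bonds=bonds, source="fixture")
    return write_molfile(mol)


COMPOUNDS: dict[str, str] = dict(MOLBLOCKS)
COMPOUNDS["hydron"] = _HYDRON
COMPOUNDS["heme_ox"] = _porphine_iron(3)
COMPOUNDS["heme_red"] = _porphine_iron(2)


def _manifest(text: str) -> str:
    return dedent(text).lstrip()


REACTIONS: dict[str, str] = {
    # the oxidoreductase worked end-to-end: (indol-3-yl)lactate + NAD+ ->
    # (indol-3-yl)pyruvate + NADH + H+ (indolelactate dehydrogenase)
    "indolelactate_dh": _manifest("""
        name: indolelactate_dh
        ec: "1.1.1.110"
        substrates:
          - fixture:indol3yl_lactate
          - fixture:nad_plus
        products:
          - fixture:indol3yl_pyruvate
          - fixture:nadh
          - fixture:hydron
    """),
    "alcohol_dh": _manifest("""
        name: alcohol_dh
        ec: "1.1.1.1"
        substrates:
          - fixture:ethanol
          - fixture:nad_plus
        products:
          - fixture:acetaldehyde
          - fixture:nadh
          - fixture:hydron
    """),
    # listed in the direction opposite to its EC sense (arsenate reductase)
    "arsenate_reductase": _manifest("""
        name: arsenate_reductase
        ec: "1.20.4.1"
        substrates:
          - fixture:arsenate
          - {mol: "fixture:glutathione", count: 2}
        products:
          - fixture:arsenite
          - fixture:glutathione_disulfide
          - fixture:water
    """),
    # assigned 1.1.1 but the chemistry is a CH-CH dehydrogenation (1.3.1);
    # structures truncated to the reacting lactyl/enolpyruvyl ether fragment
    "udp_murnac_dh": _manifest("""
        name: udp_murnac_dh
        ec: "1.1.1.158"
        substrates:
          - fixture:lactyl_ether_frag
          - fixture:nadp_plus
        products:
          - fixture:enolpyruvyl_ether_frag
          - fixture:nadph
          - fixture:hydron
    """),
    # fits both 1.1.1 (CH-OH donor) and 1.2.1 (aldehyde donor)
    "pyridoxal_dh": _manifest("""
        name: pyridoxal_dh
        ec: "1.1.1.107"
        substrates:
          - fixture:pyridoxal
          - fixture:nad_plus
        products:
          - fixture:pyridoxolactone
          - fixture:nadh
          - fixture:hydron
    """),
    # oxidative demethylation with paired donors; the sterol is truncated
    # to a branched-alkane stand-in for the C14 methyl environment
    "sterol_demethylase": _manifest("""
        name: sterol_demethylase
        ec: "1.14.13.70"
        substrates:
          - fixture:methylbutane
          - {mol: "fixture:oxygen", count: 2}
          - fixture:nadph
          - fixture:hydron
        products:
          - fixture:butene
          - fixture:formate
          - {mol: "fixture:water", count: 2}
          - fixture:nadp_plus
    """),
    # donor has no CH-NH group: fits no defined sub-subclass
    "trimethylamine_dh": _manifest("""
        name: trimethylamine_dh
        ec: "1.5.8.2"
        substrates:
          - fixture:trimethylamine
          - fixture:water
          - fixture:lumiflavin
        products:
          - fixture:dimethylamine
          - fixture:formaldehyde
          - fixture:lumiflavin_red
    """),
    # bifunctional: the overall reaction hides a CH-OH step (1.1.3) and an
    # aldehyde step (1.2.3); the partial reactions make that auditable
    "choline_oxidase": _manifest("""
        name: choline_oxidase
        ec: "1.1.3.17"
        substrates:
          - fixture:choline
          - {mol: "fixture:oxygen", count: 2}
          - fixture:water
        products:
          - fixture:betaine
          - {mol: "fixture:hydrogen_peroxide", count: 2}
        partials:
          - substrates: ["fixture:choline", "fixture:oxygen"]
            products: ["fixture:betaine_aldehyde", "fixture:hydrogen_peroxide"]
          - substrates: ["fixture:betaine_aldehyde", "fixture:oxygen", "fixture:water"]
            products: ["fixture:betaine", "fixture:hydrogen_peroxide"]
    """),
    # diphenol donor whose carboxyl closes a new lactone ring: assigned to
    # 1.10.3 although the usual hydroxyl oxidation does not happen
    # (stylized stand-in reaction, not mass-balanced in oxygen)
    "ring_forming_oxidase": _manifest("""
        name: ring_forming_oxidase
        ec: "1.10.3"
        substrates:
          - fixture:dihydroxyphenylacetate
          - fixture:oxygen
        products:
          - fixture:hydroxybenzofuranone
          - fixture:hydrogen_peroxide
    """),
    "fumarate_hydratase": _manifest("""
        name: fumarate_hydratase
        ec: "4.2.1.2"
        substrates:
          - fixture:malate
        products:
          - fixture:fumarate
          - fixture:water
    """),
    # one reaction, two assigned EC numbers (ATPase vs myosin ATPase); the
    # audit panel lists it under both
    "atp_hydrolysis": _manifest("""
        name: atp_hydrolysis
        ec: "3.6.1.3"
        substrates:
          - fixture:atp
          - fixture:water
        products:
          - fixture:adp
          - fixture:phosphate
    """),
}

# audit panel exercising all nine consistency categories
PANEL = _manifest("""
    reactions:
      - fixture:indolelactate_dh
      - fixture:alcohol_dh
      - fixture:arsenate_reductase
      - fixture:udp_murnac_dh
      - fixture:pyridoxal_dh
      - fixture:sterol_demethylase
      - fixture:trimethylamine_dh
      - fixture:choline_oxidase
      - fixture:ring_forming_oxidase
      - fixture:fumarate_hydratase
      - {manifest: "fixture:atp_hydrolysis", ec: "3.6.1.3"}
      - {manifest: "fixture:atp_hydrolysis", ec: "3.6.4.1"}
""")


def list_fixtures() -> dict[str, list[str]]:
    return {
        "compounds": sorted(COMPOUNDS),
        "reactions": sorted(REACTIONS),
        "panels": ["panel"],
    }


def make_fixture(name: str) -> str:
    """MOL, reaction-manifest or panel text for a registered fixture name."""
    if name in COMPOUNDS:
        return COMPOUNDS[name]
    if name in REACTIONS:
        return REACTIONS[name]
    if name == "panel":
        return PANEL
    known = ", ".join(sorted([*COMPOUNDS, *REACTIONS, "panel"]))
    raise KeyError(f"unknown fixture {name!r}; known fixtures: {known}")
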