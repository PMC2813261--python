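# Functional-group catalog.
#
# Each group is a conjunction of atom coding-operator patterns joined by
# adjacency constraints (indices into `atoms`).  The `operator` string is
# the literal coding operator of the idealized atom; `wildcards` lists
# element fields ignored during matching (where the generic definition
# allows arbitrary attachment through carbon or any rest); `at_least`
# replaces a field's exact digits by a minimum summed count.
#
# The carboxylic-acid record keeps the two published operator strings
# verbatim (carboxyl carbon CO=O and hydroxyl oxygen OH-C); the third
# pattern claims the carbonyl oxygen so that a matched acid consumes its
# whole atom set.  Alcohol code A1 deliberately covers every carbinol
# carbon that still bears at least one hydrogen (the CH-OH donor group of
# EC 1.1.1), not only primary alcohols in the strict nomenclature sense:
# that is how the code is applied to (indol-3-yl)lactate in the worked
# oxidoreductase example, whose reacting hydroxyl sits on a carbon that
# also carries the carboxyl group.  Tertiary carbinols get A3.
groups:
  - code: CA
    name: carboxylic acid
    atoms:
      - operator: "C00011000000000000000000000000"   # CO=O
        wildcards: [C, R]
      - operator: "O10000010000000000000000000000"   # OH-C
      - operator: "O01000000000000000000000000000"   # carbonyl O
    adjacency: [[0, 1], [0, 2]]

  - code: ES
    name: ester (incl. lactone)
    atoms:
      - operator: "C00011000000000000000000000000"
        wildcards: [C, R]
      - operator: "O20000000000000000000000000000"   # bridging O
      - operator: "O01000000000000000000000000000"
    adjacency: [[0, 1], [0, 2]]

  - code: A1
    name: alcohol (carbinol carbon bearing H)
    atoms:
      - operator: "O10000010000000000000000000000"   # hydroxyl O
      - operator: "C00010010000000000000000000000"
        wildcards: [C, R]
        at_least: {H: 1}
    adjacency: [[0, 1]]

  - code: A3
    name: tertiary alcohol
    atoms:
      - operator: "O10000010000000000000000000000"
      - operator: "C30010000000000000000000000000"
    adjacency: [[0, 1]]

  - code: AL
    name: aldehyde
    atoms:
      - operator: "C10001010000000000000000000000"
        wildcards: [C, R]
      - operator: "O01000000000000000000000000000"
    adjacency: [[0, 1]]

  - code: K
    name: ketone
    atoms:
      - operator: "C20001000000000000000000000000"
        wildcards: [R]
      - operator: "O01000000000000000000000000000"
    adjacency: [[0, 1]]

  - code: AMD
    name: amide
    atoms:
      - operator: "C10001001000000000000000000000"
        wildcards: [C, R]
      - operator: "O01000000000000000000000000000"
    adjacency: [[0, 1]]

  - code: AM1
    name: primary amine
    atoms:
      - operator: "N10000020000000000000000000000"
        wildcards: [R]

  - code: AM2
    name: secondary amine
    atoms:
      - operator: "N20000010000000000000000000000"
        wildcards: [R]

  - code: AM3
    name: tertiary amine
    atoms:
      - operator: "N30000000000000000000000000000"
        wildcards: [R]

  - code: TH
    name: thiol
    atoms:
      - operator: "S10000010000000000000000000000"
        wildcards: [R]

  - code: PO
    name: phosphate/phosphoryl group
    atoms:
      - operator: "P00031000000000000000000000000"

  - code: ETH
    name: ether oxygen
    atoms:
      - operator: "O20000000000000000000000000000"
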