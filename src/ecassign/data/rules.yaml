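# Demonstration classification rules.
#
# Each rule maps a difference-key signature plus a removed-cofactor
# context to one EC sub-subclass.  `pair_classes` lists acceptor contexts
# of which at least one must have been removed from the reaction
# (omitted = no context gate); `required_s` / `required_p` give minimum
# counts of codes on the substrate / product side of the difference key;
# `forbidden` codes must appear on neither side.  A sub-subclass may own
# several rules, one per characteristic key.  `similar_to` marks
# sub-subclasses so alike that a joint hit is reported as near-duplicate
# rather than truly ambiguous; `non_standard: true` flags rules encoding
# reactions that sit in a sub-subclass without following its usual
# pattern (audited hits through such rules are reported as unclear).
#
# Descriptions paraphrase the NC-IUBMB sub-subclass definitions.
rules:
  - id: 1.1.1.choh-k
    sub_subclass: "1.1.1"
    description: "CH-OH group of donors oxidized to a ketone, NAD(P)+ acceptor"
    pair_classes: [NAD_REDOX, NADP_REDOX]
    required_s: {A1: 1}
    required_p: {K: 1}

  - id: 1.1.1.choh-al
    sub_subclass: "1.1.1"
    description: "CH-OH group of donors oxidized to an aldehyde, NAD(P)+ acceptor"
    pair_classes: [NAD_REDOX, NADP_REDOX]
    required_s: {A1: 1}
    required_p: {AL: 1}

  - id: 1.1.1.choh-es
    sub_subclass: "1.1.1"
    description: "CH-OH group of donors oxidized into a lactone/ester, NAD(P)+ acceptor"
    pair_classes: [NAD_REDOX, NADP_REDOX]
    required_s: {A1: 1}
    required_p: {ES: 1}

  - id: 1.2.1.al-ca
    sub_subclass: "1.2.1"
    description: "aldehyde or oxo group of donors oxidized to an acid, NAD(P)+ acceptor"
    pair_classes: [NAD_REDOX, NADP_REDOX]
    required_s: {AL: 1}
    required_p: {CA: 1}

  - id: 1.2.1.al-es
    sub_subclass: "1.2.1"
    description: "aldehyde or oxo group of donors oxidized into a lactone/ester, NAD(P)+ acceptor"
    pair_classes: [NAD_REDOX, NADP_REDOX]
    required_s: {AL: 1}
    required_p: {ES: 1}

  - id: 1.3.1.chch
    sub_subclass: "1.3.1"
    description: "CH-CH group of donors dehydrogenated to C=C, NAD(P)+ acceptor"
    pair_classes: [NAD_REDOX, NADP_REDOX]
    required_s: {"C-C": 1}
    required_p: {"C=C": 1}
    forbidden: [A1, AL, "O=O"]

  - id: 1.1.3.choh-o2
    sub_subclass: "1.1.3"
    description: "CH-OH group of donors, oxygen as acceptor"
    pair_classes: [O2_H2O2]
    required_s: {A1: 1}

  - id: 1.2.3.al-o2
    sub_subclass: "1.2.3"
    description: "aldehyde or oxo group of donors, oxygen as acceptor"
    pair_classes: [O2_H2O2]
    required_s: {AL: 1}

  - id: 1.5.8.chnh-flavin
    sub_subclass: "1.5.8"
    description: "CH-NH group of donors, flavin as acceptor"
    pair_classes: [FLAVIN_REDOX]
    required_s: {AM2: 1}

  - id: 1.10.3.ring-forming
    sub_subclass: "1.10.3"
    description: >-
      diphenol donor with oxygen as acceptor, atypical outcome: the
      carboxyl group closes onto a ring carbon so that a new lactone ring
      is formed instead of the usual hydroxyl oxidation
    pair_classes: [O2_H2O2]
    required_s: {CA: 1}
    required_p: {ES: 1}
    non_standard: true

  - id: 1.14.13.paired-o2
    sub_subclass: "1.14.13"
    description: >-
      paired donors with incorporation or reduction of molecular oxygen,
      NAD(P)H as one donor, incorporation of one atom of oxygen
    pair_classes: [NAD_REDOX, NADP_REDOX]
    required_s: {"O=O": 1}
    similar_to: ["1.14.21"]

  - id: 1.14.21.paired-o2
    sub_subclass: "1.14.21"
    description: >-
      paired donors with incorporation or reduction of molecular oxygen,
      NAD(P)H as one donor, the other donor dehydrogenated
    pair_classes: [NAD_REDOX, NADP_REDOX]
    required_s: {"O=O": 1}
    similar_to: ["1.14.13"]

  - id: 1.20.4.as-disulfide
    sub_subclass: "1.20.4"
    description: "arsenic (or phosphorus) in donors oxidized, disulfide as acceptor"
    pair_classes: [GSSG_GSH]
    required_p: {"As=O": 1}

  - id: 4.2.1.dehydratase
    sub_subclass: "4.2.1"
    description: "hydro-lyase: breakage of a carbon-oxygen bond forming C=C"
    required_s: {A1: 1, "C-C": 1}
    required_p: {"C=C": 1}
    forbidden: [AL, ES, K, "O=O"]

  - id: 3.6.1.anhydride
    sub_subclass: "3.6.1"
    description: "hydrolysis of a phosphoanhydride (acting on acid anhydrides)"
    required_s: {PO: 1, "O-P": 1}
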