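# ecassign

Rule-based assignment of enzyme-catalysed reactions to EC sub-subclasses
from chemical structure files, with an audit mode for checking existing
EC annotations.

The EC number (class.subclass.sub-subclass.serial, maintained by the
NC-IUBMB) is the standard functional identifier for enzymes, and the
first three levels are determined by the chemistry of the catalysed
reaction: the donor group transformed and the acceptor used. `ecassign`
recovers that chemistry directly from the structures of the substrates
and products and maps it to candidate sub-subclasses. It is aimed at
people curating reaction databases, reconstructing metabolic networks,
or quality-controlling EC annotations, who need a transparent,
deterministic, editable classifier rather than a trained model.

## Method

For a reaction with substrate set *S* and product set *P*:

1. **Atom and bond coding.** Every heavy atom is encoded as a
   fixed-layout *coding operator*: the element symbol followed by 29
   slots, `CCC OOO H NNN SSS PPP RRR AsAsAs MMM XXX c`, where each
   three-slot field counts neighbours of that element class connected by
   a single, double or triple bond, `H` is the hydrogen count and `c`
   the formal charge. The methane carbon codes as
   `C00000040000000000000000000000`. Every heavy-atom bond is coded as
   `A-B`, `A=B` or `A#B`. The bag of these tokens is the molecule's
   *type multiset*.
2. **Known-pair removal.** Recurring cofactor couples (NAD⁺/NADH,
   NADP⁺/NADPH, O₂/H₂O₂, GSSG/GSH, ...) and ubiquitous species (H⁺,
   H₂O, phosphate), identified by canonical compound key, are removed
   first; the removed pair classes become the *acceptor context* of the
   reaction.
3. **Pairing.** Remaining substrates and products are paired one-to-one,
   most similar first, by the Tanimoto coefficient
   *T = a / (a + b + c)* over type multisets, where *a* counts token
   types with equal frequency on both sides, *b* types more frequent in
   the substrate and *c* types more frequent in the product
   (*T* = 1 for identical, 0 for token-disjoint molecules).
4. **Difference key.** Each pair is compared motif → functional group →
   bond → atom (matched groups/motifs mask their atoms and internal
   bonds from lower levels); equal counts cancel, and the surviving
   side-tagged types render canonically, e.g. `S:A1|P:K` — an alcohol
   (A1) lost, a ketone (K) gained.
5. **Rule lookup.** An editable YAML rule table maps difference-key
   signatures plus acceptor context to sub-subclasses (`S:A1 / P:K`
   with an NAD(P)⁺ couple removed ⇒ 1.1.1). If nothing matches, the
   reversed reaction is tried.
6. **Audit.** Against an assigned EC number each reaction falls into one
   of nine consistency categories: MATCH, REVERSED, AMBIGUOUS, MISMATCH,
   MULTI_REACTION, UNCLEAR, SIMILAR_CLASSES, NO_MATCH,
   DUPLICATE_ASSIGNMENT.

Inputs are MDL MOL V2000 connection tables, MDL RXN files, or YAML
reaction manifests; a registry of example compounds and reactions is
bundled (`ecassign fixtures list`).

## Worked example

The reaction catalysed by indolelactate dehydrogenase (EC 1.1.1.110),
(indol-3-yl)lactate + NAD⁺ → (indol-3-yl)pyruvate + NADH + H⁺:

```sh
$ ecassign classify fixture:indolelactate_dh
{
  "reaction": "indolelactate_dh",
  "assigned_ec": "1.1.1.110",
  "candidates": [
    "1.1.1"
  ],
  "matched_rules": [
    "1.1.1.choh-k"
  ],
  "direction": "forward",
  "category": "MATCH",
  "difference_key": "S:A1|P:K",
  "removed": [
    {
      "class": "NAD_REDOX",
      "molecules": [
        "nad_plus",
        "nadh"
      ]
    },
    {
      "class": "UBIQUITOUS",
      "molecules": [
        "hydron"
      ]
    }
  ]
}
```

Reading the output: the NAD⁺/NADH couple and the proton were removed as
known pairs, the two indole compounds paired as most similar, the
difference key says the substrate side lost a CH-OH group (`A1`) and the
product side gained a ketone (`K`), and with an NAD couple as acceptor
context that signature is the rule for sub-subclass 1.1.1 ("acting on
the CH-OH group of donors, with NAD⁺ or NADP⁺ as acceptor") — matching
the assigned EC number.

The audit panel over the twelve bundled case reactions
(`ecassign audit fixture:panel`) populates all nine categories,
including the reaction listed in the reverse of its EC sense (arsenate
reductase), a wrongly assigned reaction re-classified to 1.3.1
(UDP-N-acetylmuramate dehydrogenase), and ATP hydrolysis audited under
two different EC numbers.

## Extending

The classification knowledge lives in three editable YAML files shipped
under `src/ecassign/data/`: `groups.yaml` (functional-group patterns as
coding-operator conjunctions), `cofactors.yaml` (known pairs and
ubiquitous species, keyed by canonical structure key) and `rules.yaml`
(difference-key signatures per sub-subclass). All three can be replaced
on the command line (`--groups`, `--cofactors`, `--rules`). The shipped
rule set is a demonstration covering the sub-subclasses exercised by the
bundled fixtures; the file format, not the rule content, is the stable
contract.
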