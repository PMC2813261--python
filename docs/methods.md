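# Methods

This note records what `ecassign` computes, the choices made where the
design was genuinely open, and what the bundled examples do and do not
demonstrate.

## The model

An enzyme-catalysed reaction is treated as a pair of molecule multisets
(substrates, products). The classifier assumes the EC sub-subclass is a
function of (i) the cofactor couple consumed, and (ii) the net change in
typed chemical features between the matched substrate/product pairs. No
atom-atom mapping is attempted: all comparisons are at the level of type
counts, which is what makes the method fast, transparent and editable,
and which also bounds what it can express (two reactions with identical
type-level changes are indistinguishable, the root cause of the
DUPLICATE_ASSIGNMENT audit category).

### Atom coding operators

Each heavy atom is rendered as its element symbol plus 29 character
slots (`CCC OOO H NNN SSS PPP RRR AsAsAs MMM XXX c`): per element-class
field, counts of neighbours bound by single/double/triple bonds; one
hydrogen slot (hydrogen only forms single bonds); a charge character
('0'–'9' = 0…+9). The layout has named fields only for C, O, H, N, S, P
and As; metals collapse to class M, halogens to X, and everything else
(Se, B, Si, pseudo-atoms) to the rest class R with a logged warning.
Negative charges, which the published layout never shows, are encoded
'a'–'i' = −1…−9 so that non-negative codes reproduce the published
strings byte-exactly. A neighbour count above 9 raises an error rather
than saturating — a silently capped digit would corrupt every frequency
comparison downstream. Constitution only: coordinates and
stereochemistry are ignored throughout.

### Hydrogen assignment

Input connection tables are hydrogen-suppressed or mixed. Explicit
hydrogen atoms are folded into their heavy neighbour's count, then
implicit hydrogens top up to a charge-adjusted default valence
(C 4−|q|; N/P/As 3+q; O/S 2+q; halogens 1+q; metals 0). Atoms whose
drawn bonds already exceed the target (hypervalent P in a fully drawn
phosphate, coordinated N in the heme fixture) simply get zero implicit
hydrogens. A proton participant is a zero-heavy-atom species carried by
molecule-level free-H/charge fields and handled by the ubiquitous
species list, never by the coding layer.

### Canonical compound keys

Cofactor lookup needs a key identical for identical structures and
stable under atom reordering. The builtin backend canonicalizes the
heavy graph by iterative neighbourhood refinement with deterministic
tie-splitting (branch over the first tied cell, keep the
lexicographically smallest serialization) and hashes the relabelled
atom/edge lists; the key embeds the molecular formula for readability.
An InChIKey backend (RDKit) is available; a cofactor table must store
keys from the backend it is used with, and the shipped table stores
builtin keys. Keys are computed on the kekulized graph, so two different
kekulé drawings of the same aromatic system get different keys; the
shipped fixtures are internally consistent, but user-supplied cofactor
structures should be standardized the same way the table entries were.

### Functional groups and motifs

A functional group is a conjunction of coding-operator patterns on
adjacent atoms — no SMARTS engine. A pattern is the literal operator of
the idealized atom with selected fields wildcarded (where the generic
definition allows arbitrary attachment) or replaced by a minimum count
(the alcohol carbon requires ≥1 H). The carboxylic-acid group ships with
the two published operators verbatim plus a third pattern claiming the
carbonyl oxygen, so that a matched group consumes its complete atom set.

The alcohol code A1 deliberately means "carbinol carbon still bearing a
hydrogen" — the CH-OH donor of sub-subclass 1.1.1 — rather than
"primary alcohol" in the strict nomenclature sense, matching how the
code is applied in the published worked example to (indol-3-yl)lactate
(a secondary alcohol); a separate secondary-alcohol code would
double-match that example and break its printed key. Tertiary carbinols
get A3. Within one group code an atom serves at most one match
(candidates consumed in ascending atom-index order, so the match
multiset is permutation-stable); different group codes may overlap (an
ester's bridging oxygen also matches ETH), which is harmless because
rules use minimum counts.

Structural motifs sit above groups and are perceived in code on top of
ring perception (smallest set of smallest rings via a minimum cycle
basis; ties broken by ring size, atom-index sum, then lexicographic
order): heme (four 5-membered N-heterocycles sharing a central iron)
with cytochrome redox state from the iron charge (+3 CYO / +2 CYR);
iron-sulfur clusters (connected Fe/S subgraph, ≥2 Fe and ≥2 S; ISR only
when every iron is ≤ +2, otherwise ISO); flavins (6-6-6 fused system:
all-carbon ring + 2-N central ring + 2-N ring with two exocyclic
carbonyls; FLO when a central-ring nitrogen carries a double bond, FLR
otherwise); phenols (benzene carbocycle bearing a hydroxyl).

### Similarity and pairing

T = a/(a+b+c) over type multisets, with a = types of equal nonzero
frequency, b = types more frequent in the substrate (including those
absent from the product), c = the converse. Both-empty compares as 1
(identical degenerate species), empty-vs-nonempty as 0. Pair assignment
is greedy by descending similarity — "start with the most similar pair"
taken literally — not an optimal-assignment solve; ties break on the
lexicographic canonical keys of the two molecules, so pairing is
deterministic under any input ordering. A property test compares greedy
with the exhaustive optimum on small random reactions and logs (does
not fail on) disagreements, since greedy is the specified behaviour.

### Difference keys

Levels are compared motif → group → bond → atom. Masking: atoms inside
any group/motif match are invisible at atom level; a bond is masked iff
both endpoints lie inside one single match. This keeps the informative
boundary bonds — malate → fumarate retains the substrate-side C-C token
(and the A1 group holds the broken C-O internally) while the worked
alcohol-to-ketone example reduces exactly to `S:A1|P:K`. Cancellation
uses one running ledger across all pairs of the reaction (types matched
across different pairs also cancel); unpaired leftovers contribute their
full token sets. Because cancellation is multiset subtraction, the final
ledger is independent of pair order; the per-pair formulation is kept in
one function (`build_difference_key`) so a strictly per-pair reading
could be swapped in without touching anything else. Rendering is
canonical — ASCII-sorted codes per side, `*n` count suffixes, sides
joined by `|`, the all-cancelled key rendering as the empty string — so
identical reactions give byte-identical keys.

### Rules and audit

A rule = sub-subclass + optional acceptor-context gate (any-of over
removed pair classes) + minimum code counts per side + forbidden codes +
flags. Matching tries the forward direction first and the reversed
reaction only if nothing matched. The shipped rules for 1.3.1 and 4.2.1
carry forbidden codes (A1/AL/ES/K/`O=O`) to keep bond-level C-C/C=C
surpluses from firing on alcohol/aldehyde oxidations or oxygenase
chemistry; the published method does not disclose its rule internals,
so forbidden-code gating is this artifact's own rule content.

Audit categories are assigned in a fixed precedence:
DUPLICATE_ASSIGNMENT (the same difference key carries >1 distinct
assigned sub-subclass across the audited set) → MULTI_REACTION (a
declared partial reaction classifies outside the assigned sub-subclass)
→ NO_MATCH → UNCLEAR (every matched rule is flagged non-standard) →
REVERSED / MATCH / SIMILAR_CLASSES / AMBIGUOUS (assigned among the
candidates; SIMILAR_CLASSES when every co-candidate is marked a
near-duplicate of the assigned class in the rule file) → MISMATCH.
Multi-reaction enzymes and unclear assignments have no algorithmic
criterion in the published method; here they are annotation-driven —
partial reactions are declared in the reaction manifest (mirroring how
such reactions are printed as Reactions I/II/III), and non-standard
rules are flagged in the rule file.

## Bundled data and its limits

The fixture registry holds ~50 hand-committed kekulized V2000 blocks
(from methane to NAD⁺/NADP⁺ at full size, ~44–48 heavy atoms) and 12
reaction manifests covering all nine audit categories. Three fixtures
are deliberate stand-ins, labelled as such: the UDP-N-acetylmuramate
couple is truncated to the reacting lactyl/enolpyruvyl methyl-ether
fragment, the sterol 14-demethylase substrate to a branched alkane
(2-methylbutane → but-2-ene + formate), and the heme core is a stylized
porphyrin for motif perception, not protoporphyrin IX. One fixture
reaction (the ring-forming 1.10.3 case) is not oxygen-balanced; the
manifest format makes all participants explicit and the pipeline never
assumes balance.

What passing tests show: the coding layer reproduces the published
operator strings byte-exactly; the pipeline reproduces the published
worked example and case-study outcomes end-to-end; every stage is
deterministic and permutation-invariant. What they do not show:
performance of the shipped demonstration rule set on a large curated
reaction corpus — the published evaluation used a private database of
3,788 reactions and a private rule set covering 229 sub-subclasses,
neither distributed. The rule *format* is the contract; coverage is
meant to be extended by users.

## Numerical and degenerate-input choices

- Tanimoto needs no tolerance (exact rational arithmetic on counts);
  report comparisons are on rendered strings.
- Aromatic (type 4) bonds are kekulized through RDKit at parse time;
  without RDKit such input is rejected with instructions to supply a
  kekulized table. V3000 is rejected.
- `M  CHG` properties override the atom-block charge column (MDL
  semantics: any CHG property resets all atom-block charges).
- Disconnected structures (salts, clusters) are legal molecules.
- Duplicate bonds, bonds to missing atoms, and empty reaction sides are
  hard parse errors with line numbers where available.
- The water/ammonia row of the published known-pair list ships disabled:
  the two are not a conserved structural couple, and consuming them as a
  pair would silently delete reactants. Enable it explicitly if desired.
- Ubiquitous species are removed only when listed (H⁺, H₂O, phosphate in
  the shipped table); every removal is logged in the result provenance.
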