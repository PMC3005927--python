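# Methods

This note records the model behind `mutimpact`, the parameters that matter,
the numerical and design choices made where the design was genuinely open,
and what the synthetic test worlds do and do not demonstrate.

## Document model

Documents are plain UTF-8 text.  Character coordinates are 0-based
half-open; amino-acid positions are 1-based, matching the convention wNm
mutation mentions use.  Tokenization splits on whitespace and detaches the
edge punctuation `.,;:()[]` into separate tokens; `/` and `-` stay inside
tokens so `kcat/Km` and `30-40%` survive intact.  Distance scoring counts
only whitespace-delimited, non-punctuation tokens ("space tokens"), so a
parenthesis never inflates a distance.  Sentence boundaries are orthographic
— `.?!` followed by whitespace and an uppercase letter or digit — guarded
by a configurable protected-abbreviation list (`e.g.`, `i.e.`, `et al.`,
`Fig.`, …); decimal numbers are safe because a boundary requires whitespace
directly after the punctuation.  The original pipeline this re-implements
used a framework-supplied tokenizer/splitter whose exact configuration is
unavailable, so behavior on edge punctuation may differ; the splitter here
is deterministic and covered by round-trip and idempotence property tests.

## Named entity recognition

**Mutations.**  Three pattern families: one-letter wNm (`W125F`),
three-letter wNm (`Trp125Phe`, series split on `+`), and the
natural-language frame "replacement/substitution/mutation of Trp-125 …
with/to arginine".  A word-boundary guard (no adjacent alphanumerics)
rejects matches embedded in strain, plasmid or cell-line identifiers
(`GJ10`, `pW125Fx`).  Silent substitutions (wildtype = mutant) and unknown
residue names are rejected.  These three families cover the protein-level
point-mutation mention forms that matter here; DNA-level mentions and
insertions/deletions are out of scope.

**Proteins, genes, organisms.**  Gazetteer matching from the lexicon:
multiword names match case-insensitively (recall), single-word names
case-sensitively (precision), organism names always case-insensitively.
Overlaps within a kind resolve longest-match-wins, leftmost on ties.

**Properties.**  Function mentions are noun phrases ending at a head noun in
{activity, binding, affinity, specificity}; the phrase is the maximal
contiguous run of content words (no stop words, digits, punctuation or
direction words) ending at the head.  This is a deliberately shallow,
dictionary-driven chunker rather than a POS-tagged one: the head-noun
anchor makes it adequate and fully deterministic.  Kinetic variables match
surface variants of K_M, k_cat and the compound k_cat/K_M with
longest-match precedence (the compound suppresses its parts); a variable
fused to math characters (`Km=5`, `2Km`) is rejected as part of a larger
expression.  Impacts on stability are not modeled.

**Direction words.**  Five disjoint categories — positive, negative,
neutral, negation, non-neutral — seeded with curated words (increase,
enhance, higher, improve / abolish, decrease, reduce, lower, inhibit,
impair, loose, defect, disrupt, diminish / identical, similar, full /
without, no, not / affect, effect, alter, differ) and expanded with regular
inflectional and nominal variants (-s/-es, -d/-ed, -ing, -uce→-uction,
-t→-tion, plus a small table of irregulars such as alter→alteration).
Matching is token-exact and case-insensitive with no stemming at match
time, which keeps matches auditable.  A form derivable in two categories
keeps the first category in a fixed order, with a logged warning.  The
expansion will not reproduce any particular curated list word-for-word;
words like "intact" that plausibly signal neutrality are absent unless
seeded.

## Grounding

**Candidate pool.**  Accessions of every matched protein/gene name, plus
accessions of lexicon names equal to a matched name with an alphanumeric
suffix (optionally space- or hyphen-separated) — a cheap stand-in for
long-form/short-form co-reference.  The pool is trimmed to accessions whose
mention-frequency support is ≥ ceil(f × max support) with f = 0.5 by
default (the trimming threshold is genuinely open; 0.5 keeps clear
majorities and drops singletons).  Accessions from organisms the document
never mentions are then discarded; the filter is skipped when no organism
is mentioned and rolled back with a warning when it would empty the pool.

**Mutation grounding.**  The pairwise-regex algorithm described in the
README.  Search details that the one-paragraph description leaves open and
that are fixed here:

* every overlapping match offset is scanned (first-match would make the
  result order-dependent);
* the displacement search is bounded at |d| ≤ 10 by default — enough for
  Met cleavage and short signal peptides while keeping the brute-force
  oracle cheap; configurable;
* tie-breaking is total: maximal grounded count, then least |d|, then
  lexicographically smallest accession, then smallest signed d;
* at least two mentions at distinct positions are required — a single
  mention admits no pair and the algorithm refuses rather than guessing.

An independent oracle (`brute_force_ground`) scores every (accession,
displacement) pair exhaustively with the same tie-breaks; equality with the
regex path is asserted on hundreds of random instances in the test suite
and recomputed by the acceptance script.

**Function grounding.**  Mention tokens and GO synonyms are prepared
identically: lowercase, stop-word removal (a fixed ~60-word English list
shipped in the package), Snowball English stemming.  The stemmer is a
self-contained implementation of the published Snowball English (Porter2)
algorithm, validated against hand-traced word/stem pairs.  The "relative
intersection" of prepared sets N and G is Jaccard |N∩G|/|N∪G| by default —
symmetric and bounded in [0,1] — with one-sided |N∩G|/|G| and |N∩G|/|N|
selectable; the choice is isolated behind one function.  Candidate concepts
are the GO annotations of pooled accessions plus their is_a ancestors
(descendants are not considered); the best score over all synonyms wins,
ties to the smallest GO id; nothing scoring above zero means no grounding.

## Relation detection

Sentences holding two or more properties are segmented between consecutive
properties at the first comma, else before the first standalone "and", else
immediately before the later property.  Within a segment the non-negation
direction term nearest the property (in space tokens, ties to the earlier
term) sets the direction; a negation term within 2 space tokens before it
remaps {positive→neutral, negative→neutral, neutral→non-neutral,
non-neutral→neutral}.  The remap table and the nearest-term rule are this
package's reconstruction of an impact-rule set whose original form is not
publicly available; they are consistent with every worked sentence the
method was built around, and the logic is isolated in `classify_impact` so
it can be swapped.  The scores

    impactScore   = 1 / tokenDistance
    relationScore = 1 / sentenceDistance

use tokenDistance = 1 + space tokens strictly between the direction word
and the property (1 when the word sits inside the noun phrase) and
sentenceDistance = 1 + sentences looked back (same sentence = 1, capped at
3 back; later sentences are never searched).  Both formulas are bounded,
monotone, and equal 1 in the same-phrase / same-sentence base cases; the
2-token negation window covers "no effect" and "not significantly
increased" without long-range overreach.  Every grounded mutation mention
at the minimal distance receives the impact.  Contradicting directions on
one (mutant, property) key are resolved by the arithmetic mean of relation
score, impact score and — for GO-grounded function properties — the
similarity score (kinetic variables have none); the highest mean survives,
ties keeping the earliest relation.  Pronominal mutant references ("the
double mutant") are not resolved; relations expressed only that way are
missed by design.

## RDF output

Instance triples over the seven mutation-impact concept classes (Protein,
ProteinMutant, ProteinProperty, ElementaryMutation, MutationSeries,
MutationSpecification, MutationImpact) in a repository namespace
(`https://w3id.org/mutimpact/vocab#` — a stand-in, since canonical IRIs
for this vocabulary are not published).  Beyond the canonical
`specifiesImpact`/`impactIsSpecifiedBy` and
`hasSequence`/`hasWildtypeResidue`, the minimal predicates needed to keep
the graph queryable are minted in the same namespace (hasMutantResidue,
hasPosition, affectsProperty, hasDirection, groundedTo, kineticVariable,
causedBy, resultsFrom, variantOf, mentionedIn).  ProteinMutant nodes carry
the mutated sequence (wildtype with the grounded residue substituted), so
the query "mutant sequences with a negative impact on property P" is a
three-hop pattern.  Node IRIs are deterministic content hashes; emitted
graphs re-parse isomorphically from both Turtle and N-Triples.  Triple
stores, SPARQL endpoints and web-service deployment are out of scope.

## Evaluation protocol

Micro-averaged exact-match precision/recall.  A grounding prediction is
correct only when document, normalized mention, accession *and* grounded
position all match (requiring the position, not just the accession, is the
stricter of the two defensible readings and is the documented choice).  A
relation is correct only when mutation, direction and property key all
match, the property compared by GO id when grounded and by variable name
otherwise.  Empty gold raises (recall undefined); an empty prediction set
reports precision 0 with an explicit flag.  Multi-point mutants are
represented one-mutation-per-mutant throughout.

## Synthetic worlds

`mutimpact.synthetic` generates complete test worlds: random sequences over
the 20-letter alphabet (default 100–180 residues), invented protein /
gene / organism names built from pronounceable syllables (checked for
substring collisions so gazetteer matching is unambiguous), a mini
molecular-function ontology (root, catalytic activity, binding, one
activity concept per protein), and 13 documents by default — two to four
planted mutations each, one impact sentence per mutation drawn from
templates modeled on how enzymology papers state such facts.  Planted
mutations are rejected-and-resampled until no competing displacement within
the ±10 search bound ranks as well as the intended one, so the gold
grounding is unique by construction.  With a non-zero distractor rate a
relation sentence refers to its mutant anaphorically and is pushed behind
three lexicon-free filler sentences, putting the mutant outside the
sentence-distance window: recall degrades, precision does not — the
precision-over-recall profile characteristic of distance-capped linking.

What passing these worlds shows: every rule fires as specified, the
grounding search is exactly equivalent to exhaustive search, displacements
are recovered, and the evaluation arithmetic is right.  What it does not
show: performance on real scientific prose — real papers contain
co-reference, nested clauses, tables, DNA-level mentions, plasmid names
and ambiguous short forms that these templates deliberately exclude, and
published corpus-level figures for methods of this family are accordingly
far from perfect.  The acceptance script therefore reports the synthetic
figures as properties of the method under controlled conditions, not as
estimates of real-corpus performance.

## Problem sizes

The default test and acceptance runs use 50-document corpora, 500 random
grounding instances for oracle comparison, and sequences up to 200
residues — sizes at which the exhaustive oracle is exact and the whole
suite runs in seconds.

## Known limitations

* No co-reference resolution for "the double/triple mutant" and nicknames.
* Total-loss-of-function phrasings ("catalytically inactive", "nonactive
  enzyme") are not mapped to negative impacts.
* Kinetic variables are not linked to their substrates.
* Single-mutation documents cannot be grounded (algorithmic precondition).
* The direction gazetteer is the seed-plus-expansion set; curated lists
  used by comparable systems are larger.
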