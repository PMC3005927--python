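# mutimpact

Rule-based extraction and grounding of protein point-mutation impacts from
free text.

Experimental results about mutants — "the W125F mutant showed a slight
reduction of activity and a larger increase of K_M" — are locked inside the
prose of enzymology papers, out of reach of variation databases and
phenotype-prediction tools. `mutimpact` turns such prose into structured,
queryable statements: it detects point-mutation mentions and normalizes them
to wNm form (wildtype residue, position, mutant residue, e.g. `W125F`),
tags protein/gene/organism names from a sequence-database-derived gazetteer,
detects protein properties (function noun phrases headed by *activity*,
*binding*, *affinity* or *specificity*, and the kinetic variables K_M,
k_cat, k_cat/K_M) together with directionality words (categorized positive /
negative / neutral / non-neutral / negation), grounds the mutations to a
database sequence, grounds function mentions to Gene Ontology
molecular-function concepts, and links everything into scored
mutant–impact relations emitted as RDF triples and standoff JSON.

## The core method

**Mutation grounding.** For every pair of normalized mentions
w₁N₁m₁ and w₂N₂m₂ (sorted by position) the pipeline builds the regular
expression

```
w1 ·{N2 − N1 − 1} w2      e.g.  A378C + S381L  →  A..S
```

and scans it over each candidate sequence (candidates are pooled from
protein/gene name matches, expanded by suffixed name variants, trimmed by
mention frequency, and cross-checked against organism mentions).  Every
match offset fixes a numbering *displacement* d = match position − N₁ —
the constant offset between the authors' residue numbering and the database
sequence (e.g. −1 after N-terminal methionine cleavage).  The remaining
mentions are verified one by one under d; the accession/displacement pair
grounding the most mentions wins, ties broken by least |d|.  Unverifiable
mentions are discarded.

**Function grounding.**  A function noun phrase is lowercased, stripped of
stop words and Snowball-stemmed into a set N, and compared against each
synonym G of the GO concepts annotated to the pooled accessions (and their
is_a ancestors) by relative intersection |N∩G| / |N∪G|; the best-scoring
concept is attached with its score.

**Relation detection.**  Sentences with several properties are segmented at
commas or "and"; within a segment, the direction word nearest the property
(negations within two tokens remap the category) forms an impact scored
1/tokenDistance.  Each impact attaches to the nearest grounded mutation
mentions within the same sentence or up to three sentences back, scored
1/sentenceDistance.  Contradicting directions on the same (mutant,
property) pair are resolved by the arithmetic mean of all scores (the GO
similarity is omitted for kinetic variables).

## Worked example

```python
import io
from mutimpact.lexicons import ProteinLexicon, load_go, build_direction_lexicon
from mutimpact.pipeline import run_text

lex = ProteinLexicon()
seq = list("M" + "A" * 199); seq[124], seq[169] = "W", "D"   # synthetic stand-in
lex.add_record("P22643", ["Haloalkane dehalogenase"], "".join(seq),
               organisms=["Xanthobacter autotrophicus"],
               go_ids=["GO:0018786"], genes=["dhlA"])
go = load_go("go.obo")           # molecular-function OBO slice

text = ("Haloalkane dehalogenase (dhlA) from Xanthobacter autotrophicus was "
        "mutated at residues 125 and 170, yielding W125F and D170N. "
        "The W125F mutant showed only a slight reduction of activity (Vmax) "
        "and a larger increase of Km with 1,2-dibromoethane.")
result = run_text("example", text, lex, go, build_direction_lexicon())
```

prints, when the relations are dumped:

```
accession: P22643 displacement: 0
grounded: ['D170N', 'W125F']
W125F  negative  GO:0003824   impact=0.50 relation=1.00 combined=0.667
W125F  positive  KM           impact=0.50 relation=1.00 combined=0.750
```

Both mutations ground onto the P22643 sequence with zero displacement.  The
second sentence yields two relations for W125F: a *negative* impact on the
activity function (grounded to a GO concept, similarity 0.5, so the
combined score is the mean of 1.0, 0.5 and 0.5) and a *positive* impact on
K_M (no similarity term, mean of 1.0 and 0.5).  D170N, mentioned a sentence
earlier, is correctly not linked — the same-sentence mutant is closer.

## Command line

```sh
mutimpact make-fixtures --seed 1 --out-dir world      # synthetic corpus + gold
mutimpact extract world/docs --lexicon world/lexicon.sp --go world/go.obo \
    --out-dir out --format ttl --format json
mutimpact evaluate --gold world/gold.tsv --lexicon world/lexicon.sp \
    --go world/go.obo --docs world/docs
```

`extract` writes one Turtle graph and one standoff JSON per document; the
graph can be pattern-queried, e.g. for the mutant sequences of all
mutations with a negative impact on a given property
(`mutimpact.rdf_output.mutant_sequences_for`).

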