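"""Self-contained synthetic test worlds.

A world bundles a mini protein lexicon (invented names, random sequences,
GO annotations), a mini molecular-function ontology, template documents
with planted mutations / properties / direction words, and the matching
gold standard.  Generation is a pure function of :class:`FixtureSpec`:
the same spec yields byte-identical output.

Documents follow sentence templates modeled on how enzyme papers state
these facts: an introduction naming protein, gene and organism; a
construction sentence listing the mutants; then one impact sentence per
planted relation ("The <wNm> mutant showed a <direction word> <property>
relative to the wildtype enzyme.").  With a non-zero distractor rate a
relation sentence instead refers to its mutant anaphorically and is pushed
behind lexicon-free filler sentences, so the mutant lies outside the
sentence-distance window — the relation stays in the gold standard but is
not expressible by the distance rules, degrading recall while leaving
precision untouched.
"""

from __future__ import annotations

import io
import random
import string
from dataclasses import dataclass, field
from pathlib import Path

from .evaluation import GoldStandard, write_gold_tsv
from .lexicons import (
    DirectionLexicon,
    GOGraph,
    ProteinLexicon,
    build_direction_lexicon,
    load_go,
)

__all__ = ["FixtureSpec", "World", "generate_world", "write_world"]

_CONSONANTS = "bdfglmnprstvz"
_VOWELS = "aeiou"

#: Surface form → gold category; every form must exist in the default
#: direction lexicon (checked at generation time).
_DIRECTION_SURFACES = {
    "positive": ("increased", "enhanced", "improved", "higher"),
    "negative": ("reduced", "decreased", "impaired", "diminished"),
    "neutral": ("similar", "identical"),
}

_KINETIC = (("Km", "KM"), ("kcat", "KCAT"), ("kcat/Km", "KCAT_OVER_KM"))

_FILLERS = (
    "Crystals were grown overnight using vapour diffusion.",
    "Samples were dialysed twice against buffer before storage.",
    "Spectra were recorded at two wavelengths per preparation.",
    "All measurements were repeated three times per batch.",
    "Cultures were harvested during late exponential growth.",
)

GO_ROOT = "GO:0003674"
GO_CATALYTIC = "GO:0003824"
GO_BINDING = "GO:0005488"


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    n_proteins: int = 8
    n_docs: int = 13
    seq_length: tuple[int, int] = (100, 180)
    mutations_per_doc: tuple[int, int] = (2, 4)
    displacement: int = 0
    distractor_rate: float = 0.0

    def validate(self) -> None:
        if self.n_proteins < 1 or self.n_docs < 1:
            raise ValueError("counts must be positive")
        if self.seq_length[0] < 30:
            raise ValueError("sequences must be at least 30 residues")
        if self.seq_length[0] > self.seq_length[1] or \
                self.mutations_per_doc[0] > self.mutations_per_doc[1]:
            raise ValueError("ranges must be (low, high) with low <= high")
        usable = self.seq_length[0] - abs(self.displacement)
        if self.mutations_per_doc[1] > usable:
            raise ValueError(
                f"cannot plant {self.mutations_per_doc[1]} mutations in "
                f"{usable} usable positions"
            )


@dataclass
class World:
    spec: FixtureSpec
    lexicon: ProteinLexicon
    go: GOGraph
    direction_lexicon: DirectionLexicon
    obo_text: str
    documents: list[tuple[str, str]]       # (doc_id, text)
    gold: GoldStandard
    protein_ids: dict[str, str] = field(default_factory=dict)  # name → accession


def _word(rng: random.Random, syllables: int) -> str:
    return "".join(
        rng.choice(_CONSONANTS) + rng.choice(_VOWELS) for _ in range(syllables)
    )


def _unique_words(rng: random.Random, count: int, syllables: int) -> list[str]:
    words: list[str] = []
    while len(words) < count:
        w = _word(rng, syllables)
        if all(w not in other and other not in w for other in words):
            words.append(w)
    return words


def _go_id(i: int) -> str:
    return f"GO:{7100000 + i:07d}"


def _make_obo(terms: list[tuple[str, str, list[str], list[str]]]) -> str:
    """terms: (id, name, synonyms, parents) — molecular_function stanzas."""
    chunks = ["format-version: 1.2", "ontology: go", ""]
    for go_id, name, synonyms, parents in terms:
        lines = [
            "[Term]",
            f"id: {go_id}",
            f"name: {name}",
            "namespace: molecular_function",
        ]
        for syn in synonyms:
            lines.append(f'synonym: "{syn}" EXACT []')
        for parent in parents:
            lines.append(f"is_a: {parent}")
        chunks.append("\n".join(lines))
        chunks.append("")
    return "\n".join(chunks)


def _plant_mutations(
    rng: random.Random, sequence: str, k: int, displacement: int,
    max_search: int = 10,
) -> list[tuple[str, int, str]] | None:
    """Choose k (wildtype, author position, mutant) triples consistent with
    *sequence* at *displacement*, such that no competing displacement within
    the search bound grounds as many mentions at an equal-or-better rank.
    Returns None when the draw fails (caller retries)."""
    n = len(sequence)
    lo = max(1, 1 + displacement)
    candidates = [p for p in range(lo, n + 1)]
    if len(candidates) < k:
        return None
    seq_positions = sorted(rng.sample(candidates, k))
    triples = []
    for sp in seq_positions:
        wt = sequence[sp - 1]
        mutant = rng.choice([a for a in "ACDEFGHIKLMNPQRSTVWY" if a != wt])
        author_pos = sp - displacement
        triples.append((wt, author_pos, mutant))

    def count_at(d: int) -> int:
        return sum(
            1
            for wt, pos, _ in triples
            if 1 <= pos + d <= n and sequence[pos + d - 1] == wt
        )

    best_rank = (-k, abs(displacement), displacement)
    for d in range(-max_search, max_search + 1):
        if d == displacement:
            continue
        rank = (-count_at(d), abs(d), d)
        if rank <= best_rank:
            return None
    return triples


def generate_world(spec: FixtureSpec) -> World:
    """Build the complete world for *spec* (deterministic in the seed)."""
    spec.validate()
    rng = random.Random(spec.seed)
    dlex = build_direction_lexicon()
    for surfaces in _DIRECTION_SURFACES.values():
        for surface in surfaces:
            assert dlex.category(surface) is not None, surface

    n = spec.n_proteins
    words = _unique_words(rng, 3 * n + 2, 3)
    lexicon = ProteinLexicon()
    go_terms = [
        (GO_ROOT, "molecular_function", [], []),
        (GO_CATALYTIC, "catalytic activity", ["enzyme activity"], [GO_ROOT]),
        (GO_BINDING, "binding", [], [GO_ROOT]),
    ]
    protein_ids: dict[str, str] = {}
    protein_names: list[str] = []
    activity_ids: dict[str, str] = {}

    for i in range(n):
        accession = f"P{10000 + i}"
        w1, w2, gstem = words[3 * i : 3 * i + 3]
        protein_name = f"{w1.capitalize()} {w2}ase"
        gene = gstem[:3] + string.ascii_uppercase[i % 26]
        genus = words[3 * n].capitalize()
        organism = f"{genus} {w1}ensis"
        sequence = "".join(
            rng.choice("ACDEFGHIKLMNPQRSTVWY")
            for _ in range(rng.randint(*spec.seq_length))
        )
        go_id = _go_id(i)
        go_terms.append(
            (go_id, f"{protein_name.lower()} activity",
             [f"{w2}ase activity"], [GO_CATALYTIC])
        )
        lexicon.add_record(
            accession, [protein_name], sequence,
            organisms=[organism], go_ids=[go_id], genes=[gene],
        )
        protein_ids[protein_name] = accession
        protein_names.append(protein_name)
        activity_ids[accession] = go_id

    obo_text = _make_obo(go_terms)
    go = load_go(io.StringIO(obo_text))

    gold = GoldStandard()
    documents: list[tuple[str, str]] = []
    for di in range(spec.n_docs):
        doc_id = f"doc{di:03d}"
        protein_name = protein_names[di % n]
        accession = protein_ids[protein_name]
        sequence = lexicon.sequence(accession)
        gene = next(
            name for name, flags in lexicon.name_flags.items()
            if flags["entity_kind"] == "Gene"
            and accession in lexicon.name_to_accessions[name]
        )
        organism = sorted(lexicon.accession_to_organism[accession])[0]

        k = rng.randint(*spec.mutations_per_doc)
        triples = None
        for _ in range(1000):
            triples = _plant_mutations(rng, sequence, k, spec.displacement)
            if triples is not None:
                break
        if triples is None:
            raise ValueError(
                f"could not plant {k} unambiguous mutations in {doc_id}"
            )
        mutations = [f"{wt}{pos}{mut}" for wt, pos, mut in triples]

        sentences = [
            f"{protein_name} ({gene}) from {organism} catalyses the "
            f"conversion of model substrates.",
            "The mutants " + ", ".join(mutations[:-1]) +
            (" and " if len(mutations) > 1 else "") + mutations[-1] +
            " were constructed by site-directed mutagenesis.",
        ]

        for (wt, pos, mut), wnm in zip(triples, mutations):
            gold.add_mutation(doc_id, wnm, accession, pos + spec.displacement)
            category = rng.choice(tuple(_DIRECTION_SURFACES))
            surface = rng.choice(_DIRECTION_SURFACES[category])
            article = "an" if surface[0] in "aeiou" else "a"
            if rng.random() < 0.5:
                phrase = f"{protein_name.lower()} activity"
                key = activity_ids[accession]
            else:
                variable, key = rng.choice(_KINETIC)
                phrase = variable
            gold.add_relation(doc_id, wnm, category, key)
            anaphoric = rng.random() < spec.distractor_rate
            if anaphoric:
                sentences.extend(rng.sample(_FILLERS, 3))
                sentences.append(
                    f"This mutant showed {article} {surface} {phrase} "
                    f"relative to the wildtype enzyme."
                )
            else:
                sentences.append(
                    f"The {wnm} mutant showed {article} {surface} {phrase} "
                    f"relative to the wildtype enzyme."
                )
        documents.append((doc_id, " ".join(sentences)))

    return World(
        spec=spec,
        lexicon=lexicon,
        go=go,
        direction_lexicon=dlex,
        obo_text=obo_text,
        documents=documents,
        gold=gold,
        protein_ids=protein_ids,
    )


def write_world(world: World, out_dir: str | Path) -> None:
    """Materialize a world as plain-text files: lexicon flat file, OBO,
    one .txt per document, and the gold TSV."""
    out = Path(out_dir)
    (out / "docs").mkdir(parents=True, exist_ok=True)
    (out / "lexicon.sp").write_text(world.lexicon.to_flat_text(),
                                    encoding="utf-8")
    (out / "go.obo").write_text(world.obo_text, encoding="utf-8")
    for doc_id, text in world.documents:
        (out / "docs" / f"{doc_id}.txt").write_text(text, encoding="utf-8")
    write_gold_tsv(world.gold, out / "gold.tsv")
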