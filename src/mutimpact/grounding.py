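"""Grounding: proteins to accessions, mutation sets to sequence positions,
and function mentions to Gene Ontology concepts.

Mutation grounding is the pairwise-regex algorithm: for every pair of
normalized mentions w1·N1·m1 and w2·N2·m2 (sorted by position) the pattern
``w1 . {N2-N1-1} w2`` is scanned over each candidate sequence; every match
offset fixes a numbering displacement d = match_position − N1 under which
the remaining mentions are verified one by one.  The accession/displacement
grounding the most mentions wins, ties broken by least |d|, then by
lexicographically smallest accession.  Displacements model the constant
offset between author numbering and database numbering (N-terminal Met
cleavage, signal peptides, …).
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field

from ._stem import stem
from .lexicons import GOGraph, ProteinLexicon, STOP_WORDS
from .ner import MutationMention, PropertyMention
from .textmodel import Document

log = logging.getLogger(__name__)

__all__ = [
    "CandidatePool",
    "GroundingResult",
    "GroundedFunction",
    "build_candidate_pool",
    "build_pair_regex",
    "ground_mutations",
    "brute_force_ground",
    "prepare_tokens",
    "similarity",
    "ground_function",
    "DEFAULT_MAX_DISPLACEMENT",
    "DEFAULT_POOL_FRACTION",
]

#: Displacement search bound: covers Met cleavage and short signal-peptide
#: offsets while keeping exhaustive verification cheap.
DEFAULT_MAX_DISPLACEMENT = 10
#: Candidate accessions must reach this fraction of the top support count.
DEFAULT_POOL_FRACTION = 0.5


@dataclass
class CandidatePool:
    """Candidate accessions with mention-frequency support counts."""

    support: dict[str, int] = field(default_factory=dict)
    organism_filtered: bool = False

    @property
    def accessions(self) -> list[str]:
        return sorted(self.support)

    def __bool__(self) -> bool:
        return bool(self.support)


def build_candidate_pool(
    doc: Document,
    lex: ProteinLexicon,
    fraction: float = DEFAULT_POOL_FRACTION,
) -> CandidatePool:
    """Pool candidate accessions from protein/gene mentions.

    Each mention contributes the accessions of its name plus the accessions
    of lexicon names formed by appending an alphanumeric suffix to it
    (catches short forms whose long form carries a trailing qualifier).
    The pool is trimmed to accessions with support ≥ ceil(fraction × max),
    then cross-checked against the document's organism mentions; the
    organism filter is skipped when no organism is mentioned, and if it
    would empty the pool the pre-filter pool is kept with a warning.
    """
    support: dict[str, int] = {}
    mentioned_organisms: set[str] = set()
    for ann in doc.annotations:
        if ann.kind in ("Protein", "Gene"):
            name = ann.features["name"]
            accs = set(ann.features.get("accessions", ()))
            accs |= lex.suffix_expansions(name)
            for acc in accs:
                support[acc] = support.get(acc, 0) + 1
        elif ann.kind == "Organism":
            mentioned_organisms.add(ann.features["name"].lower())

    if not support:
        return CandidatePool()

    top = max(support.values())
    cutoff = math.ceil(fraction * top)
    trimmed = {a: c for a, c in support.items() if c >= cutoff}

    organism_filtered = False
    if mentioned_organisms:
        filtered = {
            a: c
            for a, c in trimmed.items()
            if {o.lower() for o in lex.accession_to_organism.get(a, ())}
            & mentioned_organisms
        }
        if filtered:
            trimmed = filtered
            organism_filtered = True
        else:
            log.warning(
                "organism filter would empty the candidate pool; keeping "
                "%d unfiltered accession(s)", len(trimmed)
            )
    return CandidatePool(support=trimmed, organism_filtered=organism_filtered)


def build_pair_regex(m1: MutationMention, m2: MutationMention) -> str:
    """Pattern ``w1 .{N2-N1-1} w2`` for two mentions (sorted by position).

    For A378C and S381L this is ``A..S``.  Equal positions have no valid
    pattern and raise :class:`ValueError` (the pair is skipped upstream).
    """
    lo, hi = sorted((m1, m2), key=lambda m: m.position)
    gap = hi.position - lo.position - 1
    if gap < 0:
        raise ValueError("mutation pair with equal positions")
    return lo.wildtype + "." * gap + hi.wildtype


@dataclass
class GroundingResult:
    """Outcome of grounding one document's mutation set."""

    accession: str | None
    sequence: str | None
    displacement: int
    grounded: frozenset[MutationMention]
    discarded: frozenset[MutationMention]

    @property
    def success(self) -> bool:
        return self.accession is not None and bool(self.grounded)

    def grounded_position(self, mention: MutationMention) -> int:
        """1-based database-sequence position of a grounded mention."""
        return mention.position + self.displacement


def _verify(sequence: str, mentions: frozenset[MutationMention],
            d: int) -> frozenset[MutationMention]:
    """Mentions whose wildtype residue matches sequence[N+d] (1-based)."""
    ok = []
    for m in mentions:
        pos = m.position + d
        if 1 <= pos <= len(sequence) and sequence[pos - 1] == m.wildtype:
            ok.append(m)
    return frozenset(ok)


def ground_mutations(
    mentions: set[MutationMention] | frozenset[MutationMention],
    pool: CandidatePool,
    lex: ProteinLexicon,
    max_displacement: int = DEFAULT_MAX_DISPLACEMENT,
) -> GroundingResult:
    """Ground a document's unique mutation set onto a pooled sequence.

    Requires at least two distinct mutation positions — a single mention
    admits no pair regex, so the algorithm has nothing to anchor on.
    Returns an empty grounding (everything discarded) when no pair pattern
    matches any candidate sequence within the displacement bound.
    """
    unique: dict[str, MutationMention] = {}
    for m in sorted(mentions, key=lambda m: (m.position, m.wildtype, m.mutant)):
        unique.setdefault(m.normalized, m)
    mset = frozenset(unique.values())
    if len({m.position for m in mset}) < 2:
        raise ValueError(
            "mutation grounding requires at least two point mutations at "
            "distinct positions"
        )
    if not pool:
        raise ValueError("empty candidate pool")

    pairs = [
        (a, b)
        for i, a in enumerate(sorted(mset, key=lambda m: m.position))
        for b in sorted(mset, key=lambda m: m.position)[i + 1 :]
        if a.position != b.position
    ]

    best: tuple[int, int, str, int] | None = None  # (-count, |d|, acc, d)
    best_grounded: frozenset[MutationMention] = frozenset()
    for acc in pool.accessions:
        seq = lex.sequence(acc)
        seen_d: set[int] = set()
        for a, b in pairs:
            lo = min(a, b, key=lambda m: m.position)
            pattern = re.compile("(?=" + build_pair_regex(a, b) + ")")
            for m in pattern.finditer(seq):
                d = (m.start() + 1) - lo.position
                if abs(d) > max_displacement or d in seen_d:
                    continue
                seen_d.add(d)
                grounded = _verify(seq, mset, d)
                key = (-len(grounded), abs(d), acc, d)
                if best is None or key < best:
                    best = key
                    best_grounded = grounded

    if best is None or len(best_grounded) < 2:
        return GroundingResult(None, None, 0, frozenset(), mset)
    _, _, acc, d = best
    return GroundingResult(
        accession=acc,
        sequence=lex.sequence(acc),
        displacement=d,
        grounded=best_grounded,
        discarded=mset - best_grounded,
    )


def brute_force_ground(
    mentions: set[MutationMention] | frozenset[MutationMention],
    pool: CandidatePool,
    lex: ProteinLexicon,
    max_displacement: int = DEFAULT_MAX_DISPLACEMENT,
) -> GroundingResult:
    """Independent oracle: exhaustively score every (accession, displacement)
    pair in [−bound, bound], keeping candidates that ground ≥ 2 mentions,
    with the same tie-breaking as :func:`ground_mutations`."""
    unique: dict[str, MutationMention] = {}
    for m in sorted(mentions, key=lambda m: (m.position, m.wildtype, m.mutant)):
        unique.setdefault(m.normalized, m)
    mset = frozenset(unique.values())
    best: tuple[int, int, str, int] | None = None
    best_grounded: frozenset[MutationMention] = frozenset()
    for acc in pool.accessions:
        seq = lex.sequence(acc)
        for d in range(-max_displacement, max_displacement + 1):
            grounded = _verify(seq, mset, d)
            # a pair regex needs two verified mentions at distinct positions
            if len({m.position for m in grounded}) < 2:
                continue
            key = (-len(grounded), abs(d), acc, d)
            if best is None or key < best:
                best = key
                best_grounded = grounded
    if best is None:
        return GroundingResult(None, None, 0, frozenset(), mset)
    _, _, acc, d = best
    return GroundingResult(acc, lex.sequence(acc), d, best_grounded,
                           mset - best_grounded)


def prepare_tokens(words: list[str] | tuple[str, ...]) -> frozenset[str]:
    """Lowercase, drop stop words, Snowball-stem; return the stem set."""
    return frozenset(
        stem(w.lower()) for w in words if w.lower() not in STOP_WORDS
    )


def similarity(n: frozenset[str], g: frozenset[str],
               mode: str = "jaccard") -> float:
    """Relative intersection of two prepared stem sets.

    ``jaccard`` (default) is |N∩G| / |N∪G|; ``over_g`` and ``over_n``
    normalize by one side only.  All are in [0, 1] and 1.0 iff the compared
    sets coincide (for jaccard) or one contains the other (one-sided).
    """
    if not n or not g:
        return 0.0
    inter = len(n & g)
    if mode == "jaccard":
        return inter / len(n | g)
    if mode == "over_g":
        return inter / len(g)
    if mode == "over_n":
        return inter / len(n)
    raise ValueError(f"unknown similarity mode: {mode!r}")


@dataclass(frozen=True)
class GroundedFunction:
    mention: PropertyMention
    go_id: str
    similarity: float


def ground_function(
    mention: PropertyMention,
    pool: CandidatePool,
    lex: ProteinLexicon,
    go: GOGraph,
    mode: str = "jaccard",
) -> GroundedFunction | None:
    """Ground a function noun phrase to a GO molecular-function concept.

    Candidate concepts are the GO annotations of pooled accessions plus all
    their is_a ancestors; the score for a concept is the maximum relative
    intersection between the prepared noun-phrase stems and any of the
    concept's prepared synonyms.  Returns ``None`` when nothing scores > 0.
    Ties on score go to the lexicographically smallest GO id.
    """
    if mention.kind != "function":
        raise ValueError("only function mentions are grounded to GO")
    candidates: set[str] = set()
    for acc in pool.accessions:
        for go_id in lex.accession_to_go.get(acc, ()):
            if go_id in go:
                candidates.add(go_id)
                candidates.update(go.ancestors(go_id))
    if not candidates:
        log.info("pooled accessions carry no GO annotations")
        return None

    n = prepare_tokens(mention.np_tokens)
    best_id, best_score = None, 0.0
    for go_id in sorted(candidates):
        for syn in go.synonyms(go_id):
            g = prepare_tokens(syn.split())
            score = similarity(n, g, mode)
            if score > best_score:
                best_id, best_score = go_id, score
    if best_id is None:
        return None
    return GroundedFunction(mention, best_id, best_score)
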