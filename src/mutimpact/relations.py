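"""Relation detection: impact statements and mutant–impact relations.

An *impact* is a (direction, property) pair found inside a sentence segment
holding exactly one property; its score is 1/tokenDistance, where
tokenDistance is 1 plus the number of whitespace-delimited tokens strictly
between the directionality word and the property (1 when the word sits
inside the property's noun phrase).  A *mutant–impact relation* attaches
the impact to the nearest grounded mutation mentions, searching the same
sentence and then up to three previous sentences; its score is
1/sentenceDistance.  Contradictory directions on the same (mutant,
property) pair are resolved by the arithmetic mean of all scores — the
relation score, the impact score, and for grounded function properties the
GO similarity score (omitted for kinetic variables, which carry none).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace

from .ner import DirectionTerm, MutationMention, PropertyMention
from .textmodel import Document, Sentence, space_tokens_between

__all__ = [
    "ImpactStatement",
    "MutantImpactRelation",
    "segment_properties",
    "classify_impact",
    "link_mutants",
    "resolve_contradictions",
    "NEGATION_REMAP",
    "NEGATION_WINDOW",
    "MAX_PREVIOUS_SENTENCES",
]

#: How a negation word within the window remaps the adjacent direction.
NEGATION_REMAP = {
    "positive": "neutral",
    "negative": "neutral",
    "neutral": "non_neutral",
    "non_neutral": "neutral",
}
#: Negation must occur within this many space tokens before the direction word.
NEGATION_WINDOW = 2
#: An impact may look back at most this many sentences for its mutant.
MAX_PREVIOUS_SENTENCES = 3


@dataclass(frozen=True)
class ImpactStatement:
    direction: str                 # positive | negative | neutral | non_neutral
    property: PropertyMention
    token_distance: int
    sentence_index: int

    @property
    def impact_score(self) -> float:
        return 1.0 / self.token_distance


@dataclass(frozen=True)
class MutantImpactRelation:
    mutation: MutationMention
    impact: ImpactStatement
    sentence_distance: int         # 1 = same sentence, up to 4

    @property
    def relation_score(self) -> float:
        return 1.0 / self.sentence_distance

    @property
    def combined_score(self) -> float:
        """Arithmetic mean of relation score, impact score and (when the
        property is a grounded function) the GO similarity score."""
        scores = [self.relation_score, self.impact.impact_score]
        sim = self.impact.property.similarity
        if self.impact.property.kind == "function" and sim is not None:
            scores.append(sim)
        return sum(scores) / len(scores)

    @property
    def key(self) -> tuple[str, str]:
        return (self.mutation.normalized, self.impact.property.key)


def segment_properties(
    sentence: Sentence, text: str, properties: list[PropertyMention]
) -> list[tuple[int, int]]:
    """Split a sentence into segments holding exactly one property each.

    Between consecutive properties the split lands after the first comma or
    before the first standalone "and"; absent both, immediately before the
    later property.  With 0 or 1 properties the whole sentence is one
    segment.
    """
    props = sorted(properties, key=lambda p: p.start)
    if len(props) <= 1:
        return [(sentence.start, sentence.end)]
    cuts = [sentence.start]
    for left, right in zip(props, props[1:]):
        between = text[left.end : right.start]
        comma = between.find(",")
        and_m = re.search(r"\band\b", between)
        if comma >= 0 and (not and_m or comma < and_m.start()):
            cuts.append(left.end + comma + 1)
        elif and_m:
            cuts.append(left.end + and_m.start())
        else:
            cuts.append(right.start)
    cuts.append(sentence.end)
    return list(zip(cuts, cuts[1:]))


def classify_impact(
    sentence: Sentence,
    segment: tuple[int, int],
    prop: PropertyMention,
    terms: list[DirectionTerm],
) -> ImpactStatement | None:
    """Classify the impact on *prop* within *segment*.

    The non-negation direction term nearest the property (in space tokens,
    ties to the earlier term) sets the direction; a negation term within
    :data:`NEGATION_WINDOW` space tokens before it remaps the category per
    :data:`NEGATION_REMAP`.  Returns ``None`` when the segment has no
    direction term.
    """
    lo, hi = segment
    in_seg = [t for t in terms if t.start >= lo and t.end <= hi]
    candidates = [t for t in in_seg if t.category != "negation"]
    if not candidates:
        return None

    def distance(term: DirectionTerm) -> int:
        if prop.start <= term.start and term.end <= prop.end:
            return 1
        return 1 + space_tokens_between(sentence, term.span, prop.span)

    chosen = min(candidates, key=lambda t: (distance(t), t.start))
    direction = chosen.category
    for neg in in_seg:
        if neg.category != "negation" or neg.start >= chosen.start:
            continue
        if space_tokens_between(sentence, neg.span, chosen.span) < NEGATION_WINDOW:
            direction = NEGATION_REMAP[direction]
            break
    return ImpactStatement(
        direction=direction,
        property=prop,
        token_distance=distance(chosen),
        sentence_index=sentence.index,
    )


def link_mutants(
    impacts: list[ImpactStatement],
    mentions: list[MutationMention],
    doc: Document,
) -> list[MutantImpactRelation]:
    """Attach each impact to the nearest grounded mutation mentions.

    *mentions* must be occurrence-level (with spans) and already restricted
    to grounded mutations.  The same sentence is searched first, then up to
    :data:`MAX_PREVIOUS_SENTENCES` previous ones; every mention at the
    minimal distance receives the relation; following sentences are never
    searched.
    """
    by_sentence: dict[int, list[MutationMention]] = {}
    for m in mentions:
        sent = doc.sentence_of(m.start)
        if sent is not None:
            by_sentence.setdefault(sent.index, []).append(m)

    relations: list[MutantImpactRelation] = []
    for impact in impacts:
        for back in range(0, MAX_PREVIOUS_SENTENCES + 1):
            idx = impact.sentence_index - back
            if idx < 0:
                break
            found = by_sentence.get(idx, ())
            if found:
                seen: set[str] = set()
                for m in sorted(found, key=lambda m: m.start):
                    if m.normalized in seen:
                        continue
                    seen.add(m.normalized)
                    relations.append(
                        MutantImpactRelation(m, impact, sentence_distance=back + 1)
                    )
                break
    return relations


def resolve_contradictions(
    relations: list[MutantImpactRelation],
) -> list[MutantImpactRelation]:
    """Resolve direction contradictions on the same (mutant, property) key.

    When a mutant is asserted to have differing directions of impact on one
    property, only the relation with the highest combined (mean) score
    survives; ties keep the relation occurring earliest in the document.
    Uncontradicted relations pass through unchanged.
    """
    groups: dict[tuple[str, str], list[MutantImpactRelation]] = {}
    for rel in relations:
        groups.setdefault(rel.key, []).append(rel)
    out: list[MutantImpactRelation] = []
    for group in groups.values():
        directions = {r.impact.direction for r in group}
        if len(directions) <= 1:
            out.extend(group)
        else:
            out.append(
                max(group, key=lambda r: (r.combined_score, -r.impact.property.start))
            )
    out.sort(key=lambda r: (r.impact.property.start, r.mutation.start))
    return out


def apply_similarity(impact: ImpactStatement, go_id: str,
                     score: float) -> ImpactStatement:
    """Return a copy of *impact* whose property carries a GO grounding."""
    prop = replace(impact.property, go_id=go_id, similarity=score)
    return replace(impact, property=prop)
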