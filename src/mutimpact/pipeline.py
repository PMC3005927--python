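"""End-to-end pipeline: text in, grounded mutant–impact relations out.

Stages, in order: tokenize/sentence-split, NER (mutations, entities,
properties, direction words), candidate-accession pooling, mutation
grounding, GO grounding of function mentions, property segmentation and
impact classification, mutant linking, contradiction resolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from . import grounding as gr
from . import ner, relations as rel
from .lexicons import DirectionLexicon, GOGraph, ProteinLexicon
from .textmodel import Document, build_document

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_document", "run_text"]


@dataclass
class PipelineConfig:
    pool_fraction: float = gr.DEFAULT_POOL_FRACTION
    max_displacement: int = gr.DEFAULT_MAX_DISPLACEMENT
    similarity_mode: str = "jaccard"


@dataclass
class PipelineResult:
    document: Document
    mutation_mentions: list[ner.MutationMention] = field(default_factory=list)
    pool: gr.CandidatePool = field(default_factory=gr.CandidatePool)
    grounding: gr.GroundingResult | None = None
    impacts: list[rel.ImpactStatement] = field(default_factory=list)
    relations: list[rel.MutantImpactRelation] = field(default_factory=list)


def run_document(doc: Document, lex: ProteinLexicon, go: GOGraph | None,
                 dlex: DirectionLexicon,
                 config: PipelineConfig | None = None) -> PipelineResult:
    config = config or PipelineConfig()
    result = PipelineResult(document=doc)

    ner.annotate_document(doc, lex, dlex)
    result.mutation_mentions = ner.find_mutation_mentions(doc)

    result.pool = gr.build_candidate_pool(doc, lex, config.pool_fraction)

    unique_positions = {m.position for m in result.mutation_mentions}
    if result.pool and len(unique_positions) >= 2:
        result.grounding = gr.ground_mutations(
            set(result.mutation_mentions), result.pool, lex,
            config.max_displacement,
        )
    elif result.mutation_mentions:
        log.info(
            "%s: grounding skipped (%d mention position(s), pool size %d)",
            doc.doc_id, len(unique_positions), len(result.pool.support),
        )

    # impacts, sentence by sentence
    for sent in doc.sentences:
        props = ner.find_property_mentions(sent, doc.text, dlex)
        if not props:
            continue
        terms = ner.find_direction_terms(sent, dlex)
        segments = rel.segment_properties(sent, doc.text, props)
        for prop in props:
            segment = next(
                (s for s in segments if s[0] <= prop.start and prop.end <= s[1]),
                (sent.start, sent.end),
            )
            impact = rel.classify_impact(sent, segment, prop, terms)
            if impact is None:
                continue
            if prop.kind == "function" and go is not None and result.pool:
                gf = gr.ground_function(
                    prop, result.pool, lex, go, config.similarity_mode
                )
                if gf is not None:
                    impact = rel.apply_similarity(impact, gf.go_id, gf.similarity)
            result.impacts.append(impact)

    if result.grounding is not None and result.grounding.success:
        grounded_forms = {m.normalized for m in result.grounding.grounded}
        occurrences = [
            m for m in result.mutation_mentions if m.normalized in grounded_forms
        ]
        raw = rel.link_mutants(result.impacts, occurrences, doc)
        result.relations = rel.resolve_contradictions(raw)
    return result


def run_text(doc_id: str, text: str, lex: ProteinLexicon, go: GOGraph | None,
             dlex: DirectionLexicon,
             config: PipelineConfig | None = None) -> PipelineResult:
    return run_document(build_document(doc_id, text), lex, go, dlex, config)
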