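"""Serialize pipeline results as RDF instance triples plus standoff JSON.

The class vocabulary follows the mutation-impact concept set — Protein,
ProteinMutant, ProteinProperty, ElementaryMutation, MutationSeries,
MutationSpecification, MutationImpact — under a repository namespace.
Beyond the canonical ``specifiesImpact``/``impactIsSpecifiedBy`` pair and
the ``hasSequence``/``hasWildtypeResidue`` datatype properties, a minimal
set of predicates (hasMutantResidue, hasPosition, affectsProperty,
hasDirection, groundedTo, mentionedIn) is minted in the same namespace;
GO-grounded properties additionally link to their GO IRI.

Node IRIs are deterministic functions of the document id and content, so a
rerun over the same corpus emits an isomorphic graph.
"""

from __future__ import annotations

import hashlib
import json
from typing import TYPE_CHECKING

from rdflib import Graph, Literal, Namespace, RDF, URIRef
from rdflib.namespace import XSD

if TYPE_CHECKING:  # pragma: no cover
    from .pipeline import PipelineResult

__all__ = ["MIO", "GO_BASE", "emit_triples", "mutant_sequences_for",
           "standoff_json"]

#: Repository stand-in namespace for the mutation-impact vocabulary.
MIO = Namespace("https://w3id.org/mutimpact/vocab#")
DATA = Namespace("https://w3id.org/mutimpact/data/")
GO_BASE = "http://purl.obolibrary.org/obo/"

def _iri(*parts: str) -> URIRef:
    digest = hashlib.sha1("|".join(parts).encode()).hexdigest()[:12]
    return DATA[f"{parts[0]}-{digest}"]


def _go_iri(go_id: str) -> URIRef:
    return URIRef(GO_BASE + go_id.replace(":", "_"))


def _mutated(sequence: str, position: int, mutant: str) -> str:
    return sequence[: position - 1] + mutant + sequence[position:]


def emit_triples(result: "PipelineResult") -> Graph:
    """Build the instance graph for one processed document.

    One MutationSpecification node ties together the Protein (with its
    accession and hasSequence literal), the grounded ElementaryMutations,
    their ProteinMutants (with the mutated sequence), and each
    MutationImpact.  Documents whose grounding failed yield a graph holding
    the document node only.
    """
    g = Graph()
    g.bind("mio", MIO)
    doc_id = result.document.doc_id
    # the document node carries an identifier literal only; rdf:type is
    # reserved for the seven mutation-impact concept classes
    doc_node = DATA[f"document-{doc_id}"]
    g.add((doc_node, MIO.hasIdentifier, Literal(doc_id)))

    grounding = result.grounding
    if grounding is None or not grounding.success:
        return g

    spec = _iri("specification", doc_id, grounding.accession or "")
    g.add((spec, RDF.type, MIO.MutationSpecification))
    g.add((spec, MIO.mentionedIn, doc_node))

    protein = _iri("protein", grounding.accession)
    g.add((protein, RDF.type, MIO.Protein))
    g.add((protein, MIO.hasAccession, Literal(grounding.accession)))
    g.add((protein, MIO.hasSequence, Literal(grounding.sequence)))
    g.add((spec, MIO.describesProtein, protein))

    series = _iri("series", doc_id, grounding.accession or "")
    g.add((series, RDF.type, MIO.MutationSeries))
    g.add((spec, MIO.hasMutationSeries, series))

    mutation_nodes: dict[str, URIRef] = {}
    for mention in sorted(grounding.grounded, key=lambda m: m.normalized):
        pos = grounding.grounded_position(mention)
        node = _iri("mutation", grounding.accession, mention.normalized)
        mutation_nodes[mention.normalized] = node
        g.add((node, RDF.type, MIO.ElementaryMutation))
        g.add((node, MIO.hasWildtypeResidue, Literal(mention.wildtype)))
        g.add((node, MIO.hasMutantResidue, Literal(mention.mutant)))
        g.add((node, MIO.hasPosition, Literal(pos, datatype=XSD.integer)))
        g.add((node, MIO.hasNormalizedForm, Literal(mention.normalized)))
        g.add((series, MIO.containsMutation, node))

        mutant = _iri("mutant", grounding.accession, mention.normalized)
        g.add((mutant, RDF.type, MIO.ProteinMutant))
        g.add((mutant, MIO.resultsFrom, node))
        g.add((mutant, MIO.variantOf, protein))
        g.add((mutant, MIO.hasSequence,
               Literal(_mutated(grounding.sequence, pos, mention.mutant))))

    for i, rel in enumerate(result.relations):
        prop = rel.impact.property
        impact_node = _iri("impact", doc_id, str(i), rel.mutation.normalized,
                           rel.impact.direction, prop.key)
        g.add((impact_node, RDF.type, MIO.MutationImpact))
        g.add((impact_node, MIO.hasDirection, MIO[rel.impact.direction]))
        g.add((impact_node, MIO.hasScore,
               Literal(round(rel.combined_score, 6), datatype=XSD.double)))
        g.add((spec, MIO.specifiesImpact, impact_node))
        g.add((impact_node, MIO.impactIsSpecifiedBy, spec))

        mut_node = mutation_nodes.get(rel.mutation.normalized)
        if mut_node is not None:
            g.add((impact_node, MIO.causedBy, mut_node))

        prop_node = _iri("property", prop.key)
        g.add((prop_node, RDF.type, MIO.ProteinProperty))
        g.add((prop_node, MIO.hasLabel, Literal(prop.head)))
        if prop.kind == "function" and prop.go_id:
            g.add((prop_node, MIO.groundedTo, _go_iri(prop.go_id)))
        elif prop.kind == "kinetic":
            g.add((prop_node, MIO.kineticVariable, Literal(prop.variable)))
        g.add((impact_node, MIO.affectsProperty, prop_node))
    return g


def mutant_sequences_for(graph: Graph, direction: str,
                         property_key: str) -> set[str]:
    """Mutant sequences whose mutation has the given direction of impact on
    the given property (GO id or kinetic variable name) — the query shape
    "which proteins were mutated so that there is a <direction> impact on
    <property>, and what are the mutant sequences"."""
    if property_key.startswith("GO:"):
        prop_clause = f"?prop mio:groundedTo <{_go_iri(property_key)}> ."
    else:
        prop_clause = f'?prop mio:kineticVariable "{property_key}" .'
    q = f"""
    PREFIX mio: <{MIO}>
    SELECT DISTINCT ?seq WHERE {{
        ?impact a mio:MutationImpact ;
                mio:hasDirection mio:{direction} ;
                mio:affectsProperty ?prop ;
                mio:causedBy ?mutation .
        {prop_clause}
        ?mutant mio:resultsFrom ?mutation ;
                mio:hasSequence ?seq .
    }}
    """
    return {str(row.seq) for row in graph.query(q)}


def standoff_json(result: "PipelineResult") -> str:
    """Human-readable standoff annotation dump for one document."""
    doc = result.document
    payload = {
        "doc_id": doc.doc_id,
        "annotations": [
            {"kind": a.kind, "span": [a.start, a.end],
             "surface": doc.text[a.start : a.end], "features": a.features}
            for a in doc.annotations
        ],
        "grounding": None,
        "relations": [],
    }
    if result.grounding is not None and result.grounding.success:
        gr = result.grounding
        payload["grounding"] = {
            "accession": gr.accession,
            "displacement": gr.displacement,
            "grounded": sorted(m.normalized for m in gr.grounded),
            "discarded": sorted(m.normalized for m in gr.discarded),
        }
    for rel in result.relations:
        prop = rel.impact.property
        payload["relations"].append(
            {
                "mutation": rel.mutation.normalized,
                "direction": rel.impact.direction,
                "property_kind": prop.kind,
                "property_key": prop.key,
                "go_id": prop.go_id,
                "similarity": prop.similarity,
                "impact_score": rel.impact.impact_score,
                "relation_score": rel.relation_score,
                "combined_score": rel.combined_score,
            }
        )
    return json.dumps(payload, indent=2, sort_keys=False)
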