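"""Precision/recall evaluation against gold-standard annotations.

Two tasks are scored, micro-averaged over documents:

* mutation grounding — a prediction (doc, wNm, accession, grounded
  position) is correct only on exact match of all four parts;
* mutant–impact relations — (doc, wNm, direction, property key) with the
  property compared by GO id when grounded and by variable name otherwise;
  every part must be correct.

Gold standards are unique-per-document sets; predictions are deduplicated
the same way, so duplicates never change counts.

Gold TSV columns: doc_id, record_type (mutation|relation), mutation,
accession, position, direction, property_key (unused fields empty).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

__all__ = ["GoldStandard", "Metrics", "grounding_metrics", "relation_metrics",
           "grounding_predictions", "relation_predictions",
           "load_gold_tsv", "write_gold_tsv"]

GOLD_COLUMNS = ("doc_id", "record_type", "mutation", "accession",
                "position", "direction", "property_key")


@dataclass
class GoldStandard:
    """Unique per-document gold mutations and relations."""

    mutations: set[tuple[str, str, str, int]] = field(default_factory=set)
    relations: set[tuple[str, str, str, str]] = field(default_factory=set)

    def add_mutation(self, doc_id: str, normalized: str, accession: str,
                     position: int) -> None:
        self.mutations.add((doc_id, normalized, accession, int(position)))

    def add_relation(self, doc_id: str, normalized: str, direction: str,
                     property_key: str) -> None:
        self.relations.add((doc_id, normalized, direction, property_key))


@dataclass(frozen=True)
class Metrics:
    precision: float
    recall: float
    n_predicted: int
    n_gold: int
    n_correct: int
    #: set when precision is the 0-by-convention of an empty prediction set
    precision_undefined: bool = False


def _prf(pred: set, gold: set) -> Metrics:
    if not gold:
        raise ValueError("empty gold standard: recall is undefined")
    correct = pred & gold
    if pred:
        precision, undefined = len(correct) / len(pred), False
    else:
        precision, undefined = 0.0, True
    return Metrics(
        precision=precision,
        recall=len(correct) / len(gold),
        n_predicted=len(pred),
        n_gold=len(gold),
        n_correct=len(correct),
        precision_undefined=undefined,
    )


def grounding_metrics(
    predictions: set[tuple[str, str, str, int]], gold: GoldStandard
) -> Metrics:
    """Precision = correctly grounded / all grounded; recall = correctly
    grounded / all uniquely mentioned gold mutations."""
    return _prf(set(predictions), gold.mutations)


def relation_metrics(
    predictions: set[tuple[str, str, str, str]], gold: GoldStandard
) -> Metrics:
    """Strict triple matching: property, direction and causal mutation must
    all be correct."""
    return _prf(set(predictions), gold.relations)


def grounding_predictions(results) -> set[tuple[str, str, str, int]]:
    """(doc, wNm, accession, grounded position) tuples from pipeline results."""
    preds = set()
    for result in results:
        grounding = result.grounding
        if grounding is None or not grounding.success:
            continue
        for mention in grounding.grounded:
            preds.add(
                (result.document.doc_id, mention.normalized,
                 grounding.accession, grounding.grounded_position(mention))
            )
    return preds


def relation_predictions(results) -> set[tuple[str, str, str, str]]:
    """(doc, wNm, direction, property key) tuples from pipeline results."""
    return {
        (result.document.doc_id, rel.mutation.normalized,
         rel.impact.direction, rel.impact.property.key)
        for result in results
        for rel in result.relations
    }


def load_gold_tsv(path: str | Path) -> GoldStandard:
    gold = GoldStandard()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            if row["record_type"] == "mutation":
                gold.add_mutation(row["doc_id"], row["mutation"],
                                  row["accession"], int(row["position"]))
            elif row["record_type"] == "relation":
                gold.add_relation(row["doc_id"], row["mutation"],
                                  row["direction"], row["property_key"])
            else:
                raise ValueError(f"unknown record_type: {row['record_type']!r}")
    return gold


def write_gold_tsv(gold: GoldStandard, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(GOLD_COLUMNS)
        for doc_id, normalized, accession, position in sorted(gold.mutations):
            writer.writerow([doc_id, "mutation", normalized, accession,
                             position, "", ""])
        for doc_id, normalized, direction, key in sorted(gold.relations):
            writer.writerow([doc_id, "relation", normalized, "", "",
                             direction, key])
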