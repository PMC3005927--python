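"""Gazetteers and mappings backing NER and grounding.

Three resources are served here:

* :class:`ProteinLexicon` — the name ↔ accession ↔ sequence ↔ GO-annotation
  mappings (the grounding database) loaded from a simplified Swiss-Prot-style
  flat file or built in memory.
* :class:`GOGraph` — the molecular-function slice of the Gene Ontology with
  synonyms and is_a ancestors, loaded from OBO via ``obonet``.
* :class:`DirectionLexicon` — five disjoint word lists (positive, negative,
  neutral, negation, non-neutral) seeded with curated directionality words
  and expanded with regular inflectional/nominal variants so matching can be
  token-exact with no stemming.

The simplified flat-file grammar uses the classic two-letter line codes::

    AC   P22643
    DE   Haloalkane dehalogenase
    GN   dhlA
    OS   Xanthobacter autotrophicus
    DR   GO; GO:0018786
    SQ   MINAIRTPDQR...
    //

Multiple DE/GN/OS/DR lines per record are allowed; SQ may span lines.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import obonet

log = logging.getLogger(__name__)

__all__ = [
    "ProteinLexicon",
    "GOGraph",
    "DirectionLexicon",
    "load_protein_lexicon",
    "load_go",
    "build_direction_lexicon",
    "DEFAULT_DIRECTION_SEEDS",
    "STOP_WORDS",
    "AMINO_ACIDS",
]

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Fixed English stop-word list used for noun-phrase preparation and GO
#: synonym comparison.  Deliberately small and frozen: determinism matters
#: more than coverage here.
STOP_WORDS = frozenset("""
a an and are as at be been being but by did do does for from had has have
in into is it its of on or over such that the their then there these this
to under upon was were which while with within
""".split())


@dataclass
class LexiconRecordError(Exception):
    line_number: int
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"line {self.line_number}: {self.message}"


@dataclass
class ProteinLexicon:
    """Name/accession/sequence/organism/GO mappings for grounding."""

    name_to_accessions: dict[str, set[str]] = field(default_factory=dict)
    #: per-name flags; multiword names are matched case-insensitively
    name_flags: dict[str, dict] = field(default_factory=dict)
    accession_to_sequence: dict[str, str] = field(default_factory=dict)
    accession_to_organism: dict[str, set[str]] = field(default_factory=dict)
    accession_to_go: dict[str, set[str]] = field(default_factory=dict)
    organism_names: set[str] = field(default_factory=set)

    def add_record(self, accession: str, names: list[str], sequence: str,
                   organisms: list[str] = (), go_ids: list[str] = (),
                   genes: list[str] = ()) -> None:
        sequence = sequence.upper()
        bad = set(sequence) - AMINO_ACIDS
        if bad:
            raise ValueError(f"invalid residue(s) {sorted(bad)} in {accession}")
        self.accession_to_sequence[accession] = sequence
        self.accession_to_organism.setdefault(accession, set()).update(organisms)
        self.accession_to_go.setdefault(accession, set()).update(go_ids)
        self.organism_names.update(organisms)
        for name, entity_kind in [(n, "Protein") for n in names] + \
                                 [(g, "Gene") for g in genes]:
            multiword = len(name.split()) >= 2
            self.name_to_accessions.setdefault(name, set()).add(accession)
            self.name_flags[name] = {
                "multiword": multiword,
                "case_sensitive": not multiword,
                "entity_kind": entity_kind,
            }

    def names(self) -> list[str]:
        return list(self.name_to_accessions)

    def sequence(self, accession: str) -> str:
        return self.accession_to_sequence[accession]

    def suffix_expansions(self, name: str) -> set[str]:
        """Accessions of lexicon names equal to *name* plus an alphanumeric
        suffix (poor-man's long-form/short-form co-reference)."""
        out: set[str] = set()
        for other, accs in self.name_to_accessions.items():
            if other != name and other.startswith(name) and \
                    re.fullmatch(r"[ -]?[A-Za-z0-9]+", other[len(name):]):
                out.update(accs)
        return out

    def to_flat_text(self) -> str:
        """Serialize back to the simplified flat-file format (round-trips)."""
        acc_names: dict[str, list[str]] = {a: [] for a in self.accession_to_sequence}
        for name, accs in self.name_to_accessions.items():
            for acc in accs:
                acc_names[acc].append(name)
        chunks = []
        for acc in sorted(self.accession_to_sequence):
            lines = [f"AC   {acc}"]
            for name in sorted(acc_names[acc]):
                code = "GN" if self.name_flags[name]["entity_kind"] == "Gene" else "DE"
                lines.append(f"{code}   {name}")
            for org in sorted(self.accession_to_organism.get(acc, ())):
                lines.append(f"OS   {org}")
            for go_id in sorted(self.accession_to_go.get(acc, ())):
                lines.append(f"DR   GO; {go_id}")
            seq = self.accession_to_sequence[acc]
            lines.append("SQ   " + seq)
            lines.append("//")
            chunks.append("\n".join(lines))
        return "\n".join(chunks) + ("\n" if chunks else "")


def load_protein_lexicon(path: str | Path) -> ProteinLexicon:
    """Parse the simplified Swiss-Prot-subset flat file at *path*.

    Records missing AC or SQ, or whose sequence contains a character outside
    the 20-letter amino-acid alphabet, are rejected with a logged error
    naming the line; the remainder of the file still loads.
    """
    lex = ProteinLexicon()
    text = Path(path).read_text(encoding="utf-8")
    record: dict = {"names": [], "genes": [], "organisms": [], "go": [], "seq": []}
    record_start = 1

    def flush(end_line: int) -> None:
        nonlocal record
        if not any((record["names"], record["genes"], record["seq"],
                    record.get("ac"))):
            return
        try:
            if "ac" not in record:
                raise ValueError("record missing AC line")
            if not record["seq"]:
                raise ValueError("record missing SQ line")
            lex.add_record(
                record["ac"], record["names"], "".join(record["seq"]),
                record["organisms"], record["go"], genes=record["genes"],
            )
        except ValueError as exc:
            log.error("rejected record ending at line %d: %s", end_line, exc)
        record = {"names": [], "genes": [], "organisms": [], "go": [], "seq": []}

    in_seq = False
    lines = text.splitlines()
    for lineno, line in enumerate(lines, start=1):
        if line.strip() == "//":
            flush(lineno)
            in_seq = False
            record_start = lineno + 1
            continue
        code, _, rest = line.partition("   ")
        rest = rest.strip()
        if code == "AC":
            record["ac"] = rest
            in_seq = False
        elif code == "DE":
            if rest:
                record["names"].append(rest)
            in_seq = False
        elif code == "GN":
            if rest:
                record["genes"].append(rest)
            in_seq = False
        elif code == "OS":
            if rest:
                record["organisms"].append(rest)
            in_seq = False
        elif code == "DR":
            m = re.search(r"GO[;:]\s*(GO:\d{7})", rest)
            if m:
                record["go"].append(m.group(1))
            in_seq = False
        elif code == "SQ":
            record["seq"].append(rest.replace(" ", ""))
            in_seq = True
        elif in_seq and line.strip():
            record["seq"].append(line.replace(" ", "").strip())
    flush(len(lines))
    _ = record_start  # kept for symmetric error reporting
    return lex


@dataclass
class GOGraph:
    """Molecular-function GO slice: id → name/synonyms/parents."""

    concepts: dict[str, dict] = field(default_factory=dict)

    def __contains__(self, go_id: str) -> bool:
        return go_id in self.concepts

    def name(self, go_id: str) -> str:
        return self.concepts[go_id]["name"]

    def synonyms(self, go_id: str) -> set[str]:
        return self.concepts[go_id]["synonyms"]

    def parents(self, go_id: str) -> set[str]:
        return self.concepts[go_id]["parents"]

    def ancestors(self, go_id: str) -> set[str]:
        """All is_a ancestors (transitive closure, excluding *go_id*)."""
        seen: set[str] = set()
        stack = list(self.parents(go_id))
        while stack:
            cur = stack.pop()
            if cur in seen or cur not in self.concepts:
                continue
            seen.add(cur)
            stack.extend(self.parents(cur))
        return seen

    def validate_acyclic(self) -> None:
        g = nx.DiGraph(
            (child, parent)
            for child, meta in self.concepts.items()
            for parent in meta["parents"]
            if parent in self.concepts
        )
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            return
        raise ValueError(f"is_a cycle among GO terms: {cycle}")


def load_go(path) -> GOGraph:
    """Load the molecular_function namespace of an OBO file.

    *path* may be a filesystem path or an open text handle.  Obsolete terms
    are dropped, synonyms include the primary name, and the retained is_a
    graph is checked to be acyclic.
    """
    net = obonet.read_obo(path if hasattr(path, "read") else str(path))
    go = GOGraph()
    for node, data in net.nodes(data=True):
        if data.get("namespace") != "molecular_function":
            continue
        if data.get("is_obsolete") == "true":
            continue
        synonyms = {data["name"]} if "name" in data else set()
        for syn in data.get("synonym", ()):
            m = re.match(r'"(.*?)"', syn)
            if m:
                synonyms.add(m.group(1))
        go.concepts[node] = {
            "name": data.get("name", node),
            "synonyms": synonyms,
            "parents": set(data.get("is_a", ())),
        }
    go.validate_acyclic()
    return go


#: Curated directionality seed words, one list per category.
DEFAULT_DIRECTION_SEEDS: dict[str, tuple[str, ...]] = {
    "positive": ("increase", "enhance", "higher", "improve"),
    "negative": ("abolish", "decrease", "reduce", "lower", "inhibit",
                 "impair", "loose", "defect", "disrupt", "diminish"),
    "neutral": ("identical", "similar", "full"),
    "negation": ("without", "no", "not"),
    "non_neutral": ("affect", "effect", "alter", "differ"),
}

#: Irregular nominalizations the suffix rules cannot derive.
_EXTRA_FORMS = {
    "alter": ("alteration", "alterations"),
    "differ": ("difference", "differences", "different"),
    "loose": ("loss", "lost"),
}

CATEGORY_ORDER = ("positive", "negative", "neutral", "negation", "non_neutral")


def _inflect(word: str) -> list[str]:
    """Deterministic inflectional/nominal variants of a seed word."""
    forms = [word]
    if word.endswith(("s", "sh", "ch", "x")):
        forms.append(word + "es")
    else:
        forms.append(word + "s")
    if word.endswith("e"):
        forms.append(word + "d")
        forms.append(word[:-1] + "ing")
    else:
        forms.append(word + "ed")
        forms.append(word + "ing")
    # nominalizations, only where orthographically regular
    if word.endswith("uce"):
        forms.append(word[:-3] + "uction")   # reduce -> reduction
        forms.append(word[:-3] + "uctions")
    elif word.endswith("t") and not word.endswith("ct"):
        forms.append(word + "ion")           # inhibit -> inhibition
        forms.append(word + "ions")
    forms.extend(_EXTRA_FORMS.get(word, ()))
    return forms


@dataclass
class DirectionLexicon:
    """Word → category map; categories partition the vocabulary."""

    word_to_category: dict[str, str] = field(default_factory=dict)

    def category(self, surface: str) -> str | None:
        return self.word_to_category.get(surface.lower())

    def words(self, category: str) -> set[str]:
        return {w for w, c in self.word_to_category.items() if c == category}


def build_direction_lexicon(
    seed_lists: dict[str, tuple[str, ...]] | None = None,
) -> DirectionLexicon:
    """Expand the five seed lists with inflected/nominal variants.

    A form derivable from seeds in two categories keeps the category listed
    first in :data:`CATEGORY_ORDER` (first-category-wins, logged).
    """
    seeds = seed_lists if seed_lists is not None else DEFAULT_DIRECTION_SEEDS
    dlex = DirectionLexicon()
    for category in CATEGORY_ORDER:
        for seed in seeds.get(category, ()):
            for form in _inflect(seed.lower()):
                prev = dlex.word_to_category.get(form)
                if prev is None:
                    dlex.word_to_category[form] = category
                elif prev != category:
                    log.warning(
                        "direction word %r seeded in %s and %s; keeping %s",
                        form, prev, category, prev,
                    )
    return dlex
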