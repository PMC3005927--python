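"""Named entity recognition: mutations, proteins/genes/organisms,
protein properties (function noun phrases + kinetic variables), and
directionality words.

Mutation detection covers three pattern families — one-letter wNm
(``W125F``), three-letter wNm (``Trp125Phe``), and the natural-language
"replacement of Trp-125 with arginine" frame — which between them cover the
mention forms that matter for protein-level point mutations.  A
word-boundary guard rejects matches embedded in longer alphanumeric
identifiers (strain names like ``GJ10``, plasmids, cell lines).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .lexicons import DirectionLexicon, ProteinLexicon, STOP_WORDS
from .textmodel import Annotation, Document, Sentence

__all__ = [
    "MutationMention",
    "PropertyMention",
    "DirectionTerm",
    "find_mutation_mentions",
    "normalize_mutation",
    "find_entity_mentions",
    "find_property_mentions",
    "find_direction_terms",
    "annotate_document",
]

AA1 = "ACDEFGHIKLMNPQRSTVWY"

THREE_TO_ONE = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
}

FULL_TO_ONE = {
    "alanine": "A", "arginine": "R", "asparagine": "N",
    "aspartate": "D", "aspartic acid": "D", "cysteine": "C",
    "glutamine": "Q", "glutamate": "E", "glutamic acid": "E",
    "glycine": "G", "histidine": "H", "isoleucine": "I", "leucine": "L",
    "lysine": "K", "methionine": "M", "phenylalanine": "F", "proline": "P",
    "serine": "S", "threonine": "T", "tryptophan": "W", "tyrosine": "Y",
    "valine": "V",
}

_RESIDUE_CODES = {**{k: v for k, v in THREE_TO_ONE.items()},
                  **{k.lower(): v for k, v in THREE_TO_ONE.items()},
                  **{k.upper(): v for k, v in THREE_TO_ONE.items()},
                  **FULL_TO_ONE,
                  **{a: a for a in AA1}}

_GUARD_L = r"(?<![A-Za-z0-9])"
_GUARD_R = r"(?![A-Za-z0-9])"

_ONE_LETTER = re.compile(_GUARD_L + rf"([{AA1}])(\d+)([{AA1}])" + _GUARD_R)
_THREE = "|".join(THREE_TO_ONE)
_THREE_LETTER = re.compile(
    _GUARD_L + rf"({_THREE})(\d+)({_THREE})" + _GUARD_R, re.IGNORECASE
)
_FULL_NAMES = "|".join(sorted(FULL_TO_ONE, key=len, reverse=True))
_FRAME_RESIDUE = re.compile(
    _GUARD_L + rf"({_THREE})-?(\d+)" + _GUARD_R, re.IGNORECASE
)
_FRAME = re.compile(
    rf"\b(?:replacement|substitution|mutation)s?\s+of\s+"
    rf"((?:({_THREE})-?\d+)(?:(?:,\s*|\s+or\s+|\s+and\s+)(?:{_THREE})-?\d+)*)"
    rf"\s+(?:with|to|by|into)\s+({_FULL_NAMES})\b",
    re.IGNORECASE,
)


@dataclass(frozen=True)
class MutationMention:
    """A normalized protein point mutation anchored to a text span."""

    wildtype: str
    position: int
    mutant: str
    start: int = 0
    end: int = 0

    def __post_init__(self) -> None:
        if self.wildtype == self.mutant:
            raise ValueError("wildtype and mutant residues are identical")
        if self.position < 1:
            raise ValueError("positions are 1-based")

    @property
    def normalized(self) -> str:
        return f"{self.wildtype}{self.position}{self.mutant}"

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


def normalize_mutation(raw: str, span: tuple[int, int] = (0, 0)) -> MutationMention:
    """Normalize a raw mutation string (``Trp125Phe``, ``W125F``,
    ``Trp-125-Phe``) into wNm form.

    Raises :class:`ValueError` for unknown residue codes, identical
    wildtype/mutant residues, or position 0 — the mention is rejected.
    """
    m = re.fullmatch(r"([A-Za-z]+)-?(\d+)-?([A-Za-z]+)", raw.strip())
    if not m:
        raise ValueError(f"unparseable mutation mention: {raw!r}")
    wt_raw, pos, mut_raw = m.groups()
    wt = _RESIDUE_CODES.get(wt_raw) or _RESIDUE_CODES.get(wt_raw.lower())
    mut = _RESIDUE_CODES.get(mut_raw) or _RESIDUE_CODES.get(mut_raw.lower())
    if wt is None or mut is None:
        raise ValueError(f"unknown residue code in {raw!r}")
    return MutationMention(wt, int(pos), mut, span[0], span[1])


def find_mutation_mentions(doc: Document) -> list[MutationMention]:
    """All point-mutation mentions in document order.

    Precedence: one-letter wNm, then three-letter wNm, then the
    natural-language replacement frame; later families never overlap a span
    already claimed.  Series joined by ``+`` fall out as individual matches
    (``+`` is not a word character, so the boundary guard admits them).
    """
    text = doc.text
    mentions: list[MutationMention] = []
    claimed: list[tuple[int, int]] = []

    def free(a: int, b: int) -> bool:
        return all(b <= s or a >= e for s, e in claimed)

    for m in _ONE_LETTER.finditer(text):
        wt, pos, mut = m.group(1), int(m.group(2)), m.group(3)
        if wt != mut and pos >= 1:
            mentions.append(MutationMention(wt, pos, mut, m.start(), m.end()))
            claimed.append(m.span())

    for m in _THREE_LETTER.finditer(text):
        if not free(*m.span()):
            continue
        try:
            mentions.append(
                normalize_mutation(m.group(0), m.span())
            )
            claimed.append(m.span())
        except ValueError:
            continue

    for frame in _FRAME.finditer(text):
        mutant_code = FULL_TO_ONE[frame.group(3).lower()]
        list_start = frame.start(1)
        for res in _FRAME_RESIDUE.finditer(frame.group(1)):
            a = list_start + res.start()
            b = list_start + res.end()
            if not free(a, b):
                continue
            try:
                wt = THREE_TO_ONE[res.group(1).capitalize()]
                mentions.append(
                    MutationMention(wt, int(res.group(2)), mutant_code, a, b)
                )
                claimed.append((a, b))
            except ValueError:
                continue

    mentions.sort(key=lambda mm: mm.start)
    return mentions


def find_entity_mentions(doc: Document, lex: ProteinLexicon) -> list[Annotation]:
    """Gazetteer matches for protein, gene and organism names.

    Multiword protein/gene names and all organism names match
    case-insensitively; single-word names case-sensitively.  Overlaps within
    a kind resolve longest-match-wins, ties to the leftmost.
    """
    candidates: list[tuple[int, int, str, str]] = []
    for name, flags in lex.name_flags.items():
        pattern = re.escape(name).replace(r"\ ", r"\s+")
        rx = re.compile(
            _GUARD_L + pattern + _GUARD_R,
            0 if flags["case_sensitive"] else re.IGNORECASE,
        )
        for m in rx.finditer(doc.text):
            candidates.append((m.start(), m.end(), flags["entity_kind"], name))
    for org in lex.organism_names:
        rx = re.compile(
            _GUARD_L + re.escape(org).replace(r"\ ", r"\s+") + _GUARD_R,
            re.IGNORECASE,
        )
        for m in rx.finditer(doc.text):
            candidates.append((m.start(), m.end(), "Organism", org))

    annotations: list[Annotation] = []
    for kind in ("Protein", "Gene", "Organism"):
        picks: list[tuple[int, int, str]] = []
        for start, end, k, name in sorted(
            (c for c in candidates if c[2] == kind),
            key=lambda c: (c[0], -(c[1] - c[0])),
        ):
            if all(end <= s or start >= e for s, e, _ in picks):
                picks.append((start, end, name))
        for start, end, name in picks:
            features = {"name": name}
            if kind != "Organism":
                features["accessions"] = sorted(lex.name_to_accessions[name])
            annotations.append(Annotation(kind, start, end, features))
    annotations.sort(key=lambda a: (a.start, a.kind))
    return annotations


HEAD_NOUNS = frozenset({"activity", "binding", "affinity", "specificity"})

_KM_PAT = r"[Kk](?:_?[Mm]\b|\([Mm]\))"
_KCAT_PAT = r"[Kk](?:_?cat\b|\(cat\))"
_COMPOUND = re.compile(rf"({_KCAT_PAT})\s*/\s*({_KM_PAT})")
_KM = re.compile(_KM_PAT)
_KCAT = re.compile(_KCAT_PAT)
_MATH_CHARS = set("=+×*^<>~")


@dataclass
class PropertyMention:
    """A protein property: a function noun phrase or a kinetic variable."""

    kind: str                       # "function" | "kinetic"
    start: int
    end: int
    head: str
    np_tokens: tuple[str, ...] = ()
    variable: str | None = None     # KM | KCAT | KCAT_OVER_KM
    sentence_index: int = 0
    #: filled by GO grounding when applicable
    go_id: str | None = None
    similarity: float | None = None

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def key(self) -> str:
        """Comparison key: GO id when grounded, else variable or head noun."""
        if self.kind == "kinetic":
            return self.variable or self.head
        return self.go_id or self.head.lower()


def _is_content_token(surface: str, dlex: DirectionLexicon | None) -> bool:
    if not re.fullmatch(r"[A-Za-z][A-Za-z-]*", surface):
        return False
    if surface.lower() in STOP_WORDS:
        return False
    if dlex is not None and dlex.category(surface) is not None:
        return False
    return True


def _kinetic_ok(text: str, start: int, end: int) -> bool:
    """Reject variables embedded in a larger expression (``Km=``, ``2Km``)."""
    before = text[start - 1] if start > 0 else " "
    after = text[end] if end < len(text) else " "
    if before.isalnum() or before in _MATH_CHARS or before in "/_":
        return False
    if after.isalnum() or after in _MATH_CHARS or after in "/_":
        return False
    return True


def find_property_mentions(
    sentence: Sentence, text: str, dlex: DirectionLexicon | None = None
) -> list[PropertyMention]:
    """Function noun phrases (head ∈ activity/binding/affinity/specificity)
    and kinetic variables (K_M, k_cat, k_cat/K_M) in one sentence.

    The function noun phrase is the maximal contiguous run of content words
    (no stop words, punctuation, digits or direction words) ending at the
    head noun.  Kinetic variants match longest-first so the compound
    k_cat/K_M suppresses its parts; variables fused to math characters are
    rejected.
    """
    out: list[PropertyMention] = []

    tokens = sentence.tokens
    for i, tok in enumerate(tokens):
        if tok.surface.lower() not in HEAD_NOUNS:
            continue
        j = i
        while j > 0 and _is_content_token(tokens[j - 1].surface, dlex) \
                and tokens[j - 1].surface.lower() not in HEAD_NOUNS:
            j -= 1
        np = tokens[j : i + 1]
        out.append(
            PropertyMention(
                kind="function",
                start=np[0].start,
                end=np[-1].end,
                head=tok.surface.lower(),
                np_tokens=tuple(t.surface for t in np),
                sentence_index=sentence.index,
            )
        )

    claimed: list[tuple[int, int]] = []
    sent_text = text
    lo, hi = sentence.start, sentence.end
    for rx, var in ((_COMPOUND, "KCAT_OVER_KM"), (_KCAT, "KCAT"), (_KM, "KM")):
        for m in rx.finditer(sent_text, lo, hi):
            if any(m.end() > s and m.start() < e for s, e in claimed):
                continue
            if not _kinetic_ok(sent_text, m.start(), m.end()):
                continue
            claimed.append(m.span())
            out.append(
                PropertyMention(
                    kind="kinetic",
                    start=m.start(),
                    end=m.end(),
                    head=m.group(0),
                    variable=var,
                    sentence_index=sentence.index,
                )
            )
    out.sort(key=lambda p: p.start)
    return out


@dataclass(frozen=True)
class DirectionTerm:
    start: int
    end: int
    surface: str
    category: str

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


def find_direction_terms(sentence: Sentence, dlex: DirectionLexicon) -> list[DirectionTerm]:
    """Whole-token, case-insensitive matches against the direction lexicon."""
    out = []
    for tok in sentence.tokens:
        category = dlex.category(tok.surface)
        if category is not None:
            out.append(DirectionTerm(tok.start, tok.end, tok.surface, category))
    return out


def annotate_document(doc: Document, lex: ProteinLexicon,
                      dlex: DirectionLexicon) -> None:
    """Run every annotator and write standoff annotations into *doc*."""
    for mm in find_mutation_mentions(doc):
        doc.annotations.append(
            Annotation("Mutation", mm.start, mm.end,
                       {"normalized": mm.normalized, "wildtype": mm.wildtype,
                        "position": mm.position, "mutant": mm.mutant})
        )
    doc.annotations.extend(find_entity_mentions(doc, lex))
    for sent in doc.sentences:
        for pm in find_property_mentions(sent, doc.text, dlex):
            feats = {"head": pm.head, "np_tokens": list(pm.np_tokens)}
            if pm.variable:
                feats["variable"] = pm.variable
            kind = "KineticVariable" if pm.kind == "kinetic" else "FunctionProperty"
            doc.annotations.append(Annotation(kind, pm.start, pm.end, feats))
        for dt in find_direction_terms(sent, dlex):
            doc.annotations.append(
                Annotation("Direction", dt.start, dt.end,
                           {"surface": dt.surface, "category": dt.category})
            )
    doc.annotations.sort(key=lambda a: (a.start, a.kind))
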