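"""Shared document model: tokenization, sentence splitting, standoff annotations.

All downstream annotators (NER, grounding, relation detection) operate on a
:class:`Document` built by :func:`build_document`.  Character coordinates are
0-based half-open offsets into the document text; amino-acid sequence
positions elsewhere in the package are 1-based, following the biological
convention used by wNm mutation mentions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator

__all__ = [
    "Token",
    "Sentence",
    "Annotation",
    "Document",
    "tokenize",
    "split_sentences",
    "build_document",
    "DEFAULT_PROTECTED_ABBREVIATIONS",
]

#: Punctuation detached from the edges of whitespace-delimited chunks.
#: '/' and '-' are deliberately absent so "kcat/Km" and "30-40%" survive
#: as single tokens (kinetic-variable and percentage mentions need them).
_DETACH = ".,;:()[]"

#: Abbreviations that never terminate a sentence.  The splitter is otherwise
#: purely orthographic, so this list is the only linguistic knowledge it has.
DEFAULT_PROTECTED_ABBREVIATIONS = (
    "e.g.", "i.e.", "et al.", "cf.", "vs.", "ca.", "Fig.", "fig.",
    "Figs.", "Ref.", "Eq.", "No.", "approx.",
)


@dataclass(frozen=True)
class Token:
    """A minimal text token anchored to character offsets."""

    start: int
    end: int
    surface: str
    #: True for the first token emitted from a whitespace-delimited chunk.
    #: Token-distance scoring counts only these ("space tokens"), so detached
    #: punctuation never inflates a distance.
    is_space_delimited: bool = True

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def is_punctuation(self) -> bool:
        return all(ch in _DETACH for ch in self.surface)


@dataclass(frozen=True)
class Sentence:
    start: int
    end: int
    index: int
    tokens: tuple[Token, ...] = ()

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


#: Closed set of annotation kinds written into the standoff model.
ANNOTATION_KINDS = frozenset(
    {"Mutation", "Protein", "Gene", "Organism", "FunctionProperty",
     "KineticVariable", "Direction"}
)


@dataclass
class Annotation:
    kind: str
    start: int
    end: int
    features: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ANNOTATION_KINDS:
            raise ValueError(f"unknown annotation kind: {self.kind!r}")

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class Document:
    doc_id: str
    text: str
    sentences: tuple[Sentence, ...] = ()
    annotations: list[Annotation] = field(default_factory=list)

    def sentence_of(self, offset: int) -> Sentence | None:
        """Sentence whose span contains *offset*, or the nearest preceding one."""
        best = None
        for sent in self.sentences:
            if sent.start <= offset < sent.end:
                return sent
            if sent.start <= offset:
                best = sent
        return best

    def annotations_of(self, kind: str) -> list[Annotation]:
        return [a for a in self.annotations if a.kind == kind]


def tokenize(text: str, base: int = 0) -> list[Token]:
    """Split *text* on whitespace, detaching edge punctuation ``.,;:()[]``.

    Every non-whitespace character belongs to exactly one token.  Offsets are
    shifted by *base* so sentence-local tokenization can carry document
    coordinates.
    """
    tokens: list[Token] = []
    for m in re.finditer(r"\S+", text):
        chunk, start = m.group(), m.start()
        # peel leading punctuation
        lead = 0
        while lead < len(chunk) and chunk[lead] in _DETACH:
            lead += 1
        trail = len(chunk)
        while trail > lead and chunk[trail - 1] in _DETACH:
            trail -= 1
        pieces: list[tuple[int, int]] = []
        pieces.extend((i, i + 1) for i in range(0, lead))
        if trail > lead:
            pieces.append((lead, trail))
        pieces.extend((i, i + 1) for i in range(trail, len(chunk)))
        for k, (a, b) in enumerate(pieces):
            tokens.append(
                Token(base + start + a, base + start + b, chunk[a:b],
                      is_space_delimited=(k == 0))
            )
    return tokens


def _protected_at(text: str, dot: int, protected: Iterable[str]) -> bool:
    for abbr in protected:
        n = len(abbr)
        if dot - n + 1 >= 0 and text[dot - n + 1 : dot + 1] == abbr:
            before = text[dot - n] if dot - n >= 0 else " "
            if not before.isalnum():
                return True
    return False


def _boundaries(text: str, protected: Iterable[str]) -> Iterator[int]:
    for m in re.finditer(r"[.?!]+", text):
        end = m.end()
        rest = text[end:]
        ws = re.match(r"\s+", rest)
        if not ws:
            continue
        nxt = end + ws.end()
        if nxt >= len(text):
            continue
        if not (text[nxt].isupper() or text[nxt].isdigit()):
            continue
        if text[m.end() - 1] == "." and _protected_at(text, m.end() - 1, protected):
            continue
        yield end


def split_sentences(
    text: str,
    protected: Iterable[str] = DEFAULT_PROTECTED_ABBREVIATIONS,
) -> list[Sentence]:
    """Split *text* at ``[.?!]`` + whitespace + capital/digit boundaries.

    Protected abbreviations never split; decimal numbers are safe because a
    boundary requires whitespace directly after the punctuation.  Sentence
    spans are trimmed to non-whitespace extents and cover all non-whitespace
    text.
    """
    cuts = [0, *_boundaries(text, tuple(protected)), len(text)]
    sentences: list[Sentence] = []
    for raw_start, raw_end in zip(cuts, cuts[1:]):
        seg = text[raw_start:raw_end]
        stripped = seg.strip()
        if not stripped:
            continue
        start = raw_start + (len(seg) - len(seg.lstrip()))
        end = start + len(stripped)
        sentences.append(Sentence(start, end, index=len(sentences)))
    return sentences


def build_document(doc_id: str, text: str,
                   protected: Iterable[str] = DEFAULT_PROTECTED_ABBREVIATIONS,
                   ) -> Document:
    """Tokenize and sentence-split *text* into a :class:`Document`."""
    sentences = []
    for sent in split_sentences(text, protected):
        toks = tuple(tokenize(text[sent.start : sent.end], base=sent.start))
        sentences.append(Sentence(sent.start, sent.end, sent.index, toks))
    return Document(doc_id=doc_id, text=text, sentences=tuple(sentences))


def space_tokens_between(sentence: Sentence, span_a: tuple[int, int],
                         span_b: tuple[int, int]) -> int:
    """Number of whitespace-delimited, non-punctuation tokens strictly
    between two character spans (order-insensitive)."""
    lo = min(span_a[1], span_b[1])
    hi = max(span_a[0], span_b[0])
    return sum(
        1
        for t in sentence.tokens
        if t.start >= lo and t.end <= hi
        and t.is_space_delimited and not t.is_punctuation
    )
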