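"""Snowball English ("Porter2") stemmer.

Used to normalize protein-function noun phrases and Gene Ontology synonyms
before set comparison.  This is a self-contained implementation of the
published Snowball English algorithm: regions R1/R2, the exceptional forms,
and steps 0 through 5, with the gener-/commun-/arsen- R1 adjustment.
Only lowercase ASCII input is expected; callers lowercase first.
"""

from __future__ import annotations

__all__ = ["stem"]

_VOWELS = "aeiouy"
_DOUBLES = ("bb", "dd", "ff", "gg", "mm", "nn", "pp", "rr", "tt")
_LI_ENDING = "cdeghkmnrt"

_EXCEPTIONS1 = {
    "skis": "ski", "skies": "sky", "dying": "die", "lying": "lie",
    "tying": "tie", "idly": "idl", "gently": "gentl", "ugly": "ugli",
    "early": "earli", "only": "onli", "singly": "singl",
    "sky": "sky", "news": "news", "howe": "howe", "atlas": "atlas",
    "cosmos": "cosmos", "bias": "bias", "andes": "andes",
}
_EXCEPTIONS2 = frozenset(
    {"inning", "outing", "canning", "herring", "earring",
     "proceed", "exceed", "succeed"}
)


def _is_vowel(word: str, i: int) -> bool:
    return word[i] in _VOWELS


def _regions(word: str) -> tuple[int, int]:
    """Start offsets of R1 and R2 (len(word) when a region is empty)."""
    n = len(word)
    r1 = n
    for prefix in ("gener", "commun", "arsen"):
        if word.startswith(prefix):
            r1 = len(prefix)
            break
    else:
        for i in range(n - 1):
            if _is_vowel(word, i) and not _is_vowel(word, i + 1):
                r1 = i + 2
                break
    r2 = n
    for i in range(r1, n - 1):
        if _is_vowel(word, i) and not _is_vowel(word, i + 1):
            r2 = i + 2
            break
    return r1, r2


def _short_syllable_at(word: str, i: int) -> bool:
    """True when a short syllable ends with the vowel at index *i*."""
    n = len(word)
    if i == 0:
        return n >= 2 and _is_vowel(word, 0) and not _is_vowel(word, 1)
    return (
        0 < i < n - 1
        and _is_vowel(word, i)
        and not _is_vowel(word, i + 1)
        and word[i + 1] not in "wxY"
        and not _is_vowel(word, i - 1)
    )


def _is_short(word: str, r1: int) -> bool:
    return r1 >= len(word) and len(word) >= 2 and _short_syllable_at(word, len(word) - 2)


def _has_vowel(segment: str) -> bool:
    return any(ch in _VOWELS for ch in segment)


def stem(word: str) -> str:  # noqa: C901 - faithful transcription of the algorithm
    word = word.lower()
    if len(word) <= 2:
        return word
    if word.startswith("'"):
        word = word[1:]
    if word in _EXCEPTIONS1:
        return _EXCEPTIONS1[word]

    # mark consonantal y as Y
    if word.startswith("y"):
        word = "Y" + word[1:]
    word = "".join(
        "Y" if ch == "y" and i > 0 and word[i - 1] in _VOWELS else ch
        for i, ch in enumerate(word)
    )

    r1, r2 = _regions(word)

    # step 0 — apostrophe suffixes
    for suf in ("'s'", "'s", "'"):
        if word.endswith(suf):
            word = word[: -len(suf)]
            break

    # step 1a
    if word.endswith("sses"):
        word = word[:-2]
    elif word.endswith(("ied", "ies")):
        word = word[:-3] + ("i" if len(word) > 4 else "ie")
    elif word.endswith(("us", "ss")):
        pass
    elif word.endswith("s") and _has_vowel(word[:-2]):
        word = word[:-1]

    if word in _EXCEPTIONS2:
        return word

    # step 1b
    step1b_done = False
    for suf, rep in (("eedly", "ee"), ("eed", "ee")):
        if word.endswith(suf):
            if len(word) - len(suf) >= r1:
                word = word[: -len(suf)] + rep
            step1b_done = True
            break
    if not step1b_done:
        for suf in ("edly", "ingly", "ed", "ing"):
            if word.endswith(suf) and _has_vowel(word[: -len(suf)]):
                word = word[: -len(suf)]
                if word.endswith(("at", "bl", "iz")):
                    word += "e"
                elif word.endswith(_DOUBLES):
                    word = word[:-1]
                elif _is_short(word, r1):
                    word += "e"
                break

    # step 1c
    if (
        len(word) > 2
        and word[-1] in "yY"
        and word[-2] not in _VOWELS
    ):
        word = word[:-1] + "i"

    # step 2 (longest suffix first)
    step2 = (
        ("ization", "ize"), ("ational", "ate"), ("fulness", "ful"),
        ("ousness", "ous"), ("iveness", "ive"), ("tional", "tion"),
        ("biliti", "ble"), ("lessli", "less"), ("entli", "ent"),
        ("ation", "ate"), ("alism", "al"), ("aliti", "al"),
        ("ousli", "ous"), ("iviti", "ive"), ("fulli", "ful"),
        ("enci", "ence"), ("anci", "ance"), ("abli", "able"),
        ("izer", "ize"), ("ator", "ate"), ("alli", "al"),
        ("bli", "ble"), ("ogi", None), ("li", None),
    )
    for suf, rep in step2:
        if word.endswith(suf):
            if len(word) - len(suf) >= r1:
                if suf == "ogi":
                    if word.endswith("logi"):
                        word = word[:-1]
                elif suf == "li":
                    if len(word) >= 3 and word[-3] in _LI_ENDING:
                        word = word[:-2]
                else:
                    word = word[: -len(suf)] + rep
            break

    # step 3
    step3 = (
        ("ational", "ate"), ("tional", "tion"), ("alize", "al"),
        ("icate", "ic"), ("iciti", "ic"), ("ative", ""),
        ("ical", "ic"), ("ness", ""), ("ful", ""),
    )
    for suf, rep in step3:
        if word.endswith(suf):
            if len(word) - len(suf) >= r1:
                if suf == "ative":
                    if len(word) - len(suf) >= r2:
                        word = word[: -len(suf)]
                else:
                    word = word[: -len(suf)] + rep
            break

    # step 4
    step4 = (
        "ement", "ance", "ence", "able", "ible", "ment",
        "ant", "ate", "ent", "ism", "iti", "ive", "ize", "ous",
        "ion", "al", "er", "ic",
    )
    for suf in step4:
        if word.endswith(suf):
            if len(word) - len(suf) >= r2:
                if suf == "ion":
                    if len(word) >= 4 and word[-4] in "st":
                        word = word[:-3]
                else:
                    word = word[: -len(suf)]
            break

    # step 5
    if word.endswith("e"):
        base = len(word) - 1
        if base >= r2 or (
            base >= r1 and not (len(word) >= 2 and _short_syllable_at(word, len(word) - 3))
        ):
            word = word[:-1]
    elif word.endswith("ll") and len(word) - 1 >= r2:
        word = word[:-1]

    return word.replace("Y", "y")
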