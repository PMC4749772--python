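"""Per-token feature extraction for sequence labeling.

25 features in 7 groups per token: adjacency to whitespace (3), the
surrounding tokens (2), character n-gram prefixes/suffixes for n=1..4 (8),
word shapes (3), orthographic flags (7), token length (1) and a chemical
affix flag (1). Values are plain strings, ints and bools so the vectors
export cleanly to the tab-separated files classic CRF/SVM toolkits consume.

Feature extraction looks only at the source text, the token offsets and
the affix lexicon — never at gold labels.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Union

from .lexicon import Lexicon
from .tokenizer import TokenSequence

PAD = "<PAD>"

FeatureValue = Union[str, int, bool]

#: group name -> ordered feature names; the canonical column order.
FEATURE_GROUPS: dict[str, tuple[str, ...]] = {
    "space": ("has_right_space", "has_left_space", "has_both_spaces"),
    "context": ("prev_token", "next_token"),
    "ngram_affix": (
        "prefix_1", "prefix_2", "prefix_3", "prefix_4",
        "suffix_1", "suffix_2", "suffix_3", "suffix_4",
    ),
    "word_shape": ("word_shape", "digital_shape", "summarized_shape"),
    "orthographic": (
        "is_all_uppercase", "has_slash", "has_punctuation", "has_real_number",
        "starts_with_digit", "starts_with_uppercase", "uppercase_gt2",
    ),
    "length": ("token_length",),
    "chem_affix": ("has_chem_affix",),
}

FEATURE_NAMES: tuple[str, ...] = tuple(
    name for group in FEATURE_GROUPS.values() for name in group
)
assert len(FEATURE_NAMES) == 25 and len(FEATURE_GROUPS) == 7

#: feature name -> its group.
GROUP_OF: dict[str, str] = {
    name: group for group, names in FEATURE_GROUPS.items() for name in names
}


@dataclass(frozen=True)
class FeatureVector:
    """Exactly the 25 named features of one token in context."""

    values: dict[str, FeatureValue]

    def __post_init__(self) -> None:
        if tuple(self.values) != FEATURE_NAMES:
            raise ValueError("feature vector must contain exactly the 25 named features")

    def __getitem__(self, name: str) -> FeatureValue:
        return self.values[name]

    def group(self, group: str) -> dict[str, FeatureValue]:
        return {n: self.values[n] for n in FEATURE_GROUPS[group]}


def space_features(seq: TokenSequence, i: int) -> tuple[bool, bool, bool]:
    """(has_right_space, has_left_space, has_both); document edges count as space."""
    t = seq[i]
    text = seq.source_text
    left = t.start == 0 or text[t.start - 1].isspace()
    right = t.end == len(text) or text[t.end].isspace()
    return right, left, right and left


def context_words(seq: TokenSequence, i: int) -> tuple[str, str]:
    """Surfaces of the previous and next token; PAD at document edges."""
    prev = seq[i - 1].surface if i > 0 else PAD
    nxt = seq[i + 1].surface if i + 1 < len(seq) else PAD
    return prev, nxt


def ngram_affixes(surface: str) -> tuple[str, ...]:
    """Prefixes then suffixes for n=1..4; short tokens repeat the whole surface."""
    pre = tuple(surface[: min(n, len(surface))] for n in range(1, 5))
    suf = tuple(surface[-min(n, len(surface)) :] for n in range(1, 5))
    return pre + suf


def _char_class(c: str) -> str:
    if c.isascii() and c.isupper():
        return "A"
    if c.isascii() and c.islower():
        return "a"
    if c.isascii() and c.isdigit():
        return "0"
    if c.isalpha():  # non-ASCII letter (Greek etc.)
        return "g"
    return "p"


def word_shapes(surface: str) -> tuple[str, str, str]:
    """(count shape, digital shape, summarized shape).

    Count shape tallies uppercase/lowercase/digit/punctuation/Greek
    characters as ``U:a|L:b|D:c|P:d|G:e``; the digital shape maps each
    character to its class (A a 0 p g); the summarized shape collapses
    runs of equal classes.
    """
    classes = [_char_class(c) for c in surface]
    counts = {k: 0 for k in "Aa0pg"}
    for c in classes:
        counts[c] += 1
    count_shape = (
        f"U:{counts['A']}|L:{counts['a']}|D:{counts['0']}"
        f"|P:{counts['p']}|G:{counts['g']}"
    )
    digital = "".join(classes)
    summarized = re.sub(r"(.)\1+", r"\1", digital)
    return count_shape, digital, summarized


_REAL_NUMBER = re.compile(r"\d+(?:\.\d+)?")


def orthographic(surface: str) -> tuple[bool, ...]:
    """The seven orthographic flags (see FEATURE_GROUPS['orthographic'])."""
    upper_count = sum(1 for c in surface if c.isascii() and c.isupper())
    return (
        surface.isupper() and any(c.isalpha() for c in surface),
        "/" in surface,
        any(_char_class(c) == "p" for c in surface),
        bool(_REAL_NUMBER.search(surface)),
        surface[0].isdigit(),
        surface[0].isupper(),
        upper_count > 2,
    )


def token_length(surface: str) -> int:
    return len(surface)


def chem_affix_flag(surface: str, affixes: Lexicon) -> bool:
    """True iff any lexicon affix is a case-insensitive prefix or suffix."""
    low = surface.casefold()
    return any(
        low.startswith(a) or low.endswith(a)
        for a in (x.casefold() for x in affixes.entries)
    )


def extract_features(seq: TokenSequence, i: int, affixes: Lexicon) -> FeatureVector:
    """All 7 groups for token ``i`` of ``seq``; deterministic."""
    if not 0 <= i < len(seq):
        raise IndexError(f"token index {i} out of range for {len(seq)} tokens")
    s = seq[i].surface
    right, left, both = space_features(seq, i)
    prev, nxt = context_words(seq, i)
    grams = ngram_affixes(s)
    shapes = word_shapes(s)
    ortho = orthographic(s)
    ordered: list[FeatureValue] = [
        right, left, both,
        prev, nxt,
        *grams,
        *shapes,
        *ortho,
        token_length(s),
        chem_affix_flag(s, affixes),
    ]
    return FeatureVector(dict(zip(FEATURE_NAMES, ordered)))


def extract_all(seq: TokenSequence, affixes: Lexicon) -> list[FeatureVector]:
    return [extract_features(seq, i, affixes) for i in range(len(seq))]


def _encode(v: FeatureValue) -> str:
    if isinstance(v, bool):
        return "1" if v else "0"
    return str(v)


def write_features(
    rows: Iterable[tuple[str, FeatureVector]], path, header: bool = True
) -> None:
    """Write ``(surface, vector)`` rows as TSV in the canonical column order."""
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write("\t".join(("token",) + FEATURE_NAMES) + "\n")
        for surface, vec in rows:
            fh.write(
                "\t".join([surface] + [_encode(vec[n]) for n in FEATURE_NAMES]) + "\n"
            )


def read_features(path) -> list[tuple[str, FeatureVector]]:
    """Re-parse a feature TSV written by :func:`write_features`."""
    bool_names = {
        n
        for n in FEATURE_NAMES
        if n.startswith(("has_", "is_", "starts_")) or n == "uppercase_gt2"
    }
    out: list[tuple[str, FeatureVector]] = []
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        return out
    assert lines[0].split("\t") == ["token", *FEATURE_NAMES], "unexpected header"
    for line in lines[1:]:
        cells = line.split("\t")
        surface, rest = cells[0], cells[1:]
        vals: dict[str, FeatureValue] = {}
        for name, cell in zip(FEATURE_NAMES, rest):
            if name in bool_names:
                vals[name] = cell == "1"
            elif name == "token_length":
                vals[name] = int(cell)
            else:
                vals[name] = cell
        out.append((surface, FeatureVector(vals)))
    return out
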