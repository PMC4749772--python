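"""Offset-preserving rule-based tokenization for chemical text.

The rule tokenizer proceeds in three steps:

1. split raw text at whitespace;
2. split each token at a known domain affix (prefix), then — unless the
   token exactly matches a known entity surface form (the *lexicon gate*) —
   at punctuation, digit/letter boundaries, non-ASCII letters and case
   changes;
3. repair over-splitting with five rules: merge separated numeric chains
   (Rule 1), absorb balanced containers around them (Rule 2), re-attach a
   single capital to a following lowercase run (Rule 3), merge consecutive
   sub-tokens whose concatenation is a known chemical name (Rule 4), and
   split a plural surface into base form + suffix when the base is a known
   name (Rule 5).

Every token carries exact character offsets into the source document, so
the output can be aligned against gold entity annotations; interleaving
token surfaces with the skipped source slices reconstructs the input
byte-for-byte.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable, Iterable, Optional

from .lexicon import CasePolicy, Lexicon, LexiconSet


@dataclass(frozen=True, slots=True)
class Token:
    """A surface string anchored to half-open character offsets."""

    surface: str
    start: int
    end: int
    doc_id: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty token span [{self.start},{self.end})")
        if len(self.surface) != self.end - self.start:
            raise ValueError("surface length does not match span")
        if any(c.isspace() for c in self.surface):
            raise ValueError(f"token surface contains whitespace: {self.surface!r}")


@dataclass(frozen=True)
class TokenSequence:
    """An ordered, non-overlapping tokenization of one document."""

    doc_id: str
    source_text: str
    tokens: tuple[Token, ...]

    def __post_init__(self) -> None:
        prev_end = 0
        for t in self.tokens:
            if t.start < prev_end:
                raise ValueError("tokens overlap or are out of order")
            if self.source_text[t.start : t.end] != t.surface:
                raise ValueError(
                    f"token {t.surface!r} does not match source slice "
                    f"{self.source_text[t.start:t.end]!r}"
                )
            prev_end = t.end

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self):
        return iter(self.tokens)

    def __getitem__(self, i: int) -> Token:
        return self.tokens[i]

    def surfaces(self) -> list[str]:
        return [t.surface for t in self.tokens]

    def reconstruct(self) -> str:
        """Re-insert inter-token source slices; equals ``source_text``."""
        out: list[str] = []
        pos = 0
        for t in self.tokens:
            out.append(self.source_text[pos : t.start])
            out.append(t.surface)
            pos = t.end
        out.append(self.source_text[pos:])
        return "".join(out)

    def with_tokens(self, tokens: Iterable[Token]) -> "TokenSequence":
        return TokenSequence(self.doc_id, self.source_text, tuple(tokens))


_DEFAULT_SEPARATORS = frozenset({".", ",", "/", "-", "_"})
_DEFAULT_CONTAINERS = (("(", ")"), ("[", "]"), ("{", "}"))


@dataclass(frozen=True)
class TokenizerConfig:
    """Knobs of the rule tokenizer.

    Defaults implement the standard behaviour: digit runs kept whole,
    camel-case-aware case splitting, all five repair rules on, a 5-token
    merge window, ``. , / - _`` as numeric separators, round/square/curly
    containers, and plural suffixes tried in the order ies, es, s.
    """

    digit_policy: str = "run"  # "run": maximal digit run is one token; "char": each digit
    case_change_split: bool = True
    # "camel": an uppercase run followed by lowercase also splits before its
    # final capital (so "CONCLUSIONGlucose" -> CONCLUSION | G | lucose and
    # Rule 3 can rebuild "Glucose"); "plain": split only between two adjacent
    # letters of differing case (the naive splitter that yields "lucose").
    case_split_mode: str = "camel"
    rule1: bool = True
    rule2: bool = True
    rule3: bool = True
    rule4: bool = True
    rule5: bool = True
    rule4_window: int = 5
    rule1_separators: frozenset[str] = _DEFAULT_SEPARATORS
    containers: tuple[tuple[str, str], ...] = _DEFAULT_CONTAINERS
    plural_suffixes: tuple[str, ...] = ("ies", "es", "s")
    # None: use the entity lexicon's own policy; otherwise override.
    entity_gate_case: Optional[CasePolicy] = None

    def __post_init__(self) -> None:
        if self.rule4_window < 2:
            raise ValueError("rule4_window must be >= 2")
        if self.rule1 and not self.rule1_separators:
            raise ValueError("rule 1 enabled with empty separator set")
        if self.rule2 and not self.containers:
            raise ValueError("rule 2 enabled with empty container set")
        if self.digit_policy not in ("run", "char"):
            raise ValueError(f"unknown digit_policy {self.digit_policy!r}")
        if self.case_split_mode not in ("camel", "plain"):
            raise ValueError(f"unknown case_split_mode {self.case_split_mode!r}")


def split_whitespace(text: str, doc_id: str = "") -> TokenSequence:
    """Step 1: maximal runs of non-whitespace become tokens.

    Whitespace is ``str.isspace`` throughout the package, so the round-trip
    invariant holds for any Unicode input.
    """
    tokens: list[Token] = []
    i, n = 0, len(text)
    while i < n:
        if text[i].isspace():
            i += 1
            continue
        j = i + 1
        while j < n and not text[j].isspace():
            j += 1
        tokens.append(Token(text[i:j], i, j, doc_id))
        i = j
    return TokenSequence(doc_id, text, tuple(tokens))


def split_affixes(seq: TokenSequence, affixes: Lexicon) -> TokenSequence:
    """Step 2.1: split each token after a known prefix affix (longest match)."""
    from .lexicon import find_prefix_affix

    out: list[Token] = []
    for t in seq:
        cut = find_prefix_affix(t.surface, affixes) if len(affixes) else None
        if cut is None:
            out.append(t)
        else:
            out.append(Token(t.surface[:cut], t.start, t.start + cut, t.doc_id))
            out.append(Token(t.surface[cut:], t.start + cut, t.end, t.doc_id))
    return seq.with_tokens(out)


def _is_ascii_alpha(c: str) -> bool:
    return c.isascii() and c.isalpha()


def _is_ascii_digit(c: str) -> bool:
    return c.isascii() and c.isdigit()


def _case_boundaries(run: str, mode: str) -> list[int]:
    """Split points (relative indices) inside a run of ASCII letters."""
    cuts: list[int] = []
    for k in range(len(run) - 1):
        a, b = run[k], run[k + 1]
        if a.isupper() != b.isupper():
            cuts.append(k + 1)
        elif (
            mode == "camel"
            and a.isupper()
            and b.isupper()
            and k + 2 < len(run)
            and run[k + 2].islower()
        ):
            # upper run about to descend into lowercase: detach its last
            # capital so the single-capital merge rule can claim it
            cuts.append(k + 1)
    return cuts


def _segment_surface(surface: str, cfg: TokenizerConfig) -> list[tuple[int, int]]:
    """Partition one whitespace-free surface into delimiter-level segments."""
    segs: list[tuple[int, int]] = []
    i, n = 0, len(surface)
    while i < n:
        c = surface[i]
        if _is_ascii_digit(c):
            j = i + 1
            if cfg.digit_policy == "run":
                while j < n and _is_ascii_digit(surface[j]):
                    j += 1
            segs.append((i, j))
            i = j
        elif _is_ascii_alpha(c):
            j = i + 1
            while j < n and _is_ascii_alpha(surface[j]):
                j += 1
            if cfg.case_change_split:
                prev = i
                for cut in _case_boundaries(surface[i:j], cfg.case_split_mode):
                    segs.append((prev, i + cut))
                    prev = i + cut
                segs.append((prev, j))
            else:
                segs.append((i, j))
            i = j
        else:
            # punctuation, symbols and non-ASCII letters (Greek etc.):
            # one character, one token
            segs.append((i, i + 1))
            i += 1
    return segs


def _gate(entities: Lexicon, cfg: TokenizerConfig) -> Lexicon:
    if cfg.entity_gate_case is None or cfg.entity_gate_case == entities.case_policy:
        return entities
    return Lexicon.from_iterable(entities.entries, cfg.entity_gate_case, entities.name)


def split_delimiters(
    seq: TokenSequence, entities: Lexicon, cfg: TokenizerConfig = TokenizerConfig()
) -> TokenSequence:
    """Step 2.2: delimiter/case splitting, skipping known entity surfaces."""
    gate = _gate(entities, cfg)
    out: list[Token] = []
    for t in seq:
        if gate.contains(t.surface):
            out.append(t)
            continue
        for a, b in _segment_surface(t.surface, cfg):
            out.append(Token(t.surface[a:b], t.start + a, t.start + b, t.doc_id))
    return seq.with_tokens(out)


def _contiguous(a: Token, b: Token) -> bool:
    return a.end == b.start


def _merge(seq: TokenSequence, toks: list[Token]) -> Token:
    start, end = toks[0].start, toks[-1].end
    return Token(seq.source_text[start:end], start, end, toks[0].doc_id)


def _is_numeric(t: Token) -> bool:
    return all(_is_ascii_digit(c) for c in t.surface)


def rule1_merge_numeric(
    seq: TokenSequence, cfg: TokenizerConfig = TokenizerConfig()
) -> TokenSequence:
    """Rule 1: numeric tokens separated by ``. , / - _`` merge into one."""
    toks = list(seq.tokens)
    out: list[Token] = []
    i = 0
    while i < len(toks):
        if _is_numeric(toks[i]):
            j = i
            while (
                j + 2 < len(toks)
                and len(toks[j + 1].surface) == 1
                and toks[j + 1].surface in cfg.rule1_separators
                and _is_numeric(toks[j + 2])
                and _contiguous(toks[j], toks[j + 1])
                and _contiguous(toks[j + 1], toks[j + 2])
            ):
                j += 2
            if j > i:
                out.append(_merge(seq, toks[i : j + 1]))
                i = j + 1
                continue
        out.append(toks[i])
        i += 1
    return seq.with_tokens(out)


def _numeric_chain_re(cfg: TokenizerConfig) -> re.Pattern[str]:
    seps = re.escape("".join(sorted(cfg.rule1_separators)))
    return re.compile(rf"\d+(?:[{seps}]\d+)*\Z")


def rule2_merge_containers(
    seq: TokenSequence, cfg: TokenizerConfig = TokenizerConfig()
) -> TokenSequence:
    """Rule 2: balanced containers around a numeric chain are absorbed."""
    chain = _numeric_chain_re(cfg)
    closers = dict(cfg.containers)
    toks = list(seq.tokens)
    out: list[Token] = []
    i = 0
    while i < len(toks):
        if (
            i + 2 < len(toks)
            and toks[i].surface in closers
            and toks[i + 2].surface == closers[toks[i].surface]
            and chain.match(toks[i + 1].surface)
            and _contiguous(toks[i], toks[i + 1])
            and _contiguous(toks[i + 1], toks[i + 2])
        ):
            out.append(_merge(seq, toks[i : i + 3]))
            i += 3
        else:
            out.append(toks[i])
            i += 1
    return seq.with_tokens(out)


def rule3_merge_case(seq: TokenSequence) -> TokenSequence:
    """Rule 3: a lone capital re-attaches to a following lowercase run."""
    toks = list(seq.tokens)
    out: list[Token] = []
    i = 0
    while i < len(toks):
        t = toks[i]
        if (
            i + 1 < len(toks)
            and len(t.surface) == 1
            and _is_ascii_alpha(t.surface)
            and t.surface.isupper()
            and toks[i + 1].surface.isascii()
            and toks[i + 1].surface.isalpha()
            and toks[i + 1].surface.islower()
            and _contiguous(t, toks[i + 1])
        ):
            out.append(_merge(seq, toks[i : i + 2]))
            i += 2
        else:
            out.append(t)
            i += 1
    return seq.with_tokens(out)


def _fold_insensitive(lex: Lexicon) -> Lexicon:
    if lex.case_policy == "insensitive":
        return lex
    return Lexicon.from_iterable(lex.entries, "insensitive", lex.name)


def rule4_merge_known(
    seq: TokenSequence, chem_names: Lexicon, cfg: TokenizerConfig = TokenizerConfig()
) -> TokenSequence:
    """Rule 4: merge up to ``rule4_window`` contiguous tokens whose
    concatenation is a known chemical name (case-insensitive, greedy
    longest-first, leftmost-first; scanning resumes after a merge)."""
    lex = _fold_insensitive(chem_names)
    toks = list(seq.tokens)
    out: list[Token] = []
    i = 0
    while i < len(toks):
        merged = None
        width = 0
        if len(lex):
            for w in range(min(cfg.rule4_window, len(toks) - i), 1, -1):
                window = toks[i : i + w]
                if all(
                    _contiguous(window[k], window[k + 1]) for k in range(w - 1)
                ) and lex.contains("".join(t.surface for t in window)):
                    merged, width = _merge(seq, window), w
                    break
        if merged is not None:
            out.append(merged)
            i += width
        else:
            out.append(toks[i])
            i += 1
    return seq.with_tokens(out)


def rule5_split_plural(
    seq: TokenSequence,
    entities: Lexicon,
    chem_names: Lexicon,
    cfg: TokenizerConfig = TokenizerConfig(),
) -> TokenSequence:
    """Rule 5: split base + plural suffix when the base is a known name.

    Suffixes are tried in order (ies, es, s); the base is the raw-stripped
    remainder (no "y" restoration) and must be a known entity or chemical
    name — the gate keeps ordinary English ("is", "its") intact.
    """
    out: list[Token] = []
    for t in seq:
        cut = None
        for suf in cfg.plural_suffixes:
            if len(t.surface) > len(suf) and t.surface.endswith(suf):
                base = t.surface[: -len(suf)]
                if entities.contains(base) or chem_names.contains(base):
                    cut = len(base)
                    break
        if cut is None:
            out.append(t)
        else:
            out.append(Token(t.surface[:cut], t.start, t.start + cut, t.doc_id))
            out.append(Token(t.surface[cut:], t.start + cut, t.end, t.doc_id))
    return seq.with_tokens(out)


def tokenize(
    text: str,
    doc_id: str = "",
    lexica: Optional[LexiconSet] = None,
    cfg: TokenizerConfig = TokenizerConfig(),
) -> TokenSequence:
    """The full rule tokenizer: Steps 1–3 composed."""
    lexica = lexica or LexiconSet.empty()
    seq = split_whitespace(text, doc_id)
    seq = split_affixes(seq, lexica.affixes)
    seq = split_delimiters(seq, lexica.entities, cfg)
    if cfg.rule1:
        seq = rule1_merge_numeric(seq, cfg)
    if cfg.rule2:
        seq = rule2_merge_containers(seq, cfg)
    if cfg.rule3:
        seq = rule3_merge_case(seq)
    if cfg.rule4:
        seq = rule4_merge_known(seq, lexica.chem_names, cfg)
    if cfg.rule5:
        seq = rule5_split_plural(seq, lexica.entities, lexica.chem_names, cfg)
    return seq


def tokenize_whitespace_baseline(
    text: str,
    doc_id: str = "",
    lexica: Optional[LexiconSet] = None,
    cfg: TokenizerConfig = TokenizerConfig(),
) -> TokenSequence:
    """Baseline: whitespace splitting only (lexica and config ignored)."""
    return split_whitespace(text, doc_id)


def tokenize_case_change_baseline(
    text: str,
    doc_id: str = "",
    lexica: Optional[LexiconSet] = None,
    cfg: TokenizerConfig = TokenizerConfig(),
) -> TokenSequence:
    """Baseline: whitespace + naive case-change splitting, no repair rules.

    Splits only between two adjacent letters of differing case, so
    "CONCLUSIONGlucose" becomes CONCLUSIONG | lucose — the failure mode the
    rule tokenizer's camel-aware splitting plus Rule 3 avoids.
    """
    seq = split_whitespace(text, doc_id)
    out: list[Token] = []
    for t in seq:
        prev = 0
        for cut in _case_boundaries(t.surface, "plain"):
            # boundaries only make sense between letters; guard mixed content
            if _is_ascii_alpha(t.surface[cut - 1]) and _is_ascii_alpha(t.surface[cut]):
                out.append(Token(t.surface[prev:cut], t.start + prev, t.start + cut, t.doc_id))
                prev = cut
        out.append(Token(t.surface[prev:], t.start + prev, t.end, t.doc_id))
    return seq.with_tokens(out)


Tokenizer = Callable[[str, str, Optional[LexiconSet], TokenizerConfig], TokenSequence]

TOKENIZERS: dict[str, Tokenizer] = {
    "rules": tokenize,
    "whitespace": tokenize_whitespace_baseline,
    "case-change": tokenize_case_change_baseline,
}


def get_tokenizer(name: str) -> Tokenizer:
    try:
        return TOKENIZERS[name]
    except KeyError:
        raise KeyError(
            f"unknown tokenizer {name!r}; available: {sorted(TOKENIZERS)}"
        ) from None
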