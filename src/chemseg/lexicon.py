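"""Word lists driving the rule tokenizer.

Four kinds of lexica are used downstream: domain affixes (for splitting
conjoined words such as "hyperinsulinaemia"), known entity surface forms
(the split-exemption gate), known chemical names (the merge lookup), and
plural suffixes (carried in the tokenizer config rather than a file).

A lexicon file is UTF-8 plain text, one entry per line; blank lines and
lines starting with ``#`` are ignored; surrounding whitespace is stripped.
"""

from __future__ import annotations

import logging
import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Optional

logger = logging.getLogger(__name__)

CasePolicy = Literal["sensitive", "insensitive"]


class LexiconError(Exception):
    """Raised when a lexicon file cannot be loaded."""


@dataclass(frozen=True)
class Lexicon:
    """A set of surface strings with a fixed case policy.

    Parameters
    ----------
    entries:
        The surface forms. Under the ``insensitive`` policy they are stored
        case-folded; :meth:`contains` folds its argument the same way.
    case_policy:
        ``"sensitive"`` (exact match) or ``"insensitive"`` (casefold match).
    name:
        A label used in logs and reports (e.g. ``"affixes"``).
    """

    entries: frozenset[str]
    case_policy: CasePolicy = "sensitive"
    name: str = ""
    # longest-first ordering cached for affix scans
    _sorted: tuple[str, ...] = field(default=(), repr=False, compare=False)

    def __post_init__(self) -> None:
        for e in self.entries:
            if not e or "\n" in e:
                raise ValueError(f"invalid lexicon entry {e!r} in {self.name!r}")
        object.__setattr__(
            self, "_sorted", tuple(sorted(self.entries, key=len, reverse=True))
        )

    @staticmethod
    def from_iterable(
        items: Iterable[str],
        case_policy: CasePolicy = "sensitive",
        name: str = "",
    ) -> "Lexicon":
        folded = set()
        for raw in items:
            s = unicodedata.normalize("NFC", raw.strip())
            if not s or s.startswith("#"):
                continue
            folded.add(s.casefold() if case_policy == "insensitive" else s)
        return Lexicon(frozenset(folded), case_policy, name)

    def contains(self, s: str) -> bool:
        """Membership test respecting the case policy; '' is never a member."""
        if not s:
            return False
        if self.case_policy == "insensitive":
            s = s.casefold()
        return s in self.entries

    __contains__ = contains

    def add(self, *items: str) -> "Lexicon":
        """Return a new lexicon with ``items`` added (lexica are immutable)."""
        return Lexicon.from_iterable(list(self.entries) + list(items),
                                     self.case_policy, self.name)

    def __len__(self) -> int:
        return len(self.entries)

    def fingerprint(self) -> str:
        """Stable short digest for run logging."""
        import hashlib

        h = hashlib.sha256("\n".join(sorted(self.entries)).encode()).hexdigest()
        return f"{self.name or 'lexicon'}:{len(self.entries)}:{h[:12]}"


def load_lexicon(
    path: str | Path, case_policy: CasePolicy = "sensitive", name: str = ""
) -> Lexicon:
    """Load a one-entry-per-line lexicon file.

    Blank lines and ``#`` comments are skipped, surrounding whitespace is
    stripped, and duplicates (after case folding, if insensitive) collapse.
    An empty result is valid but logged as a warning.
    """
    p = Path(path)
    if not p.is_file():
        raise LexiconError(f"lexicon file not found: {p}")
    lex = Lexicon.from_iterable(
        p.read_text(encoding="utf-8").splitlines(), case_policy, name or p.stem
    )
    if len(lex) == 0:
        logger.warning("lexicon %s loaded from %s is empty", lex.name, p)
    return lex


def find_prefix_affix(token: str, affixes: Lexicon) -> Optional[int]:
    """Split position after the longest affix matching at the start of ``token``.

    Matching is case-insensitive regardless of the lexicon's policy (the
    affix list mixes capitalised and lowercase forms, and "Hyper" must split
    "hyperinsulinaemia"). Returns ``None`` when no affix matches or when the
    match would leave an empty remainder; never returns 0 or ``len(token)``.
    """
    if not token:
        raise ValueError("token must be non-empty")
    low = token.casefold()
    best = 0
    for affix in affixes._sorted:
        n = len(affix)
        if n > best and n < len(token) and low.startswith(affix.casefold()):
            best = n
    return best or None


@dataclass(frozen=True)
class LexiconSet:
    """The three word lists the rule tokenizer consumes, bundled.

    ``affixes`` drive conjoined-word splitting, ``entities`` form the
    split-exemption gate, ``chem_names`` drive the known-name merge rule
    and gate the plurality split.
    """

    affixes: Lexicon
    entities: Lexicon
    chem_names: Lexicon

    @staticmethod
    def empty() -> "LexiconSet":
        return LexiconSet(
            Lexicon(frozenset(), "insensitive", "affixes"),
            Lexicon(frozenset(), "sensitive", "entities"),
            Lexicon(frozenset(), "insensitive", "chem_names"),
        )

    @staticmethod
    def builtin() -> "LexiconSet":
        return LexiconSet(builtin_affixes(), builtin_entities(), builtin_chem_names())


def _builtin(name: str) -> Path:
    return Path(str(resources.files("chemseg").joinpath("data", f"{name}.txt")))


def builtin_affixes() -> Lexicon:
    """Small curated starter list of domain affixes (e.g. hyper, anti, amino)."""
    return load_lexicon(_builtin("affixes"), "insensitive", "affixes")


def builtin_entities(case_policy: CasePolicy = "sensitive") -> Lexicon:
    """Starter list of known entity surface forms (the split-exemption gate)."""
    return load_lexicon(_builtin("entities"), case_policy, "entities")


def builtin_chem_names() -> Lexicon:
    """Starter list of known chemical names used by the merge rule."""
    return load_lexicon(_builtin("chem_names"), "insensitive", "chem_names")
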