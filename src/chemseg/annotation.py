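"""Token–entity alignment, IOB labeling and segmentation metrics.

A gold entity span is *correctly segmented* by a tokenization when its
start coincides with some token start, its end with some token end, and no
token straddles either boundary. Correct entities receive B-/I- labels over
their covered tokens; incorrectly segmented entities are reported (their
count over a corpus is NISE, the number of incorrectly segmented entities)
and, by default, their interior tokens stay O — a sequence classifier
cannot learn a span whose boundaries the tokenization destroyed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .tokenizer import Token, TokenSequence

#: ChemDNER-style chemical classes plus the drug-corpus classes.
KNOWN_CLASSES = frozenset(
    {
        "SYSTEMATIC", "ABBREVIATION", "FAMILY", "FORMULA", "IDENTIFIER",
        "MULTIPLE", "TRIVIAL", "CHEMICAL",
        "DRUG", "GROUP", "BRAND", "DRUG_N",
    }
)


class AlignmentError(Exception):
    """Raised on overlapping gold spans or document mismatches."""


@dataclass(frozen=True, slots=True)
class EntitySpan:
    """A gold annotation: document id, half-open offsets, surface, class."""

    doc_id: str
    start: int
    end: int
    surface: str
    entity_class: str

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"invalid span [{self.start},{self.end})")


@dataclass(frozen=True, slots=True)
class LabeledToken:
    token: Token
    label: str  # "O", "B-<class>" or "I-<class>"


@dataclass(frozen=True)
class CorpusStats:
    """Corpus-level segmentation summary for one tokenizer.

    NT: number of tokens. ATL: average token length in characters.
    NISE: number of incorrectly segmented entities.
    """

    tokenizer: str
    nt: int
    atl: float
    nise: int
    n_entities: int = 0


def _check_no_overlap(entities: Sequence[EntitySpan]) -> list[EntitySpan]:
    spans = sorted(entities, key=lambda e: (e.start, e.end))
    for a, b in zip(spans, spans[1:]):
        if b.start < a.end:
            raise AlignmentError(
                f"overlapping gold entities in {a.doc_id}: "
                f"[{a.start},{a.end}) {a.surface!r} and "
                f"[{b.start},{b.end}) {b.surface!r}"
            )
    return spans


def align_and_label(
    seq: TokenSequence, entities: Sequence[EntitySpan]
) -> tuple[list[LabeledToken], list[EntitySpan]]:
    """IOB-label a token sequence against gold spans.

    Returns the labeled tokens and the list of incorrectly segmented
    entities. Gold spans must not overlap and must lie within the document.
    """
    for e in entities:
        if e.doc_id and seq.doc_id and e.doc_id != seq.doc_id:
            raise AlignmentError(
                f"entity doc {e.doc_id!r} does not match sequence {seq.doc_id!r}"
            )
        if e.end > len(seq.source_text):
            raise AlignmentError(
                f"entity [{e.start},{e.end}) outside document {seq.doc_id!r} "
                f"of length {len(seq.source_text)}"
            )
    spans = _check_no_overlap(entities)

    labels = ["O"] * len(seq)
    violations: list[EntitySpan] = []
    ti = 0
    for e in spans:
        # tokens overlapping [e.start, e.end)
        while ti < len(seq) and seq[ti].end <= e.start:
            ti += 1
        overlapping: list[int] = []
        k = ti
        while k < len(seq) and seq[k].start < e.end:
            overlapping.append(k)
            k += 1
        starts_ok = any(seq[k].start == e.start for k in overlapping)
        ends_ok = any(seq[k].end == e.end for k in overlapping)
        inside = all(seq[k].start >= e.start and seq[k].end <= e.end for k in overlapping)
        if overlapping and starts_ok and ends_ok and inside:
            labels[overlapping[0]] = f"B-{e.entity_class}"
            for k in overlapping[1:]:
                labels[k] = f"I-{e.entity_class}"
        else:
            violations.append(e)
    return [LabeledToken(t, l) for t, l in zip(seq.tokens, labels)], violations


def check_label_sequence(labels: Sequence[str]) -> None:
    """Validate IOB well-formedness: I-X only after B-X or I-X."""
    prev = "O"
    for l in labels:
        if l.startswith("I-"):
            cls = l[2:]
            if not (prev == f"B-{cls}" or prev == f"I-{cls}"):
                raise ValueError(f"dangling {l} after {prev}")
        prev = l


def compute_stats(
    corpus: Iterable[TokenSequence],
    entities: Mapping[str, Sequence[EntitySpan]],
    tokenizer_name: str = "",
) -> CorpusStats:
    """NT / ATL / NISE over an annotated corpus.

    ``entities`` maps doc_id -> gold spans; every annotated document must
    appear in ``corpus``.
    """
    seqs = {s.doc_id: s for s in corpus}
    missing = set(entities) - set(seqs)
    if missing:
        raise AlignmentError(f"annotated documents missing from corpus: {sorted(missing)}")
    nt = sum(len(s) for s in seqs.values())
    total_chars = sum(len(t.surface) for s in seqs.values() for t in s)
    nise = 0
    n_ent = 0
    for doc_id, spans in entities.items():
        n_ent += len(spans)
        _, bad = align_and_label(seqs[doc_id], spans)
        nise += len(bad)
    atl = total_chars / nt if nt else 0.0
    return CorpusStats(tokenizer_name, nt, atl, nise, n_ent)


def format_stats_table(stats: Sequence[CorpusStats], corpus_name: str = "corpus") -> str:
    """Plain-text comparison table (one row per tokenizer)."""
    lines = [f"{corpus_name}", f"{'tokenizer':<14}{'NT':>10}{'ATL':>8}{'NISE':>8}"]
    for s in stats:
        lines.append(f"{s.tokenizer:<14}{s.nt:>10}{s.atl:>8.2f}{s.nise:>8}")
    return "\n".join(lines)
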