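"""Readers and writers for the corpus, annotation and CoNLL dialects.

Dialects (all UTF-8 plain text, NFC-normalized on read):

* abstracts TSV — ``doc_id <TAB> title <TAB> abstract``; the stored
  document text is ``title + "\\t" + abstract`` so that annotation offsets
  index one concatenated string per record;
* annotations TSV — ``doc_id <TAB> section <TAB> start <TAB> end <TAB>
  surface <TAB> class`` with 0-based half-open offsets into the stored
  text (section is ``T``, ``A`` or ``-`` and is informational);
* CoNLL-style token file — ``surface <TAB> start <TAB> end <TAB> label``,
  one token per line, documents introduced by ``# doc_id = <id>`` and
  separated by blank lines.

Readers are strict by default (malformed input raises with a line number);
``permissive=True`` logs and skips bad rows instead.
"""

from __future__ import annotations

import logging
import unicodedata
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .annotation import EntitySpan, LabeledToken
from .tokenizer import Token

logger = logging.getLogger(__name__)

TITLE_SEPARATOR = "\t"


class CorpusFormatError(Exception):
    """Raised on malformed corpus or annotation input."""


@dataclass(frozen=True, slots=True)
class DocumentRecord:
    """One document: id plus its full text (title TAB abstract, or raw)."""

    doc_id: str
    text: str


def _nfc(s: str) -> str:
    return unicodedata.normalize("NFC", s)


def read_abstracts(
    path: str | Path, plain_text: bool = False, permissive: bool = False
) -> list[DocumentRecord]:
    """Load documents from an abstracts TSV (or a raw text file).

    With ``plain_text`` the whole file is one record whose id is the file
    stem. Duplicate ids and rows without three columns are errors.
    """
    p = Path(path)
    if plain_text:
        return [DocumentRecord(p.stem, _nfc(p.read_text(encoding="utf-8")))]
    records: list[DocumentRecord] = []
    seen: set[str] = set()
    for lineno, line in enumerate(p.read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            msg = f"{p}:{lineno}: expected 3 tab-separated columns, got {len(parts)}"
            if permissive:
                logger.warning("skipping malformed row: %s", msg)
                continue
            raise CorpusFormatError(msg)
        doc_id, title, abstract = parts
        if doc_id in seen:
            raise CorpusFormatError(f"{p}:{lineno}: duplicate doc_id {doc_id!r}")
        seen.add(doc_id)
        records.append(DocumentRecord(doc_id, _nfc(title + TITLE_SEPARATOR + abstract)))
    return records


def write_abstracts(records: Iterable[DocumentRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            title, _, abstract = r.text.partition(TITLE_SEPARATOR)
            fh.write(f"{r.doc_id}\t{title}\t{abstract}\n")


def read_annotations(
    path: str | Path,
    documents: Mapping[str, DocumentRecord] | None = None,
    permissive: bool = False,
) -> dict[str, list[EntitySpan]]:
    """Load gold spans grouped by doc_id.

    When ``documents`` is given, offsets are validated against the stored
    text and the surface column must equal the text slice.
    """
    p = Path(path)
    spans: dict[str, list[EntitySpan]] = {}
    for lineno, line in enumerate(p.read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        try:
            if len(parts) != 6:
                raise CorpusFormatError(
                    f"{p}:{lineno}: expected 6 columns, got {len(parts)}"
                )
            doc_id, _section, start_s, end_s, surface, cls = parts
            start, end = int(start_s), int(end_s)
            if start < 0 or end <= start:
                raise CorpusFormatError(
                    f"{p}:{lineno}: invalid offsets [{start},{end}) for {doc_id!r}"
                )
            if documents is not None:
                if doc_id not in documents:
                    raise CorpusFormatError(f"{p}:{lineno}: unknown doc_id {doc_id!r}")
                text = documents[doc_id].text
                if end > len(text):
                    raise CorpusFormatError(
                        f"{p}:{lineno}: span [{start},{end}) outside document "
                        f"{doc_id!r} of length {len(text)}"
                    )
                if text[start:end] != _nfc(surface):
                    raise CorpusFormatError(
                        f"{p}:{lineno}: surface {surface!r} does not match "
                        f"text slice {text[start:end]!r}"
                    )
            spans.setdefault(doc_id, []).append(
                EntitySpan(doc_id, start, end, _nfc(surface), cls)
            )
        except (CorpusFormatError, ValueError) as exc:
            if permissive:
                logger.warning("skipping bad annotation row: %s", exc)
                continue
            if isinstance(exc, ValueError):
                raise CorpusFormatError(f"{p}:{lineno}: {exc}") from exc
            raise
    return spans


def write_annotations(
    spans: Mapping[str, Sequence[EntitySpan]],
    path: str | Path,
    documents: Mapping[str, DocumentRecord] | None = None,
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# doc_id\tsection\tstart\tend\tsurface\tclass\n")
        for doc_id in spans:
            title_len = None
            if documents is not None and doc_id in documents:
                title_len = documents[doc_id].text.find(TITLE_SEPARATOR)
            for e in spans[doc_id]:
                if title_len is None or title_len < 0:
                    section = "-"
                elif e.end <= title_len:
                    section = "T"
                elif e.start > title_len:
                    section = "A"
                else:
                    section = "-"
                fh.write(
                    f"{e.doc_id}\t{section}\t{e.start}\t{e.end}\t"
                    f"{e.surface}\t{e.entity_class}\n"
                )


def write_conll(
    labeled: Mapping[str, Sequence[LabeledToken]], path: str | Path
) -> None:
    """One token per line: surface TAB start TAB end TAB label."""
    with open(path, "w", encoding="utf-8") as fh:
        first = True
        for doc_id, rows in labeled.items():
            if not first:
                fh.write("\n")
            first = False
            fh.write(f"# doc_id = {doc_id}\n")
            for lt in rows:
                t = lt.token
                fh.write(f"{t.surface}\t{t.start}\t{t.end}\t{lt.label}\n")


def read_conll(path: str | Path) -> dict[str, list[LabeledToken]]:
    out: dict[str, list[LabeledToken]] = {}
    doc_id: str | None = None
    p = Path(path)
    for lineno, line in enumerate(p.read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        if line.startswith("# doc_id = "):
            doc_id = line[len("# doc_id = ") :]
            out.setdefault(doc_id, [])
            continue
        parts = line.split("\t")
        if len(parts) != 4 or doc_id is None:
            raise CorpusFormatError(f"{p}:{lineno}: malformed token line {line!r}")
        surface, start_s, end_s, label = parts
        out[doc_id].append(
            LabeledToken(Token(surface, int(start_s), int(end_s), doc_id), label)
        )
    return out
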