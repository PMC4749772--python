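"""Seeded synthetic corpora exhibiting known segmentation failure modes.

Real chemical-NER corpora cannot ship with a test suite, so this module
fabricates small annotated "abstracts" whose entities exercise, by
construction, the phenomena that break naive tokenizers:

* ``hyphen_conjoined`` — two entities fused by a dash ("tpgs-cisplatin");
* ``internal_space_entity`` — a systematic name with an internal space;
* ``paren_formula`` — a parenthesized numeric formula fused to a word;
* ``plural_form`` — a plural surface whose gold span is the singular;
* ``affix_containment`` — an entity embedded after a domain affix
  ("hyperinsulinaemia" / gold "insulin");
* ``case_fused`` — an entity glued to an uppercase section header
  ("CONCLUSIONGlucose" / gold "Glucose");
* ``simple_entity`` — a well-behaved control.

Entity surfaces are template-synthesized (pronounceable stems, numeric
formulas), not copied from any corpus. Every emitted gold span is verified
against the generated text, and the surfaces that the rule tokenizer's
lexicon gates need are injected into the returned lexica, so the corpus is
self-consistent: the rule tokenizer segments every covered phenomenon at
its gold boundaries while the whitespace baseline provably cannot.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .annotation import EntitySpan
from .corpus_io import DocumentRecord, TITLE_SEPARATOR
from .lexicon import Lexicon, LexiconSet

PHENOMENA = (
    "hyphen_conjoined",
    "internal_space_entity",
    "paren_formula",
    "plural_form",
    "affix_containment",
    "case_fused",
    "simple_entity",
)

#: phenomena that break whitespace-token boundaries by construction
WHITESPACE_BREAKING = frozenset(
    {"hyphen_conjoined", "paren_formula", "plural_form", "affix_containment",
     "case_fused"}
)

_AFFIXES = ("hyper", "anti", "amino")
_HEADERS = ("CONCLUSION", "RESULTS", "BACKGROUND", "METHODS", "OBJECTIVE")
_SYLLABLES = (
    "flu", "mez", "zor", "pra", "lin", "dex", "vor", "tam",
    "bil", "cos", "nid", "rup", "gal", "fen", "mo", "ket",
)
_STEM_ENDINGS = ("ine", "ol", "ate", "ium", "oxy", "il")
_FILLERS = (
    "the", "study", "shows", "that", "treatment", "with", "reduced",
    "levels", "in", "patients", "and", "observed", "effects", "were",
    "during", "analysis", "of", "response", "to", "combined",
)
_CLASS_OF = {
    "hyphen_conjoined": "TRIVIAL",
    "internal_space_entity": "SYSTEMATIC",
    "paren_formula": "FORMULA",
    "plural_form": "FAMILY",
    "affix_containment": "TRIVIAL",
    "case_fused": "TRIVIAL",
    "simple_entity": "TRIVIAL",
}


@dataclass(frozen=True)
class PhenomenonSpec:
    """One phenomenon kind with a sampling weight."""

    kind: str
    weight: float = 1.0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in PHENOMENA:
            raise ValueError(f"unknown phenomenon {self.kind!r}")
        if self.weight < 0:
            raise ValueError("weight must be >= 0")


def default_specs() -> list[PhenomenonSpec]:
    return [PhenomenonSpec(k) for k in PHENOMENA]


@dataclass(frozen=True)
class ManifestEntry:
    """Provenance of one generated gold entity."""

    doc_id: str
    start: int
    end: int
    surface: str
    kind: str
    entity_class: str


@dataclass(frozen=True)
class SyntheticCorpus:
    documents: list[DocumentRecord]
    annotations: dict[str, list[EntitySpan]]
    lexica: LexiconSet
    manifest: list[ManifestEntry]


class _StemFactory:
    def __init__(self, rng: random.Random) -> None:
        self.rng = rng
        self.used: set[str] = set()

    def stem(self) -> str:
        while True:
            s = (
                "".join(self.rng.choice(_SYLLABLES) for _ in range(self.rng.randint(2, 3)))
                + self.rng.choice(_STEM_ENDINGS)
            )
            if s in self.used:
                continue
            if any(s.startswith(a) for a in _AFFIXES) or s in _FILLERS:
                continue
            self.used.add(s)
            return s


@dataclass
class _Fragment:
    """Text chunk plus entity spans relative to its own start."""

    text: str
    spans: list[tuple[int, int, str, str]]  # rel_start, rel_end, surface, kind


def _make_fragment(
    kind: str, rng: random.Random, stems: _StemFactory,
    ent_inj: set[str], chem_inj: set[str],
) -> _Fragment:
    if kind == "simple_entity":
        s = stems.stem()
        ent_inj.add(s)
        return _Fragment(s, [(0, len(s), s, kind)])
    if kind == "hyphen_conjoined":
        a, b = stems.stem(), stems.stem()
        ent_inj.update((a, b))
        text = f"{a}-{b}"
        return _Fragment(
            text,
            [(0, len(a), a, kind), (len(a) + 1, len(text), b, kind)],
        )
    if kind == "internal_space_entity":
        n = [rng.randint(1, 9) for _ in range(4)]
        s1, s2 = stems.stem(), stems.stem()
        part1 = f"{n[0]}-({n[1]},{n[2]}-{s1}-{n[3]}-yl)"
        ent_inj.update((part1, s2))
        text = f"{part1} {s2}"
        return _Fragment(text, [(0, len(text), text, kind)])
    if kind == "paren_formula":
        host = stems.stem()  # non-entity carrier word
        opener, closer = rng.choice((("(", ")"), ("[", "]"), ("{", "}")))
        sep = rng.choice(("-", ",", "/"))
        nums = [str(rng.randint(1, 99)) for _ in range(rng.randint(2, 3))]
        formula = opener + sep.join(nums) + closer
        text = host + formula
        return _Fragment(text, [(len(host), len(text), formula, kind)])
    if kind == "plural_form":
        s = stems.stem()
        chem_inj.add(s)
        suffix = rng.choice(("s", "es", "ies"))
        return _Fragment(s + suffix, [(0, len(s), s, kind)])
    if kind == "affix_containment":
        affix = rng.choice(_AFFIXES)
        s = stems.stem()
        ent_inj.add(s)
        return _Fragment(affix + s, [(len(affix), len(affix) + len(s), s, kind)])
    if kind == "case_fused":
        header = rng.choice(_HEADERS)
        s = stems.stem().capitalize()
        ent_inj.add(s)
        return _Fragment(header + s, [(len(header), len(header) + len(s), s, kind)])
    raise ValueError(f"unknown phenomenon {kind!r}")


def generate_corpus(
    seed: int,
    n_docs: int = 20,
    specs: Optional[Sequence[PhenomenonSpec]] = None,
    lexica: Optional[LexiconSet] = None,
) -> SyntheticCorpus:
    """Generate a deterministic annotated corpus.

    Returns documents (title TAB body, as the abstracts dialect stores
    them), per-document gold spans, lexica augmented with every surface the
    rule tokenizer's gates need, and a manifest recording each entity's
    phenomenon kind.
    """
    if n_docs < 0:
        raise ValueError("n_docs must be >= 0")
    specs = list(specs) if specs is not None else default_specs()
    weights = [sp.weight for sp in specs]
    if not specs or sum(weights) <= 0:
        raise ValueError("need at least one phenomenon with positive weight")
    rng = random.Random(seed)
    stems = _StemFactory(rng)
    ent_inj: set[str] = set()
    chem_inj: set[str] = set()

    documents: list[DocumentRecord] = []
    annotations: dict[str, list[EntitySpan]] = {}
    manifest: list[ManifestEntry] = []

    for d in range(n_docs):
        doc_id = f"SYN{d:04d}"
        units: list[tuple[str, list[tuple[int, int, str, str]]]] = []

        def filler_run(lo: int, hi: int) -> None:
            for _ in range(rng.randint(lo, hi)):
                units.append((rng.choice(_FILLERS), []))

        # title
        filler_run(3, 6)
        title_units = len(units)
        # body: a few sentences, each carrying 1-3 phenomenon instances
        for _ in range(rng.randint(2, 4)):
            filler_run(2, 4)
            for _ in range(rng.randint(1, 3)):
                sp = rng.choices(specs, weights=weights, k=1)[0]
                frag = _make_fragment(sp.kind, rng, stems, ent_inj, chem_inj)
                units.append((frag.text, frag.spans))
                filler_run(1, 3)
            units.append((".", []))

        pieces: list[str] = []
        pos = 0
        doc_spans: list[EntitySpan] = []
        for idx, (text_piece, spans) in enumerate(units):
            if idx == title_units:
                sep = TITLE_SEPARATOR
            elif idx > 0:
                sep = " "
            else:
                sep = ""
            pieces.append(sep + text_piece)
            pos += len(sep)
            for rel_s, rel_e, surface, kind in spans:
                cls = _CLASS_OF[kind]
                doc_spans.append(
                    EntitySpan(doc_id, pos + rel_s, pos + rel_e, surface, cls)
                )
                manifest.append(
                    ManifestEntry(doc_id, pos + rel_s, pos + rel_e, surface, kind, cls)
                )
            pos += len(text_piece)

        text = "".join(pieces)
        for e in doc_spans:
            assert text[e.start : e.end] == e.surface, "generator offset bug"
        documents.append(DocumentRecord(doc_id, text))
        annotations[doc_id] = doc_spans

    base = lexica or LexiconSet.empty()
    out_lexica = LexiconSet(
        affixes=base.affixes.add(*_AFFIXES),
        entities=base.entities.add(*ent_inj),
        chem_names=base.chem_names.add(*chem_inj),
    )
    return SyntheticCorpus(documents, annotations, out_lexica, manifest)


def expected_violations(
    manifest: Sequence[ManifestEntry], tokenizer_name: str
) -> int:
    """Oracle NISE for a generated corpus, from construction alone.

    The whitespace baseline necessarily breaks the boundary of every entity
    whose phenomenon fuses it to surrounding text; the rule tokenizer, run
    with the generated lexica, repairs every covered phenomenon.
    """
    if tokenizer_name == "whitespace":
        return sum(1 for m in manifest if m.kind in WHITESPACE_BREAKING)
    if tokenizer_name == "rules":
        return 0
    raise ValueError(f"no violation oracle for tokenizer {tokenizer_name!r}")
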