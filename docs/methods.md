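# Methods

## Model of the task

Chemical NER is treated as sequence labeling over tokens: a tokenizer
partitions each document into whitespace-free spans with exact character
offsets, gold entities are character-offset spans, and a gold entity is
*correctly segmented* when its start coincides with a token start, its end
with a token end, and no token straddles either boundary. This boundary
criterion is the strictest reading of "the tokenization violates the
entity boundary": any weaker notion would admit entities a sequence
classifier still could not label. A corpus-level tokenizer comparison
reports NT (tokens), ATL (mean surface length in characters) and NISE
(count of incorrectly segmented entities, counted once per annotation
row — a repeated mention contributes each time it is annotated).

Tokens of an incorrectly segmented entity are labeled `O` rather than
given partial B/I labels: training data should not teach a classifier a
span whose boundaries do not exist in its input. This is the package's
choice, isolated in `align_and_label`.

Overlapping gold spans are rejected with an error rather than resolved;
the supported annotation dialect has no nesting.

## The tokenizer

Pipeline (each stage one pass, in order): whitespace split → affix split →
entity-gated delimiter split → Rule 1 → 2 → 3 → 4 → 5. No fixpoint
iteration is needed; all supported constructions resolve in one pass.
Structural invariants, enforced by the data types and property-tested:
offsets strictly ordered and non-overlapping, no surface contains
whitespace, merges never span whitespace (merging requires
source-contiguous tokens), and interleaving surfaces with skipped source
slices reconstructs the input exactly, for arbitrary Unicode input.
"Whitespace" is `str.isspace` everywhere.

Decisions taken where the design was genuinely open:

- **Affix split is prefix-only, once, leftmost-longest.** Affixes observed
  in conjoined entities are prefixes (`hyper…`, `anti…`, `amino…`);
  allowing infix/suffix matches or recursion would shred ordinary words.
  The match is case-insensitive; it applies before the entity gate, so an
  affixed surface in the entity lexicon still splits (algorithm order is
  fixed, not re-checked after merges).
- **Entity gate case policy.** Exact (case-sensitive) by default, because
  chemical abbreviations (`TPGS`, `HER2`) are case-significant; a config
  override exists (`entity_gate_case`).
- **Digit runs are atomic** (`125` is one token) under the default
  `digit_policy="run"`; splitting "at numbers" means at digit/non-digit
  boundaries. A `"char"` policy exists for tokenizer ablations.
- **Case splitting is camel-case aware.** Besides splitting between two
  adjacent letters of differing case, an uppercase run that descends into
  lowercase also splits *before its final capital*:
  `CONCLUSIONGlucose` → `CONCLUSION | G | lucose`. Rule 3 then rebuilds
  `Glucose`, so a header-fused entity is recovered — whereas a plain
  case-change splitter (shipped as the `case-change` baseline) produces
  `CONCLUSIONG | lucose` and necessarily breaks the entity. This is the
  one point where the pipeline's split and merge stages are co-designed:
  Rule 3 exists precisely because the splitter detaches single capitals
  (`Common` → `C | ommon` → `Common`).
- **Rule 2 is numeric-only**: containers are absorbed only around a
  numeric chain (digits possibly joined by Rule-1 separators), the
  construction observed in formula entities; wrapping arbitrary alphabetic
  tokens would glue parenthetical prose to its neighbors.
- **Rule 4 is greedy**: windows of length 5 down to 2 at each position,
  leftmost first, concatenation compared case-insensitively, scan resumes
  after a merged token. Greediness maximizes token length, which is the
  point of the merge stage (longer tokens are more discriminative
  features). The 5-token window is a config field (`rule4_window` ≥ 2).
- **Rule 5 is lexicon-gated and raw-stripping**: suffixes tried in order
  `ies`, `es`, `s`; the split happens only when the stripped base is a
  known entity or chemical name, and the two output tokens partition the
  original surface (no `y` restoration for `ies` — the suffix token is the
  literal tail). Ungated plural stripping would split ordinary English.
- **Non-ASCII letters** (Greek etc.) each become their own token; the
  feature extractor classes them `g` in word shapes. Unicode is normalized
  to NFC by the corpus readers (not by `tokenize` itself, so offsets always
  index the text actually passed in).

The cross-check for Rules 1–4 is an independent brute-force oracle
(`tests/oracle_merges.py`): repeated leftmost-match searching for Rules
1–3 and recursive longest-first window enumeration for Rule 4, compared
against the single-pass implementation on 1000 random ≤30-character
strings over a mixed alphabet of letters, digits, separators, containers
and spaces. Agreement is exact.

## Features

25 features in 7 fixed groups per token — space adjacency (3), ±1 context
words with a `<PAD>` sentinel at document edges (2), character prefixes
and suffixes for n = 1..4 (8), word shapes (3), orthographic flags (7),
length (1), chemical-affix flag (1). Choices the scheme leaves open:

- *n-grams of short tokens*: when `len(token) < n` the whole surface is
  used (human-readable values rather than padding characters).
- *Word shapes*: the count shape serializes the five category counts as
  `U:a|L:b|D:c|P:d|G:e`; the digital shape maps each character to
  `A a 0 p g` (upper, lower, digit, punctuation, other letter); the
  summarized shape collapses runs of equal classes — standard word-shape
  practice, with the alphabet fixed for reproducibility.
- *"has real number"*: the surface contains a digit run optionally with
  one decimal point (`\d+(\.\d+)?`).
- Features are functions of the source text, offsets and affix lexicon
  only; labels are never consulted (no leakage). Export is TSV with the
  canonical column order; written files re-parse to identical vectors.

## Synthetic corpus generator

The generator emulates the segmentation phenomena of chemical abstracts,
not their language: documents are sequences of filler words with embedded
phenomenon fragments, entity surfaces are pronounceable fabricated stems
(syllable templates ending in `-ine`, `-ol`, `-ate`, `-ium`, `-oxy`,
`-il`), numeric formulas are random digits in random balanced containers.
Seven phenomenon kinds are sampled by weight: hyphen-conjoined pairs,
internal-space systematic names, word-fused parenthesized formulas,
plural surfaces (gold = singular), affix containment (gold = stem after
`hyper`/`anti`/`amino`), header-fused capitalized entities, and
well-behaved controls. Guarantees, enforced by construction and asserted
before return:

- determinism given the seed (single `random.Random` stream);
- every gold span's surface equals the text slice;
- stems never start with a known affix, never end in a plural suffix
  trigger, never collide with filler words, and are unique per corpus —
  so no rule fires accidentally;
- surfaces that the rule tokenizer's gates need (entity parts, plural
  bases) are injected into the returned lexica;
- the manifest records each entity's phenomenon, giving a closed-form
  violation count: the whitespace baseline breaks exactly the fused
  phenomena (hyphen, formula, plural, affix, case-fused), the rule
  tokenizer with the generated lexica breaks none.

What passing on this corpus does **not** show: robustness to annotation
noise, to entity surfaces absent from the lexica, to nested or
overlapping mentions, or to corpus-scale statistics of real abstracts —
the generator makes no attempt at realistic language modeling, and NISE=0
here reflects that every gate has the lexicon entries it needs, which on
real corpora is an empirical matter of lexicon coverage.

## Problem sizes and numerics

The shipped evaluation sizes are 100 synthetic documents (≈700 gold
entities) for corpus-level checks and 1000 random strings for the
brute-force merge cross-check; both complete in seconds and scale
linearly for users who want larger runs. There is no floating-point
machinery beyond the ATL mean; all other quantities are integer counts,
so no tolerances apply. The tokenizer is stateless and deterministic:
identical text, config and lexica give identical output, and the only
randomness in the package lives in the corpus generator behind an
explicit seed.

## Known limitations

- Sentence segmentation, abbreviation expansion and Unicode-confusable
  normalization (beyond NFC) are out of scope; documents are processed
  whole.
- The entity gate is checked once, before the merge stage; a surface that
  only becomes a lexicon match after merging is not re-exempted.
- The starter lexica are deliberately tiny (they contain the documented
  examples); practical use requires lists harvested from annotated
  training data, supplied via the loader or the CLI flags.
- XML annotation formats are not parsed; the offsets-TSV dialect is the
  supported import path.
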