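"""Generate a seeded synthetic corpus and inspect its phenomena.

Each document is a fabricated abstract whose entities exhibit, by
construction, the segmentation failure modes of chemical text; the
manifest records which phenomenon produced each gold span, and the
returned lexica contain every surface the rule tokenizer's gates need.
"""

from collections import Counter

from chemseg import expected_violations, generate_corpus

corpus = generate_corpus(seed=7, n_docs=10)

doc = corpus.documents[0]
print(f"{doc.doc_id}: {doc.text[:120]!r}...\n")
for e in corpus.annotations[doc.doc_id][:5]:
    print(f"  [{e.start:>3},{e.end:>3}) {e.entity_class:<11} {e.surface}")

print("\nphenomenon mix:", dict(Counter(m.kind for m in corpus.manifest)))
print("lexica sizes: affixes", len(corpus.lexica.affixes),
      "entities", len(corpus.lexica.entities),
      "chem_names", len(corpus.lexica.chem_names))
print("whitespace-baseline violations by construction:",
      expected_violations(corpus.manifest, "whitespace"),
      "of", len(corpus.manifest), "entities")
# The rule tokenizer run with corpus.lexica scores 0 violations on the
# same corpus (see example 03).
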