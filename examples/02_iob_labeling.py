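"""IOB-label tokens against a gold chemical entity span.

A multi-token entity gets B- on its first token and I- on the rest;
everything else is O. The entity here spans four tokens of the rule
tokenization.
"""

from chemseg import EntitySpan, LexiconSet, align_and_label, tokenize

text = "inhibition of NF-kappa B activation"
start = text.index("NF-kappa B")
gold = [EntitySpan("doc1", start, start + len("NF-kappa B"), "NF-kappa B", "CHEMICAL")]

seq = tokenize(text, "doc1", LexiconSet.empty())
labeled, violations = align_and_label(seq, gold)

for lt in labeled:
    print(f"{lt.token.surface:<12}{lt.label}")
print("incorrectly segmented entities:", len(violations))

# Expected output: NF / - / kappa / B carry B-CHEMICAL then three
# I-CHEMICAL labels; the entity's boundaries coincide with token
# boundaries, so the violation list is empty.
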