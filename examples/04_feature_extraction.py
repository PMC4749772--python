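"""Extract the 25-feature representation of each token.

Seven groups: whitespace adjacency (3), context words (2), character
n-grams for n=1..4 (8), word shapes (3), orthographic flags (7), token
length (1) and a chemical-affix flag (1) — the inputs a CRF or SVM
sequence labeler trains on.
"""

from chemseg import FEATURE_GROUPS, LexiconSet, extract_features, tokenize

lexica = LexiconSet.builtin()
seq = tokenize("NaCL dissolved in H2O", "doc1", lexica)

i = seq.surfaces().index("NaCL")
vec = extract_features(seq, i, lexica.affixes)

print(f"token {seq[i].surface!r}: {len(vec.values)} features in "
      f"{len(FEATURE_GROUPS)} groups\n")
for group in FEATURE_GROUPS:
    print(f"[{group}]")
    for name, value in vec.group(group).items():
        print(f"  {name:<22}{value}")

# "NaCL" has digital shape AaAA (upper-lower-upper-upper), summarized
# shape AaA, 3 uppercase letters (so uppercase_gt2 is true), and length 4.
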