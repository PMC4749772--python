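# Known entity surface forms: whitespace tokens that exactly match an entry
# are exempt from delimiter splitting (the lexicon gate). Starter list;
# real deployments load surface forms harvested from annotated training data.
cisplatin
docetaxel
herceptin
rifampin
TPGS
HER2
d-alpha-tocopheryl-co-poly
3-(4,5-dimethylthiazol-2-yl)-2,5-diphenyl
tetrazolium
bromide
insulin
Glucose
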