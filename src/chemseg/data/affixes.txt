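# Domain-specific affixes used to split conjoined words (matched as prefixes,
# case-insensitively). Deliberately small: over-broad affix lists shred
# ordinary English words.
Hyper
Anti
Amino
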