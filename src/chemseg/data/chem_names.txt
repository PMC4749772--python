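# Known chemical names: the merge rule joins consecutive sub-tokens whose
# concatenation matches an entry (case-insensitive), and the plurality rule
# splits a trailing s/es/ies when the base form is listed here.
NaCL
H2O
Acid
salicylate
clonidine
insulin
glucose
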