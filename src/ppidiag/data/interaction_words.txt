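# Interaction trigger lexicon (verbs and nominals, lowercased)
interact
interacts
interacted
interacting
interaction
bind
binds
bound
binding
associate
associates
associated
association
activate
activates
activated
activation
inhibit
inhibits
inhibited
inhibition
phosphorylate
phosphorylates
phosphorylated
phosphorylation
regulate
regulates
regulated
regulation
complex
complexes
dimerize
dimerizes
heterodimerize
coimmunoprecipitate
coimmunoprecipitates
colocalize
colocalizes
stimulate
stimulates
stimulated
stimulation
suppress
suppresses
suppressed
mediate
mediates
mediated
modulate
modulates
modulated
recruit
recruits
recruited
cleave
cleaves
cleaved
upregulate
upregulates
downregulate
downregulates
block
blocks
blocked
promote
promotes
promoted
induce
induces
induced
require
requires
required
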