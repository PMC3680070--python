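# Negation lexicon (lowercased)
not
no
none
neither
nor
never
without
lack
lacks
lacked
lacking
absent
absence
fail
fails
failed
failure
unable
cannot
abolish
abolishes
abolished
prevent
prevents
prevented
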