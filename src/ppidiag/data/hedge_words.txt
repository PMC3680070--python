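# Hedge / speculation lexicon (lowercased)
may
might
could
can
possibly
possible
probably
probable
perhaps
likely
unlikely
suggest
suggests
suggested
suggesting
indicate
indicates
indicated
appear
appears
appeared
seem
seems
seemed
potential
potentially
putative
presumably
hypothesize
hypothesized
whether
unclear
unknown
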