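# Whole words that are themselves negations of use
nonsmoker
non-smoker
nondrinker
non-drinker
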