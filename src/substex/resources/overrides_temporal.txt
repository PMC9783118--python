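# Terms that override a negation into a positive with a past reading
since
for
last
quit
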