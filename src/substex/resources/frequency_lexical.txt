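# Lexical frequency descriptors (second frequency scan)
occ
nightly
infrequently
# extension
daily
rarely
occasionally
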