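# NegEx pre-triggers: negate a keyword within the LEFT window (before it)
no
not
denies
denied
deny
never
without
none
negative for
neg
doesn't
didn't
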