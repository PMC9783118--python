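# NegEx post-triggers: negate a keyword within the RIGHT window (after it);
# active-voice verbs like "denies" are deliberately absent — they only
# negate what follows them
no
not
denied
was denied
were denied
never
without
free
unlikely
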