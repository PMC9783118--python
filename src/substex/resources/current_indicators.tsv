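nicotine patch	smoking
smoking cessation	smoking
ethanol abstinence	alcohol
to stop	ANY
to quit	ANY
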