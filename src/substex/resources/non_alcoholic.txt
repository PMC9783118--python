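# Non-alcoholic drinks that deactivate the "drink" keyword
water
juice
coffee
# extension
tea
soda
milk
fluids
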