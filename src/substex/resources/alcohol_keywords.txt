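# Alcohol keywords (printed inventory)
alcohol
drink
drinker
drinking
beer
ethanol
etoh
etho
wine
vodka
gin
scotch
pint
# extension: inflections and common variants
drinks
drank
drinkers
beers
pints
whiskey
liquor
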