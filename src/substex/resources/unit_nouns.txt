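# Unit nouns that terminate a numeric amount pattern
pack
packs
pk
pks
ppd
drink
drinks
beer
beers
pint
pints
glass
glasses
bottle
bottles
shot
shots
cigarette
cigarettes
cigar
cigars
gallon
gallons
case
cases
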