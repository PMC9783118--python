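cigarette	smoking
cigarettes	smoking
cigar	smoking
cigars	smoking
pipe	smoking
chewing tobacco	smoking
wine	alcohol
beer	alcohol
beers	alcohol
vodka	alcohol
gin	alcohol
scotch	alcohol
whiskey	alcohol
cocaine	drugs
crack	drugs
heroin	drugs
marijuana	drugs
iv drugs	drugs
barbiturate	drugs
barbiturates	drugs
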