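# Smoking keywords (printed inventory)
smoke
smoker
smoking
tobacco
tob
cigarette
cigar
pipe
nicotine
packs
ppd
snus
weed
# extension: inflections and unit forms seen in clinical notes
smokes
smoked
smokers
cigarettes
cigars
pack
pk
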