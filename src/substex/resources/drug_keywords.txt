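# Drug keywords (printed inventory)
ivdu
cocaine
heroin
marijuana
crack
drug abuse
barbiturate
# extension: bare noun and inflections (needed for e.g. "abuse of drugs")
drug
drugs
barbiturates
narcotics
opioid
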