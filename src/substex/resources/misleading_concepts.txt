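# Phrases that contain a substance keyword with an inverse meaning
smoke inhalation
vaginal pack
drug allergies
drug allergy
drug rash
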