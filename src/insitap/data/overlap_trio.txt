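# The three gene symbols our interactor list shares with the largest prior
# FLAG-tag purification study: cullin 4B, importin subunit alpha-2 and DNA
# topoisomerase II alpha.
Cul4b
Kpna2
Top2a
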