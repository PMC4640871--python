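# Choroid plexus marker panel (highly expressed choroid-plexus transcripts)
Ttr
Igf2
Igfbp2
Prlr
Enpp2
Sostdc1
1500015O10Rik
Kl
Clic6
Kcne2
F5
Slc4a5
Aqp1
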