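# Septal nuclei marker panel (triangular/lateral septal nucleus)
Eomes
Ebf3
Sln
Postn
Gpr88
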