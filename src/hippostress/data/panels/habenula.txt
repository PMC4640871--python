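# Habenula marker panel
Gpr151
Slc5a7
Syt9
Irx1
Tac2
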