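6
synthetic CH5+ stand-in, Cs frozen-core CISD/STO-3G relaxation, R=1.3 A, E_CISD=-40.00685118, center-of-mass frame
C    -0.005354522538     0.000000000000     0.108012960277
H     1.097695237314     0.000000000000     0.342967518618
H     0.449231971895     0.000000000000    -1.194050979255
H    -0.459941016971     0.000000000000    -1.189923100191
H    -0.511615404778     0.960094261520     0.377457372273
H    -0.511615404778    -0.960094261520     0.377457372273
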