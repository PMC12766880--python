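6
synthetic CH5+ stand-in, Cs frozen-core CISD/STO-3G relaxation, R=1.6 A, E_CISD=-39.99875800, center-of-mass frame
C    -0.001265498136     0.000000000000     0.161784383135
H     1.116826426843     0.000000000000     0.314250179266
H     0.405366876800     0.000000000000    -1.440486390256
H    -0.407897873072     0.000000000000    -1.435944843474
H    -0.549613680515     0.971448850748     0.317921058409
H    -0.549613680515    -0.971448850748     0.317921058409
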