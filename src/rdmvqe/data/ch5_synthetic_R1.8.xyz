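6
synthetic CH5+ stand-in, Cs frozen-core CISD/STO-3G relaxation, R=1.8 A, E_CISD=-39.99156357, center-of-mass frame
C    -0.000475644911     0.000000000000     0.195518231190
H     1.127183186900     0.000000000000     0.296891850249
H     0.390452372412     0.000000000000    -1.602794084181
H    -0.391403662234     0.000000000000    -1.606169453439
H    -0.560284237301     0.978551160859     0.292034799634
H    -0.560284237301    -0.978551160859     0.292034799634
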