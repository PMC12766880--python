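6
synthetic CH5+ stand-in, Cs frozen-core CISD/STO-3G relaxation, R=2.1 A, E_CISD=-39.98369335, center-of-mass frame
C    -0.000127052722     0.000000000000     0.241066866201
H     1.136039141750     0.000000000000     0.289716495527
H     0.377152326092     0.000000000000    -1.850928884788
H    -0.377406431536     0.000000000000    -1.866937382810
H    -0.567136120651     0.984868288337     0.278903944501
H    -0.567136120651    -0.984868288337     0.278903944501
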