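6
synthetic CH5+ stand-in, Cs frozen-core CISD/STO-3G relaxation, R=1.4 A, E_CISD=-40.00520143, center-of-mass frame
C    -0.003250583693     0.000000000000     0.126258611198
H     1.103774086529     0.000000000000     0.335205947488
H     0.429434337153     0.000000000000    -1.275536098687
H    -0.435935504539     0.000000000000    -1.271946678917
H    -0.529284387957     0.963169014315     0.354468586828
H    -0.529284387957    -0.963169014315     0.354468586828
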