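CCO
c1ccccc1
CC.CC
CC(C)Cc1ccc(C)cc1C(C)C(=O)O
C(
CN1C=NC2=C1C(=O)N(C)C(=O)N2C
c1ccccc1.O
CCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCC
CC(=O)Oc1ccccc1C(=O)O
NCC(=O)O
CC(N)Cc1ccccc1
OCC1OC(O)C(O)C(O)C1O
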