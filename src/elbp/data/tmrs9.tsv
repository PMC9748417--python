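gene	beta
IRF1	-0.03085
RHOA	-1.03491
PLAUR	0.5868
NCF2	-0.2188
CXCR4	-0.2273
HCK	-0.1201
LYZ	-0.1773
RGS1	-0.1244
VCAN	0.2259
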