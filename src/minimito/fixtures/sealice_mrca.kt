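#taxon sealice_mrca
#missing C D F G S1 S2 W Y nad6
#source inferred most recent common ancestor of seal lice (expected)
E-cob
H-nad5
I-cox1-L2
K-nad4
M-L1-rrnL-V
P-cox3-A
Q!-nad1!-T*!
R-nad4L
atp8-atp6-N
cox2
nad2
nad3
rrnS
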