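#taxon anoplura_mrca
#source inferred most recent common ancestor of sucking lice (prior work)
C-rrnS
D-Y-cox2-nad6
E-cob-S1-S2
F-H-nad5
I-cox1-L2
K-nad4
M-L1-rrnL-V
Q!-nad1!-T*!-G-nad3-W
R-nad4L-P-cox3-A
atp8-atp6-N
nad2
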