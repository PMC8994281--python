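#taxon pedicinus_obtusus
#missing C N
#source macaque louse; cox2 and nad2 minichromosomes merged
E-cob
F-T-D-H-R-nad4L
G-nad3-W
I-cox1-L2
K-nad4
M-L1-rrnL-V
P-nad6
Q!-nad1!
S1-S2
Y-cox2-nad2
atp8-atp6
cox3-A
nad5
rrnS
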