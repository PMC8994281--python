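#taxon lepidophthirus_macrorhini
#missing C F G R S1 S2 Y nad3 nad4L nad6
#source southern elephant seal louse; 11 minichromosomes, 27 of 37 genes
atp8-atp6-N
cox2
D-rrnS
E-cob
H-nad5-W2
I-cox1-L2
K-nad4
M-L1-rrnL-V
nad2
P-cox3-A
Q!-nad1!-T*!-W1
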