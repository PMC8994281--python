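#taxon proechinophthirus_fluctus
#missing A D F L1 L2 M N P S1 V Y atp6 atp8 nad6 rrnL
#source northern fur seal louse; 10 minichromosomes, 22 of 37 genes
C-cox2
E-cob
G-cox3
H-nad5
I-cox1
K-nad4
Q!-nad1!-T!
R-nad4L-rrnS
S2-nad3
W-nad2
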