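#taxon antarctophthirus_carlinii
#missing C D F M S1 V nad6
#source Weddell seal louse; 9 minichromosomes, 30 of 37 genes
E-cob-H-nad5
G-K-nad4
I-cox1-L2-L1-rrnL
P-cox3-A
Q!-nad1!-T!
S2-cox2
W-R-nad4L
Y-nad2-nad3-rrnS
atp8-atp6-N
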