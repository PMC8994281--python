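#taxon antarctophthirus_microchir
#missing A C E F G H L1 L2 M N Q R S1 S2 V nad4L nad6
#source Australian sea lion louse; 12 minichromosomes, 20 of 37 genes
I-cox1
K-nad4
P-cox3
W-rrnS
Y-cob
atp8-atp6-D
cox2
nad1!-T!
nad2
nad3
nad5
rrnL
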