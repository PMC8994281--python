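#taxon haematopinus_apri
#source wild pig louse; 9 minichromosomes (least fragmented)
C-rrnS
D-Y-cox2-nad6
E-cob-S1-S2
F-H-nad5
I-cox1-L2-nad2
M-L1-rrnL-V
Q!-nad1!-T*!-G-nad3-W
R-nad4L-P-cox3-A
atp8-atp6-N-K-nad4
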