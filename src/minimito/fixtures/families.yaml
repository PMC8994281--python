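antarctophthirus_carlinii: Echinophthiriidae
antarctophthirus_lobodontis: Echinophthiriidae
antarctophthirus_microchir: Echinophthiriidae
lepidophthirus_macrorhini: Echinophthiriidae
proechinophthirus_fluctus: Echinophthiriidae
sealice_mrca: Echinophthiriidae
haematopinus_apri: Haematopinidae
pedicinus_obtusus: Pedicinidae
pthirus_pubis: Pthiridae
pthirus_gorillae: Pthiridae
primate_mrca: Pthiridae
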