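(haematopinus_apri,(pedicinus_obtusus,(pthirus_pubis,pthirus_gorillae)pthirus_mrca)primate_mrca,(lepidophthirus_macrorhini,(proechinophthirus_fluctus,(antarctophthirus_microchir,(antarctophthirus_carlinii,antarctophthirus_lobodontis)lobodontini)antarctophthirus_mrca)echinophthirius_core)sealice_mrca)anoplura_mrca;
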