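site,n_native_species,n_alien_species,alien_species_pct,alien_flower_pct,trait_similarity_mean,trait_similarity_sd
Chapo 1,9,3,25,11,0.80,0.04
Playa Maya,7,2,22,40,0.79,0.04
Chapo 2,10,4,28,78,0.77,0.11
Telchac,8,6,42,79,0.78,0.05
Cancunito,4,4,50,90,0.80,0.03
Punta Meco,8,6,42,92,0.79,0.03
Sisal,9,6,27,96,0.78,0.04
Charcas,9,3,27,97,0.81,0.03
Chabihau,11,9,47,99,0.79,0.04
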