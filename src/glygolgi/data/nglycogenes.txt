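# Curated N-glycosylation gene panel (76 genes).
# Editable text resource: one gene symbol per line, '#' starts a comment.
# Covers LLO assembly (Alg/Dpm/Dpagt1), oligosaccharyltransferase,
# ER glucosidases and folding lectins, Golgi mannosidases, GlcNAc
# branching (Mgat), core fucosylation and GDP-Fuc supply, galactosyl-
# and sialyltransferases, and nucleotide-sugar synthesis/transport.
Alg1
Alg2
Alg3
Alg5
Alg6
Alg8
Alg9
Alg10
Alg11
Alg12
Alg13
Alg14
Dpagt1
Dpm1
Dpm2
Dpm3
Rpn1
Rpn2
Ddost
Stt3a
Stt3b
Dad1
Tusc3
Mogs
Ganab
Prkcsh
Uggt1
Calr
Canx
Edem1
Man1a1
Man1a2
Man1b1
Man1c1
Man2a1
Man2a2
Mgat1
Mgat2
Mgat3
Mgat4a
Mgat4b
Mgat5
Mgat5b
Fut8
Fpgt
Gmds
Tsta3
Slc35c1
B4galt1
B4galt2
B4galt3
B4galt4
B4galt5
B4galt6
B4galt7
St3gal1
St3gal2
St3gal3
St3gal4
St6gal1
St6gal2
Slc35a1
Slc35a2
Slc35a3
Slc35b4
Slc35d1
Gale
Ugp2
Uap1
Gne
Cmas
Nans
Gmppa
Gmppb
Gfpt1
Pgm3
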