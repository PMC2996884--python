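# Binary enhancer presence/absence per species: activity x genomic location.
# Soft entries (marginal observation calls): Dgri epidermal_5prime, Dwil
# epidermal_intron; both shipped as 1, overridable in load_yellow_characters.
taxon	epidermal_5prime	epidermal_intron	vein_5prime	vein_intron	bristle_5prime	bristle_intron
Dmel	1	0	0	1	0	1
Dpse	1	1	0	1	0	1
Dwil	1	1	1	0	0	1
Dmoj	0	1	1	1	0	1
Dvir	1	1	1	1	0	1
Dgri	1	1	0	0	0	1
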