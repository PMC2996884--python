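# Span (bp) of each surveyed locus: the yellow gene plus its 5' intergenic
# region, computed from the 1-based inclusive assembly coordinates.
species	length
Dmel	8311
Dpse	10398
Dwil	10238
Dmoj	18072
Dvir	17199
Dgri	14565
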