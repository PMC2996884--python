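# cisarch

Comparative analysis of *cis*-regulatory architecture: where do a gene's
tissue-specific enhancers sit in the genome, and how did they get there?

Enhancers can end up in different genomic regions (5′ intergenic vs
intronic) in different species by two very different routes: **relocation
of an existing element** via segmental duplication or transposition, or
**sequential nucleotide substitution** that builds an enhancer de novo in
one place while destroying it in another.  The two routes leave different
sequence footprints.  A duplication of a 5′ enhancer into the intron
predicts sequence similarity between one species' 5′ region and another's
intron (and between the two regions within one genome); gradual
substitution predicts *only collinear* similarity — blocks whose
coordinates increase monotonically in both sequences.

`cisarch` implements the complete computational chain for making this
call on locus-scale (5–20 kb) sequences, plus the ancestral-state
reconstruction that summarizes the history, for audiences working on
regulatory evolution in *Drosophila* or comparable systems:

- **Spaced-seed seed-and-extend local alignment** (`cisarch.seed_align`):
  19-nt spaced seed with 12 care positions, ungapped extension stopping
  at 2 mismatches per end, HSP length filter, anchored affine-gap x-drop
  gapped extension (HOXD70 scores, gap open 400 / extend 30).
- **Shuffle-null significance calibration** (`cisarch.calibration`): the
  minimum HSP length *L* in the `--mismatch 2,L`-style criterion is set
  empirically as the smallest threshold at which a real-vs-shuffled
  self-comparison yields zero significant blocks.
- **Dotplot collinearity classification** (`cisarch.collinearity`):
  region labelling, maximum-weight collinear chain
  (longest-increasing-subsequence), and a per-pair verdict:
  `collinear_only`, `duplication_or_transposition`, or `no_similarity`.
- **Loss-biased Sankoff parsimony** (`cisarch.parsimony`): ancestral
  presence/absence of each enhancer activity × location character on the
  six-species tree under loss-cheaper-than-gain costs, with all
  most-parsimonious reconstructions enumerated.
- **Synthetic data with ground truth** (`cisarch.synthetic`):
  tree-structured sequence evolution with substitutions, indels,
  duplications and transpositions, plus binary gain/loss character
  histories — every event logged and replayable.

See `docs/methods.md` for the model details and design choices.

## Worked example

Reconstruct the ancestral enhancer architecture of the *yellow* locus
from the shipped six-species presence/absence fixture (costs: loss 1,
gain 2):

```sh
$ cisarch ancestral --out-dir anc_out
epidermal_5prime: root state 1, cost 1
epidermal_intron: root state 1, cost 1
vein_5prime: root state 1, cost 2
vein_intron: root state 1, cost 2
bristle_5prime: root state 0, cost 0
bristle_intron: root state 1, cost 0
per-lineage losses -> anc_out/loss_summary.tsv
```

Root state 1 for all four epidermal/vein characters means the most
parsimonious common ancestor carried *both* a 5′ intergenic and an
intronic enhancer for epidermal-cell and wing-vein expression, while
bristle activity was intronic only (root 0 for `bristle_5prime`).  The
loss summary shows at least one enhancer loss on the root-to-tip path of
every species except *D. virilis*:

```
        loss_always  loss_ever
Dgri    True         True
Dmel    True         True
Dmoj    True         True
Dpse    True         True
Dvir    False        False
Dwil    True         True
```

Calibrating the alignment significance threshold on a synthetic
six-locus concatenation (the real locus spans, GC 0.40, 79,283 bp with
spacers) against one shuffle replicate:

```python
>>> import cisarch as ca
>>> loci = ca.make_locus_fixture([8311, 10398, 10238, 18072, 17199, 14565],
...                              gc=0.4, rng_seed=42)
>>> cat, _ = ca.concatenate(loci, spacer_len=100)
>>> r = ca.calibrate_min_length(cat, rng_seed=4)
>>> r.chosen, r.counts[19], r.counts[22]
(23, 48, 3)
```

At the relaxed threshold 19 this replicate finds 48 chance similarity
regions in the shuffled null; by length 23 none survive, so 23 is the
calibrated minimum HSP length for this replicate.  Because the crossing
tracks the few best chance alignments, single replicates vary; the
multi-replicate mode (`calibrate_replicates`, CLI `cisarch calibrate`)
reports the modal threshold and the full distribution.

Other subcommands: `align` (blocks + dotplot coordinates for any two
FASTA sequences), `classify` (mechanism verdict for one pair),
`pairgrid` (all-pairs grid including self-comparisons), `simulate`
(synthetic loci, tree-evolved sequences, character histories).  Every
run writes a `manifest.json` sufficient to reproduce it.

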