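# Methods

`cisarch` asks how the tissue-specific enhancers of a gene can come to sit
in different genomic regions (5′ intergenic vs intron) in different
species, using locus-scale sequence comparison and ancestral-state
reconstruction.  Two mechanisms are contrasted: *relocation of existing
elements* (segmental duplication or transposition, which leaves similarity
between non-homologous regions) and *sequential nucleotide substitution*
(de novo construction/destruction of binding sites, which leaves only
collinear similarity).  The package implements the full computational
chain — pairwise local alignment, empirical significance calibration,
dotplot collinearity classification, and weighted-parsimony reconstruction
of ancestral enhancer locations — together with a synthetic-data generator
that replaces the wet-lab inputs and carries full ground truth.

## Seed-and-extend alignment (`seed_align`)

The aligner follows the BLASTZ/LASTZ architecture:

1. **Spaced seeding.**  A hit is any position pair whose 19-column window
   matches at the 12 care positions of the spaced seed
   `1110100110010101111` (the canonical 12-of-19 pattern of this aligner
   family; any weight-12/length-19 pattern can be supplied).  Windows
   containing a masked care position in either sequence are skipped.
   Reverse-strand hits are found against the reverse complement of the
   target and reported with a strand flag.
2. **Ungapped extension.**  Each hit is extended column by column in both
   directions; a side stops after it has encountered
   `max_mismatch_per_end = 2` mismatches, reached a masked position, or hit
   the sequence boundary.  Mismatches at don't-care positions inside the
   seed do not count toward the stop budget (the budget governs extension
   columns only).  The extension is trimmed so its first and last columns
   are matches, which makes the length criterion well defined.
3. **HSP filter.**  Extended seeds at least `min_hsp_len` columns long
   (default 23; the relaxed setting is 19, the seed length) are
   high-scoring segment pairs; overlapping extensions on one diagonal are
   deduplicated to the longest.
4. **Gapped extension.**  Each surviving HSP anchors an affine-gap x-drop
   dynamic-programming extension from both of its ends (Gotoh recurrences,
   adaptive column window, x-drop 900).  Scores use the HOXD70
   substitution table (match +91/+100, transition −31, transversion −114
   to −125), gap open 400, gap extend 30.  A result is a significant
   `SimilarityBlock` if its total score reaches the final score threshold.

**Final score threshold.**  By default the threshold is *derived* from the
ungapped criterion: the score of a `min_hsp_len`-column run containing
`max_mismatch_per_end` mismatches, computed with the worst match score and
the best mismatch score of the table (e.g. 21·91 + 2·(−31) = 1849 for the
2,23 setting).  This mirrors how the reference aligner couples its gapped
score threshold to the `--mismatch N,L` criterion when that option is
used, and it is the only choice under which the empirical calibration
below is self-consistent: a fixed large threshold (e.g. 3000) can never be
reached by shuffled-sequence alignments, so the calibrated length would
degenerate to the bottom of the tested range.  A numeric override is
available (`final_score_threshold`).

Implementation notes: seeding is hash-based (packed 2-bit keys over care
positions, sorted-array join); ungapped extension is evaluated per
diagonal with vectorized mismatch bookkeeping and is verified in the test
suite against an independent per-column step-through on every tested pair;
anchors whose seed falls inside an already-accepted block *and* within
that block's diagonal band are folded into it rather than re-extended;
blocks whose paths coincide (same strand, intersecting diagonal bands,
mutual overlap > 50%) are pruned to the higher-scoring one.  Ties are
broken deterministically (higher score, then smaller query start).

## Shuffle-null calibration (`calibration`)

The minimum HSP length is not assumed; it is set empirically.  The input
loci are concatenated with 100-N spacers (so no seed spans two loci), the
concatenation is shuffled (composition-preserving mononucleotide
permutation; N positions stay in place; a dinucleotide-preserving
Altschul–Erikson shuffle is available), and the real sequence is aligned
against its shuffle.  The calibrated threshold is the smallest value for
which *zero* significant similarity regions survive; counts are
non-increasing in the threshold by construction.  If no threshold in the
tested range (default 19–60) reaches zero, the result is an explicit
failure, never a silent default.  "Significant regions" are full-pipeline
blocks by default; `hsp_only=True` counts length-filtered HSPs instead.

The null is real-vs-shuffled, not shuffled-vs-shuffled, matching how such
dotplot controls are normally drawn.  Because a single randomization is
one draw from the null, the multi-replicate mode repeats the procedure
over seeded shuffles and reports the modal threshold with the full
distribution.  On the six-locus synthetic fixture (spans 8,311 / 10,398 /
10,238 / 18,072 / 17,199 / 14,565 bp, GC 0.40, total 79,283 with spacers)
the modal threshold over ten replicates is 23–25 depending on the seed
stream, with per-replicate values ranging roughly 23–30; the relaxed
threshold 19 admits ~35–50 null regions.  The spread is a property of the
extreme-value statistics of the null (the crossing tracks the best few
chance alignments among ~10³ seed hits), and is exactly what the
multi-replicate distribution is meant to expose.

## Collinearity classification (`collinearity`)

Blocks are labelled by annotated region (5′ intergenic, exon 1, intron,
exon 2) with per-side overlap fractions.  The maximal collinear chain is a
maximum-total-aligned-length subset, strictly increasing in both query and
target start, in which consecutive members may not overlap by more than
half of the shorter span on either axis (two blocks re-using the same
region are duplication evidence, not a collinear progression); it is
computed by weighted longest-increasing-subsequence DP with deterministic
tie-breaks and verified against exhaustive subset enumeration in tests.

A pairwise comparison is classified `duplication_or_transposition` iff any
significant block is off the chain, pairs discordant non-exon regions (one
side's 5′ intergenic region with the other's intron, judged by dominant
label > 0.5), or lies on the reverse strand (inversion evidence;
switchable); `collinear_only` otherwise; `no_similarity` when no blocks
remain.  Exon-anchored blocks (dominant exon label on both sides) are
excluded from the verdict by default — homologous exons are trivially
conserved between any pair of species — but still reported.  The minimum
off-chain block length that counts as evidence is the calibrated
threshold itself; the calibration already defines significance, so no
extra margin is added.  Self-comparisons remove the trivial identity
diagonal and deduplicate mirror-image blocks; any surviving block is
within-genome duplication evidence.

## Parsimony reconstruction (`parsimony`)

Each enhancer activity × location pair is one independent binary character
on the fixed six-taxon topology `(((Dmel,Dpse),Dwil),((Dmoj,Dvir),Dgri))`.
Because mutation disrupts transcription-factor binding sites more readily
than it creates them, loss is assumed cheaper than gain: default costs
loss = 1, gain = 2, plus a `loss_only` limiting mode (gain forbidden below
the root).  Sankoff dynamic programming yields the minimal cost; the root
state is the cost-minimizing state with no prior, ties reported as
ambiguity; *all* most-parsimonious reconstructions are enumerated and
validated against exhaustive enumeration over internal-state assignments.
Per-lineage event summaries use the path convention: a loss on a shared
internal branch counts toward every descendant taxon.

The shipped character fixture encodes the observed reporter-assay calls
(present = expression above background in the tissue, regardless of the
precise spatial sub-pattern).  Two entries rest on marginal observations
and are flagged soft — Dgri epidermal_5prime (a small patch of epidermal
expression flanking two wing veins, scored 1) and Dwil epidermal_intron
(thorax+wing but not abdomen expression, scored 1) — and both can be
flipped via `load_yellow_characters`; the headline reconstruction (root
carries epidermal and vein enhancers in both locations, bristle in the
intron only, with ≥1 loss on the path to every taxon except Dvir) holds
for both settings of the Dgri entry.  Branch lengths in the shipped tree
are divergence-time-scale ages normalized to a root age of 1.0 (≈40 My);
parsimony itself uses only the topology.

## Synthetic data (`synthetic`)

The generator emulates everything the pipeline consumes:

- `make_locus_fixture` — independent uniform-random loci at given lengths
  and GC content (defaults: the six real spans, GC 0.40 ≈ the genomic
  base composition of these loci).
- `simulate_sequences` — root sequence evolved down a tree: uniform
  (Jukes–Cantor-like) substitutions at `subst_prob` per site scaled by
  branch length; Poisson indels with geometric lengths; requested
  duplications (copy-and-insert) and transpositions (cut-and-insert)
  applied on their branches with logged pre/post coordinates; annotations
  carried to the tips through every coordinate edit.
- `simulate_characters` — exact jump simulation of a two-state
  gain/loss process (rates α, β per unit branch length), every event
  logged; root states fixed or drawn from the stationary distribution.

All randomness derives from one top-level seed via `SeedSequence`
spawning (one stream per tree node, preorder), so every stage replays
independently.  Every run's `EventLog` is replayable: a log-only replay
reproduces the tip sequences byte for byte, which the tests assert.

What the generator does *not* emulate: realistic binding-site turnover,
selection, context-dependent mutation, rate heterogeneity, and the
repeat content of real loci (synthetic fixtures are unmasked, so the
shuffle-null calibration sees a slightly longer searchable sequence than
repeat-masked real data would provide).  Passing tests therefore
demonstrate correctness and power of the *method* under controlled
conditions, not performance guarantees on real genomic sequence.

## Problem sizes used in tests

The test suite runs the calibration at full scale (the 79-kb six-locus
concatenation, ten replicates).  Mechanism power/specificity use 3.8-kb
two-species loci (50 duplication and 50 substitution histories, ~10%
pairwise divergence, 300-bp duplications); aligner oracle equivalence uses
100 pairs up to 2 kb plus a 410-bp full-DP fixture.  These sizes were
chosen so that every null and power quantity is measured with meaningful
replication while the whole suite stays comfortably interactive.

## Known limitations

- The mechanism verdict is a formalization of a qualitative dotplot
  reading; its thresholds (dominant-label 0.5, 50% chain overlap) are
  design choices, not derived quantities.
- The calibrated threshold is an extreme-value statistic and varies by
  ±2 between shuffle replicates at this input size; single-replicate
  calibrations should be treated accordingly.
- No analytic E-values; significance is purely empirical, by design.
- Gapped extension is anchored and banded by the x-drop rule; it is not a
  full-sensitivity local aligner (the optimal-DP oracle exists only in
  the tests).
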