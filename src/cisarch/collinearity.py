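"""Dotplot collinearity analysis and mechanism classification.

Under descent without structural rearrangement, similarity blocks between
two orthologous loci are expected to be *collinear*: their coordinates
increase monotonically in both sequences.  An enhancer relocated by a
segmental duplication or transposition instead produces similarity pairing
non-homologous regions -- a block off the collinear chain, a block joining
one locus' 5' intergenic region to the other's intron, or (within one
genome) a surviving self-similarity block.  This module formalizes that
dotplot reading: label blocks by annotated region, find the
maximum-weight collinear chain, and classify each pairwise comparison.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .seed_align import (ExtensionParams, PairScan, SeedParams,
                         SimilarityBlock, align_pair)
from .seqio import MaskedSequence, RegionAnnotation

__all__ = [
    "DotplotReport",
    "label_blocks",
    "longest_collinear_chain",
    "classify_comparison",
    "self_similarity",
]

logger = logging.getLogger(__name__)

VERDICT_COLLINEAR = "collinear_only"
VERDICT_REARRANGED = "duplication_or_transposition"
VERDICT_NONE = "no_similarity"

_EXON_LABELS = {"exon1", "exon2"}
_DISCORDANT_PAIRS = {("five_prime", "intron"), ("intron", "five_prime")}


@dataclass
class DotplotReport:
    """Classified pairwise comparison (one cell of the dotplot grid)."""

    query_id: str
    target_id: str
    blocks: list[SimilarityBlock] = field(default_factory=list)
    chain: list[int] = field(default_factory=list)
    off_chain: list[int] = field(default_factory=list)
    discordant: list[int] = field(default_factory=list)
    reverse: list[int] = field(default_factory=list)
    excluded_exon: list[int] = field(default_factory=list)
    verdict: str = VERDICT_NONE
    self_comparison: bool = False

    def write_tsv(self, path) -> None:
        chain = set(self.chain)
        with open(path, "w") as fh:
            fh.write("query_id\tq_start\tq_end\ttarget_id\tt_start\tt_end\t"
                     "strand\tscore\tlength\tin_chain\tq_labels\tt_labels\t"
                     "discordant\texon_excluded\n")
            for i, b in enumerate(self.blocks):
                ql = _fmt_labels(b.query_labels)
                tl = _fmt_labels(b.target_labels)
                fh.write(
                    f"{b.query_id}\t{b.query_start + 1}\t{b.query_end}\t"
                    f"{b.target_id}\t{b.target_start + 1}\t{b.target_end}\t"
                    f"{b.strand}\t{b.score}\t{b.aligned_length}\t"
                    f"{int(i in chain)}\t{ql}\t{tl}\t"
                    f"{int(i in self.discordant)}\t{int(i in self.excluded_exon)}\n"
                )
            fh.write(f"#verdict\t{self.query_id}\t{self.target_id}\t{self.verdict}\n")


def _fmt_labels(labels: dict[str, float] | None) -> str:
    if not labels:
        return "."
    return ",".join(f"{k}:{v:.2f}" for k, v in sorted(labels.items()))


def label_blocks(
    blocks: list[SimilarityBlock],
    annot_q: RegionAnnotation | None,
    annot_t: RegionAnnotation | None,
) -> list[SimilarityBlock]:
    """Attach per-side region-label overlap fractions to each block.

    Blocks falling outside the annotated span get label ``other`` (a missing
    annotation labels the whole side ``other`` with a warning).
    """
    for b in blocks:
        if annot_q is None:
            b.query_labels = {"other": 1.0}
        else:
            b.query_labels = annot_q.label_fractions(b.query_start, b.query_end)
        if annot_t is None:
            b.target_labels = {"other": 1.0}
        else:
            b.target_labels = annot_t.label_fractions(b.target_start, b.target_end)
    if blocks and (annot_q is None or annot_t is None):
        logger.warning("missing annotation; blocks labeled 'other'")
    return blocks


def _dominant(labels: dict[str, float] | None) -> str | None:
    """Label covering more than half of the block side, if any."""
    if not labels:
        return None
    lab, frac = max(labels.items(), key=lambda kv: (kv[1], kv[0]))
    return lab if frac > 0.5 else None


def _is_exon_anchored(b: SimilarityBlock) -> bool:
    return _dominant(b.query_labels) in _EXON_LABELS and \
        _dominant(b.target_labels) in _EXON_LABELS


def _is_discordant(b: SimilarityBlock) -> bool:
    return (_dominant(b.query_labels), _dominant(b.target_labels)) \
        in _DISCORDANT_PAIRS


def _can_follow(a: SimilarityBlock, b: SimilarityBlock) -> bool:
    """True if block ``b`` can follow ``a`` in a collinear chain.

    Both starts must strictly increase, and neither the query nor the
    target interval may overlap the predecessor by more than half of the
    shorter span -- two blocks re-using the same region are duplication
    evidence, not a collinear progression.
    """
    if not (a.query_start < b.query_start and a.target_start < b.target_start):
        return False
    qo = min(a.query_end, b.query_end) - b.query_start
    to = min(a.target_end, b.target_end) - b.target_start
    q_lim = 0.5 * min(a.query_span, b.query_span)
    t_lim = 0.5 * min(a.target_span, b.target_span)
    return qo <= q_lim and to <= t_lim


def longest_collinear_chain(blocks: list[SimilarityBlock]) -> list[int]:
    """Maximum-total-aligned-length chain strictly increasing in both starts.

    Weighted longest-increasing-subsequence over blocks sorted by query
    start; only forward-strand blocks can be chained, and consecutive chain
    members may not substantially overlap (see :func:`_can_follow`).
    Deterministic tie-break: the chain whose blocks have the smaller query
    starts.
    """
    idx = [i for i, b in enumerate(blocks) if b.strand == "+"]
    idx.sort(key=lambda i: (blocks[i].query_start, blocks[i].target_start))
    n = len(idx)
    best_w = [0] * n
    prev = [-1] * n
    for a in range(n):
        ba = blocks[idx[a]]
        w, p = 0, -1
        for c in range(a):
            bc = blocks[idx[c]]
            if _can_follow(bc, ba):
                if best_w[c] > w:
                    w, p = best_w[c], c
        best_w[a] = w + blocks[idx[a]].aligned_length
        prev[a] = p
    if n == 0:
        return []
    end = max(range(n), key=lambda a: (best_w[a], -blocks[idx[a]].query_start))
    chain = []
    while end != -1:
        chain.append(idx[end])
        end = prev[end]
    return chain[::-1]


def classify_comparison(
    blocks: list[SimilarityBlock],
    annot_q: RegionAnnotation | None = None,
    annot_t: RegionAnnotation | None = None,
    exclude_exons: bool = True,
    min_evidence_len: int | None = None,
    count_reverse: bool = True,
    self_comparison: bool = False,
) -> DotplotReport:
    """Classify one pairwise comparison as collinear vs rearranged.

    Verdict is ``duplication_or_transposition`` iff any significant block is
    off the maximal collinear chain, pairs discordant non-exon regions
    (5' intergenic with intron), or (optionally) lies on the reverse strand;
    ``collinear_only`` otherwise; ``no_similarity`` when no (non-exon)
    blocks exist.  Exon-anchored blocks are trivially conserved between any
    pair of species and are excluded from the verdict by default (still
    reported).
    """
    if not blocks:
        return DotplotReport(query_id="", target_id="", verdict=VERDICT_NONE,
                             self_comparison=self_comparison)
    label_blocks(blocks, annot_q, annot_t)
    report = DotplotReport(query_id=blocks[0].query_id,
                           target_id=blocks[0].target_id,
                           blocks=blocks, self_comparison=self_comparison)
    min_len = 0 if min_evidence_len is None else min_evidence_len
    working: list[int] = []
    for i, b in enumerate(blocks):
        if exclude_exons and _is_exon_anchored(b):
            report.excluded_exon.append(i)
        else:
            working.append(i)
    if not working:
        report.verdict = VERDICT_NONE
        return report
    wblocks = [blocks[i] for i in working]
    chain_local = longest_collinear_chain(wblocks)
    report.chain = [working[i] for i in chain_local]
    chain_set = set(report.chain)
    for i in working:
        b = blocks[i]
        if b.strand == "-":
            report.reverse.append(i)
        if _is_discordant(b):
            report.discordant.append(i)
        if i not in chain_set and b.strand == "+" and b.aligned_length >= min_len:
            report.off_chain.append(i)
    evidence = bool(report.off_chain) or bool(report.discordant)
    if count_reverse and any(blocks[i].aligned_length >= min_len
                             for i in report.reverse):
        evidence = True
    if self_comparison:
        # any surviving non-trivial self block is a duplication candidate
        evidence = bool(working)
    report.verdict = VERDICT_REARRANGED if evidence else VERDICT_COLLINEAR
    return report


def self_similarity(
    seq: MaskedSequence,
    annot: RegionAnnotation | None = None,
    seed_params: SeedParams | None = None,
    ext_params: ExtensionParams | None = None,
    exclude_exons: bool = True,
) -> DotplotReport:
    """Within-locus duplication scan: align a sequence to itself.

    The trivial full-length identity block is removed and mirror-image
    blocks (the dotplot is symmetric) deduplicated; any surviving block is
    internal-repeat/duplication evidence -- e.g. similarity between the 5'
    intergenic region and the intron of the same locus.
    """
    blocks = align_pair(seq, seq, seed_params, ext_params)
    kept: list[SimilarityBlock] = []
    seen: set[tuple] = set()
    for b in blocks:
        if b.strand == "+" and b.query_start == b.target_start \
                and b.query_end == b.target_end:
            continue  # self-identity diagonal
        key = (min(b.query_start, b.target_start), min(b.query_end, b.target_end),
               max(b.query_start, b.target_start), max(b.query_end, b.target_end),
               b.strand)
        if key in seen:
            continue
        seen.add(key)
        kept.append(b)
    report = classify_comparison(kept, annot, annot,
                                 exclude_exons=exclude_exons,
                                 self_comparison=True)
    report.query_id = report.target_id = seq.id
    report.self_comparison = True
    if not kept:
        report.verdict = VERDICT_NONE
    return report
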