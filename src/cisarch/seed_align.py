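"""Spaced-seed seed-and-extend pairwise local alignment.

The pipeline mirrors the classic BLASTZ/LASTZ architecture:

1. every position pair whose 19-column window matches at 12 "care"
   positions (and is unmasked there in both sequences) is a *seed hit*;
2. each hit is extended without gaps in both directions, a side stopping
   once it has encountered ``max_mismatch_per_end`` mismatches (default 2),
   hit a masked position, or reached a sequence boundary; the extension is
   trimmed so that its first and last columns are matches;
3. extended seeds at least ``min_hsp_len`` columns long are *HSPs*
   (high-scoring segment pairs), deduplicated per diagonal;
4. each surviving HSP anchors a gapped extension (affine-gap x-drop dynamic
   programming from both ends); the result is kept as a
   :class:`SimilarityBlock` if its total score reaches the final score
   threshold.

By default the final score threshold is *derived* from the ungapped
criterion: the score of a ``min_hsp_len``-column run containing
``max_mismatch_per_end`` mismatches (worst match score, best mismatch
score).  This couples gapped significance to the ``--mismatch N,L`` style
criterion the ungapped stage uses, the same coupling the reference aligner
applies when that option replaces its score threshold.  A fixed numeric
threshold can be supplied instead.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .seqio import MaskedSequence

__all__ = [
    "DEFAULT_SEED_PATTERN",
    "HOXD70",
    "SeedParams",
    "ExtensionParams",
    "SeedHit",
    "HSP",
    "SimilarityBlock",
    "PairScan",
    "find_seed_hits",
    "ungapped_extend",
    "filter_hsps",
    "gapped_extend",
    "align_pair",
    "write_blocks_tsv",
    "write_dotplot",
]

#: canonical 12-of-19 spaced seed of the BLASTZ/LASTZ family
DEFAULT_SEED_PATTERN = "1110100110010101111"

#: default substitution scores (HOXD70), rows/cols ordered A, C, G, T
HOXD70 = np.array(
    [
        [91, -114, -31, -123],
        [-114, 100, -125, -31],
        [-31, -125, 100, -114],
        [-123, -31, -114, 91],
    ],
    dtype=np.int64,
)

MASK_CODE = 4
#: score of any column involving a masked position; large enough to stop
#: x-drop extension at the first masked column
MASK_SCORE = -1000

_NEG = -(1 << 40)


def _score5(sub: np.ndarray) -> np.ndarray:
    s = np.full((5, 5), MASK_SCORE, dtype=np.int64)
    s[:4, :4] = sub
    return s


@dataclass(frozen=True)
class SeedParams:
    """Spaced-seed pattern: '1' = care position, '0' = don't-care."""

    pattern: str = DEFAULT_SEED_PATTERN

    def __post_init__(self) -> None:
        if not self.pattern or set(self.pattern) - {"0", "1"}:
            raise ValueError("pattern must be a non-empty string of 0/1")
        if self.pattern[0] != "1" or self.pattern[-1] != "1":
            raise ValueError("pattern must start and end with a care position")

    @property
    def length(self) -> int:
        return len(self.pattern)

    @property
    def weight(self) -> int:
        return self.pattern.count("1")

    @property
    def care_offsets(self) -> np.ndarray:
        return np.flatnonzero(np.frombuffer(self.pattern.encode(), np.uint8) == ord("1"))


@dataclass
class ExtensionParams:
    """Parameters of the ungapped and gapped extension stages."""

    max_mismatch_per_end: int = 2
    min_hsp_len: int = 23
    substitution: np.ndarray = field(default_factory=lambda: HOXD70.copy())
    gap_open: int = 400
    gap_extend: int = 30
    xdrop: int = 900
    final_score_threshold: int | None = None
    strand_mode: str = "both"

    def __post_init__(self) -> None:
        if self.strand_mode not in ("forward", "both"):
            raise ValueError("strand_mode must be 'forward' or 'both'")
        if self.gap_open < 0 or self.gap_extend < 0 or self.xdrop < 0:
            raise ValueError("penalties must be >= 0")
        self.substitution = np.asarray(self.substitution, dtype=np.int64)
        if self.substitution.shape != (4, 4):
            raise ValueError("substitution table must be 4x4")

    def score_threshold(self, min_hsp_len: int | None = None) -> int:
        """Final gapped score threshold.

        If ``final_score_threshold`` is unset, returns the score of a run of
        ``min_hsp_len`` columns containing ``max_mismatch_per_end``
        mismatches, scored with the worst match and best mismatch entries of
        the substitution table.
        """
        if self.final_score_threshold is not None:
            return self.final_score_threshold
        L = self.min_hsp_len if min_hsp_len is None else min_hsp_len
        n = self.max_mismatch_per_end
        diag = np.diag(self.substitution)
        off = self.substitution[~np.eye(4, dtype=bool)]
        return int((L - n) * diag.min() + n * off.max())


@dataclass(frozen=True)
class SeedHit:
    """One spaced-seed match.

    ``target_pos`` is given on the strand the comparison runs on: for
    ``strand == '-'`` it indexes the reverse-complemented target.
    """

    query_pos: int
    target_pos: int
    strand: str = "+"


@dataclass(frozen=True)
class HSP:
    """Gap-free extended seed; intervals are half-open, equal width."""

    query_start: int
    query_end: int
    target_start: int
    target_end: int
    strand: str
    mismatches: int
    score: int

    @property
    def length(self) -> int:
        return self.query_end - self.query_start

    @property
    def diagonal(self) -> int:
        return self.target_start - self.query_start


@dataclass
class SimilarityBlock:
    """One gapped local alignment between two sequences.

    Coordinates are half-open and *forward-strand* on both sequences; for
    ``strand == '-'`` the aligned path pairs the query interval with the
    reverse complement of the target interval.
    """

    query_id: str
    target_id: str
    query_start: int
    query_end: int
    target_start: int
    target_end: int
    strand: str
    score: int
    aligned_length: int
    gaps: int
    anchor_max_len: int = 0
    query_labels: dict[str, float] | None = None
    target_labels: dict[str, float] | None = None

    @property
    def query_span(self) -> int:
        return self.query_end - self.query_start

    @property
    def target_span(self) -> int:
        return self.target_end - self.target_start

    def transpose(self) -> "SimilarityBlock":
        """The same alignment viewed with query and target swapped."""
        return SimilarityBlock(
            query_id=self.target_id,
            target_id=self.query_id,
            query_start=self.target_start,
            query_end=self.target_end,
            target_start=self.query_start,
            target_end=self.query_end,
            strand=self.strand,
            score=self.score,
            aligned_length=self.aligned_length,
            gaps=self.gaps,
            anchor_max_len=self.anchor_max_len,
            query_labels=self.target_labels,
            target_labels=self.query_labels,
        )


def _revcomp_codes(codes: np.ndarray) -> np.ndarray:
    out = codes[::-1].copy()
    lt4 = out < 4
    out[lt4] = 3 - out[lt4]
    return out


def _window_keys(codes: np.ndarray, offsets: np.ndarray, length: int):
    """Spaced-seed keys and validity for every window start."""
    n = len(codes) - length + 1
    if n <= 0:
        return np.empty(0, np.int64), np.empty(0, bool)
    keys = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for k, off in enumerate(offsets):
        col = codes[off : off + n].astype(np.int64)
        valid &= col < 4
        keys += col << (2 * k)
    return keys, valid


def find_seed_hits(
    query: MaskedSequence,
    target: MaskedSequence,
    params: SeedParams | None = None,
    strand_mode: str = "forward",
) -> list[SeedHit]:
    """All spaced-seed matches between query and target.

    Windows containing a masked care position in either sequence are
    skipped.  Sequences shorter than the pattern yield no hits.
    """
    params = params or SeedParams()
    hits: list[SeedHit] = []
    strands = ("+",) if strand_mode == "forward" else ("+", "-")
    qcodes = query.codes
    for strand in strands:
        tcodes = target.codes if strand == "+" else _revcomp_codes(target.codes)
        for q, t in _hit_pairs(qcodes, tcodes, params):
            hits.append(SeedHit(int(q), int(t), strand))
    hits.sort(key=lambda h: (h.strand, h.query_pos, h.target_pos))
    return hits


def _hit_pairs(qcodes, tcodes, params: SeedParams):
    offs = params.care_offsets
    L = params.length
    qk, qv = _window_keys(qcodes, offs, L)
    tk, tv = _window_keys(tcodes, offs, L)
    qpos = np.flatnonzero(qv)
    tpos = np.flatnonzero(tv)
    if len(qpos) == 0 or len(tpos) == 0:
        return np.empty((0, 2), dtype=np.int64)
    tkeys = tk[tpos]
    order = np.argsort(tkeys, kind="stable")
    tkeys_sorted = tkeys[order]
    tpos_sorted = tpos[order]
    qkeys = qk[qpos]
    left = np.searchsorted(tkeys_sorted, qkeys, side="left")
    right = np.searchsorted(tkeys_sorted, qkeys, side="right")
    counts = right - left
    which = np.flatnonzero(counts)
    if len(which) == 0:
        return np.empty((0, 2), dtype=np.int64)
    q_rep = np.repeat(qpos[which], counts[which])
    t_idx = np.concatenate([np.arange(left[i], right[i]) for i in which])
    return np.stack([q_rep, tpos_sorted[t_idx]], axis=1)


def ungapped_extend(
    hit: SeedHit,
    query: MaskedSequence,
    target: MaskedSequence,
    params: ExtensionParams | None = None,
    seed_params: SeedParams | None = None,
) -> HSP:
    """Extend one seed hit without gaps (reference step-through version).

    Extension proceeds column by column on each side of the seed span,
    stopping when that side has encountered ``max_mismatch_per_end``
    mismatches, a masked position, or the sequence boundary; the result is
    trimmed so its first and last columns are matches.  Mismatches at
    don't-care positions inside the seed do not count toward the stop
    budget.
    """
    params = params or ExtensionParams()
    seed_params = seed_params or SeedParams()
    S = _score5(params.substitution)
    qcodes = query.codes
    tcodes = target.codes if hit.strand == "+" else _revcomp_codes(target.codes)
    L = seed_params.length
    budget = params.max_mismatch_per_end

    def is_match(qi: int, tj: int) -> bool:
        return qcodes[qi] == tcodes[tj] and qcodes[qi] < 4

    def is_masked(qi: int, tj: int) -> bool:
        return qcodes[qi] == 4 or tcodes[tj] == 4

    # right side
    qi, tj = hit.query_pos + L, hit.target_pos + L
    mm = 0
    last_match_r = hit.query_pos + L - 1
    while qi < len(qcodes) and tj < len(tcodes):
        if is_masked(qi, tj):
            break
        if is_match(qi, tj):
            last_match_r = qi
        else:
            mm += 1
            if mm >= budget:
                break
        qi += 1
        tj += 1
    # left side
    qi, tj = hit.query_pos - 1, hit.target_pos - 1
    mm = 0
    first_match_l = hit.query_pos
    while qi >= 0 and tj >= 0:
        if is_masked(qi, tj):
            break
        if is_match(qi, tj):
            first_match_l = qi
        else:
            mm += 1
            if mm >= budget:
                break
        qi -= 1
        tj -= 1
    d = hit.target_pos - hit.query_pos
    qs, qe = first_match_l, last_match_r + 1
    cols_q = qcodes[qs:qe]
    cols_t = tcodes[qs + d : qe + d]
    mismatches = int(np.sum((cols_q != cols_t) | (cols_q >= 4)))
    score = int(S[cols_q, cols_t].sum())
    return HSP(qs, qe, qs + d, qe + d, hit.strand, mismatches, score)


def filter_hsps(hsps: list[HSP], min_hsp_len: int) -> list[HSP]:
    """Per-diagonal dedup (overlapping intervals keep the longest) + length filter."""
    by_diag: dict[tuple[str, int], list[HSP]] = {}
    for h in hsps:
        by_diag.setdefault((h.strand, h.diagonal), []).append(h)
    kept: list[HSP] = []
    for group in by_diag.values():
        group.sort(key=lambda h: (h.query_start, -h.length))
        cluster: list[HSP] = []
        cluster_end = -1
        for h in group:
            if cluster and h.query_start >= cluster_end:
                kept.append(max(cluster, key=lambda x: (x.length, -x.query_start)))
                cluster = []
            cluster.append(h)
            cluster_end = max(cluster_end, h.query_end)
        if cluster:
            kept.append(max(cluster, key=lambda x: (x.length, -x.query_start)))
    kept = [h for h in kept if h.length >= min_hsp_len]
    kept.sort(key=lambda h: (h.strand, h.query_start, h.target_start))
    return kept


@dataclass
class _Ext:
    score: int
    qi: int
    tj: int
    gaps: int
    cols: int


def _xdrop_extend(a: np.ndarray, b: np.ndarray, S: np.ndarray,
                  gap_open: int, gap_extend: int, xdrop: int) -> _Ext:
    """Affine-gap x-drop extension alignment of prefixes of ``a`` and ``b``.

    Returns the best-scoring end cell (score >= 0; the empty extension always
    scores 0) along with the gap-run count and aligned-column count of one
    optimal path to it.  Gotoh recurrences, rows over ``a``; per-row column
    window maintained from the x-drop pruning.
    """
    la, lb = len(a), len(b)
    best, bi, bj, bg, bc = 0, 0, 0, 0, 0
    if la == 0 or lb == 0:
        return _Ext(best, bi, bj, bg, bc)
    openc = gap_open + gap_extend
    # row 0: leading gap in a
    max0 = min(lb, (xdrop - gap_open) // gap_extend if gap_extend else lb)
    max0 = max(max0, 0)
    cols = np.arange(0, max0 + 1)
    H = -(gap_open + gap_extend * cols).astype(np.int64)
    H[0] = 0
    GH = np.where(cols > 0, 1, 0).astype(np.int64)
    CH = cols.astype(np.int64).copy()
    F = np.full(len(cols), _NEG, dtype=np.int64)
    GF = np.zeros(len(cols), dtype=np.int64)
    CF = np.zeros(len(cols), dtype=np.int64)
    lo = 0  # column index of cols[0]

    for i in range(1, la + 1):
        hi = lo + len(H) - 1
        nlo, nhi = lo, min(lb, hi + 1)
        if nlo > nhi:
            break
        n = nhi - nlo + 1
        jj = np.arange(nlo, nhi + 1)
        # diagonal: new[j] needs old H[j-1]
        diag = np.full(n, _NEG, dtype=np.int64)
        Gd = np.zeros(n, dtype=np.int64)
        Cd = np.zeros(n, dtype=np.int64)
        src_lo = max(nlo, lo + 1)  # smallest new j with old j-1 available
        if src_lo <= nhi:
            o0 = src_lo - 1 - lo          # index into old arrays
            o1 = min(nhi - 1, lo + len(H) - 1) - lo + 1
            m = o1 - o0
            if m > 0:
                sub = S[a[i - 1], b[src_lo - 1 : src_lo - 1 + m]]
                sl = src_lo - nlo
                diag[sl : sl + m] = H[o0:o1] + sub
                Gd[sl : sl + m] = GH[o0:o1]
                Cd[sl : sl + m] = CH[o0:o1] + 1
        # vertical gap (gap in b): from old row same column
        Fn = np.full(n, _NEG, dtype=np.int64)
        GFn = np.zeros(n, dtype=np.int64)
        CFn = np.zeros(n, dtype=np.int64)
        ov0 = max(nlo, lo)
        ov1 = min(nhi, lo + len(H) - 1)
        if ov0 <= ov1:
            s = ov0 - nlo
            m = ov1 - ov0 + 1
            o = ov0 - lo
            f_open = H[o : o + m] - openc
            f_ext = F[o : o + m] - gap_extend
            take_open = f_open >= f_ext
            Fn[s : s + m] = np.where(take_open, f_open, f_ext)
            GFn[s : s + m] = np.where(take_open, GH[o : o + m] + 1, GF[o : o + m])
            CFn[s : s + m] = np.where(take_open, CH[o : o + m], CF[o : o + m]) + 1
        # H0 = max(diag, F) (prefer diagonal on ties)
        useF = Fn > diag
        H0 = np.where(useF, Fn, diag)
        G0 = np.where(useF, GFn, Gd)
        C0 = np.where(useF, CFn, Cd)
        # horizontal gap (gap in a) within the new row, from H0 cells
        vals = H0 - gap_open + gap_extend * jj
        runmax = np.maximum.accumulate(vals)
        runarg = np.maximum.accumulate(
            np.where(vals >= runmax, np.arange(n), -1)
        )
        E = np.full(n, _NEG, dtype=np.int64)
        Esrc = np.zeros(n, dtype=np.int64)
        if n > 1:
            E[1:] = runmax[:-1] - gap_extend * jj[1:]
            Esrc[1:] = runarg[:-1]
        useE = E > H0
        Hn = np.where(useE, E, H0)
        Gn = G0.copy()
        Cn = C0.copy()
        if useE.any():
            k = Esrc[useE]
            Gn[useE] = G0[k] + 1
            Cn[useE] = C0[k] + (jj[useE] - jj[k])
        # x-drop pruning
        rowmax = int(Hn.max()) if n else _NEG
        if rowmax > best:
            at = int(np.argmax(Hn))
            best, bi, bj = rowmax, i, int(jj[at])
            bg, bc = int(Gn[at]), int(Cn[at])
        alive = Hn >= best - xdrop
        if not alive.any():
            break
        a0 = int(np.argmax(alive))
        a1 = n - 1 - int(np.argmax(alive[::-1]))
        Hn[~alive] = _NEG
        H, GH, CH = Hn[a0 : a1 + 1], Gn[a0 : a1 + 1], Cn[a0 : a1 + 1]
        F, GF, CF = Fn[a0 : a1 + 1], GFn[a0 : a1 + 1], CFn[a0 : a1 + 1]
        lo = nlo + a0
    return _Ext(int(best), int(bi), int(bj), int(bg), int(bc))


def _diag_band(blk: dict) -> tuple[int, int]:
    """Range of diagonals the block's aligned path can traverse."""
    d0 = blk["ts"] - blk["qs"]
    d1 = blk["te"] - blk["qe"]
    return (d0, d1) if d0 <= d1 else (d1, d0)


class PairScan:
    """Cached seed-and-extend scan of one sequence pair.

    Computes seed hits and maximal ungapped HSPs once, caches the gapped
    extension of every HSP, and can then report the significant
    :class:`SimilarityBlock` set for any ``min_hsp_len`` cheaply -- the
    calibration module exploits this when sweeping length thresholds.
    """

    def __init__(
        self,
        query: MaskedSequence,
        target: MaskedSequence,
        seed_params: SeedParams | None = None,
        ext_params: ExtensionParams | None = None,
    ):
        self.query = query
        self.target = target
        self.seed_params = seed_params or SeedParams()
        self.ext_params = ext_params or ExtensionParams()
        self._S5 = _score5(self.ext_params.substitution)
        self._hsps: list[HSP] | None = None
        self._gapped_cache: dict[HSP, tuple] = {}
        self._tcodes = {"+": target.codes}
        if self.ext_params.strand_mode == "both":
            self._tcodes["-"] = _revcomp_codes(target.codes)

    # ---------------- ungapped stage ----------------

    def hsps(self) -> list[HSP]:
        """Maximal per-diagonal-deduplicated HSPs on all scanned strands."""
        if self._hsps is None:
            out: list[HSP] = []
            for strand, tcodes in self._tcodes.items():
                out.extend(self._strand_hsps(strand, tcodes))
            self._hsps = filter_hsps(out, self.seed_params.length)
        return self._hsps

    def _strand_hsps(self, strand: str, tcodes: np.ndarray) -> list[HSP]:
        qcodes = self.query.codes
        pairs = _hit_pairs(qcodes, tcodes, self.seed_params)
        if len(pairs) == 0:
            return []
        L = self.seed_params.length
        budget = self.ext_params.max_mismatch_per_end
        diags = pairs[:, 1] - pairs[:, 0]
        out: list[HSP] = []
        for d in np.unique(diags):
            seeds = np.unique(pairs[diags == d, 0])
            q0 = max(0, -int(d))
            t0 = q0 + int(d)
            dlen = min(len(qcodes) - q0, len(tcodes) - t0)
            qa = qcodes[q0 : q0 + dlen]
            ta = tcodes[t0 : t0 + dlen]
            maskcol = (qa == 4) | (ta == 4)
            eq = (qa == ta) & ~maskcol
            mm_pos = np.flatnonzero(~eq & ~maskcol)
            mk_pos = np.flatnonzero(maskcol)
            sv = self._S5[qa, ta]
            cum = np.concatenate([[0], np.cumsum(sv)])
            mmset = set(mm_pos.tolist())
            mkset = set(mk_pos.tolist())
            s_arr = seeds - q0  # seed offsets in diagonal coordinates
            e_arr = s_arr + L
            def nth_at_or_after(pos_arr, starts, n):
                if len(pos_arr) == 0:
                    return np.full(len(starts), dlen)
                idx = np.searchsorted(pos_arr, starts) + n - 1
                return np.where(idx < len(pos_arr),
                                pos_arr[np.minimum(idx, len(pos_arr) - 1)], dlen)

            def nth_before(pos_arr, starts, n):
                if len(pos_arr) == 0:
                    return np.full(len(starts), -1)
                idx = np.searchsorted(pos_arr, starts) - n
                return np.where(idx >= 0, pos_arr[np.maximum(idx, 0)], -1)

            # right stop: budget-th plain mismatch (or first mask) at/after seed end
            stop_r = np.minimum(nth_at_or_after(mm_pos, e_arr, budget),
                                nth_at_or_after(mk_pos, e_arr, 1))
            # left stop: budget-th plain mismatch (or first mask) below seed start
            stop_l = np.maximum(nth_before(mm_pos, s_arr, budget),
                                nth_before(mk_pos, s_arr, 1))
            for s, e, sr, sl in zip(s_arr, e_arr, stop_r, stop_l):
                right = int(sr) - 1
                while right >= e and (right in mmset or right in mkset):
                    right -= 1
                if right < e:
                    right = int(e) - 1  # seed's last column is a care match
                left = int(sl) + 1
                while left < s and (left in mmset or left in mkset):
                    left += 1
                if left > s:
                    left = int(s)
                nmm = int(np.searchsorted(mm_pos, right + 1)
                          - np.searchsorted(mm_pos, left))
                score = int(cum[right + 1] - cum[left])
                out.append(HSP(q0 + left, q0 + right + 1,
                               t0 + left, t0 + right + 1,
                               strand, nmm, score))
        return out

    # ---------------- gapped stage ----------------

    def _gapped(self, h: HSP):
        """Gapped x-drop extension of an anchor; cached, threshold-free."""
        res = self._gapped_cache.get(h)
        if res is not None:
            return res
        p = self.ext_params
        qcodes = self.query.codes
        tcodes = self._tcodes[h.strand]
        left = _xdrop_extend(qcodes[: h.query_start][::-1],
                             tcodes[: h.target_start][::-1],
                             self._S5, p.gap_open, p.gap_extend, p.xdrop)
        right = _xdrop_extend(qcodes[h.query_end :],
                              tcodes[h.target_end :],
                              self._S5, p.gap_open, p.gap_extend, p.xdrop)
        res = (
            h.score + left.score + right.score,
            h.query_start - left.qi,
            h.query_end + right.qi,
            h.target_start - left.tj,
            h.target_end + right.tj,
            left.gaps + right.gaps,
            left.cols + h.length + right.cols,
        )
        self._gapped_cache[h] = res
        return res

    def blocks(self, min_hsp_len: int | None = None) -> list[SimilarityBlock]:
        """Significant similarity blocks at the given HSP length threshold."""
        p = self.ext_params
        t = p.min_hsp_len if min_hsp_len is None else min_hsp_len
        thr = p.score_threshold(t)
        cand = [h for h in self.hsps() if h.length >= t]
        cand.sort(key=lambda h: (-h.score, h.query_start, h.target_start, h.strand))
        accepted: list[dict] = []
        for h in cand:
            placed = False
            for blk in accepted:
                d0, d1 = _diag_band(blk)
                if (blk["strand"] == h.strand
                        and blk["qs"] <= h.query_start and h.query_end <= blk["qe"]
                        and blk["ts"] <= h.target_start and h.target_end <= blk["te"]
                        and d0 <= h.target_start - h.query_start <= d1):
                    blk["anchor_max_len"] = max(blk["anchor_max_len"], h.length)
                    placed = True
                    break
            if placed:
                continue
            score, qs, qe, ts, te, gaps, cols = self._gapped(h)
            if score >= thr:
                accepted.append(dict(strand=h.strand, qs=qs, qe=qe, ts=ts, te=te,
                                     score=score, gaps=gaps, cols=cols,
                                     anchor_max_len=h.length))
        accepted = self._prune_redundant(accepted)
        blocks = [self._finalize(b) for b in accepted]
        blocks.sort(key=lambda b: (b.query_start, b.target_start, b.strand))
        return blocks

    @staticmethod
    def _prune_redundant(accepted: list[dict]) -> list[dict]:
        """Drop blocks whose path coincides with a higher-scoring one.

        Two blocks are considered coincident when, on the same strand, their
        diagonal bands intersect and both the query and the target interval
        of the shorter overlap the longer by more than half.
        """
        accepted = sorted(accepted, key=lambda b: (-b["score"], b["qs"], b["ts"]))
        kept: list[dict] = []
        for b in accepted:
            redundant = False
            for k in kept:
                if k["strand"] != b["strand"]:
                    continue
                kd0, kd1 = _diag_band(k)
                bd0, bd1 = _diag_band(b)
                if kd1 < bd0 or bd1 < kd0:
                    continue
                qo = min(k["qe"], b["qe"]) - max(k["qs"], b["qs"])
                to = min(k["te"], b["te"]) - max(k["ts"], b["ts"])
                qlen = b["qe"] - b["qs"]
                tlen = b["te"] - b["ts"]
                if qo > 0.5 * qlen and to > 0.5 * tlen:
                    k["anchor_max_len"] = max(k["anchor_max_len"], b["anchor_max_len"])
                    redundant = True
                    break
            if not redundant:
                kept.append(b)
        return kept

    def _finalize(self, b: dict) -> SimilarityBlock:
        ts, te = b["ts"], b["te"]
        if b["strand"] == "-":
            Lt = len(self.target)
            ts, te = Lt - b["te"], Lt - b["ts"]
        return SimilarityBlock(
            query_id=self.query.id,
            target_id=self.target.id,
            query_start=b["qs"],
            query_end=b["qe"],
            target_start=ts,
            target_end=te,
            strand=b["strand"],
            score=int(b["score"]),
            aligned_length=int(b["cols"]),
            gaps=int(b["gaps"]),
            anchor_max_len=int(b["anchor_max_len"]),
        )


def gapped_extend(
    hsp: HSP,
    query: MaskedSequence,
    target: MaskedSequence,
    params: ExtensionParams | None = None,
) -> SimilarityBlock | None:
    """Gapped x-drop extension of a single anchor HSP.

    Returns a block only if the final score reaches the score threshold; the
    block always contains its anchor.
    """
    params = params or ExtensionParams()
    scan = PairScan(query, target, ext_params=params)
    score, qs, qe, ts, te, gaps, cols = scan._gapped(hsp)
    if score < params.score_threshold():
        return None
    return scan._finalize(dict(strand=hsp.strand, qs=qs, qe=qe, ts=ts, te=te,
                               score=score, gaps=gaps, cols=cols,
                               anchor_max_len=hsp.length))


def align_pair(
    query: MaskedSequence,
    target: MaskedSequence,
    seed_params: SeedParams | None = None,
    ext_params: ExtensionParams | None = None,
) -> list[SimilarityBlock]:
    """Full seed-and-extend pipeline: seeds -> HSPs -> anchored gapped blocks."""
    scan = PairScan(query, target, seed_params, ext_params)
    return scan.blocks()


def write_blocks_tsv(blocks: list[SimilarityBlock], path) -> None:
    """Blocks as TSV with 1-based inclusive output coordinates."""
    with open(path, "w") as fh:
        fh.write("query_id\tq_start\tq_end\ttarget_id\tt_start\tt_end\t"
                 "strand\tscore\tlength\tgaps\n")
        for b in blocks:
            fh.write(
                f"{b.query_id}\t{b.query_start + 1}\t{b.query_end}\t"
                f"{b.target_id}\t{b.target_start + 1}\t{b.target_end}\t"
                f"{b.strand}\t{b.score}\t{b.aligned_length}\t{b.gaps}\n"
            )


def write_dotplot(blocks: list[SimilarityBlock], path) -> None:
    """Block endpoints as plot-ready segment coordinates (1-based inclusive).

    One row per block: x0/x1 on the query, y0/y1 on the target; reverse
    blocks have y0 > y1 so any plotting tool draws the anti-diagonal.
    """
    with open(path, "w") as fh:
        fh.write("query_id\ttarget_id\tx0\tx1\ty0\ty1\tstrand\tscore\n")
        for b in blocks:
            if b.strand == "+":
                y0, y1 = b.target_start + 1, b.target_end
            else:
                y0, y1 = b.target_end, b.target_start + 1
            fh.write(
                f"{b.query_id}\t{b.target_id}\t{b.query_start + 1}\t"
                f"{b.query_end}\t{y0}\t{y1}\t{b.strand}\t{b.score}\n"
            )
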