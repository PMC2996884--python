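"""Empirical calibration of the minimum HSP length against a shuffle null.

The significance criterion of the alignment pipeline (the minimum length of
an extended seed treated as an HSP) is set empirically: the real sequence is
compared to a composition-preserving shuffle of itself, and the smallest
length threshold at which *no* significant similarity region survives is
adopted.  This is a purely empirical null -- no analytic E-value theory.

By default a "significant similarity region" is a :class:`SimilarityBlock`
surviving the full pipeline including the gapped stage; ``hsp_only=True``
counts gap-free HSPs passing the length filter instead.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .seed_align import ExtensionParams, PairScan, SeedParams
from .seqio import MaskedSequence, shuffle_sequence

__all__ = [
    "CalibrationResult",
    "CalibrationSummary",
    "count_null_hits",
    "calibrate_min_length",
    "calibrate_replicates",
]


@dataclass
class CalibrationResult:
    """Outcome of one calibration replicate.

    ``chosen`` is the smallest threshold with a zero null count, or ``None``
    if no threshold in the tested range reached zero (calibration failed --
    never silently defaulted).
    """

    chosen: int | None
    counts: dict[int, int]
    rng_seed: int
    replicate: int = 0

    @property
    def failed(self) -> bool:
        return self.chosen is None


@dataclass
class CalibrationSummary:
    """Multi-replicate calibration: modal threshold plus the full spread."""

    modal: int | None
    results: list[CalibrationResult] = field(default_factory=list)

    @property
    def distribution(self) -> dict[int | None, int]:
        return dict(Counter(r.chosen for r in self.results))


def _check_composition(real: MaskedSequence, shuffled: MaskedSequence) -> None:
    if real.composition() != shuffled.composition():
        raise ValueError(
            "shuffled sequence does not have the same residue composition as "
            "the real sequence; are the files paired correctly?"
        )


def count_null_hits(
    real: MaskedSequence,
    shuffled: MaskedSequence,
    threshold: int,
    seed_params: SeedParams | None = None,
    ext_params: ExtensionParams | None = None,
    hsp_only: bool = False,
    scan: PairScan | None = None,
) -> int:
    """Number of significant real-vs-shuffled similarity regions at ``threshold``.

    Pass a prepared :class:`PairScan` via ``scan`` to reuse the seed/extension
    work across thresholds; the counts are identical either way.
    """
    if scan is None:
        _check_composition(real, shuffled)
        scan = PairScan(real, shuffled, seed_params, ext_params)
    if hsp_only:
        return sum(1 for h in scan.hsps() if h.length >= threshold)
    return len(scan.blocks(threshold))


def calibrate_min_length(
    real: MaskedSequence,
    rng_seed: int,
    seed_params: SeedParams | None = None,
    ext_params: ExtensionParams | None = None,
    threshold_min: int = 19,
    threshold_max: int = 60,
    hsp_only: bool = False,
    shuffle_unit: int = 1,
    replicate: int = 0,
) -> CalibrationResult:
    """One calibration replicate: shuffle, sweep thresholds, pick the crossing.

    The null is real-vs-shuffled (not shuffled-vs-shuffled).  Counts are
    non-increasing in the threshold, and the chosen value is the smallest
    threshold whose count is zero.
    """
    if threshold_max < threshold_min:
        raise ValueError("threshold_max must be >= threshold_min")
    shuffled = shuffle_sequence(real, rng_seed, unit=shuffle_unit)
    _check_composition(real, shuffled)
    scan = PairScan(real, shuffled, seed_params, ext_params)
    counts: dict[int, int] = {}
    chosen: int | None = None
    for t in range(threshold_min, threshold_max + 1):
        counts[t] = count_null_hits(real, shuffled, t, hsp_only=hsp_only, scan=scan)
        if chosen is None and counts[t] == 0:
            chosen = t
    return CalibrationResult(chosen=chosen, counts=counts,
                             rng_seed=rng_seed, replicate=replicate)


def calibrate_replicates(
    real: MaskedSequence,
    rng_seeds: list[int],
    seed_params: SeedParams | None = None,
    ext_params: ExtensionParams | None = None,
    threshold_min: int = 19,
    threshold_max: int = 60,
    hsp_only: bool = False,
) -> CalibrationSummary:
    """Calibration over several shuffle replicates.

    Reports the modal chosen threshold (smallest value on ties) and the full
    per-replicate distribution so that the spread introduced by the choice of
    a single randomization can be quantified.
    """
    results = [
        calibrate_min_length(
            real, seed, seed_params, ext_params,
            threshold_min=threshold_min, threshold_max=threshold_max,
            hsp_only=hsp_only, replicate=i,
        )
        for i, seed in enumerate(rng_seeds)
    ]
    chosen = [r.chosen for r in results if r.chosen is not None]
    modal: int | None = None
    if chosen:
        counts = Counter(chosen)
        top = max(counts.values())
        modal = min(t for t, c in counts.items() if c == top)
    return CalibrationSummary(modal=modal, results=results)


def write_calibration_tsv(summary: CalibrationSummary, path) -> None:
    with open(path, "w") as fh:
        fh.write("replicate\trng_seed\tthreshold\tnull_count\tchosen\n")
        for r in summary.results:
            for t in sorted(r.counts):
                fh.write(f"{r.replicate}\t{r.rng_seed}\t{t}\t{r.counts[t]}\t"
                         f"{r.chosen if r.chosen is not None else 'NA'}\n")
        fh.write(f"#modal_threshold\t{summary.modal if summary.modal is not None else 'NA'}\n")
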