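"""Sequence I/O, composition-preserving shuffles, and locus concatenation.

Sequences are locus-scale (kilobases) DNA held as uppercase ``A/C/G/T/N``
strings plus a per-position boolean mask.  Masked positions -- soft-masked
(lowercase) residues in the input FASTA and every hard-masked ``N`` -- are
excluded from seeding and terminate ungapped extension downstream, which is
how repeat-masked input is conventionally treated by seed-and-extend
aligners.

Coordinates are 0-based half-open everywhere inside the library; user-facing
report writers convert to 1-based inclusive (genome-browser style).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MaskedSequence",
    "RegionAnnotation",
    "CoordinateMap",
    "read_fasta",
    "write_fasta",
    "shuffle_sequence",
    "concatenate",
    "read_region_bed",
    "write_region_bed",
]

logger = logging.getLogger(__name__)

VALID_RESIDUES = frozenset("ACGTN")
REGION_LABELS = ("five_prime", "exon1", "intron", "exon2", "other")

#: integer codes used by the alignment layer; 4 marks a masked position
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_DECODE = np.array(list("ACGTN"))


@dataclass
class MaskedSequence:
    """A DNA sequence with per-position mask flags.

    Parameters
    ----------
    id : str
        Record identifier.
    residues : str
        Uppercase DNA over ``{A, C, G, T, N}``.
    mask : numpy.ndarray of bool
        ``True`` marks positions excluded from seeding (repeat-masked or N).
    species : str
        Optional species label; defaults to ``id``.
    """

    id: str
    residues: str
    mask: np.ndarray
    species: str = ""

    def __post_init__(self) -> None:
        if self.species == "":
            self.species = self.id
        self.mask = np.asarray(self.mask, dtype=bool)
        if len(self.mask) != len(self.residues):
            raise ValueError(
                f"{self.id}: mask length {len(self.mask)} != sequence "
                f"length {len(self.residues)}"
            )
        bad = set(self.residues) - VALID_RESIDUES
        if bad:
            raise ValueError(f"{self.id}: non-IUPAC/ambiguous residues {sorted(bad)}")
        n_pos = np.frombuffer(self.residues.encode(), dtype=np.uint8) == ord("N")
        if not self.mask[n_pos].all():
            raise ValueError(f"{self.id}: every N position must be masked")
        self._codes: np.ndarray | None = None

    @classmethod
    def from_string(cls, id: str, raw: str, species: str = "") -> "MaskedSequence":
        """Build from a possibly soft-masked string (lowercase = masked)."""
        arr = np.frombuffer(raw.encode(), dtype=np.uint8)
        lower = (arr >= ord("a")) & (arr <= ord("z"))
        upper = raw.upper()
        mask = lower | (np.frombuffer(upper.encode(), dtype=np.uint8) == ord("N"))
        return cls(id=id, residues=upper, mask=mask, species=species)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def codes(self) -> np.ndarray:
        """uint8 codes A=0 C=1 G=2 T=3 with masked positions set to 4."""
        if self._codes is None:
            c = np.frombuffer(self.residues.encode(), dtype=np.uint8)
            out = np.full(len(c), 4, dtype=np.uint8)
            for base, code in (("A", 0), ("C", 1), ("G", 2), ("T", 3)):
                out[c == ord(base)] = code
            out[self.mask] = 4
            self._codes = out
        return self._codes

    def composition(self) -> dict[str, int]:
        """Counts of A, C, G, T, N in the residue string."""
        return {b: self.residues.count(b) for b in "ACGTN"}


@dataclass
class RegionAnnotation:
    """Labeled, non-overlapping, sorted half-open intervals on one sequence."""

    sequence_id: str
    intervals: list[tuple[int, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        prev_end = 0
        for start, end, label in self.intervals:
            if start < 0 or end <= start:
                raise ValueError(f"{self.sequence_id}: bad interval [{start},{end})")
            if start < prev_end:
                raise ValueError(
                    f"{self.sequence_id}: intervals overlap or are unsorted at {start}"
                )
            if label not in REGION_LABELS:
                raise ValueError(f"{self.sequence_id}: unknown label {label!r}")
            prev_end = end

    def label_fractions(self, start: int, end: int) -> dict[str, float]:
        """Fraction of ``[start, end)`` overlapping each region label.

        Positions not covered by any interval count toward ``"other"``.
        Fractions sum to 1 for any non-empty query interval.
        """
        if end <= start:
            return {}
        total = end - start
        fracs: dict[str, float] = {}
        covered = 0
        for s, e, label in self.intervals:
            ov = min(end, e) - max(start, s)
            if ov > 0:
                fracs[label] = fracs.get(label, 0.0) + ov / total
                covered += ov
        if covered < total:
            fracs["other"] = fracs.get("other", 0.0) + (total - covered) / total
        return fracs


@dataclass
class CoordinateMap:
    """Reversible mapping between concatenated and source coordinates.

    Segments tile the non-spacer portion of the concatenated sequence; spacer
    positions map to ``None``.
    """

    segments: list[tuple[str, int, int, int]] = field(default_factory=list)
    total_length: int = 0

    def to_source(self, pos: int) -> tuple[str, int] | None:
        """Map a concatenated position to ``(source_id, offset)`` or None."""
        if pos < 0 or pos >= self.total_length:
            raise IndexError(f"position {pos} outside concatenation")
        for sid, soff, coff, length in self.segments:
            if coff <= pos < coff + length:
                return sid, soff + (pos - coff)
        return None

    def to_concat(self, source_id: str, offset: int) -> int:
        """Map ``(source_id, offset)`` to its concatenated position."""
        for sid, soff, coff, length in self.segments:
            if sid == source_id and soff <= offset < soff + length:
                return coff + (offset - soff)
        raise KeyError(f"({source_id}, {offset}) not covered by any segment")

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#total_length\t{self.total_length}\n")
            fh.write("source_id\tsource_offset\tconcat_offset\tlength\n")
            for sid, soff, coff, length in self.segments:
                fh.write(f"{sid}\t{soff}\t{coff}\t{length}\n")

    @classmethod
    def read_tsv(cls, path) -> "CoordinateMap":
        segments = []
        total = 0
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#total_length"):
                    total = int(line.split("\t")[1])
                    continue
                if not line or line.startswith("source_id"):
                    continue
                sid, soff, coff, length = line.split("\t")
                segments.append((sid, int(soff), int(coff), int(length)))
        return cls(segments=segments, total_length=total)


def read_fasta(path) -> list[MaskedSequence]:
    """Read a FASTA file into :class:`MaskedSequence` records.

    Lowercase residues are interpreted as soft-masked; residues are stored
    uppercase with the mask set where the input was lowercase or ``N``.
    Ambiguity codes other than ``N`` are rejected.  Malformed input raises
    ``ValueError`` naming the offending line.
    """
    records: list[MaskedSequence] = []
    header: str | None = None
    chunks: list[str] = []
    header_line = 0

    def flush() -> None:
        if header is None:
            return
        raw = "".join(chunks)
        if not raw:
            raise ValueError(f"{path}: empty record {header!r} at line {header_line}")
        try:
            records.append(MaskedSequence.from_string(header, raw))
        except ValueError as exc:
            raise ValueError(f"{path}: record starting line {header_line}: {exc}") from exc

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].split()[0] if len(line) > 1 else ""
                if not header:
                    raise ValueError(f"{path}: empty FASTA header at line {lineno}")
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise ValueError(
                        f"{path}: sequence data before any header at line {lineno}"
                    )
                bad = set(line.upper()) - VALID_RESIDUES
                if bad:
                    raise ValueError(
                        f"{path}: invalid residues {sorted(bad)} at line {lineno}"
                    )
                chunks.append(line)
    flush()
    if not records:
        logger.warning("%s: no FASTA records found", path)
    return records


def write_fasta(seqs: list[MaskedSequence], path, width: int = 70) -> None:
    """Write records as FASTA, lower-casing soft-masked (non-N) positions."""
    with open(path, "w") as fh:
        for seq in seqs:
            arr = np.frombuffer(seq.residues.encode(), dtype=np.uint8).copy()
            soft = seq.mask & (arr != ord("N"))
            arr[soft] += 32  # to lowercase
            s = arr.tobytes().decode()
            fh.write(f">{seq.id}\n")
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def _dinucleotide_shuffle(s: str, rng: np.random.Generator) -> str:
    """Altschul-Erikson dinucleotide-preserving shuffle of ``s``."""
    if len(s) <= 2:
        return s
    # multigraph of residue transitions; find a random Eulerian path that
    # starts at s[0] and ends at s[-1] by shuffling edge lists and checking
    # that the walk consumes every edge (retry otherwise)
    edges: dict[str, list[str]] = {}
    for a, b in zip(s, s[1:]):
        edges.setdefault(a, []).append(b)
    n_edges = len(s) - 1
    for _ in range(200):
        pool = {k: list(v) for k, v in edges.items()}
        for k in pool:
            rng.shuffle(pool[k])
        walk = [s[0]]
        cur = s[0]
        for _step in range(n_edges):
            nxt_list = pool.get(cur)
            if not nxt_list:
                break
            cur = nxt_list.pop()
            walk.append(cur)
        if len(walk) == len(s):
            return "".join(walk)
    raise RuntimeError("dinucleotide shuffle failed to find an Eulerian walk")


def shuffle_sequence(
    seq: MaskedSequence,
    rng_seed: int,
    unit: int = 1,
    include_soft_masked: bool = True,
) -> MaskedSequence:
    """Composition-preserving random shuffle of a sequence.

    ``N`` positions are left in place (and stay masked); all other residues
    are permuted.  The default mononucleotide shuffle (``unit=1``) mirrors
    web-tool "Shuffle DNA" behaviour; ``unit=2`` performs a
    dinucleotide-preserving (Altschul-Erikson) shuffle per non-N run.

    With ``include_soft_masked=True`` (default) soft-masked residues join the
    shuffle pool and the output mask marks only ``N`` -- the null comparison
    then has the same effective searchable length as the real sequence.  With
    ``False``, soft-masked positions are frozen in place and keep their mask.
    """
    if len(seq) == 0:
        raise ValueError("cannot shuffle an empty sequence")
    if unit not in (1, 2):
        raise ValueError("unit must be 1 or 2")
    rng = np.random.default_rng(rng_seed)
    arr = np.array(list(seq.residues))
    if include_soft_masked:
        frozen = arr == "N"
        out_mask = frozen.copy()
    else:
        frozen = seq.mask.copy()
        frozen |= arr == "N"
        out_mask = seq.mask.copy()
    idx = np.flatnonzero(~frozen)
    if unit == 1:
        arr[idx] = arr[idx][rng.permutation(len(idx))]
    else:
        # shuffle each maximal run of free positions independently so that
        # dinucleotide composition is preserved within runs
        if len(idx):
            breaks = np.flatnonzero(np.diff(idx) > 1) + 1
            for run in np.split(idx, breaks):
                sub = "".join(arr[run])
                arr[run] = list(_dinucleotide_shuffle(sub, rng))
    return MaskedSequence(
        id=f"{seq.id}_shuffled",
        residues="".join(arr),
        mask=out_mask,
        species=seq.species,
    )


def concatenate(
    seqs: list[MaskedSequence], spacer_len: int = 100, id: str = "concat"
) -> tuple[MaskedSequence, CoordinateMap]:
    """Concatenate loci with masked N spacers and a reversible coordinate map.

    The spacer is ``N`` (masked) so no seed window can span two loci.
    """
    if not seqs:
        raise ValueError("cannot concatenate an empty list of sequences")
    if spacer_len < 0:
        raise ValueError("spacer_len must be >= 0")
    parts: list[str] = []
    masks: list[np.ndarray] = []
    segments: list[tuple[str, int, int, int]] = []
    offset = 0
    for i, seq in enumerate(seqs):
        if i > 0 and spacer_len:
            parts.append("N" * spacer_len)
            masks.append(np.ones(spacer_len, dtype=bool))
            offset += spacer_len
        parts.append(seq.residues)
        masks.append(seq.mask)
        segments.append((seq.id, 0, offset, len(seq)))
        offset += len(seq)
    cat = MaskedSequence(
        id=id, residues="".join(parts), mask=np.concatenate(masks)
    )
    return cat, CoordinateMap(segments=segments, total_length=offset)


def read_region_bed(path) -> dict[str, RegionAnnotation]:
    """Read a BED-like 4-column TSV (id, start, end, label; 0-based half-open)."""
    by_id: dict[str, list[tuple[int, int, str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}: expected 4 columns at line {lineno}")
            sid, start, end, label = fields[:4]
            by_id.setdefault(sid, []).append((int(start), int(end), label))
    return {
        sid: RegionAnnotation(sequence_id=sid, intervals=sorted(iv))
        for sid, iv in by_id.items()
    }


def write_region_bed(annots: dict[str, RegionAnnotation], path) -> None:
    with open(path, "w") as fh:
        for sid in sorted(annots):
            for start, end, label in annots[sid].intervals:
                fh.write(f"{sid}\t{start}\t{end}\t{label}\n")
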