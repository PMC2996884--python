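"""Synthetic data generation with full ground-truth event logs.

Everything the analysis pipeline consumes can be generated here: random
locus-scale fixtures at a chosen GC content, tree-structured sequence
evolution with point substitutions, indels and structural events
(segmental duplications = copy-and-insert, transpositions = cut-and-insert),
and binary gain/loss character histories on a species tree.

Every simulation draws from a single top-level seed through
``numpy.random.SeedSequence`` spawning (one child stream per tree node, in
preorder), so each stage is independently replayable, and every run returns
an :class:`EventLog` whose replay reproduces the tip sequences exactly.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .parsimony import _node_name
from .seqio import MaskedSequence, RegionAnnotation

__all__ = [
    "SeqEvolParams",
    "CharEvolParams",
    "StructuralEvent",
    "EventLog",
    "SimResult",
    "make_locus_fixture",
    "make_annotated_locus",
    "simulate_sequences",
    "simulate_characters",
    "replay_event_log",
]

_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=length, p=p)])


def make_locus_fixture(
    lengths: list[int], gc: float = 0.4, rng_seed: int = 0,
    ids: list[str] | None = None,
) -> list[MaskedSequence]:
    """Independent unmasked random sequences at the given lengths and GC."""
    if any(l <= 0 for l in lengths):
        raise ValueError("lengths must be positive")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    ids = ids or [f"locus{i}" for i in range(len(lengths))]
    return [
        MaskedSequence(id=ids[i], residues=_random_seq(rng, L, gc),
                       mask=np.zeros(L, dtype=bool))
        for i, L in enumerate(lengths)
    ]


def make_annotated_locus(
    rng_seed: int = 0,
    five_prime: int = 2000,
    exon1: int = 200,
    intron: int = 2000,
    exon2: int = 800,
    gc: float = 0.4,
    id: str = "locus",
) -> tuple[MaskedSequence, RegionAnnotation]:
    """A random locus with the canonical 5'-exon1-intron-exon2 layout."""
    rng = np.random.default_rng(rng_seed)
    total = five_prime + exon1 + intron + exon2
    seq = MaskedSequence(id=id, residues=_random_seq(rng, total, gc),
                         mask=np.zeros(total, dtype=bool))
    b0, b1, b2 = five_prime, five_prime + exon1, five_prime + exon1 + intron
    annot = RegionAnnotation(sequence_id=id, intervals=[
        (0, b0, "five_prime"), (b0, b1, "exon1"),
        (b1, b2, "intron"), (b2, total, "exon2"),
    ])
    return seq, annot


@dataclass(frozen=True)
class StructuralEvent:
    """One requested duplication or transposition.

    Coordinates refer to the sequence state on ``branch`` after that
    branch's substitutions but before its indels.
    """

    branch: str  # child-node name of the branch the event occurs on
    kind: str  # "duplication" (copy-and-insert) or "transposition" (cut-and-insert)
    source_start: int
    source_len: int
    dest_pos: int

    def __post_init__(self) -> None:
        if self.kind not in ("duplication", "transposition"):
            raise ValueError(f"unknown structural event kind {self.kind!r}")
        if self.source_len <= 0:
            raise ValueError("source_len must be positive")


@dataclass
class SeqEvolParams:
    """Tree-structured sequence evolution parameters.

    ``subst_prob`` is the per-site substitution probability on a branch of
    length 1 (probabilities scale linearly with branch length and are
    capped at 0.75); substitutions are uniform over the three alternative
    bases.  Indels arrive at ``indel_rate`` per site per unit branch length
    with 1+geometric lengths.
    """

    root_length: int = 10000
    gc: float = 0.4
    subst_prob: float = 0.05
    indel_rate: float = 0.0
    indel_ext_p: float = 0.3
    structural_events: list[StructuralEvent] = field(default_factory=list)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.subst_prob <= 1.0:
            raise ValueError("subst_prob must be in [0, 1]")
        if self.indel_rate < 0:
            raise ValueError("indel_rate must be >= 0")
        if not 0.0 < self.indel_ext_p <= 1.0:
            raise ValueError("indel_ext_p must be in (0, 1]")


@dataclass
class CharEvolParams:
    """Two-state gain/loss process: rates per unit branch length.

    ``root_state=None`` draws each character's root state from the
    stationary distribution ``gain / (gain + loss)``.
    """

    gain_rate: float = 0.1
    loss_rate: float = 1.0
    n_characters: int = 6
    root_state: int | None = 1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.gain_rate < 0 or self.loss_rate < 0:
            raise ValueError("rates must be >= 0")


@dataclass
class EventLog:
    """Ordered ground-truth record of every simulated event.

    Each record is a dict with at least ``branch`` and ``type``; replaying
    the log from the root reproduces the tip sequences byte for byte.
    """

    records: list[dict] = field(default_factory=list)

    def add(self, **rec) -> None:
        self.records.append(rec)

    def for_branch(self, branch: str) -> list[dict]:
        return [r for r in self.records if r["branch"] == branch]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


class PositionMap:
    """Composable coordinate shifts from insertions and deletions.

    Tracks edits applied to a sequence so that a position (or interval) in
    the pre-edit coordinate system can be mapped forward.  Positions deleted
    outright map to the deletion point.
    """

    def __init__(self) -> None:
        self.edits: list[tuple[int, int]] = []  # (position, signed length)

    def record_insertion(self, pos: int, length: int) -> None:
        self.edits.append((pos, length))

    def record_deletion(self, pos: int, length: int) -> None:
        self.edits.append((pos, -length))

    def map(self, pos: int) -> int:
        for epos, delta in self.edits:
            if delta >= 0:
                if pos >= epos:
                    pos += delta
            else:
                cut = -delta
                if pos >= epos + cut:
                    pos -= cut
                elif pos > epos:
                    pos = epos
        return pos

    def map_interval(self, start: int, end: int) -> tuple[int, int]:
        s, e = self.map(start), self.map(end)
        return s, max(s, e)


@dataclass
class SimResult:
    tips: dict[str, MaskedSequence]
    event_log: EventLog
    annotations: dict[str, RegionAnnotation] | None = None
    node_sequences: dict[str, str] | None = None


def _apply_substitutions(seq: list[str], p: float, rng: np.random.Generator,
                         branch: str, log: EventLog) -> None:
    if p <= 0 or not seq:
        return
    n = len(seq)
    hit = np.flatnonzero(rng.random(n) < p)
    alts = rng.integers(0, 3, size=len(hit))
    for pos, a in zip(hit, alts):
        old = seq[pos]
        if old == "N":
            continue
        choices = [b for b in "ACGT" if b != old]
        new = choices[a]
        seq[pos] = new
        log.add(branch=branch, type="substitution", pos=int(pos),
                from_base=old, to_base=new)


def _apply_structural(seq: list[str], ev: StructuralEvent,
                      log: EventLog, pmap: PositionMap) -> list[str]:
    s, L = ev.source_start, ev.source_len
    if s < 0 or s + L > len(seq):
        raise ValueError(f"structural event source [{s},{s + L}) outside "
                         f"sequence of length {len(seq)} ({ev})")
    if not 0 <= ev.dest_pos <= len(seq):
        raise ValueError(f"structural event destination {ev.dest_pos} outside "
                         f"sequence of length {len(seq)} ({ev})")
    piece = seq[s : s + L]
    if ev.kind == "duplication":
        out = seq[: ev.dest_pos] + piece + seq[ev.dest_pos :]
        pmap.record_insertion(ev.dest_pos, L)
        dest_after = ev.dest_pos
    else:  # transposition: cut, then insert at dest (dest in post-cut coords)
        if s <= ev.dest_pos <= s + L:
            raise ValueError(f"transposition destination inside source ({ev})")
        rest = seq[:s] + seq[s + L :]
        dest = ev.dest_pos - L if ev.dest_pos > s + L else ev.dest_pos
        out = rest[:dest] + piece + rest[dest:]
        pmap.record_deletion(s, L)
        pmap.record_insertion(dest, L)
        dest_after = dest
    log.add(branch=ev.branch, type=ev.kind, source_start=s, source_len=L,
            dest_pos=ev.dest_pos, dest_pos_after=dest_after)
    return out


def _apply_indels(seq: list[str], params: SeqEvolParams, blen: float,
                  rng: np.random.Generator, branch: str, log: EventLog,
                  pmap: PositionMap) -> list[str]:
    lam = params.indel_rate * blen * len(seq)
    n_events = int(rng.poisson(lam)) if lam > 0 else 0
    for _ in range(n_events):
        pos = int(rng.integers(0, len(seq) + 1))
        length = int(rng.geometric(params.indel_ext_p))
        if rng.random() < 0.5:
            ins = _random_seq(rng, length, params.gc)
            seq = seq[:pos] + list(ins) + seq[pos:]
            pmap.record_insertion(pos, length)
            log.add(branch=branch, type="insertion", pos=pos, seq=ins)
        else:
            if pos >= len(seq):
                pos = max(0, len(seq) - 1)
            length = min(length, len(seq) - pos)
            deleted = "".join(seq[pos : pos + length])
            seq = seq[:pos] + seq[pos + length :]
            pmap.record_deletion(pos, length)
            log.add(branch=branch, type="deletion", pos=pos, length=length,
                    seq=deleted)
    return seq


def simulate_sequences(
    tree: dendropy.Tree,
    params: SeqEvolParams,
    root_seq: MaskedSequence | None = None,
    root_annotation: RegionAnnotation | None = None,
) -> SimResult:
    """Evolve a root sequence down the tree with full event logging.

    Substitution probability on a branch is ``subst_prob`` scaled by branch
    length (branches without lengths count as length 1).  Structural events
    listed in ``params.structural_events`` are applied on their branches
    after substitutions and before indels, in list order.  Annotations, if
    given for the root, are carried to the tips through each branch's
    coordinate edits.
    """
    ss = np.random.SeedSequence(params.rng_seed)
    nodes = list(tree.preorder_node_iter())
    streams = {id(n): np.random.default_rng(c)
               for n, c in zip(nodes, ss.spawn(len(nodes)))}
    root_rng = streams[id(nodes[0])]
    if root_seq is None:
        root = _random_seq(root_rng, params.root_length, params.gc)
    else:
        root = root_seq.residues
    log = EventLog()
    seqs: dict[int, list[str]] = {id(tree.seed_node): list(root)}
    annots: dict[int, list[tuple[int, int, str]] | None] = {
        id(tree.seed_node): list(root_annotation.intervals)
        if root_annotation else None
    }
    ev_by_branch: dict[str, list[StructuralEvent]] = {}
    for ev in params.structural_events:
        ev_by_branch.setdefault(ev.branch, []).append(ev)
    node_sequences: dict[str, str] = {}
    for node in nodes:
        if node is tree.seed_node:
            node_sequences[_node_name(node)] = root
            continue
        name = _node_name(node)
        blen = node.edge.length if node.edge.length is not None else 1.0
        rng = streams[id(node)]
        seq = list(seqs[id(node.parent_node)])
        pmap = PositionMap()
        p = min(0.75, params.subst_prob * blen)
        _apply_substitutions(seq, p, rng, name, log)
        for ev in ev_by_branch.get(name, ()):
            seq = _apply_structural(seq, ev, log, pmap)
        seq = _apply_indels(seq, params, blen, rng, name, log, pmap)
        seqs[id(node)] = seq
        node_sequences[name] = "".join(seq)
        parent_annot = annots[id(node.parent_node)]
        if parent_annot is not None:
            mapped = []
            for s, e, lab in parent_annot:
                ms, me = pmap.map_interval(s, e)
                if me > ms:
                    mapped.append((ms, me, lab))
            annots[id(node)] = mapped
        else:
            annots[id(node)] = None
    tips: dict[str, MaskedSequence] = {}
    tip_annots: dict[str, RegionAnnotation] = {}
    for leaf in tree.leaf_node_iter():
        name = _node_name(leaf)
        res = node_sequences[name]
        tips[name] = MaskedSequence(id=name, residues=res,
                                    mask=np.zeros(len(res), dtype=bool))
        iv = annots[id(leaf)]
        if iv is not None:
            tip_annots[name] = RegionAnnotation(sequence_id=name, intervals=iv)
    return SimResult(tips=tips, event_log=log,
                     annotations=tip_annots or None,
                     node_sequences=node_sequences)


def replay_event_log(
    tree: dendropy.Tree, root_seq: str, log: EventLog
) -> dict[str, str]:
    """Re-apply the logged events from the root; returns tip sequences.

    Independent of the simulator's random streams -- only the log and the
    root sequence are consulted.
    """
    seqs: dict[int, str] = {id(tree.seed_node): root_seq}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        name = _node_name(node)
        seq = list(seqs[id(node.parent_node)])
        for rec in log.for_branch(name):
            t = rec["type"]
            if t == "substitution":
                assert seq[rec["pos"]] == rec["from_base"]
                seq[rec["pos"]] = rec["to_base"]
            elif t == "duplication":
                s, L, d = rec["source_start"], rec["source_len"], rec["dest_pos"]
                seq = seq[:d] + seq[s : s + L] + seq[d:]
            elif t == "transposition":
                s, L = rec["source_start"], rec["source_len"]
                piece = seq[s : s + L]
                rest = seq[:s] + seq[s + L :]
                d = rec["dest_pos_after"]
                seq = rest[:d] + piece + rest[d:]
            elif t == "insertion":
                seq = seq[: rec["pos"]] + list(rec["seq"]) + seq[rec["pos"] :]
            elif t == "deletion":
                seq = seq[: rec["pos"]] + seq[rec["pos"] + rec["length"] :]
            else:
                raise ValueError(f"unknown event type {t!r}")
        seqs[id(node)] = "".join(seq)
    return {_node_name(l): seqs[id(l)] for l in tree.leaf_node_iter()}


def simulate_characters(
    tree: dendropy.Tree, params: CharEvolParams
) -> tuple[pd.DataFrame, EventLog]:
    """Binary characters evolved under a continuous-time gain/loss process.

    Exact jump (Gillespie) simulation along every branch: waiting times are
    exponential with rate ``gain_rate`` in state 0 and ``loss_rate`` in
    state 1, so every gain and loss is individually logged with the node
    states it connects.
    """
    ss = np.random.SeedSequence(params.rng_seed)
    rng = np.random.default_rng(ss)
    log = EventLog()
    taxa = [_node_name(l) for l in tree.leaf_node_iter()]
    data = {t: [] for t in taxa}
    a, b = params.gain_rate, params.loss_rate
    stationary = a / (a + b) if (a + b) > 0 else 0.0
    for c in range(params.n_characters):
        cname = f"char{c}"
        if params.root_state is None:
            root_state = int(rng.random() < stationary)
        else:
            root_state = params.root_state
        states: dict[int, int] = {id(tree.seed_node): root_state}
        log.add(branch=_node_name(tree.seed_node), type="root_state",
                character=cname, state=root_state)
        for node in tree.preorder_node_iter():
            if node is tree.seed_node:
                continue
            blen = node.edge.length if node.edge.length is not None else 1.0
            s = states[id(node.parent_node)]
            t = 0.0
            while True:
                rate = params.gain_rate if s == 0 else params.loss_rate
                if rate <= 0:
                    break
                t += rng.exponential(1.0 / rate)
                if t >= blen:
                    break
                s = 1 - s
                log.add(branch=_node_name(node), type="gain" if s else "loss",
                        character=cname, time=t)
            states[id(node)] = s
        for leaf in tree.leaf_node_iter():
            data[_node_name(leaf)].append(states[id(leaf)])
    matrix = pd.DataFrame.from_dict(data, orient="index",
                                    columns=[f"char{c}" for c in
                                             range(params.n_characters)])
    return matrix, log
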