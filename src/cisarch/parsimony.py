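"""Loss-biased parsimony reconstruction of ancestral enhancer architecture.

Each enhancer activity x genomic-location pair (e.g. "epidermal enhancer in
the 5' intergenic region") is one independent binary character scored in
each species.  Because point mutations disrupt transcription-factor binding
sites far more readily than they create them, losing an enhancer activity
is assumed cheaper than gaining one: ancestral states are reconstructed by
Sankoff weighted parsimony under asymmetric gain/loss costs (default
loss=1, gain=2), with a ``loss_only`` limiting mode in which gains below
the root are forbidden outright.

All most-parsimonious reconstructions (MPRs) are enumerated; root-state
ties are reported as ambiguity, never silently resolved.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from math import inf

import dendropy
import pandas as pd

__all__ = [
    "CostScheme",
    "AncestralReconstruction",
    "load_tree",
    "load_yellow_tree",
    "load_yellow_characters",
    "read_character_matrix",
    "sankoff_reconstruct",
    "enumerate_events",
    "exhaustive_reconstruct",
    "loss_summary",
    "YELLOW_TAXA",
]

YELLOW_TAXA = ("Dmel", "Dpse", "Dwil", "Dmoj", "Dvir", "Dgri")

#: fixture entries the underlying observations leave soft (sub-pattern or
#: marginal expression calls); flip via load_yellow_characters arguments
YELLOW_SOFT_ENTRIES = (("Dgri", "epidermal_5prime"), ("Dwil", "epidermal_intron"))


@dataclass
class CostScheme:
    """Asymmetric gain/loss costs for a binary presence/absence character."""

    gain: float = 2.0
    loss: float = 1.0
    loss_only: bool = False

    def __post_init__(self) -> None:
        if self.gain <= 0 or self.loss <= 0:
            raise ValueError("costs must be positive")

    def cost(self, parent_state: int, child_state: int) -> float:
        if parent_state == child_state:
            return 0.0
        if parent_state == 0 and child_state == 1:
            return inf if self.loss_only else self.gain
        return self.loss


@dataclass
class Event:
    branch: str  # label of the child node of the branch
    character: str
    kind: str  # "gain" or "loss"

    def astuple(self) -> tuple[str, str, str]:
        return (self.branch, self.character, self.kind)


@dataclass
class CharacterReconstruction:
    character: str
    cost: float
    root_states: set[int]
    node_states: dict[str, set[int]]  # across all MPRs
    mprs: list[dict[str, int]] = field(default_factory=list)
    events_per_mpr: list[list[Event]] = field(default_factory=list)


@dataclass
class AncestralReconstruction:
    tree: dendropy.Tree
    costs: CostScheme
    characters: dict[str, CharacterReconstruction] = field(default_factory=dict)

    @property
    def total_cost(self) -> float:
        return sum(c.cost for c in self.characters.values())

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("character\tcost\tnode\tstates\n")
            for name, rec in self.characters.items():
                for node, states in sorted(rec.node_states.items()):
                    s = "/".join(str(x) for x in sorted(states))
                    fh.write(f"{name}\t{rec.cost:g}\t{node}\t{s}\n")
            fh.write("character\tmpr\tbranch\tevent\n")
            for name, rec in self.characters.items():
                for m, events in enumerate(rec.events_per_mpr):
                    for ev in events:
                        fh.write(f"{name}\t{m}\t{ev.branch}\t{ev.kind}\n")


def load_tree(source: str, is_path: bool = True) -> dendropy.Tree:
    """Read a rooted newick tree, labelling unnamed internal nodes."""
    if is_path:
        tree = dendropy.Tree.get(path=str(source), schema="newick")
    else:
        tree = dendropy.Tree.get(data=source, schema="newick")
    tree.is_rooted = True
    counter = itertools.count()
    for node in tree.preorder_node_iter():
        if node.taxon is None and node.label is None:
            node.label = f"node{next(counter)}"
    return tree


def _node_name(node: dendropy.Node) -> str:
    return node.taxon.label if node.taxon is not None else node.label


def load_yellow_tree() -> dendropy.Tree:
    """The six-species tree, branch lengths on a root-normalized time scale."""
    path = resources.files("cisarch.data") / "yellow_tree.nwk"
    return load_tree(str(path))


def read_character_matrix(path) -> pd.DataFrame:
    """Binary character matrix TSV: taxa rows, character columns, {0,1}."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if not df.isin([0, 1]).all().all():
        raise ValueError(f"{path}: character matrix entries must be 0/1")
    return df.astype(int)


def load_yellow_characters(
    dgri_epidermal_5prime: int | None = None,
    dwil_epidermal_intron: int | None = None,
) -> pd.DataFrame:
    """The shipped enhancer presence/absence fixture for the six species.

    The two soft entries (marginal calls in the underlying observations) can
    be overridden; the shipped defaults score both as present.
    """
    path = resources.files("cisarch.data") / "yellow_characters.tsv"
    df = read_character_matrix(str(path))
    if dgri_epidermal_5prime is not None:
        df.loc["Dgri", "epidermal_5prime"] = int(dgri_epidermal_5prime)
    if dwil_epidermal_intron is not None:
        df.loc["Dwil", "epidermal_intron"] = int(dwil_epidermal_intron)
    return df


def _check_taxa(tree: dendropy.Tree, matrix: pd.DataFrame) -> None:
    leaves = {_node_name(l) for l in tree.leaf_node_iter()}
    taxa = set(matrix.index)
    if leaves != taxa:
        raise ValueError(
            f"tree/matrix taxa mismatch: tree-only {sorted(leaves - taxa)}, "
            f"matrix-only {sorted(taxa - leaves)}"
        )


def sankoff_reconstruct(
    tree: dendropy.Tree, matrix: pd.DataFrame, costs: CostScheme | None = None
) -> AncestralReconstruction:
    """Minimal-cost ancestral states for every character (Sankoff DP).

    Root state is chosen by minimal cost with no prior; ties are reported as
    ambiguity and every most-parsimonious reconstruction is enumerated.
    """
    costs = costs or CostScheme()
    _check_taxa(tree, matrix)
    if matrix.isna().any().any():
        raise ValueError("character matrix contains missing entries")
    recon = AncestralReconstruction(tree=tree, costs=costs)
    for character in matrix.columns:
        tip_states = matrix[character].to_dict()
        recon.characters[character] = _sankoff_one(tree, character,
                                                   tip_states, costs)
    return recon


def _sankoff_one(
    tree: dendropy.Tree, character: str, tip_states: dict[str, int],
    costs: CostScheme,
) -> CharacterReconstruction:
    cost_tab: dict[dendropy.Node, list[float]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            s = tip_states[_node_name(node)]
            cost_tab[node] = [0.0 if s == st else inf for st in (0, 1)]
        else:
            vec = []
            for st in (0, 1):
                total = 0.0
                for child in node.child_nodes():
                    total += min(costs.cost(st, cs) + cost_tab[child][cs]
                                 for cs in (0, 1))
                vec.append(total)
            cost_tab[node] = vec
    root = tree.seed_node
    best = min(cost_tab[root])
    root_states = {st for st in (0, 1) if cost_tab[root][st] == best}

    # enumerate every most-parsimonious assignment by expanding optimal
    # child choices top-down (tree is small; MPR count is bounded anyway)
    mprs: list[dict[str, int]] = []

    def expand(assignment: dict[dendropy.Node, int],
               pending: list[dendropy.Node]) -> None:
        if not pending:
            mprs.append({_node_name(n): s for n, s in assignment.items()})
            return
        node = pending[0]
        parent_state = assignment[node.parent_node]
        opts = [cs for cs in (0, 1)
                if costs.cost(parent_state, cs) + cost_tab[node][cs]
                == min(costs.cost(parent_state, c) + cost_tab[node][c]
                       for c in (0, 1))]
        for cs in opts:
            assignment[node] = cs
            expand(assignment, pending[1:])
        del assignment[node]

    order = [n for n in tree.preorder_node_iter() if n is not root]
    for rs in sorted(root_states):
        expand({root: rs}, order)

    node_states: dict[str, set[int]] = {}
    for mpr in mprs:
        for name, s in mpr.items():
            node_states.setdefault(name, set()).add(s)
    events_per_mpr = []
    for mpr in mprs:
        events = []
        for node in tree.preorder_node_iter():
            if node is root:
                continue
            ps = mpr[_node_name(node.parent_node)]
            cs = mpr[_node_name(node)]
            if ps != cs:
                kind = "gain" if cs == 1 else "loss"
                events.append(Event(_node_name(node), character, kind))
        events_per_mpr.append(events)
    return CharacterReconstruction(
        character=character, cost=best, root_states=root_states,
        node_states=node_states, mprs=mprs, events_per_mpr=events_per_mpr,
    )


def enumerate_events(
    recon: AncestralReconstruction, tree: dendropy.Tree | None = None
) -> list[list[tuple[str, str, str]]]:
    """Per-MPR event lists as (branch, character, gain|loss) tuples.

    One entry per combination of MPRs across characters would explode; the
    per-character MPRs are independent, so events are reported per character
    MPR (the cross product is implied).
    """
    out = []
    for rec in recon.characters.values():
        for events in rec.events_per_mpr:
            out.append([ev.astuple() for ev in events])
    return out


def loss_summary(recon: AncestralReconstruction) -> pd.DataFrame:
    """Per-taxon loss report across root-to-tip paths.

    For every terminal taxon: whether at least one loss (any character) lies
    on its root-to-tip path in *every* combination of per-character MPRs
    (``always``) and in at least one (``ever``).  A loss on a shared internal
    branch counts toward every descendant taxon.
    """
    tree = recon.tree
    # taxon -> set of branch labels (child-node names) on its root path
    path_branches: dict[str, set[str]] = {}
    for leaf in tree.leaf_node_iter():
        names = set()
        node = leaf
        while node.parent_node is not None:
            names.add(_node_name(node))
            node = node.parent_node
        path_branches[_node_name(leaf)] = names
    rows = {}
    for taxon, branches in sorted(path_branches.items()):
        ever = False
        always = False
        # per character, does every MPR put a loss on this path?
        per_char_always = []
        for rec in recon.characters.values():
            hits = [any(ev.kind == "loss" and ev.branch in branches
                        for ev in events)
                    for events in rec.events_per_mpr]
            if any(hits):
                ever = True
            per_char_always.append(all(hits) and bool(hits))
        always = any(per_char_always)
        rows[taxon] = {"loss_always": always, "loss_ever": ever}
    return pd.DataFrame.from_dict(rows, orient="index")


def exhaustive_reconstruct(
    tree: dendropy.Tree, tip_states: dict[str, int], costs: CostScheme | None = None
) -> tuple[float, list[dict[str, int]]]:
    """Brute-force minimal cost over all internal-state assignments.

    Test oracle for :func:`sankoff_reconstruct`; refuses trees with more
    than 12 leaves.
    """
    costs = costs or CostScheme()
    leaves = [n for n in tree.leaf_node_iter()]
    if len(leaves) > 12:
        raise ValueError("exhaustive reconstruction limited to <= 12 leaves")
    internal = [n for n in tree.preorder_internal_node_iter()]
    best_cost = inf
    best: list[dict[str, int]] = []
    for states in itertools.product((0, 1), repeat=len(internal)):
        assign = {n: s for n, s in zip(internal, states)}
        for leaf in leaves:
            assign[leaf] = tip_states[_node_name(leaf)]
        total = 0.0
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            total += costs.cost(assign[node.parent_node], assign[node])
            if total > best_cost:
                break
        if total < best_cost:
            best_cost = total
            best = [{_node_name(n): s for n, s in assign.items()}]
        elif total == best_cost:
            best.append({_node_name(n): s for n, s in assign.items()})
    return best_cost, best
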