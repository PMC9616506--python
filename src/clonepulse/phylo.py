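"""Maximum-parsimony clone trees from binary event matrices.

Each CNA event is a binary character; the tree is rooted at an
unaberrated (all-zero) ancestor and the parsimony score is the summed
Fitch minimum-change count over events (gain and loss of a character each
cost one change). Exhaustive search over all rooted binary topologies is
used for small matrices (guaranteed optimal for <= 7 leaves); larger
matrices use seeded stepwise addition followed by nearest-neighbor
interchange. Among equally parsimonious trees, the lexicographically
smallest canonical (sorted-newick) form is returned.

The scorer packs all characters of a node's Fitch state set into a single
Python integer, two bits per event, so one up-pass costs a constant
number of big-int operations per node regardless of the event count.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

Topology = object  # nested 2-tuples of leaf labels


class EmptyMatrixError(ValueError):
    pass


def _as_frame(matrix) -> pd.DataFrame:
    """Accept an EventMatrix or a raw binary DataFrame (rows=events)."""
    df = matrix.data if hasattr(matrix, "data") else matrix
    if not isinstance(df, pd.DataFrame):
        raise TypeError("expected an EventMatrix or a pandas DataFrame")
    if df.shape[1] == 0:
        raise EmptyMatrixError("event matrix has no columns")
    if df.size and not df.isin([0, 1]).all().all():
        raise ValueError("parsimony requires a binary matrix")
    return df


# -- bit-packed Fitch scoring -------------------------------------------------

def _leaf_codes(df: pd.DataFrame) -> tuple[dict[str, int], int, int]:
    """Pack each column into an int with 2 bits per event.

    Bit 2i encodes 'state 0 possible', bit 2i+1 'state 1 possible'.
    """
    n_events = df.shape[0]
    even = sum(1 << (2 * i) for i in range(n_events)) if n_events else 0
    codes: dict[str, int] = {}
    arr = df.to_numpy()
    for j, col in enumerate(df.columns):
        code = 0
        for i in range(n_events):
            code |= 1 << (2 * i + (1 if arr[i, j] else 0))
        codes[col] = code
    return codes, even, n_events


def _fitch_up(tree: Topology, codes: Mapping[str, int], even: int, n_events: int):
    if not isinstance(tree, tuple):
        return codes[tree], 0
    lc, ls = _fitch_up(tree[0], codes, even, n_events)
    rc, rs = _fitch_up(tree[1], codes, even, n_events)
    inter = lc & rc
    nz = (inter | (inter >> 1)) & even
    full = nz | (nz << 1)
    res = (inter & full) | ((lc | rc) & ~full)
    return res, ls + rs + (n_events - nz.bit_count())


def parsimony_score(tree: Topology, codes: Mapping[str, int], even: int,
                    n_events: int) -> int:
    """Total state changes on ``tree`` rooted at an all-zero ancestor."""
    if n_events == 0:
        return 0
    res, changes = _fitch_up(tree, codes, even, n_events)
    # root edge: one change for every event whose root set excludes state 0
    return changes + (n_events - (res & even).bit_count())


# -- topology enumeration and search ------------------------------------------

def _insertions(tree: Topology, leaf):
    yield (tree, leaf)
    if isinstance(tree, tuple):
        left, right = tree
        for t in _insertions(left, leaf):
            yield (t, right)
        for t in _insertions(right, leaf):
            yield (left, t)


@lru_cache(maxsize=16)
def _all_topologies(n: int) -> tuple[Topology, ...]:
    """All rooted binary topologies over placeholder leaves 0..n-1."""
    trees: list[Topology] = [0]
    for leaf in range(1, n):
        trees = [t2 for t in trees for t2 in _insertions(t, leaf)]
    return tuple(trees)


def _substitute(tree: Topology, names: Sequence[str]) -> Topology:
    if isinstance(tree, tuple):
        return (_substitute(tree[0], names), _substitute(tree[1], names))
    return names[tree]


def canonical_newick(tree: Topology) -> str:
    if not isinstance(tree, tuple):
        return str(tree)
    a, b = sorted((canonical_newick(tree[0]), canonical_newick(tree[1])))
    return f"({a},{b})"


def _nni_neighbors(tree: Topology):
    if not isinstance(tree, tuple):
        return
    left, right = tree
    if isinstance(left, tuple):
        a, b = left
        yield ((a, right), b)
        yield ((b, right), a)
    if isinstance(right, tuple):
        a, b = right
        yield (a, (b, left))
        yield (b, (a, left))
    for sub in _nni_neighbors(left):
        yield (sub, right)
    for sub in _nni_neighbors(right):
        yield (left, sub)


def _search_exhaustive(names, codes, even, n_events):
    best = None
    for topo in _all_topologies(len(names)):
        tree = _substitute(topo, names)
        key = (parsimony_score(tree, codes, even, n_events),
               canonical_newick(tree))
        if best is None or key < best[0]:
            best = (key, tree)
    return best[1], best[0][0]


def _search_heuristic(names, codes, even, n_events, seed, n_restarts=10):
    """Stepwise addition + NNI hill climbing from several seeded orders."""
    rng = random.Random(seed)
    best_tree = None
    best_score = None
    for _ in range(n_restarts):
        order = list(names)
        rng.shuffle(order)
        tree: Topology = order[0]
        for leaf in order[1:]:
            scored = [(parsimony_score(t, codes, even, n_events), t)
                      for t in _insertions(tree, leaf)]
            low = min(s for s, _ in scored)
            ties = [t for s, t in scored if s == low]
            tree = ties[rng.randrange(len(ties))]
        score = parsimony_score(tree, codes, even, n_events)
        improved = True
        while improved:
            improved = False
            for cand in _nni_neighbors(tree):
                s = parsimony_score(cand, codes, even, n_events)
                if s < score:
                    tree, score = cand, s
                    improved = True
        if best_score is None or (score, canonical_newick(tree)) < (
            best_score, canonical_newick(best_tree)
        ):
            best_tree, best_score = tree, score
    return best_tree, best_score


# -- tree object ---------------------------------------------------------------

@dataclass
class TreeNode:
    name: str | None = None  # leaf label, or None for internal nodes
    children: list["TreeNode"] = field(default_factory=list)
    acquired: list[str] = field(default_factory=list)
    lost: list[str] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class CloneTree:
    """Rooted clone phylogeny; the root is the unaberrated ancestor."""

    root: TreeNode
    score: int
    leaves: list[str]
    topology: Topology

    def newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            label = node.name or ""
            events = [f"+{e}" for e in node.acquired] + [f"-{e}" for e in node.lost]
            comment = f"[&events={';'.join(events)}]" if events else ""
            if node.is_leaf:
                return f"{label}{comment}"
            inner = ",".join(fmt(c) for c in node.children)
            return f"({inner}){label}{comment}"

        return fmt(self.root) + ";"

    def edges(self):
        """(parent, child) pairs in preorder; the root has no parent edge."""
        out = []

        def walk(node: TreeNode):
            for child in node.children:
                out.append((node, child))
                walk(child)

        walk(self.root)
        return out


def _build_nodes(tree: Topology) -> TreeNode:
    if not isinstance(tree, tuple):
        return TreeNode(name=str(tree))
    return TreeNode(children=[_build_nodes(tree[0]), _build_nodes(tree[1])])


def _label_events(root: TreeNode, df: pd.DataFrame) -> None:
    """Assign acquired/lost event labels per edge by per-event Fitch MPR.

    Up-pass computes preliminary state sets ({0}, {1} or {0,1} encoded as
    1/2/3); the down-pass fixes each node to the parent's state when
    possible, preferring state 1 otherwise — a standard minimum-change
    refinement given the root is fixed at state 0.
    """
    leaf_states = {c: df[c].to_numpy() for c in df.columns}
    events = list(df.index)

    prelim: dict[int, np.ndarray] = {}

    def up(node: TreeNode) -> np.ndarray:
        if node.is_leaf:
            s = np.where(leaf_states[node.name] == 1, 2, 1)
        else:
            kids = [up(c) for c in node.children]
            inter = kids[0] & kids[1]
            union = kids[0] | kids[1]
            s = np.where(inter != 0, inter, union)
        prelim[id(node)] = s
        return s

    def down(node: TreeNode, parent_state: np.ndarray) -> None:
        p = prelim[id(node)]
        state = np.where((p >> (parent_state - 1)) & 1 == 1, parent_state,
                         np.where(p & 2 != 0, 2, 1))
        gained = (parent_state == 1) & (state == 2)
        lost = (parent_state == 2) & (state == 1)
        node.acquired = [e for e, g in zip(events, gained) if g]
        node.lost = [e for e, l in zip(events, lost) if l]
        for child in node.children:
            down(child, state)

    if len(events) == 0:
        return
    top = root.children[0]  # root itself is the zero ancestor
    up(top)
    down(top, np.ones(len(events), dtype=int))


def max_parsimony_tree(matrix, search: str = "auto", seed: int = 0) -> CloneTree:
    """Maximum-parsimony clone tree for a binary event matrix.

    ``search`` is ``"exhaustive"`` (optimal, feasible to ~9 leaves),
    ``"heuristic"`` (stepwise addition + NNI, seeded), or ``"auto"``
    (exhaustive up to 7 leaves). Deterministic for a fixed seed; edge
    event labels record where each event is acquired or lost.
    """
    df = _as_frame(matrix)
    names = [str(c) for c in df.columns]
    df = df.set_axis(names, axis=1)
    codes, even, n_events = _leaf_codes(df)

    if len(names) == 1:
        topo: Topology = names[0]
        score = n_events and parsimony_score(topo, codes, even, n_events)
    else:
        if search == "auto":
            search = "exhaustive" if len(names) <= 7 else "heuristic"
        if search == "exhaustive":
            topo, score = _search_exhaustive(names, codes, even, n_events)
        elif search == "heuristic":
            topo, score = _search_heuristic(names, codes, even, n_events, seed)
        else:
            raise ValueError(f"unknown search mode {search!r}")

    body = _build_nodes(topo)
    root = TreeNode(name="ancestor", children=[body])
    tree = CloneTree(root=root, score=int(score), leaves=names, topology=topo)
    _label_events(root, df)
    return tree


def tree_from_topology(topology: Topology, matrix) -> CloneTree:
    """Build a :class:`CloneTree` for a user-fixed topology.

    Scores the given topology (nested 2-tuples of column labels) against
    the matrix and assigns edge event labels, without any search.
    """
    df = _as_frame(matrix)
    names = [str(c) for c in df.columns]
    df = df.set_axis(names, axis=1)

    def leaves_of(t):
        return [t] if not isinstance(t, tuple) else leaves_of(t[0]) + leaves_of(t[1])

    if sorted(leaves_of(topology)) != sorted(names):
        raise ValueError("topology leaves do not match matrix columns")
    codes, even, n_events = _leaf_codes(df)
    score = parsimony_score(topology, codes, even, n_events)
    body = _build_nodes(topology)
    root = TreeNode(name="ancestor", children=[body])
    tree = CloneTree(root=root, score=int(score), leaves=names, topology=topology)
    _label_events(root, df)
    return tree


# -- stem and homoplasy --------------------------------------------------------

def identify_stem(event_sets: Sequence[frozenset]) -> frozenset:
    """Stem = the aberrations shared by all samples: the set intersection."""
    if not event_sets:
        raise ValueError("at least one event set is required")
    sets = [frozenset(s) for s in event_sets]
    stem = sets[0]
    for s in sets[1:]:
        stem &= s
    return stem


@dataclass
class HomoplasyReport:
    """Per-event minimum change counts on a fixed tree.

    ``min_origins`` is the Fitch minimum-change count with the root fixed
    at state 0; a loss also counts as one change. Events needing >= 2
    changes cannot be explained by a single origin on this tree and are
    flagged as parallel.
    """

    per_event: pd.DataFrame  # index: event id; columns: min_origins, parallel

    @property
    def parallel_events(self) -> list[str]:
        return list(self.per_event.index[self.per_event["parallel"]])


def detect_homoplasy(tree: CloneTree, matrix) -> HomoplasyReport:
    df = _as_frame(matrix)
    names = [str(c) for c in df.columns]
    if sorted(names) != sorted(tree.leaves):
        raise ValueError("tree leaves do not match matrix columns")
    df = df.set_axis(names, axis=1)
    codes, even, n_events = _leaf_codes(df)
    rows = []
    for i, event in enumerate(df.index):
        sub = df.iloc[[i]]
        c1, e1, _ = _leaf_codes(sub)
        changes = parsimony_score(tree.topology, c1, e1, 1)
        rows.append({"event": event, "min_origins": changes,
                     "parallel": changes >= 2})
    report = pd.DataFrame(rows).set_index("event")
    return HomoplasyReport(report)


def convergent_events(
    datasets: Mapping[str, Sequence[tuple[str, int, int, str]]],
    min_reciprocal_overlap: float = 0.5,
) -> pd.DataFrame:
    """Cross-dataset convergence table.

    Events are (chrom, start, end, direction) tuples per independent
    dataset; two events match when they share chromosome and direction and
    overlap reciprocally by at least ``min_reciprocal_overlap`` of each
    event's span. One row per matching pair from distinct datasets.
    """
    rows = []
    for (da, eva), (db, evb) in itertools.combinations(
        ((name, ev) for name, events in sorted(datasets.items()) for ev in events), 2
    ):
        if da == db:
            continue
        ca, sa, ea, dira = eva
        cb, sb, eb, dirb = evb
        if ca != cb or dira != dirb:
            continue
        ov = min(ea, eb) - max(sa, sb)
        if ov <= 0:
            continue
        if ov >= min_reciprocal_overlap * (ea - sa) and ov >= min_reciprocal_overlap * (eb - sb):
            rows.append({
                "dataset_a": da, "chrom_a": ca, "start_a": sa, "end_a": ea,
                "dataset_b": db, "chrom_b": cb, "start_b": sb, "end_b": eb,
                "direction": dira, "overlap_bp": ov,
            })
    return pd.DataFrame(rows, columns=[
        "dataset_a", "chrom_a", "start_a", "end_a",
        "dataset_b", "chrom_b", "start_b", "end_b", "direction", "overlap_bp",
    ])
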