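import itertools

import numpy as np
import pandas as pd
import pytest

from clonepulse.bulk import AllelicSegment

SMALL_GENOME = {"chr1": 80, "chr2": 70, "chr3": 60, "chr4": 50}


@pytest.fixture
def small_genome():
    return dict(SMALL_GENOME)


def make_segment(**overrides) -> AllelicSegment:
    base = dict(
        sample_id="S1", chrom="chr2", start=1, end=1_000_000, kind="gain",
        log2r=0.32, mbaf=None, n_minor=1, n_major=2, marker_count=200,
        background_ploidy=2,
    )
    base.update(overrides)
    return AllelicSegment(**base)


# ---------------------------------------------------------------------------
# Independent parsimony oracle: enumerate rooted topologies by leaf insertion
# and score each by brute-force assignment of internal node states (no Fitch).

def oracle_topologies(leaves):
    trees = [leaves[0]]
    for leaf in leaves[1:]:
        nxt = []
        for tree in trees:
            nxt.extend(_attach_everywhere(tree, leaf))
        trees = nxt
    return trees


def _attach_everywhere(tree, leaf):
    yield [tree, leaf]
    if isinstance(tree, list):
        left, right = tree
        for sub in _attach_everywhere(left, leaf):
            yield [sub, right]
        for sub in _attach_everywhere(right, leaf):
            yield [left, sub]


def oracle_tree_score(tree, column_states):
    """Min state changes over all internal labelings, root fixed at 0."""

    def nodes_and_edges(node, acc_internal, acc_edges, parent):
        me = len(acc_internal) + len(column_states)  # unique id
        if isinstance(node, list):
            acc_internal.append(me)
            acc_edges.append((parent, me))
            for child in node:
                nodes_and_edges(child, acc_internal, acc_edges, me)
        else:
            acc_edges.append((parent, node))
        return acc_internal, acc_edges

    internal, edges = nodes_and_edges(tree, [], [], "ROOT")
    best = None
    for assign in itertools.product([0, 1], repeat=len(internal)):
        states = dict(zip(internal, assign))
        states["ROOT"] = 0
        states.update(column_states)
        changes = sum(states[a] != states[b] for a, b in edges)
        if best is None or changes < best:
            best = changes
    return best


def oracle_parsimony(df: pd.DataFrame) -> int:
    """Exhaustive minimum parsimony score for a binary matrix (independent
    of the package's Fitch implementation)."""
    leaves = list(df.columns)
    if len(leaves) == 1:
        return int(df[leaves[0]].sum())
    best = None
    for tree in oracle_topologies(leaves):
        total = 0
        for _, row in df.iterrows():
            total += oracle_tree_score(tree, dict(row))
        if best is None or total < best:
            best = total
    return best
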