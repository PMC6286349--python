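import io

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from microstrat.community import OtuTable


@pytest.fixture
def small_tree():
    """((A:1,B:1):1,C:2); — the hand-enumerable 3-tip tree."""
    return TreeNode.read(io.StringIO("((A:1.0,B:1.0):1.0,C:2.0);"))


@pytest.fixture
def small_table():
    counts = pd.DataFrame(
        [[1, 1, 0], [1, 0, 1]],
        index=["s1", "s2"],
        columns=["A", "B", "C"],
    )
    tax = pd.Series(
        ["k__Bacteria;g__Alpha", "k__Bacteria;g__Alpha", "k__Bacteria;g__Gamma"],
        index=["A", "B", "C"],
    )
    return OtuTable(counts=counts, taxonomy=tax)


def random_tree(n_tips: int, rng: np.random.Generator) -> TreeNode:
    """Random rooted binary tree with uniform(0.1, 1) branch lengths."""
    nodes = [TreeNode(name=f"T{i}") for i in range(n_tips)]
    for node in nodes:
        node.length = float(rng.uniform(0.1, 1.0))
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        p = TreeNode(children=[a, b])
        p.length = float(rng.uniform(0.1, 1.0))
        nodes.append(p)
    return TreeNode(children=nodes)


def brute_force_unifrac(tree: TreeNode, counts: pd.DataFrame, variant: str) -> np.ndarray:
    """Independent UniFrac oracle: explicit per-branch descendant tip sets.

    Walks the tree recursively, collecting (length, tip-set) per branch, then
    applies the defining formulas pairwise in pure python.
    """
    branches = []

    def walk(node):
        if node.is_tip():
            tips = {node.name}
        else:
            tips = set()
            for ch in node.children:
                tips |= walk(ch)
        if node.parent is not None:
            branches.append((float(node.length or 0.0), frozenset(tips)))
        return tips

    walk(tree)
    tip_depth = {}
    for tip in tree.tips():
        d, node = 0.0, tip
        while node.parent is not None:
            d += float(node.length or 0.0)
            node = node.parent
        tip_depth[tip.name] = d
    samples = list(counts.index)
    n = len(samples)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ri = counts.loc[samples[i]]
            rj = counts.loc[samples[j]]
            pres_i = {o for o in counts.columns if ri[o] > 0}
            pres_j = {o for o in counts.columns if rj[o] > 0}
            if variant == "unweighted":
                uniq = sum(
                    l for l, tips in branches
                    if bool(tips & pres_i) != bool(tips & pres_j)
                )
                union = sum(
                    l for l, tips in branches
                    if (tips & pres_i) or (tips & pres_j)
                )
                D[i, j] = D[j, i] = uniq / union if union > 0 else 0.0
            else:
                ti, tj = ri.sum(), rj.sum()
                raw = sum(
                    l * abs(sum(ri[o] for o in tips if o in counts.columns) / ti
                            - sum(rj[o] for o in tips if o in counts.columns) / tj)
                    for l, tips in branches
                )
                if variant == "weighted_raw":
                    D[i, j] = D[j, i] = raw
                else:
                    norm = sum(
                        tip_depth[o] * (ri[o] / ti + rj[o] / tj)
                        for o in counts.columns
                    )
                    D[i, j] = D[j, i] = raw / norm if norm > 0 else 0.0
    return D
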