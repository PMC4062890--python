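"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from u6phylo.dating import MutNode, MutTree
from u6phylo.haplotree import default_tree


@pytest.fixture(scope="session")
def u6_tree():
    return default_tree()


# ---------------------------------------------------------------------------
# independent brute-force oracles for the dating statistics (no reuse of the
# MutTree caches: tips and descendant counts are re-derived by fresh walks)

def _list_tips(node: MutNode) -> list[MutNode]:
    if not node.children:
        return [node]
    out = []
    for c in node.children:
        out.extend(_list_tips(c))
    return out


def rho_bruteforce(tree: MutTree, node: MutNode | None = None) -> float:
    """Mean tip-to-node mutation count by explicit path enumeration."""
    node = node or tree.root
    tips = _list_tips(node)
    total, weight = 0, 0
    for tip in tips:
        path_len, cur = 0, tip
        while cur is not node:
            path_len += cur.length
            cur = cur.parent
        total += tip.multiplicity * path_len
        weight += tip.multiplicity
    return total / weight


def sigma_bruteforce(tree: MutTree, node: MutNode | None = None) -> float:
    """Saillard error from first principles: sqrt(sum l_i n_i^2) / N."""
    node = node or tree.root
    n_total = sum(t.multiplicity for t in _list_tips(node))

    def branches(cur: MutNode):
        for c in cur.children:
            yield c
            yield from branches(c)

    acc = 0
    for br in branches(node):
        n_i = sum(t.multiplicity for t in _list_tips(br))
        acc += br.length * n_i * n_i
    return acc ** 0.5 / n_total


def random_mut_tree(rng: np.random.Generator, max_tips: int = 12) -> MutTree:
    """A random rooted topology with integer branch lengths and multiplicities."""
    n_tips = int(rng.integers(2, max_tips + 1))
    root = MutNode(name="root")
    attachable = [root]
    for i in range(n_tips):
        parent = attachable[int(rng.integers(0, len(attachable)))]
        child = MutNode(
            name=f"n{i}",
            length=int(rng.integers(0, 6)),
            multiplicity=int(rng.integers(1, 4)),
        )
        parent.add(child)
        attachable.append(child)
    # internal nodes keep multiplicity only if they stayed tips
    for node in attachable:
        if node.children and node is not root:
            node.multiplicity = 0
    return MutTree(root)
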