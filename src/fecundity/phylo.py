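"""Phylogenetic covariance utilities shared by simulation and comparative
analyses.

Under Brownian motion the covariance of two tips equals the depth (root
to node path length) of their most recent common ancestor; the variance
of a tip is its root-to-tip depth.  Pagel's λ rescales the off-diagonal
entries of that matrix by λ ∈ [0, 1]: λ = 0 is independence between
species, λ = 1 plain Brownian motion.
"""

from __future__ import annotations

import random

import dendropy
import numpy as np

__all__ = [
    "tip_labels",
    "phylo_covariance",
    "node_covariance",
    "lambda_transform",
    "simulate_phylogeny",
]


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def _depths(tree: dendropy.Tree) -> dict:
    depth = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        depth[node] = depth[node.parent_node] + (node.edge.length or 0.0)
    return depth


def node_covariance(tree: dendropy.Tree) -> tuple[np.ndarray, list, list[str]]:
    """Brownian-motion covariance over *all* nodes of the tree.

    Returns (C, nodes, tip_names) where C[u, v] is the depth of the MRCA
    of nodes u and v and ``nodes`` fixes the index order (tips first, in
    leaf-iteration order, then internal nodes in preorder).
    """
    tips = list(tree.leaf_node_iter())
    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    nodes = tips + internals
    index = {n: i for i, n in enumerate(nodes)}
    depth = _depths(tree)
    n = len(nodes)
    C = np.zeros((n, n))

    # subtree membership, bottom-up
    under: dict = {}
    for node in tree.postorder_node_iter():
        members = [index[node]]
        for ch in node.child_nodes():
            members.extend(under[ch])
        under[node] = members

    for node in tree.preorder_node_iter():
        d = depth[node]
        i = index[node]
        C[i, i] = d
        kids = node.child_nodes()
        desc = [j for ch in kids for j in under[ch]]
        if desc:
            C[i, desc] = d
            C[desc, i] = d
        for a in range(len(kids)):
            for b in range(a + 1, len(kids)):
                ia = np.asarray(under[kids[a]])
                ib = np.asarray(under[kids[b]])
                C[np.ix_(ia, ib)] = d
                C[np.ix_(ib, ia)] = d
    return C, nodes, [t.taxon.label for t in tips]


def phylo_covariance(tree: dendropy.Tree) -> tuple[np.ndarray, list[str]]:
    """Tip-to-tip Brownian covariance matrix and the tip label order."""
    C, nodes, names = node_covariance(tree)
    k = len(names)
    return C[:k, :k], names


def lambda_transform(C: np.ndarray, lam: float) -> np.ndarray:
    """Scale off-diagonal entries of a BM covariance by λ ∈ [0, 1]."""
    if not (0.0 <= lam <= 1.0):
        raise ValueError(f"lambda {lam} outside [0, 1]")
    out = lam * C
    np.fill_diagonal(out, np.diag(C))
    return out


def simulate_phylogeny(n_tips: int, rng: np.random.Generator) -> dendropy.Tree:
    """Random ultrametric pure-birth (Yule) tree with ``n_tips`` leaves
    labeled s1..sN, rescaled to unit root-to-tip depth."""
    if n_tips < 3:
        raise ValueError("need at least 3 tips")
    from dendropy.simulate import treesim

    py_rng = random.Random(int(rng.integers(2**31 - 1)))
    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_tips,
        rng=py_rng,
    )
    # drop the stem edge above the root: shared history starts at the MRCA
    tree.seed_node.edge.length = None
    # the simulation stops at the n-th speciation, leaving the newest
    # tips with zero-length terminal edges; extend every terminal edge
    # equally (tree stays ultrametric, all branch lengths positive)
    depth0 = max(_depths(tree)[leaf] for leaf in tree.leaf_node_iter())
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + 0.05 * depth0
    # unit depth so σ²_BM is per total tree height
    d = _depths(tree)
    depth = max(d[leaf] for leaf in tree.leaf_node_iter())
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= depth
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"s{i + 1}"
    return tree
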