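"""Phylogenetic tree utilities: newick I/O and the Brownian-motion
covariance structure shared by the trait simulator and Blomberg's K.
"""

from __future__ import annotations

import random as _random

import numpy as np
import dendropy
from dendropy.simulate import treesim


def read_newick(path_or_string: str, from_string: bool = False) -> dendropy.Tree:
    if from_string:
        return dendropy.Tree.get(data=path_or_string, schema="newick")
    return dendropy.Tree.get(path=path_or_string, schema="newick")


def write_newick(tree: dendropy.Tree, path: str) -> None:
    tree.write(path=path, schema="newick")


def random_coalescent_tree(labels: list[str] | int, seed: int = 0,
                           pop_size: float = 1.0) -> dendropy.Tree:
    """A seeded Kingman-coalescent tree (strictly positive branch lengths)."""
    if isinstance(labels, int):
        labels = [f"T{i + 1:02d}" for i in range(labels)]
    tns = dendropy.TaxonNamespace(labels)
    return treesim.pure_kingman_tree(taxon_namespace=tns, pop_size=pop_size,
                                     rng=_random.Random(seed))


def tree_vcv(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """Taxon labels and the Brownian-motion variance-covariance matrix V.

    V[i, j] is the shared root-to-MRCA branch length of tips i and j;
    V[i, i] is the root-to-tip distance. Requires non-negative branch
    lengths and a tree of positive total depth.
    """
    tree = tree.clone(depth=1)
    root = tree.seed_node
    # node depths from the root
    depth = {root: 0.0}
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        bl = node.edge.length if node.edge.length is not None else 0.0
        if bl < 0:
            raise ValueError("negative branch length in tree")
        depth[node] = depth[node.parent_node] + bl

    leaves = [lf for lf in tree.leaf_node_iter()]
    labels = [lf.taxon.label for lf in leaves]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate tip labels")
    idx = {lf: i for i, lf in enumerate(leaves)}
    n = len(leaves)
    V = np.zeros((n, n))
    for lf in leaves:
        V[idx[lf], idx[lf]] = depth[lf]

    # postorder: leaf sets per node; pairs first meeting at `node` share depth[node]
    below: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = [idx[node]]
            continue
        children = [below.pop(c) for c in node.child_nodes()]
        for a in range(len(children)):
            for b in range(a + 1, len(children)):
                for i in children[a]:
                    for j in children[b]:
                        V[i, j] = V[j, i] = depth[node]
        below[node] = [i for ch in children for i in ch]

    if np.max(np.diag(V)) <= 0:
        raise ValueError("tree has zero total depth (no positive branch lengths)")
    return labels, V
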