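"""Small helpers around dendropy trees used across modules."""

from __future__ import annotations

import dendropy


def parse_newick(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick", rooting="force-rooted")


def to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick", suppress_rooting=True, suppress_annotations=True
    ).strip()


def leaf_names(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def mrca_leafset(tree: dendropy.Tree, names) -> set[str]:
    """Leaf labels under the MRCA of the given taxa."""
    mrca = tree.mrca(taxon_labels=list(names))
    return {lf.taxon.label for lf in mrca.leaf_iter()}


def assign_node_ids(tree: dendropy.Tree) -> None:
    """Deterministic post-order ids: leaves keep their taxon label,
    internal nodes get ``nd000``, ``nd001``, ... in post-order."""
    counter = 0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node.label = node.taxon.label
        else:
            node.label = f"nd{counter:03d}"
            counter += 1


def node_ids(tree: dendropy.Tree) -> list[str]:
    return [n.label for n in tree.postorder_node_iter()]


def node_by_id(tree: dendropy.Tree, label: str) -> dendropy.Node:
    for node in tree.postorder_node_iter():
        if node.label == label:
            return node
    raise KeyError(label)


def root_distances(tree: dendropy.Tree) -> dict[str, float]:
    """Sum of branch lengths from the root to every node, keyed by node id."""
    out: dict[str, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            out[node.label] = 0.0
        else:
            out[node.label] = out[node.parent_node.label] + (node.edge.length or 0.0)
    return out


def clade_nodes(tree: dendropy.Tree, leaf_labels) -> set[str]:
    """Node ids of the MRCA of ``leaf_labels`` and everything below it."""
    mrca = tree.mrca(taxon_labels=list(leaf_labels))
    return {n.label for n in mrca.preorder_iter()}
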