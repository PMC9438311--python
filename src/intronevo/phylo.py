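"""Exon-based phylogenetics: K2P distances, neighbour joining, rooting.

Distances are Kimura two-parameter: with P and Q the transition and
transversion proportions over counted sites,

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q).

Pairwise transition/transversion counts are pooled across families
before the formula is applied (robust for short alignments); trees are
built with Saitou-Nei neighbour joining using a deterministic
lexicographic tie-break, and rooted on a declared outgroup.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from . import _treeutil as tu
from ._align import StickyScoring, encode, nw_align

log = logging.getLogger(__name__)


class SaturationError(ValueError):
    """Raised when observed divergence is too high for the K2P formula
    (1 - 2P - Q <= 0 or 1 - 2Q <= 0)."""


def k2p_counts(a: str, b: str) -> tuple[int, int, int]:
    """Transition, transversion and counted-site totals for two aligned
    equal-length sequences.  Columns where either symbol is not a plain
    base (gap, N, ...) are excluded."""
    if len(a) != len(b):
        raise ValueError("aligned sequences must have equal length")
    ca = encode(a)
    cb = encode(b)
    valid = (ca < 4) & (cb < 4)
    xa, xb = ca[valid], cb[valid]
    diff = xa != xb
    ts = int((diff & ((xa ^ xb) == 2)).sum())
    tv = int(diff.sum()) - ts
    return ts, tv, int(valid.sum())


def k2p_from_counts(n_ts: int, n_tv: int, n_sites: int) -> float:
    if n_sites <= 0:
        raise ValueError("no counted sites")
    P = n_ts / n_sites
    Q = n_tv / n_sites
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(
            f"saturated pair: P={P:.4f}, Q={Q:.4f} (1-2P-Q={w1:.4f}, 1-2Q={w2:.4f})"
        )
    return float(-0.5 * np.log(w1) - 0.25 * np.log(w2))


def kimura2p(a: str, b: str) -> float:
    """K2P distance between two aligned sequences."""
    return k2p_from_counts(*k2p_counts(a, b))


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray          # symmetric, zero diagonal
    n_sites: np.ndarray         # aligned sites counted per pair

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.all(np.isfinite(m)) or (np.diag(m) != 0).any() or (m < 0).any():
            raise ValueError("distances must be finite, non-negative, zero diagonal")
        self.matrix = m

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.ids, columns=self.ids)

    def write_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for i, name in enumerate(self.ids):
                row = " ".join(f"{v:.8f}" for v in self.matrix[i])
                fh.write(f"{name:<12s}{row}\n")


_BASE_SCORING = StickyScoring()  # meta symbols never occur in exon alignments


def _align_counts(a: str, b: str) -> tuple[int, int, int]:
    """Pairwise-align two exon sequences (global NW) and count
    transitions/transversions over aligned columns."""
    ca, cb = encode(a), encode(b)
    _, pairs = nw_align(ca, cb, _BASE_SCORING)
    if not pairs:
        return 0, 0, 0
    idx = np.asarray(pairs)
    xa = ca[idx[:, 0]]
    xb = cb[idx[:, 1]]
    valid = (xa < 4) & (xb < 4)
    xa, xb = xa[valid], xb[valid]
    diff = xa != xb
    ts = int((diff & ((xa ^ xb) == 2)).sum())
    tv = int(diff.sum()) - ts
    return ts, tv, int(valid.sum())


def distance_matrix(
    family_seqs: dict[str, dict[str, str]],
    min_coverage: float = 1.0,
    max_families: int | None = None,
) -> DistanceMatrix:
    """Pooled-count K2P distance matrix from per-family exon sequences.

    ``family_seqs`` maps family -> species -> spliced exon sequence.
    Families present in at least ``min_coverage`` (fraction) of the
    species are used; per species pair, counts are pooled across all
    shared families before applying the K2P formula.
    """
    species = sorted({sp for fam in family_seqs.values() for sp in fam})
    n = len(species)
    fams = [
        f for f in sorted(family_seqs)
        if len(family_seqs[f]) >= min_coverage * n
    ]
    if max_families is not None:
        fams = fams[:max_families]
    if not fams:
        raise ValueError("no family passes the coverage threshold")
    idx = {sp: i for i, sp in enumerate(species)}
    ts = np.zeros((n, n), dtype=np.int64)
    tv = np.zeros((n, n), dtype=np.int64)
    ns = np.zeros((n, n), dtype=np.int64)
    for f in fams:
        seqs = family_seqs[f]
        present = sorted(seqs)
        for a, b in itertools.combinations(present, 2):
            i, j = idx[a], idx[b]
            t1, t2, m = _align_counts(seqs[a], seqs[b])
            ts[i, j] += t1
            tv[i, j] += t2
            ns[i, j] += m
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if ns[i, j] == 0:
                raise ValueError(
                    f"species pair {species[i]}/{species[j]} shares no aligned sites"
                )
            D[i, j] = D[j, i] = k2p_from_counts(int(ts[i, j]), int(tv[i, j]),
                                                int(ns[i, j]))
    return DistanceMatrix(ids=species, matrix=D, n_sites=ns + ns.T)


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbour joining.

    Deterministic: when several pairs minimise the Q criterion, the
    lexicographically smallest (label, label) pair is joined.  Negative
    branch lengths are clamped to zero with a warning.  The returned
    tree is unrooted (trifurcating seed node).
    """
    n0 = len(dm.ids)
    if n0 < 3:
        raise ValueError("neighbour joining needs >= 3 taxa")
    labels = list(dm.ids)
    D = {a: {b: dm.matrix[i, j] for j, b in enumerate(labels)}
         for i, a in enumerate(labels)}
    taxa = dendropy.TaxonNamespace()
    nodes: dict[str, dendropy.Node] = {}
    for name in labels:
        nd = dendropy.Node()
        nd.taxon = taxa.new_taxon(name)
        nodes[name] = nd
    active = sorted(labels)
    join_count = 0

    def clamp(x: float, a: str, b: str) -> float:
        if x < 0:
            log.warning("negative NJ branch length %.4g (%s/%s) clamped to 0", x, a, b)
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        r = {a: sum(D[a][b] for b in active if b != a) for a in active}
        best = None
        for a, b in itertools.combinations(active, 2):
            q = (m - 2) * D[a][b] - r[a] - r[b]
            key = (q, a, b)
            if best is None or key < best:
                best = key
        _, a, b = best
        la = 0.5 * D[a][b] + (r[a] - r[b]) / (2.0 * (m - 2))
        lb = D[a][b] - la
        parent_label = f"__nj{join_count}"
        join_count += 1
        parent = dendropy.Node()
        nodes[a].edge.length = clamp(la, a, b)
        nodes[b].edge.length = clamp(lb, a, b)
        parent.add_child(nodes[a])
        parent.add_child(nodes[b])
        nodes[parent_label] = parent
        D[parent_label] = {}
        for c in active:
            if c in (a, b):
                continue
            d = 0.5 * (D[a][c] + D[b][c] - D[a][b])
            D[parent_label][c] = d
            D[c][parent_label] = d
        D[parent_label][parent_label] = 0.0
        active = sorted([c for c in active if c not in (a, b)] + [parent_label])

    a, b, c = active
    la = 0.5 * (D[a][b] + D[a][c] - D[b][c])
    lb = 0.5 * (D[a][b] + D[b][c] - D[a][c])
    lc = 0.5 * (D[a][c] + D[b][c] - D[a][b])
    root = dendropy.Node()
    for lbl, ln in ((a, la), (b, lb), (c, lc)):
        nodes[lbl].edge.length = clamp(ln, lbl, lbl)
        root.add_child(nodes[lbl])
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


def root_tree(tree: dendropy.Tree, outgroup: list[str] | set[str]) -> dendropy.Tree:
    """Root an unrooted NJ tree on the branch separating the outgroup.

    The outgroup must form one side of a bipartition; the root bisects
    that branch.  Node ids are then assigned deterministically in
    post-order.
    """
    outgroup = set(outgroup)
    all_leaves = set(tu.leaf_names(tree))
    if not outgroup or not outgroup < all_leaves:
        raise ValueError("outgroup must be a proper, non-empty subset of the taxa")
    target = None
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = {lf.taxon.label for lf in node.leaf_iter()}
        if below == outgroup or (all_leaves - below) == outgroup:
            target = node
            break
    if target is None:
        raise ValueError("outgroup does not form a clade in the unrooted tree")
    edge = target.edge
    half = 0.5 * (edge.length or 0.0)
    tree.reroot_at_edge(edge, length1=half, length2=half)
    tree.is_rooted = True
    tu.assign_node_ids(tree)
    return tree
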