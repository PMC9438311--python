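"""Sankoff maximum-parsimony reconstruction of discretised intron sizes.

Intron lengths are discretised to integral ``10*log2`` states; the
transition cost between states is their absolute difference.  For each
intron the classic Sankoff dynamic program is run over the species tree
(bottom-up cost vectors on a bounded state lattice, top-down backtrace),
yielding ancestral size states at every internal node and the total
parsimony cost.  Downstream summaries trace cumulative size change
along branches, extract mode lines from ancestral-vs-extant joint
distributions, and measure the proportion of anciently long introns
that have been minimised (76-100 bp) in extant species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.signal import find_peaks

from . import _treeutil as tu

log = logging.getLogger(__name__)

_INF = np.float64(np.inf)


def discretize_size(length_bp) -> int | np.ndarray:
    """Size state = round(10*log2(length)), round-half-even.

    Invertible to length within half a discretisation step.
    """
    arr = np.asarray(length_bp, dtype=float)
    if np.any(arr < 1):
        raise ValueError("intron length must be >= 1 bp")
    out = np.round(10.0 * np.log2(arr)).astype(np.int64)
    return int(out) if np.isscalar(length_bp) else out


def decode_state(state) -> float | np.ndarray:
    """Length (bp) corresponding to a size state."""
    out = 2.0 ** (np.asarray(state, dtype=float) / 10.0)
    return float(out) if np.isscalar(state) else out


def _dist_transform(cost: np.ndarray) -> np.ndarray:
    """min_t cost[t] + |s - t| for the unit-spaced lattice (two-pass)."""
    idx = np.arange(cost.size, dtype=float)
    fwd = np.minimum.accumulate(cost - idx) + idx
    bwd = (np.minimum.accumulate((cost + idx)[::-1]) - idx[::-1])[::-1]
    return np.minimum(fwd, bwd)


def sankoff_reconstruct(
    tree,
    leaf_states: dict[str, int | None],
    margin: int = 10,
) -> tuple[dict[str, int], float]:
    """Sankoff parsimony for one intron.

    ``leaf_states`` maps species to observed discretised states; species
    mapped to ``None`` (or absent) contribute an all-zero cost vector
    (standard missing-data handling).  Backtrace ties are broken toward
    the state closest to the parent's chosen state, then the smallest
    state; at the root the smallest minimal-cost state is chosen.

    Returns the chosen state per node id and the total parsimony cost
    (sum over edges of |parent - child|).
    """
    observed = sorted(
        int(s) for s in leaf_states.values() if s is not None and not np.isnan(s)
    )
    if len(observed) == 0:
        raise ValueError("no observed leaf states")
    lo = observed[0] - margin
    hi = observed[-1] + margin
    lattice = np.arange(lo, hi + 1)
    S = lattice.size

    cost: dict[str, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            sp = node.taxon.label
            s = leaf_states.get(sp)
            if s is None or (isinstance(s, float) and np.isnan(s)):
                cost[node.label] = np.zeros(S)
            else:
                c = np.full(S, _INF)
                c[int(s) - lo] = 0.0
                cost[node.label] = c
        else:
            total = np.zeros(S)
            for child in node.child_nodes():
                total += _dist_transform(cost[child.label])
            cost[node.label] = total

    states: dict[str, int] = {}
    for node in tree.preorder_node_iter():
        c = cost[node.label]
        if node.parent_node is None:
            best = np.flatnonzero(c == c.min())
            states[node.label] = int(lattice[best[0]])  # smallest state at root
        else:
            sp_state = states[node.parent_node.label]
            total = c + np.abs(lattice - sp_state)
            best = np.flatnonzero(total == total.min())
            # closest to the parent's state, then smallest
            dist = np.abs(lattice[best] - sp_state)
            best = best[dist == dist.min()]
            chosen = int(lattice[best[0]])
            states[node.label] = chosen
            if best.size > 1:
                log.debug("Sankoff tie at node %s resolved to %d", node.label, chosen)

    total_cost = 0.0
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            total_cost += abs(states[node.label] - states[node.parent_node.label])
    # observed leaves pin their own states; assert reconstruction stayed in hull
    root_cost = float(cost[tree.seed_node.label].min())
    assert total_cost == root_cost, "backtrace cost mismatch"
    return states, total_cost


@dataclass
class AncestralSizeTable:
    """Per intron x per node size states plus parsimony costs."""

    states: pd.DataFrame   # index intron id, columns node ids (leaves + internal)
    costs: pd.Series

    def node_states(self, node_id: str) -> pd.Series:
        return self.states[node_id]

    def write(self, path) -> None:
        out = self.states.copy()
        out["parsimony_cost"] = self.costs
        out.index.name = "intron"
        out.to_csv(path, sep="\t", na_rep="NA", float_format="%.0f")


def sankoff_table(tree, leaf_state_table: pd.DataFrame, margin: int = 10) -> AncestralSizeTable:
    """Run Sankoff for every intron (rows) over species columns.

    Introns with no observed species are skipped with a warning.
    """
    node_order = tu.node_ids(tree)
    rows = {}
    costs = {}
    species = [c for c in leaf_state_table.columns]
    for intron, row in leaf_state_table.iterrows():
        leaf_states = {
            sp: (None if pd.isna(row[sp]) else int(row[sp])) for sp in species
        }
        if all(v is None for v in leaf_states.values()):
            log.warning("intron %s has no observed states; skipped", intron)
            continue
        states, cost = sankoff_reconstruct(tree, leaf_states, margin=margin)
        rows[intron] = [states[n] for n in node_order]
        costs[intron] = cost
    states_df = pd.DataFrame.from_dict(rows, orient="index", columns=node_order)
    states_df.index.name = "intron"
    return AncestralSizeTable(states=states_df, costs=pd.Series(costs, name="cost"))


def branch_changes(table: AncestralSizeTable, tree) -> pd.DataFrame:
    """Cumulative change in mean size state from the root, per node.

    Returns one row per node: distance from root (sum of branch lengths,
    i.e. cumulative K2P distance when the tree is the exon NJ tree) and
    the mean over introns of (state at node - state at root).  The root
    row is (0, 0) by definition.
    """
    dists = tu.root_distances(tree)
    root_id = tree.seed_node.label
    root_states = table.states[root_id]
    rows = []
    for node in tree.preorder_node_iter():
        nid = node.label
        rows.append(dict(
            node=nid,
            is_leaf=node.is_leaf(),
            clade=getattr(node, "clade", ""),
            root_dist=dists[nid],
            cum_mean_change=float((table.states[nid] - root_states).mean()),
        ))
    return pd.DataFrame(rows)


@dataclass
class ModeLine:
    """A ridge of per-ancestral-column peaks in the blurred joint
    distribution of ancestral vs extant size states."""

    taxon: str
    ancestral_states: np.ndarray
    extant_modes: np.ndarray  # smoothed, float


def mode_lines(
    ancestral_states: np.ndarray,
    extant_states: np.ndarray,
    taxon: str = "",
    blur_sd: float = 6.0,
    min_state: int = 63,           # introns longer than 75 bp only
    join_tol: float = 9.0,
    max_column_gap: int = 3,
    smooth_sd: float = 2.0,
) -> list[ModeLine]:
    """Extract mode lines from the ancestral-vs-extant joint distribution.

    The 2-D histogram on the integral state grid is standardised
    column-wise (ancestral columns), blurred with a Gaussian (sd
    ``blur_sd`` states, kernel truncated at 4 sd), per-column peaks are
    picked and adjacent-column peaks joined into lines (gaps up to
    ``max_column_gap`` columns are bridged), then each line is smoothed
    with a normal kernel.
    """
    a = np.asarray(ancestral_states)
    e = np.asarray(extant_states)
    keep = (a >= min_state) & (e >= min_state)
    a, e = a[keep], e[keep]
    if a.size == 0:
        return []
    a0, a1 = int(a.min()), int(a.max())
    e0, e1 = int(e.min()), int(e.max())
    H = np.zeros((e1 - e0 + 1, a1 - a0 + 1))
    np.add.at(H, (e - e0, a - a0), 1.0)

    counts = H.sum(axis=0)
    Z = H.copy()
    nonempty = counts > 0
    mu = H[:, nonempty].mean(axis=0)
    sd = H[:, nonempty].std(axis=0)
    sd[sd == 0] = 1.0
    Z[:, nonempty] = (H[:, nonempty] - mu) / sd
    B = gaussian_filter(Z, sigma=blur_sd, truncate=4.0, mode="nearest")

    lines: list[dict] = []
    for col in range(B.shape[1]):
        if not nonempty[col]:
            continue
        colv = B[:, col]
        padded = np.r_[-np.inf, colv, -np.inf]
        peaks, _ = find_peaks(padded)
        peaks -= 1
        if peaks.size == 0:
            peaks = np.array([int(np.argmax(colv))])
        for p in sorted(peaks, key=lambda i: -colv[i]):
            row_state = p + e0
            best = None
            for ln in lines:
                gap = col - ln["cols"][-1]
                if 0 < gap <= max_column_gap and ln["col_claimed"] != col:
                    d = abs(ln["rows"][-1] - row_state)
                    if d <= join_tol and (best is None or d < best[0]):
                        best = (d, ln)
            if best is not None:
                ln = best[1]
                ln["cols"].append(col)
                ln["rows"].append(row_state)
                ln["col_claimed"] = col
            else:
                lines.append(dict(cols=[col], rows=[row_state], col_claimed=col))

    out = []
    for ln in lines:
        cols = np.asarray(ln["cols"]) + a0
        rows = np.asarray(ln["rows"], dtype=float)
        if rows.size >= 3 and smooth_sd > 0:
            w = int(np.ceil(3 * smooth_sd))
            kern = np.exp(-0.5 * (np.arange(-w, w + 1) / smooth_sd) ** 2)
            kern /= kern.sum()
            pad = np.r_[np.full(w, rows[0]), rows, np.full(w, rows[-1])]
            rows = np.convolve(pad, kern, mode="valid")
        out.append(ModeLine(taxon=taxon, ancestral_states=cols, extant_modes=rows))
    out.sort(key=lambda l: (l.ancestral_states[0], l.extant_modes[0]))
    return out


def minimised_proportion(
    ancestral_states: np.ndarray,
    extant_lengths: np.ndarray,
    window: tuple = (76, 100),
    bin_width: int = 10,
) -> pd.DataFrame:
    """Per ancestral-size bin, the fraction of introns whose extant
    length lies in the minimised window [76, 100] bp (inclusive).

    Bins are ``bin_width`` states wide (default 10 states = 1 log2
    unit); empty bins are absent from the output, not zero.
    """
    a = np.asarray(ancestral_states)
    L = np.asarray(extant_lengths, dtype=float)
    keep = ~np.isnan(L)
    a, L = a[keep], L[keep]
    bins = (a // bin_width) * bin_width
    mini = (L >= window[0]) & (L <= window[1])
    df = pd.DataFrame(dict(anc_bin=bins, minimised=mini))
    out = df.groupby("anc_bin").agg(n=("minimised", "size"),
                                    proportion=("minimised", "mean"))
    return out.reset_index()
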