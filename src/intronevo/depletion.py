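"""Functional-term depletion scans over genes ordered by intron length.

Genes are scored by the largest of their introns' minimum-across-clade
lengths ("longest minimal clade intron length"); for each functional
term, nested gene sets from short to long are tested for depletion of
term members with the lower-tail hypergeometric probability
P(X <= q | N, m, k).  Terms whose members systematically carry long
introns show a depletion minimum near the boundary separating the short
and long intron classes.

No multiple-testing correction is applied (curves are reported raw);
the number of terms tested is included so users can correct.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .orthology import OrthologyTable

log = logging.getLogger(__name__)

MIN_TERM_SIZE = 5


def gene_length_statistic(
    orthology: OrthologyTable,
    clade_species: list[str],
) -> pd.Series:
    """Per gene: max over its introns of the min-across-clade length.

    The minimum is taken over clade species with data for the intron;
    genes with no intron data in the clade are excluded with a warning.
    """
    present = [s for s in clade_species if s in orthology.data.columns]
    if len(present) < 2:
        raise ValueError("clade must have >= 2 species in the orthology")
    minima = orthology.data[present].min(axis=1)
    genes = orthology.genes
    stat = minima.groupby(genes).max()
    n_dropped = int(stat.isna().sum())
    if n_dropped:
        log.warning("%d genes with no intron data in clade excluded", n_dropped)
    return stat.dropna().sort_index()


def nested_depletion_scan(
    gene_values: pd.Series,
    term_table: pd.DataFrame,
    thresholds: np.ndarray | None = None,
    max_thresholds: int = 512,
) -> pd.DataFrame:
    """Depletion curves for every term with >= 5 annotated genes.

    For each threshold T the nested set is the genes with value <= T;
    the depletion probability is the hypergeometric lower tail
    P(X <= q) with population N (all scored genes), m term members and
    draw size k = |nested set|.  Output is long-format with one row per
    (term, threshold); the minimal-p threshold per term is marked.
    """
    if thresholds is None:
        thresholds = np.unique(gene_values.to_numpy())
        if thresholds.size > max_thresholds:
            idx = np.linspace(0, thresholds.size - 1, max_thresholds).astype(int)
            thresholds = thresholds[np.unique(idx)]
    thresholds = np.asarray(thresholds, dtype=float)
    if not np.all(np.diff(thresholds) >= 0):
        raise ValueError("thresholds must be ascending")

    genes = gene_values.index.to_numpy()
    values = gene_values.to_numpy(dtype=float)
    N = genes.size
    order = np.argsort(values, kind="stable")
    sorted_vals = values[order]
    k_at = np.searchsorted(sorted_vals, thresholds, side="right")

    terms = term_table[term_table.gene_id.isin(genes)]
    term_sizes = terms.groupby("term_id").size()
    gene_pos = pd.Series(np.arange(N), index=genes)

    frames = []
    for term_id, m in term_sizes.items():
        if m < MIN_TERM_SIZE:
            log.info("term %s has %d members (<%d); skipped", term_id, m, MIN_TERM_SIZE)
            continue
        members = terms.loc[terms.term_id == term_id, "gene_id"].unique()
        member_vals = np.sort(values[gene_pos[members].to_numpy()])
        q_at = np.searchsorted(member_vals, thresholds, side="right")
        m_eff = member_vals.size
        with np.errstate(divide="ignore", invalid="ignore"):
            p = hypergeom.cdf(q_at, N, m_eff, k_at)
            expected = k_at * m_eff / N
            obs_exp = np.where(
                (q_at > 0) & (expected > 0), np.log2(q_at / np.where(expected > 0, expected, 1)),
                -np.inf,
            )
        valid = k_at >= 1
        df = pd.DataFrame(dict(
            term=term_id,
            threshold=thresholds[valid],
            threshold_log2=np.log2(thresholds[valid]),
            k=k_at[valid], q=q_at[valid], m=m_eff, N=N,
            p=p[valid], log2_obs_exp=obs_exp[valid],
        ))
        df["is_min_p"] = False
        if len(df):
            df.loc[df.index[int(np.argmin(df.p.to_numpy()))], "is_min_p"] = True
        frames.append(df)
    if not frames:
        raise ValueError("no term with >= 5 members among scored genes")
    return pd.concat(frames, ignore_index=True)


def min_p_thresholds(curves: pd.DataFrame) -> pd.Series:
    """Threshold (bp) of minimal depletion p per term."""
    sub = curves[curves.is_min_p]
    return sub.set_index("term")["threshold"]


def random_gene_control(
    orthology: OrthologyTable,
    n_introns: int,
    seed: int = 0,
) -> list[str]:
    """Genes owning ``n_introns`` introns sampled without replacement
    from the orthology (control for gene-size bias in length-based
    selections); reproducible under the seed."""
    introns = orthology.data.index.to_numpy()
    if n_introns > introns.size:
        raise ValueError("cannot sample more introns than the orthology holds")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(introns, size=n_introns, replace=False)
    genes = sorted({i.split(":")[0] for i in chosen})
    return genes
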