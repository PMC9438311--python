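"""Conserved sequence detection within orthologous introns.

A seed (reference-species) intron is locally aligned to each partner
species' orthologous intron; the per-orthologue-set top score is judged
against a search-space null model: scores of alignments of
NON-orthologous seed sequences of similar length follow an approximate
power law in the search space (seed length x summed partner lengths),
so conservation is called when log(top score) exceeds the linear fit of
log score on log space by more than the 95th percentile of control
residuals.

Local alignments are found with a recursive Smith-Waterman: the optimal
alignment is reported, its seed interval is masked with a sentinel
symbol, and the search repeats until the best score drops below a
threshold.  Seed intervals of the reported hits are therefore pairwise
disjoint; partner intervals may overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._align import MASK, LocalScoring, encode, sw_align, sw_best

log = logging.getLogger(__name__)

MAX_SEARCH_SPACE = 1e8


@dataclass
class LocalAlignmentHit:
    seed_id: str
    partner_species: str
    partner_id: str
    seed_start: int
    seed_end: int
    partner_start: int
    partner_end: int
    score: int
    round: int


def recursive_local_align(
    seed_seq: str,
    partner_seq: str,
    scoring: LocalScoring = LocalScoring(),
    min_score: int = 20,
    max_space: float = MAX_SEARCH_SPACE,
    max_rounds: int = 50,
    seed_id: str = "seed",
    partner_id: str = "partner",
    partner_species: str = "?",
) -> list[LocalAlignmentHit]:
    """All non-overlapping (in the seed) local alignments of a pair.

    The optimal alignment is extracted, its seed interval replaced by a
    masking sentinel that cannot align to anything, and the alignment
    repeated until the best score falls below ``min_score``.  Scores are
    non-increasing across rounds.  Pairs whose search space (product of
    lengths) exceeds ``max_space`` are skipped with a warning.
    """
    l1, l2 = len(seed_seq), len(partner_seq)
    if l1 * l2 > max_space:
        log.warning("search space %g > %g for %s/%s; pair skipped",
                    l1 * l2, max_space, seed_id, partner_id)
        return []
    a = encode(seed_seq)
    b = encode(partner_seq)
    hits: list[LocalAlignmentHit] = []
    for rnd in range(1, max_rounds + 1):
        score, ai, bi = sw_align(a, b, scoring)
        if score < min_score or ai is None:
            break
        hits.append(LocalAlignmentHit(
            seed_id=seed_id, partner_species=partner_species,
            partner_id=partner_id,
            seed_start=int(ai[0]), seed_end=int(ai[1]),
            partner_start=int(bi[0]), partner_end=int(bi[1]),
            score=int(score), round=rnd,
        ))
        a[ai[0]:ai[1]] = MASK
    return hits


def hits_table(hits: list[LocalAlignmentHit]) -> pd.DataFrame:
    cols = ["seed_id", "partner_species", "partner_id", "seed_start", "seed_end",
            "partner_start", "partner_end", "score", "round"]
    return pd.DataFrame([h.__dict__ for h in hits], columns=cols)


# --------------------------------------------------------------------------
# intron set selection


def select_intron_sets(
    orthology,
    clade_species: list[str],
    n_select: int = 2000,
    seed: int = 0,
    long_min_bp: float = 1024,
    med_range_bp: tuple = (256, 1024),
    short_range_bp: tuple = (90, 256),
    ctl_median_max_bp: float = 256,
    ctl_reference_min_bp: float = 1024,
) -> dict[str, list[str]]:
    """Labelled intron sets by clade length profile.

    * ``long``: all introns with clade-min >= 1024 bp
    * ``med``: lowest clade-length-variance ``n_select`` introns with
      clade-min in (256, 1024)
    * ``short``: as med, within [90, 256); ``short2``: a random sample
      from the same range
    * ``ctl``: clade-median < 256 bp but reference length > 1024 bp,
      sampled randomly (long in the reference, short across the clade)

    Sets smaller than ``n_select`` are used in full with a warning.
    Sampling is deterministic under ``seed``.
    """
    present = [s for s in clade_species if s in orthology.data.columns]
    cmin = orthology.clade_min(present)
    cmed = orthology.clade_median(present)
    log_len = np.log2(orthology.data[present])
    cvar = log_len.var(axis=1)
    ref_len = orthology.data[orthology.reference]
    rng = np.random.default_rng(seed)

    def lowest_variance(mask: pd.Series, n: int) -> list[str]:
        ids = cvar[mask].dropna().sort_values(kind="stable").index
        return list(ids[:n])

    def sample(mask: pd.Series, n: int, label: str) -> list[str]:
        ids = np.asarray(sorted(orthology.data.index[mask]))
        if ids.size <= n:
            if ids.size < n:
                log.warning("set %s has only %d introns (requested %d); using all",
                            label, ids.size, n)
            return list(ids)
        return sorted(rng.choice(ids, size=n, replace=False))

    sets = {
        "long": sorted(orthology.data.index[cmin >= long_min_bp]),
        "med": lowest_variance(
            (cmin > med_range_bp[0]) & (cmin < med_range_bp[1]), n_select),
        "short": lowest_variance(
            (cmin >= short_range_bp[0]) & (cmin < short_range_bp[1]), n_select),
        "short2": sample(
            (cmin >= short_range_bp[0]) & (cmin < short_range_bp[1]),
            n_select, "short2"),
        "ctl": sample(
            (cmed < ctl_median_max_bp) & (ref_len > ctl_reference_min_bp),
            n_select, "ctl"),
    }
    for label in ("med", "short"):
        if len(sets[label]) < n_select:
            log.warning("set %s has only %d introns (requested %d); using all",
                        label, len(sets[label]), n_select)
    return sets


# --------------------------------------------------------------------------
# repeat filtering


class GenomeKmerCounter:
    """Count genome loci matching >= 50% of a query sequence's length.

    A k-mer index of the genome stands in for a full genome aligner:
    exact 31-mer matches of the query vote on genome diagonals; votes
    are clustered into candidate loci and a locus counts when the union
    of its matching k-mer windows covers at least half the query.
    K-mers occurring more than ``max_kmer_hits`` times in the genome are
    ignored, so simple repeats and homopolymers report zero loci.
    """

    def __init__(self, genome: str, k: int = 31, max_kmer_hits: int = 50):
        self.k = k
        self.max_kmer_hits = max_kmer_hits
        codes = encode(genome).astype(np.int64)
        kmers, pos = self._kmerize(codes)
        order = np.argsort(kmers, kind="stable")
        self._kmers = kmers[order]
        self._pos = pos[order]

    def _kmerize(self, codes: np.ndarray):
        k = self.k
        n = codes.size - k + 1
        if n <= 0:
            return np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64)
        valid = codes < 4
        window_valid = np.ones(n, dtype=bool)
        bad = np.flatnonzero(~valid)
        for off in range(k):
            idx = bad - off
            idx = idx[(idx >= 0) & (idx < n)]
            window_valid[idx] = False
        val = np.zeros(codes.size - k + 1, dtype=np.uint64)
        c = codes.astype(np.uint64)
        for j in range(k):
            val = (val << np.uint64(2)) | c[j:j + n]
        pos = np.flatnonzero(window_valid).astype(np.int64)
        return val[window_valid], pos

    def count_loci(self, seq: str, cluster_gap: int = 64) -> int:
        k = self.k
        if len(seq) < k:
            return 0
        codes = encode(seq).astype(np.int64)
        qk, qpos = self._kmerize(codes)
        diags = []
        offsets = []
        for kmer, off in zip(qk, qpos):
            a = np.searchsorted(self._kmers, kmer, side="left")
            b = np.searchsorted(self._kmers, kmer, side="right")
            if b - a == 0 or b - a > self.max_kmer_hits:
                continue
            gp = self._pos[a:b]
            diags.append(gp - off)
            offsets.append(np.full(b - a, off))
        if not diags:
            return 0
        diags = np.concatenate(diags)
        offsets = np.concatenate(offsets)
        order = np.argsort(diags, kind="stable")
        diags, offsets = diags[order], offsets[order]
        half = 0.5 * len(seq)
        count = 0
        start = 0
        for i in range(1, diags.size + 1):
            if i == diags.size or diags[i] - diags[i - 1] > cluster_gap:
                offs = np.sort(offsets[start:i])
                covered = 0
                run_a = run_b = None
                for o in offs:
                    if run_a is None:
                        run_a, run_b = o, o + k
                    elif o <= run_b:
                        run_b = max(run_b, o + k)
                    else:
                        covered += run_b - run_a
                        run_a, run_b = o, o + k
                if run_a is not None:
                    covered += run_b - run_a
                if covered >= half:
                    count += 1
                start = i
        return count


def repeat_filter(seqs: dict[str, str], counter) -> list[str]:
    """Keep sequences matching exactly 1 or 2 genome loci.

    More than 2 loci marks a dispersed repeat; zero loci (the sequence
    cannot even find itself) marks a simple repeat collapsed by the
    counter.  Both are removed.
    """
    retained = []
    for sid in sorted(seqs):
        c = counter.count_loci(seqs[sid])
        if c in (1, 2):
            retained.append(sid)
        else:
            log.info("repeat filter: %s has %d genome loci; removed", sid, c)
    return retained


# --------------------------------------------------------------------------
# null model and calls


@dataclass
class NullModel:
    """Linear fit of log(top score) on log(search space) over control
    (non-orthologous) alignments, with the 95th-percentile residual
    cutoff used to flag conservation."""

    intercept: float
    slope: float
    residuals: np.ndarray
    cutoff: float

    def predict(self, space: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.log(np.asarray(space, dtype=float))

    def residual(self, score: np.ndarray, space: np.ndarray) -> np.ndarray:
        return np.log(np.asarray(score, dtype=float)) - self.predict(space)


def fit_null_model(scores: np.ndarray, spaces: np.ndarray,
                   min_controls: int = 50) -> NullModel:
    """Least-squares fit of log score on log space; natural logs (the
    scale cancels in residual-percentile flagging)."""
    s = np.asarray(scores, dtype=float)
    x = np.asarray(spaces, dtype=float)
    ok = (s > 0) & (x > 0)
    s, x = s[ok], x[ok]
    if s.size < min_controls:
        raise ValueError(f"need >= {min_controls} control points, got {s.size}")
    slope, intercept = np.polyfit(np.log(x), np.log(s), 1)
    model = NullModel(intercept=float(intercept), slope=float(slope),
                      residuals=np.empty(0), cutoff=0.0)
    res = model.residual(s, x)
    model.residuals = res
    model.cutoff = float(np.percentile(res, 95))
    return model


def top_scores(
    seed_seqs: dict[str, str],
    partner_seqs: dict[str, dict[str, str]],
    scoring: LocalScoring = LocalScoring(),
    max_space: float = MAX_SEARCH_SPACE,
) -> pd.DataFrame:
    """Per orthologue set: the maximal local-alignment score over
    partner species and the total search space l_seed * sum(l_partner).

    Sets without any usable partner are reported with NaN score
    (no-data), not zero.
    """
    rows = []
    for sid in sorted(seed_seqs):
        seed = seed_seqs[sid]
        partners = partner_seqs.get(sid, {})
        best = np.nan
        space = 0.0
        n_used = 0
        for sp in sorted(partners):
            pseq = partners[sp]
            if len(seed) * len(pseq) > max_space:
                log.warning("search space > %g for %s vs %s; skipped",
                            max_space, sid, sp)
                continue
            s, _, _ = sw_best(encode(seed), encode(pseq), scoring)
            space += float(len(pseq))
            n_used += 1
            if np.isnan(best) or s > best:
                best = float(s)
        rows.append(dict(
            intron=sid, top_score=best,
            space=len(seed) * space if n_used else np.nan,
            n_partners=n_used, seed_len=len(seed),
        ))
    return pd.DataFrame(rows)


def conservation_calls(scores: pd.DataFrame, model: NullModel) -> pd.DataFrame:
    """Residual against the null model and conservation flag per set
    member (flagged iff residual > cutoff); no-data members keep NaN."""
    out = scores.copy()
    ok = out.top_score.notna() & (out.top_score > 0) & (out.space > 0)
    out["residual"] = np.nan
    out.loc[ok, "residual"] = model.residual(
        out.loc[ok, "top_score"].to_numpy(), out.loc[ok, "space"].to_numpy()
    )
    out["flagged"] = pd.array(out.residual > model.cutoff, dtype="boolean")
    out.loc[~ok, "flagged"] = pd.NA
    return out


def flagged_proportions(calls: pd.DataFrame, by: str = "set_label") -> pd.Series:
    """Fraction of members flagged per set label (no-data excluded)."""
    sub = calls[calls.flagged.notna()]
    return sub.groupby(by).flagged.mean()


def pick_control_seed(
    seed_len: int,
    pool: pd.Series,
    exclude_gene: str,
    tolerance: float = 0.25,
) -> str | None:
    """Nearest-length non-orthologous reference intron within +-25%.

    ``pool`` maps intron id ("gene:rank") to reference length.
    """
    lengths = pool[[not i.startswith(exclude_gene + ":") for i in pool.index]]
    if lengths.empty:
        return None
    diff = (lengths - seed_len).abs()
    best = diff.idxmin()
    if abs(lengths[best] - seed_len) > tolerance * seed_len:
        return None
    return best
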