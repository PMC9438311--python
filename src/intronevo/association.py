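"""Cross-species intron-size association statistics.

Three ways of asking how intron size co-varies between species over the
orthology: plug-in mutual information of discretised sizes with a
margin-permutation significance test; quantile cross-prediction (do
introns long across one clade predict long orthologues in another?);
and size-partitioned Pearson correlations (are long introns better
size-conserved than short ones?).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MIN_PAIRED_INTRONS = 100


def _log2_bins(lengths: np.ndarray) -> np.ndarray:
    """Integral log2(length) bin codes (the analysis' size scale)."""
    return np.floor(np.log2(np.asarray(lengths, dtype=float))).astype(np.int64)


def _joint_counts(ca: np.ndarray, cb: np.ndarray) -> np.ndarray:
    ka = ca.max() + 1
    kb = cb.max() + 1
    return np.bincount(ca * kb + cb, minlength=ka * kb).reshape(ka, kb)


def mi_from_counts(counts: np.ndarray) -> float:
    """Plug-in (maximum-likelihood) mutual information in bits."""
    n = counts.sum()
    if n == 0:
        raise ValueError("empty contingency table")
    p = counts / n
    pa = p.sum(axis=1, keepdims=True)
    pb = p.sum(axis=0, keepdims=True)
    mask = p > 0
    return float((p[mask] * np.log2(p[mask] / (pa @ pb)[mask])).sum())


def entropy_bits(codes: np.ndarray) -> float:
    c = np.bincount(codes - codes.min())
    p = c[c > 0] / c.sum()
    return float(-(p * np.log2(p)).sum())


def mutual_information(
    sizes_a: np.ndarray,
    sizes_b: np.ndarray,
    bin_scheme: str = "log2",
) -> float:
    """MI (bits) between two species' intron sizes over shared orthologues.

    Sizes are discretised to integral log2 bins (the package default;
    the only scheme currently implemented).
    """
    if bin_scheme != "log2":
        raise ValueError(f"unknown bin scheme {bin_scheme!r}")
    a = np.asarray(sizes_a, dtype=float)
    b = np.asarray(sizes_b, dtype=float)
    if a.size != b.size:
        raise ValueError("paired size vectors must have equal length")
    if a.size < MIN_PAIRED_INTRONS:
        raise ValueError(f"need >= {MIN_PAIRED_INTRONS} paired introns, got {a.size}")
    ca = _log2_bins(a)
    cb = _log2_bins(b)
    return mi_from_counts(_joint_counts(ca - ca.min(), cb - cb.min()))


@dataclass
class MIResult:
    species_a: str
    species_b: str
    mi_bits: float
    p_value: float
    n: int
    n_perm: int
    bin_scheme: str = "log2"


def mi_permutation_test(
    sizes_a: np.ndarray,
    sizes_b: np.ndarray,
    n_perm: int = 10000,
    seed: int = 0,
    species_a: str = "a",
    species_b: str = "b",
) -> MIResult:
    """Margin-permutation test of MI.

    One margin is permuted; p uses the add-one estimator
    p = (1 + #{MI_perm >= MI_obs}) / (n_perm + 1), so p is never 0 and
    its resolution is 1/(n_perm+1).
    """
    a = np.asarray(sizes_a, dtype=float)
    b = np.asarray(sizes_b, dtype=float)
    if a.size < MIN_PAIRED_INTRONS:
        raise ValueError(f"need >= {MIN_PAIRED_INTRONS} paired introns, got {a.size}")
    ca = _log2_bins(a)
    cb = _log2_bins(b)
    ca -= ca.min()
    cb -= cb.min()
    obs = mi_from_counts(_joint_counts(ca, cb))
    rng = np.random.default_rng(seed)
    n_ge = 0
    perm = cb.copy()
    for _ in range(n_perm):
        rng.shuffle(perm)
        if mi_from_counts(_joint_counts(ca, perm)) >= obs:
            n_ge += 1
    p = (1 + n_ge) / (n_perm + 1)
    return MIResult(species_a=species_a, species_b=species_b, mi_bits=obs,
                    p_value=p, n=int(a.size), n_perm=n_perm)


@dataclass
class QuantilePrediction:
    threshold_log2: float
    n_above: int
    frac_above_50: float
    frac_above_95: float
    log2_obs_exp_50: float
    log2_obs_exp_95: float


def quantile_cross_prediction(
    reference_medians: np.ndarray,
    target_medians: np.ndarray,
    threshold_log2: float,
) -> QuantilePrediction:
    """Among introns whose reference-clade median log2 size exceeds the
    threshold, the fraction whose target-clade median exceeds the target
    clade's own 50th / 95th percentile, with log2 observed/expected
    ratios (expected 0.5 and 0.05 under no association)."""
    r = np.asarray(reference_medians, dtype=float)
    t = np.asarray(target_medians, dtype=float)
    ok = ~(np.isnan(r) | np.isnan(t))
    r, t = r[ok], t[ok]
    q50, q95 = np.quantile(t, [0.5, 0.95])
    sel = r > threshold_log2
    n = int(sel.sum())
    if n < 20:
        log.warning("only %d introns above threshold %.2f", n, threshold_log2)
    if n == 0:
        return QuantilePrediction(threshold_log2, 0, np.nan, np.nan, np.nan, np.nan)
    f50 = float((t[sel] > q50).mean())
    f95 = float((t[sel] > q95).mean())
    with np.errstate(divide="ignore"):
        return QuantilePrediction(
            threshold_log2=threshold_log2, n_above=n,
            frac_above_50=f50, frac_above_95=f95,
            log2_obs_exp_50=float(np.log2(f50 / 0.5)) if f50 > 0 else -np.inf,
            log2_obs_exp_95=float(np.log2(f95 / 0.05)) if f95 > 0 else -np.inf,
        )


@dataclass
class PartitionCorrelation:
    r_short: float
    r_long: float
    ratio: float
    n_short: int
    n_long: int
    reliable: bool   # False when |r_short| < 0.05 (ratio unstable)


def size_partition_correlations(
    reference_log2: np.ndarray,
    partner_log2: np.ndarray,
    floor_bp: float = 76.0,
    cap_quantile: float = 0.99,
    min_pairs: int = 30,
) -> PartitionCorrelation:
    """Pearson correlations of log2 sizes for short vs long introns.

    Introns at least ``floor_bp`` in both species and within the
    reference species' ``cap_quantile`` percentile are split at the
    midpoint of the reference log-size range into two equal-range sets;
    correlations are computed per set and their ratio r_long/r_short
    reported (flagged unreliable when r_short is near zero).
    """
    r = np.asarray(reference_log2, dtype=float)
    p = np.asarray(partner_log2, dtype=float)
    lo = np.log2(floor_bp)
    ok = ~(np.isnan(r) | np.isnan(p)) & (r >= lo) & (p >= lo)
    r, p = r[ok], p[ok]
    if r.size == 0:
        raise ValueError("no paired introns above the floor")
    cap = np.quantile(r, cap_quantile)
    keep = r <= cap
    r, p = r[keep], p[keep]
    mid = 0.5 * (lo + cap)
    short = r < mid
    long_ = ~short
    if short.sum() < min_pairs or long_.sum() < min_pairs:
        raise ValueError(
            f"partition too small: {int(short.sum())} short / {int(long_.sum())} long "
            f"pairs (need >= {min_pairs})"
        )
    r_short = float(np.corrcoef(r[short], p[short])[0, 1])
    r_long = float(np.corrcoef(r[long_], p[long_])[0, 1])
    reliable = abs(r_short) >= 0.05
    ratio = r_long / r_short if r_short != 0 else np.inf
    return PartitionCorrelation(
        r_short=r_short, r_long=r_long, ratio=float(ratio),
        n_short=int(short.sum()), n_long=int(long_.sum()), reliable=reliable,
    )


def pairwise_mi_matrix(
    orthology_data: pd.DataFrame,
    species: list[str] | None = None,
    n_perm: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """MI (bits) for all species pairs sharing enough orthologous introns.

    ``orthology_data`` is the orthology length matrix (introns x
    species).  When ``n_perm`` > 0, permutation p-values are computed
    too and returned in a long-format frame; otherwise a square MI
    matrix is returned.
    """
    species = species or list(orthology_data.columns)
    if n_perm > 0:
        rows = []
        for i, a in enumerate(species):
            for b in species[i + 1:]:
                sub = orthology_data[[a, b]].dropna()
                res = mi_permutation_test(
                    sub[a].to_numpy(), sub[b].to_numpy(),
                    n_perm=n_perm, seed=seed, species_a=a, species_b=b,
                )
                rows.append(res.__dict__)
        return pd.DataFrame(rows)
    M = pd.DataFrame(0.0, index=species, columns=species)
    for i, a in enumerate(species):
        sub_a = orthology_data[a]
        M.loc[a, a] = mutual_information(sub_a.dropna(), sub_a.dropna())
        for b in species[i + 1:]:
            sub = orthology_data[[a, b]].dropna()
            mi = mutual_information(sub[a].to_numpy(), sub[b].to_numpy())
            M.loc[a, b] = M.loc[b, a] = mi
    return M
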