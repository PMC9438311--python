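"""Mutual information, permutation tests, quantile prediction and
size-partitioned correlations."""

from __future__ import annotations

import numpy as np
import pytest

from intronevo.association import (entropy_bits, mi_from_counts,
                                   mi_permutation_test, mutual_information,
                                   quantile_cross_prediction,
                                   size_partition_correlations, _log2_bins)


def test_mi_identity_channel_equals_entropy():
    rng = np.random.default_rng(0)
    sizes = np.exp2(rng.uniform(6, 14, 500))
    mi = mutual_information(sizes, sizes)
    h = entropy_bits(_log2_bins(sizes))
    assert mi == pytest.approx(h, abs=1e-12)


def test_mi_two_by_two_diagonal_is_one_bit():
    counts = np.array([[5, 0], [0, 5]])
    assert mi_from_counts(counts) == pytest.approx(1.0, abs=1e-12)


def test_mi_is_symmetric_and_nonnegative():
    rng = np.random.default_rng(1)
    a = np.exp2(rng.uniform(6, 14, 400))
    b = np.exp2(rng.uniform(6, 14, 400))
    m1 = mutual_information(a, b)
    m2 = mutual_information(b, a)
    assert m1 == pytest.approx(m2, abs=1e-12)
    assert m1 >= 0


def test_mi_matches_sklearn():
    from sklearn.metrics import mutual_info_score

    rng = np.random.default_rng(2)
    a = np.exp2(rng.uniform(6, 12, 300))
    b = a * np.exp2(rng.normal(0, 0.5, 300))
    ours = mutual_information(a, b)
    theirs = mutual_info_score(_log2_bins(a), _log2_bins(b)) / np.log(2)
    assert ours == pytest.approx(theirs, abs=1e-10)


def test_mi_requires_minimum_sample():
    with pytest.raises(ValueError):
        mutual_information(np.full(50, 100.0), np.full(50, 100.0))


def test_independent_streams_have_small_mi():
    rng = np.random.default_rng(3)
    a = np.exp2(rng.uniform(6, 14, 1000))
    b = np.exp2(rng.uniform(6, 14, 1000))
    assert mutual_information(a, b) < 0.05


def test_coarsening_bins_never_increases_mi():
    """Data-processing inequality on random joint distributions."""
    rng = np.random.default_rng(4)
    for _ in range(50):
        ka, kb = rng.integers(3, 9, size=2)
        counts = rng.integers(0, 20, size=(ka, kb))
        fine = mi_from_counts(counts)
        # merge a random adjacent pair of rows
        i = int(rng.integers(0, ka - 1))
        merged = np.vstack([counts[:i], counts[i] + counts[i + 1],
                            counts[i + 2:]])
        assert mi_from_counts(merged) <= fine + 1e-12


def test_perfect_dependence_gives_minimal_p():
    rng = np.random.default_rng(5)
    a = np.exp2(rng.uniform(6, 14, 500))
    res = mi_permutation_test(a, a, n_perm=99, seed=0)
    assert res.p_value == pytest.approx(1 / 100)


def test_permutation_test_is_deterministic_under_seed():
    rng = np.random.default_rng(6)
    a = np.exp2(rng.uniform(6, 14, 300))
    b = a * np.exp2(rng.normal(0, 1.0, 300))
    p1 = mi_permutation_test(a, b, n_perm=200, seed=7).p_value
    p2 = mi_permutation_test(a, b, n_perm=200, seed=7).p_value
    assert p1 == p2


def test_quantile_self_prediction_is_total():
    rng = np.random.default_rng(8)
    m = rng.uniform(6, 14, 2000)
    thr = float(np.quantile(m, 0.5))
    qp = quantile_cross_prediction(m, m, thr)
    assert qp.frac_above_50 == 1.0


def test_quantile_null_matches_expectation():
    rng = np.random.default_rng(9)
    r = rng.uniform(6, 14, 2000)
    t = rng.uniform(6, 14, 2000)
    qp = quantile_cross_prediction(r, t, float(np.quantile(r, 0.5)))
    assert abs(qp.frac_above_50 - 0.5) < 0.05
    assert abs(qp.frac_above_95 - 0.05) < 0.05


def test_quantile_prediction_on_cohort_exceeds_null(default_orthology,
                                                    default_cohort):
    from intronevo.simulate import background_species, contracted_species

    orth = default_orthology
    con = contracted_species(default_cohort.tree)
    bak = background_species(default_cohort.tree)
    ref = np.log2(orth.clade_median(con))
    tgt = np.log2(orth.clade_median(bak))
    fracs = []
    for thr in (9.0, 10.0, 11.0):
        qp = quantile_cross_prediction(ref, tgt, thr)
        assert qp.frac_above_95 / 0.05 >= 2.0
        fracs.append((qp.frac_above_50, qp.frac_above_95))
    # monotone non-decreasing in the threshold
    assert fracs == sorted(fracs)


def test_partition_correlation_affine_identity():
    rng = np.random.default_rng(10)
    r = rng.uniform(np.log2(76), 14, 2000)
    pc = size_partition_correlations(r, r + 1.0)
    assert pc.r_short == pytest.approx(1.0)
    assert pc.r_long == pytest.approx(1.0)
    assert pc.ratio == pytest.approx(1.0)


def test_partition_correlation_null_flagged_unreliable():
    rng = np.random.default_rng(11)
    r = rng.uniform(np.log2(76), 14, 3000)
    p = rng.uniform(np.log2(76), 14, 3000)
    pc = size_partition_correlations(r, p)
    assert abs(pc.r_short) < 0.1 and abs(pc.r_long) < 0.1
    assert not pc.reliable


def test_partition_correlation_small_set_errors():
    r = np.full(40, 10.0)
    with pytest.raises(ValueError):
        size_partition_correlations(r[:20], r[:20])


def test_partition_ratio_grows_with_divergence(default_orthology,
                                               default_cohort):
    """Long (retained-class) introns stay size-correlated across
    species while free introns carry little heritable size signal, so
    r_long/r_short > 1, and the contrast grows with divergence
    (Spearman rho > 0 over the K2P-ordered pairs).  Non-contracted
    partners are used: total in-clade minimisation leaves no short-set
    signal to correlate."""
    from scipy.stats import spearmanr

    from intronevo import _treeutil as tu
    from intronevo.simulate import contracted_species

    orth = default_orthology
    tree = default_cohort.tree
    con = set(contracted_species(tree))
    ref = "mam01"
    partners = [s for s in orth.species if s != ref and s not in con]
    assert len(partners) >= 6
    rd = tu.root_distances(tree)
    ratios, dists = [], []
    for sp in partners:
        sub = orth.data[[ref, sp]].dropna()
        pc = size_partition_correlations(
            np.log2(sub[ref].to_numpy()), np.log2(sub[sp].to_numpy()))
        assert pc.ratio > 1.0
        mrca = tree.mrca(taxon_labels=[ref, sp]).label
        dists.append(rd[ref] + rd[sp] - 2 * rd[mrca])
        ratios.append(pc.ratio)
    assert spearmanr(dists, ratios).statistic > 0
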