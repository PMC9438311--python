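"""Generator behaviour: tree construction, limits, floors, determinism."""

from __future__ import annotations

import numpy as np
import pytest

from intronevo import _treeutil as tu
from intronevo.phylo import kimura2p
from intronevo.simulate import (ConfigurationError, SimulationConfig,
                                contracted_drift_path, contracted_species,
                                simulate_cohort, simulate_species_tree)


def test_explicit_newick_is_echoed():
    cfg = SimulationConfig(n_species=3, tree_shape="((A:1,B:1):1,C:2);",
                           contracted_clade=("A", "B"))
    tree = simulate_species_tree(cfg)
    assert sorted(tu.leaf_names(tree)) == ["A", "B", "C"]
    assert tu.mrca_leafset(tree, ["A", "B"]) == {"A", "B"}


def test_random_birth_is_deterministic():
    n1 = tu.to_newick(simulate_species_tree(SimulationConfig(seed=1)))
    n2 = tu.to_newick(simulate_species_tree(SimulationConfig(seed=1)))
    assert n1 == n2
    n3 = tu.to_newick(simulate_species_tree(SimulationConfig(seed=2)))
    assert n1 != n3


def test_contracted_clade_is_monophyletic():
    cfg = SimulationConfig(n_species=12, contracted_clade=5, seed=4)
    tree = simulate_species_tree(cfg)
    con = contracted_species(tree)
    assert len(con) == 5
    assert tu.mrca_leafset(tree, con) == set(con)


def test_non_monophyletic_contracted_request_errors():
    cfg = SimulationConfig(n_species=4, tree_shape="((A:1,B:1):1,(C:1,D:1):1);",
                           contracted_clade=("A", "C"))
    with pytest.raises(ConfigurationError, match="monophyletic"):
        simulate_species_tree(cfg)


def test_tree_is_binary_with_positive_branch_lengths():
    tree = simulate_species_tree(SimulationConfig(seed=5))
    for node in tree.preorder_node_iter():
        if not node.is_leaf():
            assert len(node.child_nodes()) == 2
        if node.parent_node is not None:
            assert node.edge.length > 0


def test_config_validation():
    with pytest.raises(ConfigurationError):
        SimulationConfig(retained_fraction=1.5)
    with pytest.raises(ConfigurationError):
        SimulationConfig(retained_floor_bp=10, floor_bp=76)
    with pytest.raises(ConfigurationError):
        SimulationConfig(element_len_bp=500, retained_floor_bp=256)


def test_zero_noise_zero_drift_keeps_root_lengths():
    cfg = SimulationConfig(seed=6, n_species=6, contracted_clade=2,
                           n_families=20, log2_sigma=0.0,
                           log2_drift_contracted=0.0, minimisation_rate=0.0)
    cohort = simulate_cohort(cfg)
    wide = cohort.truth.orthology.pivot_table(
        index=["gene", "rank"], columns="species", values="length_bp")
    assert (wide.nunique(axis=1) == 1).all()


def test_zero_substitution_rate_gives_identical_exons():
    cfg = SimulationConfig(seed=6, n_species=6, contracted_clade=2,
                           n_families=10, subst_rate=0.0)
    cohort = simulate_cohort(cfg)
    ref = cohort.transcripts[cohort.species[0]]
    g0 = cohort.genomes[cohort.species[0]]
    from intronevo.annotation import intron_interval

    def spliced(sp):
        out = {}
        for tr in cohort.transcripts[sp]:
            chrom = cohort.genomes[sp][tr.chrom]
            s = "".join(chrom[a:b] for a, b in tr.exons)
            if tr.strand == "-":
                from intronevo._align import encode, decode, reverse_complement
                s = decode(reverse_complement(encode(s)))
            out[tr.gene] = s
        return out

    s0 = spliced(cohort.species[0])
    for sp in cohort.species[1:]:
        s1 = spliced(sp)
        for gene in s0:
            assert s0[gene] == s1[gene]
            assert kimura2p(s0[gene], s1[gene]) == 0.0


def test_drift_shifts_mean_log2_by_drift_times_path():
    """With a non-binding floor, the contracted/background mean log2
    difference equals drift x path length to within 20%."""
    cfg = SimulationConfig(seed=8, n_families=100, floor_bp=1,
                           retained_floor_bp=1, retained_fraction=0.0,
                           log2_drift_contracted=-1.0, log2_sigma=0.2,
                           minimisation_rate=0.0)
    tree = simulate_species_tree(cfg)
    cohort = simulate_cohort(cfg, tree)
    anc = cohort.truth.ancestral_log2
    con = contracted_species(tree)
    bak = [s for s in cohort.species if s not in con and s != "out01"]
    diff = anc[con].mean().mean() - anc[bak].mean().mean()
    path = contracted_drift_path(tree, con[0])
    expected = cfg.log2_drift_contracted * path
    assert abs(diff - expected) <= 0.2 * abs(expected)


def test_floors_hold_in_truth_and_files(small_cohort, tmp_path):
    truth = small_cohort.truth
    klass = truth.intron_class.set_index(["gene", "rank"]).intron_class
    orth = truth.orthology.set_index(["gene", "rank"])
    cfg = small_cohort.config
    joined = orth.join(klass)
    assert (joined.length_bp >= cfg.floor_bp).all()
    retained = joined[joined.intron_class == "retained"]
    assert (retained.length_bp >= cfg.retained_floor_bp).all()
    # and in the written annotation files
    from intronevo.annotation import extract_introns, read_annotation

    small_cohort.write(tmp_path / "c")
    for sp in small_cohort.species:
        cat = extract_introns(read_annotation(tmp_path / "c" / f"{sp}.gff3",
                                              species=sp))
        assert (cat.length >= cfg.floor_bp).all()


def test_free_introns_spike_at_floor_under_strong_drift(default_cohort):
    truth = default_cohort.truth
    free = truth.intron_class.intron_class.to_numpy() == "free"
    con = contracted_species(default_cohort.tree)
    for sp in con:
        L = truth.orthology[truth.orthology.species == sp].sort_values(
            ["gene", "rank"]).length_bp.to_numpy()
        frac = ((L[free] >= 76) & (L[free] <= 100)).mean()
        assert frac > 0.25


def test_every_intron_appears_once_per_species_in_truth(default_cohort):
    t = default_cohort.truth.orthology
    counts = t.groupby(["gene", "rank", "species"]).size()
    assert (counts == 1).all()
    n_introns = len(default_cohort.truth.intron_class)
    assert len(t) == n_introns * len(default_cohort.species)


def test_identical_config_and_seed_give_byte_identical_files(tmp_path):
    cfg = SimulationConfig(seed=9, n_species=5, contracted_clade=2, n_families=8)
    for d in ("a", "b"):
        simulate_cohort(cfg, simulate_species_tree(cfg)).write(tmp_path / d)
    files_a = sorted((tmp_path / "a").rglob("*"))
    for fa in files_a:
        if fa.is_file():
            fb = tmp_path / "b" / fa.relative_to(tmp_path / "a")
            assert fa.read_bytes() == fb.read_bytes(), fa.name


def test_planted_elements_only_in_retained_introns(small_cohort):
    truth = small_cohort.truth
    assert len(truth.elements) > 0
    klass = truth.intron_class.set_index(["gene", "rank"]).intron_class
    keys = truth.elements.set_index(["gene", "rank"]).index.unique()
    assert (klass.loc[keys] == "retained").all()
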