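"""Synthetic multi-species cohorts with known intron-size evolution.

The generator emulates the statistical structure the analysis assumes:

* a rooted, ultrametric species tree containing a designated
  "contracted" clade (a teleost-like group under genome contraction),
  one outgroup species, and a "background" clade (mammal-like);
* single-copy gene families with intron positions fixed at family
  creation and conserved across species (no gain/loss);
* intron sizes evolving on the log2 scale as Brownian motion reflected
  at a hard lower floor (76 bp); introns belong to one of two classes -
  "free" introns additionally experience a negative size drift on every
  branch inside the contracted clade, while "retained" introns resist
  contraction (no drift) and are reflected at a higher class floor;
* exon sequences evolving under a Kimura two-parameter substitution
  model; intron sequence is unalignable background except for conserved
  elements planted in retained introns;
* a gene-to-term table in which a few "planted" terms preferentially
  annotate retained-class genes.

Class membership is assigned at the gene level (all introns of a
retained gene are retained), so ``retained_fraction`` is both the
fraction of retained genes and the expected fraction of retained
introns.  Identical config + seed yields byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml

from . import _treeutil as tu
from ._align import reverse_complement
from .annotation import TranscriptModel, write_fasta, write_gff3

log = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    pass


_DNA = np.frombuffer(b"ACGTN", dtype=np.uint8)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Size parameters are on the log2(bp) scale; branch lengths are in
    expected substitutions per site when multiplied by ``subst_rate``.
    """

    n_species: int = 12
    tree_shape: str = "random-birth"          # or an explicit newick string
    contracted_clade: int | tuple = 5         # size, or explicit leaf labels
    n_families: int = 200
    introns_per_gene_mean: float = 7.0
    introns_per_gene_dispersion: float = 3.0
    retained_fraction: float = 0.25
    log2_drift_contracted: float = -3.0       # per unit branch length, free class
    log2_sigma: float = 0.25                  # Brownian step scale per sqrt(branch length)
    minimisation_rate: float = 0.25           # per unit branch length, free class,
                                              # contracted clade: jump-to-floor rate
    floor_bp: int = 76
    retained_floor_bp: int = 256
    free_root_log2_mean: float = 9.8
    free_root_log2_sd: float = 0.5
    retained_root_log2_mean: float = 9.5
    retained_root_log2_sd: float = 1.7        # total (between-gene + within-gene)
    retained_within_gene_sd: float = 0.4      # intron scatter around the gene mean
    first_intron_log2_boost: float = 0.5
    exon_len_range: tuple = (80, 200)
    ts_tv_ratio: float = 2.0
    subst_rate: float = 0.05                  # substitutions/site per unit branch length
    element_len_bp: int = 50
    element_identity: float = 0.9
    n_terms: int = 40
    planted_terms: int = 5
    term_size_mean: float = 45.0
    planted_term_purity: float = 0.9
    spacer_bp: int = 500
    tree_depth: float = 1.5
    seed: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.retained_fraction <= 1.0:
            raise ConfigurationError("retained_fraction must be in [0, 1]")
        if self.floor_bp < 1:
            raise ConfigurationError("floor_bp must be >= 1")
        if self.retained_floor_bp < self.floor_bp:
            raise ConfigurationError("retained_floor_bp must be >= floor_bp")
        if self.n_species < 3:
            raise ConfigurationError("need at least 3 species")
        if self.retained_fraction > 0 and self.element_len_bp > self.retained_floor_bp:
            raise ConfigurationError(
                "element_len_bp exceeds the shortest possible retained intron"
            )

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["contracted_clade"] = (
            list(d["contracted_clade"])
            if not isinstance(d["contracted_clade"], int)
            else d["contracted_clade"]
        )
        d["exon_len_range"] = list(d["exon_len_range"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if isinstance(d.get("contracted_clade"), list):
            d["contracted_clade"] = tuple(d["contracted_clade"])
        if isinstance(d.get("exon_len_range"), list):
            d["exon_len_range"] = tuple(d["exon_len_range"])
        return cls(**d)


# --------------------------------------------------------------------------
# species tree


def _random_topology(names: list[str], rng: np.random.Generator) -> dendropy.Node:
    """Random sequential-coalescence topology over the given tip names."""
    nodes = []
    for name in names:
        n = dendropy.Node()
        n.tip_name = name
        nodes.append(n)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(parent)
    return nodes[0]


def _assign_ultrametric_ages(node: dendropy.Node, age: float, rng: np.random.Generator) -> None:
    node.age_ = age
    for child in node.child_nodes():
        if child.is_leaf():
            child.age_ = 0.0
        else:
            _assign_ultrametric_ages(child, age * rng.uniform(0.5, 0.8), rng)


def simulate_species_tree(config: SimulationConfig) -> dendropy.Tree:
    """Rooted binary species tree with a monophyletic contracted clade.

    For ``tree_shape="random-birth"`` the tree is ultrametric with total
    depth ``tree_depth``: the root splits into an outgroup tip and the
    ingroup; the ingroup splits into the contracted clade and the
    background clade, each with a random internal topology.  Leaves are
    labelled ``tel*`` (contracted), ``mam*`` (background) and ``out01``
    (outgroup), and every node carries a ``clade`` attribute.

    An explicit newick in ``tree_shape`` is echoed as-is; in that case
    ``contracted_clade`` must list leaf labels forming a clade.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))

    if config.tree_shape != "random-birth":
        tree = tu.parse_newick(config.tree_shape)
        labels = set(tu.leaf_names(tree))
        if len(labels) != config.n_species:
            raise ConfigurationError(
                f"newick has {len(labels)} leaves, config.n_species={config.n_species}"
            )
        contracted = config.contracted_clade
        if isinstance(contracted, int):
            raise ConfigurationError(
                "explicit newick requires contracted_clade to list leaf labels"
            )
        contracted = set(contracted)
        if not contracted <= labels:
            raise ConfigurationError("contracted_clade labels missing from tree")
        if tu.mrca_leafset(tree, contracted) != contracted:
            raise ConfigurationError("requested contracted_clade is not monophyletic")
        _label_clades(tree, contracted, set())
        tu.assign_node_ids(tree)
        return tree

    k = config.contracted_clade
    if not isinstance(k, int):
        raise ConfigurationError("random-birth requires an integer contracted clade size")
    if not 1 <= k <= config.n_species - 2:
        raise ConfigurationError("contracted clade size must leave >=2 other species")
    m = config.n_species - k - 1
    tel = [f"tel{i + 1:02d}" for i in range(k)]
    mam = [f"mam{i + 1:02d}" for i in range(m)]

    root = dendropy.Node()
    out_node = dendropy.Node()
    out_node.tip_name = "out01"
    out_node.age_ = 0.0
    ingroup = dendropy.Node()
    root.add_child(out_node)
    root.add_child(ingroup)
    tel_root = _random_topology(tel, rng) if k > 1 else _make_tip(tel[0])
    mam_root = _random_topology(mam, rng) if m > 1 else _make_tip(mam[0])
    ingroup.add_child(tel_root)
    ingroup.add_child(mam_root)

    root.age_ = config.tree_depth
    ingroup.age_ = config.tree_depth * 0.8
    for sub in (tel_root, mam_root):
        if sub.is_leaf():
            sub.age_ = 0.0
        else:
            _assign_ultrametric_ages(sub, ingroup.age_ * rng.uniform(0.55, 0.75), rng)

    taxon_ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    tree.seed_node = root
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = round(node.parent_node.age_ - node.age_, 10)
        if node.is_leaf():
            node.taxon = taxon_ns.new_taxon(node.tip_name)
    tree.is_rooted = True
    _label_clades(tree, set(tel), {"out01"})
    tu.assign_node_ids(tree)
    return tree


def _make_tip(name: str) -> dendropy.Node:
    n = dendropy.Node()
    n.tip_name = name
    n.age_ = 0.0
    return n


def _label_clades(tree: dendropy.Tree, contracted: set, outgroup: set) -> None:
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            lbl = node.taxon.label
            node.clade = (
                "contracted" if lbl in contracted
                else "outgroup" if lbl in outgroup
                else "background"
            )
        else:
            kid_clades = {c.clade for c in node.child_nodes()}
            node.clade = kid_clades.pop() if len(kid_clades) == 1 else "ancestral"


def clade_table(tree: dendropy.Tree) -> pd.DataFrame:
    rows = [
        dict(species=lf.taxon.label, clade=lf.clade)
        for lf in tree.leaf_node_iter()
    ]
    return pd.DataFrame(rows).sort_values("species").reset_index(drop=True)


def contracted_species(tree: dendropy.Tree) -> list[str]:
    return sorted(r.species for _, r in clade_table(tree).iterrows()
                  if r.clade == "contracted")


def background_species(tree: dendropy.Tree) -> list[str]:
    return sorted(r.species for _, r in clade_table(tree).iterrows()
                  if r.clade == "background")


# --------------------------------------------------------------------------
# sequence evolution


def _k2p_probs(d: float, ts_tv: float) -> tuple[float, float]:
    """Expected transition (P) and transversion (Q) proportions after
    ``d`` expected substitutions/site under Kimura's two-parameter model."""
    beta = 1.0 / (2.0 * ts_tv + 2.0)
    alpha = ts_tv / (ts_tv + 1.0)
    e_b = np.exp(-4.0 * beta * d)
    e_ab = np.exp(-2.0 * (alpha + beta) * d)
    P = 0.25 + 0.25 * e_b - 0.5 * e_ab
    Q = 0.5 - 0.5 * e_b
    return float(P), float(Q)


def _k2p_evolve(codes: np.ndarray, d: float, ts_tv: float,
                rng: np.random.Generator) -> np.ndarray:
    """Evolve a coded sequence for distance ``d`` (site-wise sampling of
    the K2P transition probabilities)."""
    if d <= 0:
        return codes.copy()
    P, Q = _k2p_probs(d, ts_tv)
    u = rng.random(codes.size)
    out = codes.copy()
    ts_mask = u < P
    out[ts_mask] ^= 2
    tv_mask = (u >= P) & (u < P + Q)
    flip = rng.integers(0, 2, size=int(tv_mask.sum()))
    xor = np.where(flip == 0, 1, 3).astype(np.int8)
    out[tv_mask] ^= xor
    return out


def _reflect(x: np.ndarray, floor: np.ndarray) -> np.ndarray:
    return floor + np.abs(x - floor)


def _evolve_sizes(tree, root_log2, floors, is_free, drift, sigma,
                  min_rate, contracted_nodes, rng, step=0.05):
    """Reflected Brownian evolution of log2 sizes along the tree.

    Returns ``{node_id: log2 size array}`` for every node.  Branches
    whose child node lies in the contracted clade (stem included) apply
    ``drift`` to free-class introns, and additionally minimise each
    free intron with rate ``min_rate`` per unit branch length (a jump
    to just above the floor, emulating lineage-specific loss of intron
    sequence; jumps are inherited by descendant lineages).  Reflection
    is applied per Euler step so strong drift piles mass against the
    floor instead of folding it upwards.
    """
    values = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            values[node.label] = _reflect(root_log2.copy(), floors)
            continue
        x = values[node.parent_node.label].copy()
        L = node.edge.length or 0.0
        if L > 0:
            in_clade = node.label in contracted_nodes
            mu = np.where(is_free & in_clade, drift, 0.0)
            n_steps = max(1, int(np.ceil(L / step)))
            dt = L / n_steps
            sd = sigma * np.sqrt(dt)
            for _ in range(n_steps):
                x = x + mu * dt + sd * rng.standard_normal(x.size)
                x = _reflect(x, floors)
            if in_clade and min_rate > 0:
                p_jump = 1.0 - np.exp(-min_rate * L)
                jump = is_free & (rng.random(x.size) < p_jump)
                if jump.any():
                    x[jump] = floors[jump] + np.abs(
                        rng.normal(0.0, 0.15, int(jump.sum())))
        values[node.label] = x
    return values


# --------------------------------------------------------------------------
# cohort assembly


@dataclass
class TruthTables:
    """Ground truth of a simulated cohort.

    * ``orthology``: long table (family, gene, rank, species, length_bp)
    * ``ancestral_log2``: rows keyed ``gene:rank``, columns = node ids
      (leaves and internals), values = true log2 sizes
    * ``intron_class``: per intron (family, gene, rank, intron_class)
    * ``elements``: planted element coordinates, intron-local, transcript
      orientation (family, gene, rank, species, start, end)
    * ``terms``: gene-to-term truth with a ``planted`` flag
    """

    orthology: pd.DataFrame
    ancestral_log2: pd.DataFrame
    intron_class: pd.DataFrame
    elements: pd.DataFrame
    terms: pd.DataFrame

    def root_log2(self) -> pd.Series:
        root_col = self.ancestral_log2.columns[-1]
        return self.ancestral_log2[root_col]

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.orthology.to_csv(outdir / "true_orthology.tsv", sep="\t", index=False)
        self.ancestral_log2.to_csv(outdir / "true_ancestral_log2.tsv", sep="\t",
                                   float_format="%.6f")
        self.intron_class.to_csv(outdir / "true_class.tsv", sep="\t", index=False)
        self.elements.to_csv(outdir / "true_elements.tsv", sep="\t", index=False)
        self.terms.to_csv(outdir / "true_terms.tsv", sep="\t", index=False)


@dataclass
class Cohort:
    config: SimulationConfig
    tree: dendropy.Tree
    species: list[str]
    transcripts: dict            # species -> list[TranscriptModel]
    genomes: dict                # species -> {chrom: str}
    family_table: pd.DataFrame   # family_id, species, gene_id
    term_table: pd.DataFrame     # gene_id, term_id
    truth: TruthTables

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for sp in self.species:
            write_gff3(self.transcripts[sp], outdir / f"{sp}.gff3")
            write_fasta(self.genomes[sp], outdir / f"{sp}.fa")
        self.family_table.to_csv(outdir / "families.tsv", sep="\t", index=False)
        self.term_table.to_csv(outdir / "terms.tsv", sep="\t", index=False)
        clade_table(self.tree).to_csv(outdir / "clades.tsv", sep="\t", index=False)
        with open(outdir / "tree.nwk", "w") as fh:
            fh.write(tu.to_newick(self.tree) + "\n")
        self.config.to_yaml(outdir / "config.yaml")
        self.truth.write(outdir / "truth")


def _codes_to_str(codes: np.ndarray) -> str:
    return _DNA[np.asarray(codes, dtype=np.int64)].tobytes().decode("ascii")


def simulate_cohort(config: SimulationConfig,
                    tree: dendropy.Tree | None = None) -> Cohort:
    """Generate annotations, genomes, family/term tables and truth."""
    if tree is None:
        tree = simulate_species_tree(config)
    species = sorted(tu.leaf_names(tree))
    contracted = [s for s in species
                  if tu.node_by_id(tree, s).clade == "contracted"]
    contracted_nodes = (
        tu.clade_nodes(tree, contracted) if contracted else set()
    )

    ss = np.random.SeedSequence([config.seed, 1])
    (rng_fam, rng_sizes, rng_exons, rng_terms,
     rng_elements, rng_species_master) = [
        np.random.default_rng(s) for s in ss.spawn(6)
    ]
    species_rngs = {
        sp: np.random.default_rng(s)
        for sp, s in zip(species, np.random.SeedSequence([config.seed, 2]).spawn(len(species)))
    }

    # ---- family skeletons -------------------------------------------------
    mean1 = max(config.introns_per_gene_mean - 1.0, 0.1)
    k_disp = config.introns_per_gene_dispersion
    p_nb = k_disp / (k_disp + mean1)
    n_introns_per_gene = 1 + rng_fam.negative_binomial(k_disp, p_nb, config.n_families)
    strands = rng_fam.choice(np.array(["+", "-"]), config.n_families)
    retained_gene = rng_fam.random(config.n_families) < config.retained_fraction

    families = [f"fam{i:04d}" for i in range(config.n_families)]
    genes = [f"g{i:04d}" for i in range(config.n_families)]

    exon_lens = []
    for i in range(config.n_families):
        n_ex = n_introns_per_gene[i] + 1
        exon_lens.append(rng_exons.integers(config.exon_len_range[0],
                                            config.exon_len_range[1] + 1, n_ex))

    # intron index arrays
    fam_idx = np.concatenate([
        np.full(n_introns_per_gene[i], i) for i in range(config.n_families)
    ])
    ranks = np.concatenate([
        np.arange(1, n_introns_per_gene[i] + 1) for i in range(config.n_families)
    ])
    n_introns = fam_idx.size
    is_free = ~retained_gene[fam_idx]
    log2_floor = np.log2(config.floor_bp)
    log2_rfloor = np.log2(config.retained_floor_bp)
    floors = np.where(is_free, log2_floor, log2_rfloor)

    # ---- root sizes and evolution ----------------------------------------
    # retained introns share a gene-level size factor (genes differ in how
    # long their retained introns are); the marginal sd stays at
    # retained_root_log2_sd
    within = min(config.retained_within_gene_sd, config.retained_root_log2_sd)
    between = float(np.sqrt(config.retained_root_log2_sd ** 2 - within ** 2))
    gene_mu = config.retained_root_log2_mean + rng_sizes.normal(
        0.0, between, config.n_families)
    root_log2 = np.where(
        is_free,
        rng_sizes.normal(config.free_root_log2_mean, config.free_root_log2_sd, n_introns),
        gene_mu[fam_idx] + rng_sizes.normal(0.0, within, n_introns),
    )
    root_log2 = root_log2 + np.where(ranks == 1, config.first_intron_log2_boost, 0.0)
    node_log2 = _evolve_sizes(
        tree, root_log2, floors, is_free,
        config.log2_drift_contracted, config.log2_sigma,
        config.minimisation_rate, contracted_nodes, rng_sizes,
    )
    lengths = {
        sp: np.round(2.0 ** node_log2[sp]).astype(np.int64) for sp in species
    }

    # ---- exon sequence evolution (K2P) ------------------------------------
    exome_len = int(sum(int(e.sum()) for e in exon_lens))
    root_exome = rng_exons.integers(0, 4, exome_len).astype(np.int8)
    exome = {}

    def _walk(node, seq):
        exome[node.label] = seq
        for child in node.child_nodes():
            d = config.subst_rate * (child.edge.length or 0.0)
            _walk(child, _k2p_evolve(seq, d, config.ts_tv_ratio, rng_exons))

    _walk(tree.seed_node, root_exome)

    exon_offsets = []
    off = 0
    for i in range(config.n_families):
        offs = []
        for L in exon_lens[i]:
            offs.append((off, off + int(L)))
            off += int(L)
        exon_offsets.append(offs)

    # ---- planted elements --------------------------------------------------
    elen = config.element_len_bp
    element_master = {}
    for j in range(n_introns):
        if not is_free[j]:
            element_master[j] = rng_elements.integers(0, 4, elen).astype(np.int8)

    # ---- per-species assembly ---------------------------------------------
    transcripts: dict[str, list[TranscriptModel]] = {}
    genomes: dict[str, dict[str, str]] = {}
    element_rows = []
    intron_ptr = np.zeros(config.n_families + 1, dtype=np.int64)
    np.cumsum(n_introns_per_gene, out=intron_ptr[1:])

    for sp in species:
        rng_sp = species_rngs[sp]
        sp_len = lengths[sp]
        chrom_parts = []
        sp_models = []
        pos = 0
        spacer = "N" * config.spacer_bp
        for i in range(config.n_families):
            j0, j1 = intron_ptr[i], intron_ptr[i + 1]
            ilens = sp_len[j0:j1]
            if (~is_free[j0:j1]).any() and (ilens[~is_free[j0:j1]] < elen).any():
                raise ConfigurationError(
                    "element_len_bp exceeds a simulated retained intron length"
                )
            # transcript-orientation gene sequence
            parts = []
            local = 0
            exon_locals = []
            for e, (a, b) in enumerate(exon_offsets[i]):
                ex = exome[sp][a:b]
                exon_locals.append((local, local + ex.size))
                parts.append(ex)
                local += ex.size
                if e < len(exon_offsets[i]) - 1:
                    j = j0 + e
                    iseq = rng_sp.integers(0, 4, int(ilens[e])).astype(np.int8)
                    if not is_free[j]:
                        offset = int(rng_sp.integers(0, int(ilens[e]) - elen + 1))
                        master = element_master[j].copy()
                        corrupt = rng_sp.random(elen) >= config.element_identity
                        if corrupt.any():
                            shift = rng_sp.integers(1, 4, int(corrupt.sum())).astype(np.int8)
                            master[corrupt] = (master[corrupt] + shift) % 4
                        iseq[offset:offset + elen] = master
                        element_rows.append(dict(
                            family=families[i], gene=genes[i], rank=int(ranks[j]),
                            species=sp, start=offset, end=offset + elen,
                        ))
                    parts.append(iseq)
                    local += iseq.size
            gene_t = np.concatenate(parts)
            gene_len = gene_t.size
            strand = strands[i]
            gene_g = gene_t if strand == "+" else reverse_complement(gene_t)
            chrom_parts.append(spacer)
            gene_start = pos + config.spacer_bp
            chrom_parts.append(_codes_to_str(gene_g))
            # exon genomic intervals
            exon_g = []
            for (la, lb) in exon_locals:
                if strand == "+":
                    exon_g.append((gene_start + la, gene_start + lb))
                else:
                    exon_g.append((gene_start + gene_len - lb, gene_start + gene_len - la))
            sp_models.append(TranscriptModel(
                species=sp, gene=genes[i], transcript=f"t{i:04d}",
                chrom="chr1", strand=strand, exons=exon_g, canonical=True,
            ))
            pos = gene_start + gene_len
        chrom_parts.append(spacer)
        genomes[sp] = {"chr1": "".join(chrom_parts)}
        transcripts[sp] = sp_models

    # ---- tables ------------------------------------------------------------
    family_table = pd.DataFrame([
        dict(family_id=families[i], species=sp, gene_id=genes[i])
        for i in range(config.n_families) for sp in species
    ])

    intron_ids = [f"{genes[fam_idx[j]]}:{ranks[j]}" for j in range(n_introns)]
    orth_rows = []
    for sp in species:
        for j in range(n_introns):
            orth_rows.append(dict(
                family=families[fam_idx[j]], gene=genes[fam_idx[j]],
                rank=int(ranks[j]), species=sp, length_bp=int(lengths[sp][j]),
            ))
    truth_orth = pd.DataFrame(orth_rows)

    anc = pd.DataFrame(
        {nid: node_log2[nid] for nid in tu.node_ids(tree)},
        index=pd.Index(intron_ids, name="intron"),
    )

    klass = pd.DataFrame(dict(
        family=[families[i] for i in fam_idx],
        gene=[genes[i] for i in fam_idx],
        rank=ranks,
        intron_class=np.where(is_free, "free", "retained"),
    ))

    # ---- terms -------------------------------------------------------------
    retained_genes = [genes[i] for i in range(config.n_families) if retained_gene[i]]
    free_genes = [genes[i] for i in range(config.n_families) if not retained_gene[i]]
    term_rows = []
    for t in range(config.n_terms):
        term_id = f"T{t:03d}"
        planted = t < config.planted_terms
        m = max(5, int(rng_terms.poisson(config.term_size_mean)))
        members: set[str] = set()
        guard = 0
        while len(members) < m and guard < 20 * m:
            guard += 1
            if planted and retained_genes and rng_terms.random() < config.planted_term_purity:
                members.add(retained_genes[int(rng_terms.integers(0, len(retained_genes)))])
            elif planted and free_genes:
                members.add(free_genes[int(rng_terms.integers(0, len(free_genes)))])
            else:
                members.add(genes[int(rng_terms.integers(0, config.n_families))])
        for g in sorted(members):
            term_rows.append(dict(gene_id=g, term_id=term_id, planted=planted))
    truth_terms = pd.DataFrame(term_rows)
    term_table = truth_terms[["gene_id", "term_id"]].copy()

    truth = TruthTables(
        orthology=truth_orth,
        ancestral_log2=anc,
        intron_class=klass,
        elements=pd.DataFrame(element_rows) if element_rows else pd.DataFrame(
            columns=["family", "gene", "rank", "species", "start", "end"]),
        terms=truth_terms,
    )
    return Cohort(
        config=config, tree=tree, species=species, transcripts=transcripts,
        genomes=genomes, family_table=family_table, term_table=term_table,
        truth=truth,
    )


def contracted_drift_path(tree: dendropy.Tree, leaf: str) -> float:
    """Total branch length over which contraction drift acts on the path
    from the root to ``leaf`` (edges whose child node lies inside the
    contracted clade, stem included)."""
    contracted = [s for s in tu.leaf_names(tree)
                  if tu.node_by_id(tree, s).clade == "contracted"]
    if not contracted:
        return 0.0
    nodes = tu.clade_nodes(tree, contracted)
    total = 0.0
    node = tu.node_by_id(tree, leaf)
    while node.parent_node is not None:
        if node.label in nodes:
            total += node.edge.length or 0.0
        node = node.parent_node
    return total
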