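"""End-to-end orchestration of the intron-size evolution analysis.

Stages run in dependency order with plain-file handoff:

    simulate -> catalog -> distributions -> orthology -> tree ->
    ancestry -> associate -> deplete -> conserve -> report

Each stage writes tab-separated artefacts into the output directory;
every written file is content-hashed (sha256) into ``hashes.json`` and
headline statistics are collected into ``report.txt``.  All randomness
is seeded from the config, so two runs with identical config produce
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import _treeutil as tu
from . import ancestral, association, conservation, depletion, distributions
from ._align import LocalScoring, encode, decode, reverse_complement
from .annotation import (extract_introns, genome_size, read_annotation,
                         read_genome, intron_sequence)
from .orthology import OrthologyTable, build_orthology
from .phylo import distance_matrix, neighbor_joining, root_tree
from .simulate import (Cohort, SimulationConfig, clade_table,
                       simulate_cohort, simulate_species_tree)

log = logging.getLogger(__name__)

STAGES = ["simulate", "catalog", "distributions", "orthology", "tree",
          "ancestry", "associate", "deplete", "conserve"]

_DEPS = {
    "catalog": ["simulate"],
    "distributions": ["catalog"],
    "orthology": ["catalog"],
    "tree": ["orthology"],
    "ancestry": ["tree"],
    "associate": ["orthology"],
    "deplete": ["orthology"],
    "conserve": ["orthology"],
}


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Single configuration object for ``run_pipeline``.

    Thresholds default to the analysis' standard values: the 256-bp
    short/long boundary, the 76-100 bp minimised window, the 32-bp/2.5%
    annotation QC rule and the 1024-bp long-set floor.
    """

    outdir: str = "intronevo_out"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    input_dir: str | None = None        # pre-existing cohort directory (skips simulate)
    stages: list = field(default_factory=lambda: list(STAGES))
    reference_species: str = "mam01"
    outgroup: list = field(default_factory=lambda: ["out01"])
    min_species: float = 0.8
    boundary_bp: float = 256.0
    minimised_window: tuple = (76, 100)
    qc_min_bp: int = 32
    qc_max_fraction: float = 0.025
    long_min_bp: float = 1024.0
    n_distance_families: int = 30
    mi_n_perm: int = 200
    conserve_n_select: int = 60
    conserve_max_partners: int = 3
    conserve_min_score: int = 20
    conserve_min_controls: int = 50
    seed: int = 1

    def to_yaml_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["minimised_window"] = list(self.minimised_window)
        d["simulation"]["contracted_clade"] = (
            self.simulation.contracted_clade
            if isinstance(self.simulation.contracted_clade, int)
            else list(self.simulation.contracted_clade)
        )
        d["simulation"]["exon_len_range"] = list(self.simulation.exon_len_range)
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        sim = d.pop("simulation", {})
        if isinstance(sim.get("contracted_clade"), list):
            sim["contracted_clade"] = tuple(sim["contracted_clade"])
        if isinstance(sim.get("exon_len_range"), list):
            sim["exon_len_range"] = tuple(sim["exon_len_range"])
        if isinstance(d.get("minimised_window"), list):
            d["minimised_window"] = tuple(d["minimised_window"])
        return cls(simulation=SimulationConfig(**sim), **d)

    def config_hash(self) -> str:
        d = self.to_yaml_dict()
        d.pop("outdir", None)  # output location is not an analysis parameter
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, na_rep="NA", float_format="%.6g")


class Pipeline:
    """Stage runner holding in-memory artefacts between stages."""

    def __init__(self, config: RunConfig):
        self.cfg = config
        self.out = Path(config.outdir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.art: dict = {}
        self.report: dict[str, list[str]] = {}
        self._done: set[str] = set()

    # -- helpers ----------------------------------------------------------

    def _require(self, stage: str) -> None:
        for dep in _DEPS.get(stage, []):
            if dep not in self._done:
                raise PipelineError(
                    f"stage '{stage}' requires stage '{dep}' which has not run"
                )

    def _say(self, stage: str, line: str) -> None:
        self.report.setdefault(stage, []).append(line)

    # -- stages -----------------------------------------------------------

    def stage_simulate(self) -> None:
        cfg = self.cfg
        cohort_dir = self.out / "cohort"
        if cfg.input_dir is not None:
            cohort_dir = Path(cfg.input_dir)
            log.info("using pre-existing cohort at %s", cohort_dir)
        else:
            tree = simulate_species_tree(cfg.simulation)
            cohort = simulate_cohort(cfg.simulation, tree)
            cohort.write(cohort_dir)
            self.art["cohort"] = cohort
        self.art["cohort_dir"] = cohort_dir
        clades = pd.read_csv(cohort_dir / "clades.tsv", sep="\t")
        self.art["clades"] = clades
        self.art["species"] = sorted(clades.species)
        self.art["contracted"] = sorted(clades.species[clades.clade == "contracted"])
        self.art["background"] = sorted(clades.species[clades.clade == "background"])
        self._say("simulate", f"cohort of {len(clades)} species at {cohort_dir}")
        self._say("simulate",
                  f"contracted clade: {','.join(self.art['contracted'])}")

    def stage_catalog(self) -> None:
        self._require("catalog")
        cohort_dir = self.art["cohort_dir"]
        catalogues = {}
        transcripts = {}
        genomes = {}
        gsizes = {}
        for sp in self.art["species"]:
            models = read_annotation(cohort_dir / f"{sp}.gff3", species=sp)
            transcripts[sp] = models
            genomes[sp] = read_genome(cohort_dir / f"{sp}.fa")
            gsizes[sp] = genome_size(cohort_dir / f"{sp}.fa")
            catalogues[sp] = extract_introns(models)
        self.art.update(catalogues=catalogues, transcripts=transcripts,
                        genomes=genomes, genome_sizes=gsizes)
        cat = pd.concat(catalogues.values(), ignore_index=True)
        _write_tsv(cat, self.out / "intron_catalogue.tsv")
        self._say("catalog", f"{len(cat)} introns catalogued over "
                             f"{len(catalogues)} species")

    def stage_distributions(self) -> None:
        self._require("distributions")
        cfg = self.cfg
        rows = []
        dens_list = []
        for sp in self.art["species"]:
            cat = self.art["catalogues"][sp]
            dens = distributions.size_density(cat)
            dens_list.append(dens)
            antimode = distributions.find_antimode(dens, 6.0, 12.0)
            rows.append(dict(
                species=sp,
                genome_bp=self.art["genome_sizes"][sp],
                n_introns=len(cat),
                frac_below_boundary=distributions.fraction_below(cat, cfg.boundary_bp),
                frac_below_boundary_rank1=distributions.fraction_below(
                    cat, cfg.boundary_bp, rank_filter="rank=1"),
                antimode_log2=np.nan if antimode is None else antimode,
                antimode_bp=np.nan if antimode is None else 2.0 ** antimode,
                frac_below_qc=distributions.fraction_below(cat, cfg.qc_min_bp),
            ))
        summary = pd.DataFrame(rows)
        qc_included = distributions.qc_species_filter(
            self.art["catalogues"], cfg.qc_min_bp, cfg.qc_max_fraction)
        summary["qc_included"] = summary.species.isin(qc_included)
        self.art["size_summary"] = summary
        self.art["qc_included"] = qc_included
        _write_tsv(summary, self.out / "size_summary.tsv")
        _write_tsv(distributions.density_table(dens_list),
                   self.out / "size_densities.tsv")
        con = summary[summary.species.isin(self.art["contracted"])]
        self._say("distributions",
                  f"contracted antimodes (bp): " +
                  ", ".join(f"{v:.0f}" for v in con.antimode_bp.dropna()))
        self._say("distributions",
                  f"fraction<{cfg.boundary_bp:.0f}bp contracted "
                  f"{con.frac_below_boundary.mean():.3f} vs background "
                  f"{summary[summary.species.isin(self.art['background'])].frac_below_boundary.mean():.3f}")

    def stage_orthology(self) -> None:
        self._require("orthology")
        cohort_dir = self.art["cohort_dir"]
        family_table = pd.read_csv(cohort_dir / "families.tsv", sep="\t")
        orth = build_orthology(
            self.art["transcripts"], self.art["genomes"], family_table,
            reference=self.cfg.reference_species,
            min_species=self.cfg.min_species,
        )
        self.art["orthology"] = orth
        self.art["family_table"] = family_table
        orth.write(self.out / "orthology.tsv")
        filled = orth.data.notna().to_numpy().mean()
        self._say("orthology",
                  f"{len(orth.data)} reference introns x {len(orth.species)} "
                  f"species ({filled:.1%} cells filled)")

    def stage_tree(self) -> None:
        self._require("tree")
        fams = {}
        by_gene = {sp: {t.gene: t for t in trs}
                   for sp, trs in self.art["transcripts"].items()}
        fam_tbl = self.art["family_table"]
        for fid, fam in fam_tbl.groupby("family_id"):
            seqs = {}
            for _, row in fam.iterrows():
                tr = by_gene.get(row.species, {}).get(row.gene_id)
                if tr is None:
                    continue
                chrom = self.art["genomes"][row.species][tr.chrom]
                s = "".join(chrom[a:b] for a, b in tr.exons)
                if tr.strand == "-":
                    s = decode(reverse_complement(encode(s)))
                seqs[row.species] = s
            fams[fid] = seqs
        dm = distance_matrix(fams, min_coverage=1.0,
                             max_families=self.cfg.n_distance_families)
        self.art["distance_matrix"] = dm
        dm.write_phylip(self.out / "distances.phy")
        nj = neighbor_joining(dm)
        rooted = root_tree(nj, self.cfg.outgroup)
        # transfer clade labels from the cohort clade table
        clades = dict(zip(self.art["clades"].species, self.art["clades"].clade))
        for node in rooted.postorder_node_iter():
            if node.is_leaf():
                node.clade = clades.get(node.taxon.label, "background")
            else:
                kid = {c.clade for c in node.child_nodes()}
                node.clade = kid.pop() if len(kid) == 1 else "ancestral"
        self.art["tree"] = rooted
        with open(self.out / "nj_tree.nwk", "w") as fh:
            fh.write(tu.to_newick(rooted) + "\n")
        self._say("tree", f"NJ tree rooted on {{{','.join(self.cfg.outgroup)}}}; "
                          f"max K2P distance {dm.matrix.max():.4f}")

    def stage_ancestry(self) -> None:
        self._require("ancestry")
        orth = self.art["orthology"]
        tree = self.art["tree"]
        with np.errstate(invalid="ignore"):
            states = orth.data.apply(
                lambda col: np.round(10 * np.log2(col)), axis=0)
        table = ancestral.sankoff_table(tree, states)
        self.art["ancestral"] = table
        table.write(self.out / "ancestral_states.tsv")
        changes = ancestral.branch_changes(table, tree)
        self.art["branch_changes"] = changes
        _write_tsv(changes, self.out / "branch_changes.tsv")

        # ancestor of everything but the outgroup ("JVA-like" reference node)
        ingroup = [s for s in self.art["species"] if s not in self.cfg.outgroup]
        anc_node = tree.mrca(taxon_labels=ingroup).label
        self.art["ancestor_node"] = anc_node
        anc_states = table.states[anc_node].to_numpy()

        minim = []
        for sp in self.art["species"]:
            extant = orth.data[sp].reindex(table.states.index).to_numpy()
            mp = ancestral.minimised_proportion(
                anc_states, extant, window=self.cfg.minimised_window)
            mp.insert(0, "species", sp)
            minim.append(mp)
        minim = pd.concat(minim, ignore_index=True)
        self.art["minimised"] = minim
        _write_tsv(minim, self.out / "minimised_proportions.tsv")

        lines_rows = []
        for sp in self.art["species"]:
            extant = orth.data[sp].reindex(table.states.index)
            ok = extant.notna()
            mls = ancestral.mode_lines(
                anc_states[ok.to_numpy()],
                np.round(10 * np.log2(extant[ok])).astype(int).to_numpy(),
                taxon=sp)
            for k, ml in enumerate(mls):
                for a, e in zip(ml.ancestral_states, ml.extant_modes):
                    lines_rows.append(dict(taxon=sp, line=k,
                                           ancestral_state=int(a),
                                           extant_mode=float(e)))
        _write_tsv(pd.DataFrame(lines_rows), self.out / "mode_lines.tsv")

        leaf_ch = changes[changes.is_leaf]
        con = leaf_ch[leaf_ch.clade == "contracted"].cum_mean_change
        bak = leaf_ch[leaf_ch.clade == "background"].cum_mean_change
        self._say("ancestry",
                  f"cumulative mean state change: contracted "
                  f"[{con.min():.1f}, {con.max():.1f}], background "
                  f"[{bak.min():.1f}, {bak.max():.1f}] (10*log2 states)")

    def stage_associate(self) -> None:
        self._require("associate")
        cfg = self.cfg
        orth = self.art["orthology"]
        usable = [s for s in self.art.get("qc_included", orth.species)
                  if s in orth.species]
        M = association.pairwise_mi_matrix(orth.data, usable)
        self.art["mi_matrix"] = M
        _write_tsv(M, self.out / "mi_matrix.tsv", index=True)
        pvals = association.pairwise_mi_matrix(
            orth.data, usable, n_perm=cfg.mi_n_perm, seed=cfg.seed)
        _write_tsv(pvals, self.out / "mi_permutation.tsv")
        self.art["mi_pvals"] = pvals

        con = [s for s in self.art["contracted"] if s in usable]
        bak = [s for s in self.art["background"] if s in usable]
        ref_med = np.log2(orth.clade_median(con))
        tgt_med = np.log2(orth.clade_median(bak))
        qrows = []
        for thr in (8.0, 9.0, 10.0, 11.0):
            qp = association.quantile_cross_prediction(ref_med, tgt_med, thr)
            qrows.append(qp.__dict__)
        qdf = pd.DataFrame(qrows)
        self.art["quantile_prediction"] = qdf
        _write_tsv(qdf, self.out / "quantile_prediction.tsv")

        # partitioned correlations against non-contracted partners: the
        # contracted clade's total minimisation destroys the short-set
        # signal, so the long/short contrast is read off the background
        ref = cfg.reference_species
        partners = [s for s in usable if s != ref and s not in con]
        prows = []
        for sp in partners:
            sub = orth.data[[ref, sp]].dropna()
            try:
                pc = association.size_partition_correlations(
                    np.log2(sub[ref]), np.log2(sub[sp]))
                prows.append(dict(species=sp, **pc.__dict__))
            except ValueError as exc:
                log.warning("partition correlation %s: %s", sp, exc)
        pdf = pd.DataFrame(prows)
        self.art["partition_correlations"] = pdf
        _write_tsv(pdf, self.out / "partition_correlations.tsv")

        q10 = qdf[qdf.threshold_log2 == 10.0].iloc[0]
        self._say("associate",
                  f"introns with contracted-clade median >2^10 bp: "
                  f"{q10.frac_above_50:.0%} above background 50th pct, "
                  f"{q10.frac_above_95:.0%} above 95th pct")
        self._say("associate",
                  f"all {len(pvals)} MI permutation p-values <= "
                  f"{pvals.p_value.max():.4g}")

    def stage_deplete(self) -> None:
        self._require("deplete")
        orth = self.art["orthology"]
        term_table = pd.read_csv(self.art["cohort_dir"] / "terms.tsv", sep="\t")
        stat = depletion.gene_length_statistic(orth, self.art["contracted"])
        curves = depletion.nested_depletion_scan(stat, term_table)
        self.art["gene_stat"] = stat
        self.art["depletion_curves"] = curves
        _write_tsv(curves, self.out / "depletion_curves.tsv")
        minp = curves[curves.is_min_p].sort_values("p")
        self._say("deplete",
                  f"strongest depletion: term {minp.iloc[0].term} at "
                  f"{minp.iloc[0].threshold:.0f} bp (p={minp.iloc[0].p:.3g})")

    def stage_conserve(self) -> None:
        self._require("conserve")
        cfg = self.cfg
        orth = self.art["orthology"]
        ref = cfg.reference_species
        partners = self.art["contracted"][:cfg.conserve_max_partners]
        sets = conservation.select_intron_sets(
            orth, self.art["contracted"], n_select=cfg.conserve_n_select,
            seed=cfg.seed, long_min_bp=cfg.long_min_bp)
        by_gene = {sp: {t.gene: t for t in trs}
                   for sp, trs in self.art["transcripts"].items()}

        def seq_of(sp: str, intron_id: str) -> str | None:
            gene, rank = intron_id.split(":")
            tr = by_gene[sp].get(gene)
            if tr is None or int(rank) >= len(tr.exons):
                return None
            return intron_sequence(tr, self.art["genomes"][sp], int(rank))

        counter = conservation.GenomeKmerCounter(
            "".join(self.art["genomes"][ref].values()))
        scoring = LocalScoring()
        pool = orth.data[ref].dropna()
        calls_frames = []
        n_controls = {}
        for label in ("ctl", "med", "long", "short", "short2"):
            ids = [i for i in sets[label] if not pd.isna(orth.data.loc[i, ref])]
            seed_seqs = {i: seq_of(ref, i) for i in ids}
            seed_seqs = {i: s for i, s in seed_seqs.items() if s}
            kept = conservation.repeat_filter(seed_seqs, counter)
            n_controls[label] = (len(seed_seqs), len(kept))
            seed_seqs = {i: seed_seqs[i] for i in kept}
            partner_seqs = {}
            for i in seed_seqs:
                ps = {}
                for sp in partners:
                    if not pd.isna(orth.data.loc[i, sp]):
                        s = seq_of(sp, i)
                        if s:
                            ps[sp] = s
                partner_seqs[i] = ps
            sc = conservation.top_scores(seed_seqs, partner_seqs,
                                         scoring=scoring)
            sc.insert(0, "set_label", label)
            calls_frames.append(sc)
            # control alignments: non-orthologous seed of similar length
            if label in ("ctl", "med", "long"):
                ctl_seed_seqs = {}
                ctl_partner = {}
                for i in seed_seqs:
                    cid = conservation.pick_control_seed(
                        len(seed_seqs[i]), pool, exclude_gene=i.split(":")[0])
                    if cid is None:
                        continue
                    cseq = seq_of(ref, cid)
                    if not cseq:
                        continue
                    key = f"{i}|{cid}"
                    ctl_seed_seqs[key] = cseq
                    ctl_partner[key] = partner_seqs[i]
                csc = conservation.top_scores(ctl_seed_seqs, ctl_partner,
                                              scoring=scoring)
                csc.insert(0, "set_label", f"control_{label}")
                calls_frames.append(csc)
        allsc = pd.concat(calls_frames, ignore_index=True)
        controls = allsc[allsc.set_label.str.startswith("control_")]
        ok = controls.top_score.notna() & (controls.top_score > 0)
        model = conservation.fit_null_model(
            controls.top_score[ok].to_numpy(), controls.space[ok].to_numpy(),
            min_controls=cfg.conserve_min_controls)
        calls = conservation.conservation_calls(allsc, model)
        self.art["conservation_calls"] = calls
        self.art["null_model"] = model
        _write_tsv(calls, self.out / "conservation_calls.tsv")
        props = conservation.flagged_proportions(calls)
        self.art["conservation_props"] = props
        _write_tsv(props.reset_index(), self.out / "conservation_proportions.tsv")
        with open(self.out / "null_model.txt", "w") as fh:
            fh.write(f"slope\t{model.slope:.6f}\n"
                     f"intercept\t{model.intercept:.6f}\n"
                     f"cutoff\t{model.cutoff:.6f}\n"
                     f"n_controls\t{model.residuals.size}\n")
        self._say("conserve",
                  "flagged proportions: " + ", ".join(
                      f"{k}={v:.2f}" for k, v in props.items()))

    # -- driver -----------------------------------------------------------

    def run(self) -> dict:
        t0 = time.time()
        for stage in STAGES:
            if stage not in self.cfg.stages:
                continue
            ts = time.time()
            getattr(self, f"stage_{stage}")()
            self._done.add(stage)
            log.info("stage %s done in %.1fs", stage, time.time() - ts)
        self._write_report()
        self._write_hashes()
        log.info("pipeline done in %.1fs", time.time() - t0)
        return self.art

    def _write_report(self) -> None:
        lines = [f"# intronevo {__version__} pipeline report",
                 f"# config_hash={self.cfg.config_hash()}", ""]
        for stage in STAGES:
            if stage in self.report:
                lines.append(f"## {stage}")
                lines.extend(self.report[stage])
                lines.append("")
        with open(self.out / "report.txt", "w") as fh:
            fh.write("\n".join(lines))
        with open(self.out / "config_echo.yaml", "w") as fh:
            yaml.safe_dump(self.cfg.to_yaml_dict(), fh, sort_keys=True)

    def _write_hashes(self) -> None:
        hashes = {}
        for path in sorted(self.out.rglob("*")):
            if path.is_file() and path.name != "hashes.json":
                hashes[str(path.relative_to(self.out))] = hashlib.sha256(
                    path.read_bytes()).hexdigest()
        with open(self.out / "hashes.json", "w") as fh:
            json.dump(hashes, fh, indent=1, sort_keys=True)


def run_pipeline(config: RunConfig) -> dict:
    return Pipeline(config).run()
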