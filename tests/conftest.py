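"""Shared fixtures: cohorts and pipeline artefacts are expensive, so
they are built once per session and reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from intronevo.orthology import build_orthology
from intronevo.pipeline import RunConfig, run_pipeline
from intronevo.simulate import SimulationConfig, simulate_cohort, simulate_species_tree


@pytest.fixture(scope="session")
def default_cohort():
    """The default study cohort: 12 species, 200 single-copy families."""
    cfg = SimulationConfig(seed=1)
    return simulate_cohort(cfg, simulate_species_tree(cfg))


@pytest.fixture(scope="session")
def small_cohort():
    """A light cohort for I/O round-trips and smoke tests."""
    cfg = SimulationConfig(seed=3, n_species=6, contracted_clade=2, n_families=30)
    return simulate_cohort(cfg, simulate_species_tree(cfg))


@pytest.fixture(scope="session")
def default_orthology(default_cohort):
    return build_orthology(
        default_cohort.transcripts, default_cohort.genomes,
        default_cohort.family_table, reference="mam01",
    )


@pytest.fixture(scope="session")
def truth_matrix(default_cohort):
    """Truth orthology as an intron x species length matrix keyed like
    the inferred table."""
    t = default_cohort.truth.orthology.pivot_table(
        index=["gene", "rank"], columns="species", values="length_bp")
    t.index = [f"{g}:{r}" for g, r in t.index]
    return t


@pytest.fixture(scope="session")
def pipeline_art(tmp_path_factory):
    """One full default pipeline run (synthetic cohort, all stages)."""
    out = tmp_path_factory.mktemp("pipeline")
    cfg = RunConfig(outdir=str(out), seed=1)
    return run_pipeline(cfg)


@pytest.fixture()
def toy_gff3(tmp_path):
    """Write a GFF3 text to a temp file and return the path."""

    def _write(text: str):
        p = tmp_path / "toy.gff3"
        p.write_text(text)
        return p

    return _write
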