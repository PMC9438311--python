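"""Annotation parsing, intron extraction and genome I/O."""

from __future__ import annotations

import gzip

import numpy as np
import pytest

from intronevo.annotation import (extract_introns, genome_size,
                                  read_annotation, write_gff3, read_genome)
from intronevo.simulate import SimulationConfig, simulate_cohort, simulate_species_tree

TWO_EXON_GENE = """##gff-version 3
chr1\tsrc\tgene\t1\t300\t.\t{strand}\t.\tID=geneA
chr1\tsrc\tmRNA\t1\t300\t.\t{strand}\t.\tID=trA;Parent=geneA
chr1\tsrc\texon\t1\t100\t.\t{strand}\t.\tID=trA.e1;Parent=trA
chr1\tsrc\texon\t201\t300\t.\t{strand}\t.\tID=trA.e2;Parent=trA
"""

THREE_EXON_MINUS = """##gff-version 3
chr1\tsrc\tgene\t1\t500\t.\t-\t.\tID=geneB
chr1\tsrc\tmRNA\t1\t500\t.\t-\t.\tID=trB;Parent=geneB
chr1\tsrc\texon\t1\t100\t.\t-\t.\tID=trB.e1;Parent=trB
chr1\tsrc\texon\t201\t300\t.\t-\t.\tID=trB.e2;Parent=trB
chr1\tsrc\texon\t401\t500\t.\t-\t.\tID=trB.e3;Parent=trB
"""

TWO_TRANSCRIPTS = """##gff-version 3
chr1\tsrc\tgene\t1\t300\t.\t+\t.\tID=geneC
chr1\tsrc\tmRNA\t1\t300\t.\t+\t.\tID=trС_long;Parent=geneC
chr1\tsrc\texon\t1\t150\t.\t+\t.\tID=e1;Parent=trС_long
chr1\tsrc\texon\t201\t300\t.\t+\t.\tID=e2;Parent=trС_long
chr1\tsrc\tmRNA\t1\t300\t.\t+\t.\tID=trC_flagged;Parent=geneC;canonical=1
chr1\tsrc\texon\t1\t100\t.\t+\t.\tID=e3;Parent=trC_flagged
chr1\tsrc\texon\t251\t300\t.\t+\t.\tID=e4;Parent=trC_flagged
"""


def test_two_exon_gene_parses_to_one_transcript(toy_gff3):
    models = read_annotation(toy_gff3(TWO_EXON_GENE.format(strand="+")), species="sp")
    assert len(models) == 1
    assert models[0].exons == [(0, 100), (200, 300)]
    assert models[0].strand == "+"


def test_minus_strand_same_intervals_reversed_ranks(toy_gff3):
    plus = read_annotation(toy_gff3(TWO_EXON_GENE.format(strand="+")), species="sp")
    minus = read_annotation(toy_gff3(TWO_EXON_GENE.format(strand="-")), species="sp")
    assert plus[0].exons == minus[0].exons
    cat = extract_introns(minus)
    # single intron: bases 101..200 inclusive -> length 100, rank 1
    assert cat.length.tolist() == [100]
    assert cat["rank"].tolist() == [1]
    assert (cat.start.iloc[0], cat.end.iloc[0]) == (100, 200)


def test_minus_strand_rank_one_is_genomically_last_gap(toy_gff3):
    models = read_annotation(toy_gff3(THREE_EXON_MINUS), species="sp")
    cat = extract_introns(models).sort_values("start")
    # genomic gaps: [100,200) and [300,400); on '-' the last gap is rank 1
    assert cat["rank"].tolist() == [2, 1]


def test_canonical_policy_prefers_flag_else_longest(toy_gff3):
    path = toy_gff3(TWO_TRANSCRIPTS)
    flagged = read_annotation(path, species="sp", canonical_policy="flag-else-longest")
    assert flagged[0].transcript == "trC_flagged"
    longest = read_annotation(path, species="sp", canonical_policy="longest")
    assert longest[0].transcript == "trС_long"  # 250 exonic bases vs 150


def test_single_exon_transcript_yields_no_introns(toy_gff3):
    text = """##gff-version 3
chr1\tsrc\tgene\t1\t100\t.\t+\t.\tID=g
chr1\tsrc\tmRNA\t1\t100\t.\t+\t.\tID=t;Parent=g
chr1\tsrc\texon\t1\t100\t.\t+\t.\tID=t.e1;Parent=t
"""
    cat = extract_introns(read_annotation(toy_gff3(text), species="sp"))
    assert len(cat) == 0


def test_unparseable_line_raises_with_line_number(toy_gff3):
    text = "##gff-version 3\nchr1\tonly\tthree\n"
    with pytest.raises(ValueError, match="line 2"):
        read_annotation(toy_gff3(text), species="sp")


def test_overlapping_exons_reject_transcript(toy_gff3, caplog):
    import logging
    from intronevo.annotation import TranscriptModel

    tr = TranscriptModel(species="sp", gene="g", transcript="t", chrom="chr1",
                         strand="+", exons=[(0, 100), (50, 150)])
    with caplog.at_level(logging.WARNING):
        cat = extract_introns([tr])
    assert len(cat) == 0
    assert "overlapping" in caplog.text


def test_abutting_exons_drop_zero_length_intron(caplog):
    import logging
    from intronevo.annotation import TranscriptModel

    tr = TranscriptModel(species="sp", gene="g", transcript="t", chrom="chr1",
                         strand="+", exons=[(0, 100), (100, 150), (200, 250)])
    with caplog.at_level(logging.WARNING):
        cat = extract_introns([tr])
    assert cat.length.tolist() == [50]
    assert "zero-length" in caplog.text


def test_short_introns_flagged_not_dropped():
    from intronevo.annotation import TranscriptModel

    tr = TranscriptModel(species="sp", gene="g", transcript="t", chrom="chr1",
                         strand="+", exons=[(0, 10), (20, 30), (130, 140)])
    cat = extract_introns([tr])
    assert cat.flag_short.tolist() == [True, False]


def test_genome_size_sums_bases_and_counts_ns(tmp_path):
    p = tmp_path / "g.fa"
    p.write_text(">a\n" + "A" * 1000 + "\n>b\n" + "C" * 2000 + "N" * 345 + "\n")
    assert genome_size(p) == 3345
    gz = tmp_path / "g.fa.gz"
    with gzip.open(gz, "wt") as fh:
        fh.write(p.read_text())
    assert genome_size(gz) == 3345


def test_genome_size_empty_file_errors(tmp_path):
    p = tmp_path / "empty.fa"
    p.write_text("")
    with pytest.raises(ValueError):
        genome_size(p)


def test_exon_plus_intron_lengths_equal_genomic_span(small_cohort):
    for sp, models in small_cohort.transcripts.items():
        cat = extract_introns(models)
        intron_sum = cat.groupby("transcript").length.sum()
        for tr in models:
            total = tr.exonic_span + int(intron_sum.get(tr.transcript, 0))
            assert total == tr.genomic_span


def test_round_trip_catalogue_matches_truth_exactly(small_cohort, tmp_path):
    """Writing GFF3 and re-reading reproduces every true intron length."""
    small_cohort.write(tmp_path / "cohort")
    truth = small_cohort.truth.orthology
    for sp in small_cohort.species:
        models = read_annotation(tmp_path / "cohort" / f"{sp}.gff3", species=sp)
        cat = extract_introns(models).set_index(["gene", "rank"]).length
        t = truth[truth.species == sp].set_index(["gene", "rank"]).length_bp
        assert len(cat) == len(t)
        assert (cat.sort_index() == t.sort_index()).all()
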