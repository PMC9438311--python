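"""Annotation and genome I/O: transcript models and the intron catalogue.

Every downstream stage works from the per-species intron catalogue
produced here: one canonical transcript per gene, introns inferred from
the gaps between consecutive exons, ranks assigned in transcription
(5'->3') order.

Coordinates are 0-based half-open internally; GFF3/GTF files are read
and written 1-based inclusive, with conversion confined to this module.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO

log = logging.getLogger(__name__)

#: introns shorter than this are kept but flagged; a high fraction of
#: them marks a poorly assembled/annotated genome (see distributions.qc_species_filter)
SHORT_INTRON_FLAG_BP = 32

CATALOGUE_COLUMNS = [
    "species", "gene", "transcript", "rank", "length",
    "chrom", "start", "end", "strand", "log2_length", "flag_short",
]


@dataclass
class TranscriptModel:
    """One transcript: ordered exon intervals on a chromosome.

    ``exons`` are 0-based half-open intervals sorted in genomic order and
    must not overlap.
    """

    species: str
    gene: str
    transcript: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    canonical: bool = False

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript} has no exons")
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        for (a, b) in self.exons:
            if b <= a:
                raise ValueError(f"empty exon {a}-{b} in {self.transcript}")

    @property
    def exonic_span(self) -> int:
        return sum(b - a for a, b in self.exons)

    @property
    def genomic_span(self) -> int:
        return self.exons[-1][1] - self.exons[0][0]

    def has_overlapping_exons(self) -> bool:
        return any(self.exons[i][1] > self.exons[i + 1][0]
                   for i in range(len(self.exons) - 1))


@dataclass(frozen=True)
class IntronRecord:
    species: str
    gene: str
    transcript: str
    rank: int          # 1 = first intron in transcription order
    length: int
    chrom: str
    start: int         # 0-based half-open genomic interval
    end: int
    strand: str

    @property
    def log2_length(self) -> float:
        return float(np.log2(self.length))


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _prescan(path) -> None:
    """Fail fast on malformed annotation lines, reporting the line number."""
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )


def read_annotation(
    path,
    species: str | None = None,
    canonical_policy: str = "flag-else-longest",
) -> list[TranscriptModel]:
    """Read a GFF3/GTF file and return one canonical transcript per gene.

    ``canonical_policy``:

    * ``"flag-else-longest"`` (default): prefer a transcript carrying a
      truthy ``canonical`` attribute; otherwise fall back to the longest
      exonic span (ties broken by transcript id).
    * ``"longest"``: longest exonic span regardless of flags.

    Genes without exon features are skipped with a logged warning.
    """
    if canonical_policy not in ("flag-else-longest", "longest"):
        raise ValueError(f"unknown canonical_policy {canonical_policy!r}")
    _prescan(path)
    species = species or Path(path).stem.split(".")[0]
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    by_gene: dict[str, list[TranscriptModel]] = {}
    flagged: dict[str, set[str]] = {}
    transcript_types = ("mRNA", "transcript")
    seen_transcripts = set()
    for ttype in transcript_types:
        for tr in db.features_of_type(ttype):
            if tr.id in seen_transcripts:
                continue
            seen_transcripts.add(tr.id)
            exons = [(e.start - 1, e.end) for e in db.children(tr, featuretype="exon")]
            if not exons:
                continue
            gene_id = tr.attributes.get("Parent", [tr.attributes.get("gene_id", [tr.id])[0]])[0]
            model = TranscriptModel(
                species=species, gene=gene_id, transcript=tr.id,
                chrom=tr.seqid, strand=tr.strand, exons=exons,
                canonical=tr.attributes.get("canonical", ["0"])[0] in ("1", "true", "True"),
            )
            by_gene.setdefault(gene_id, []).append(model)
            if model.canonical:
                flagged.setdefault(gene_id, set()).add(tr.id)
    # genes annotated but without any exon-bearing transcript
    for gene in db.features_of_type("gene"):
        if gene.id not in by_gene:
            log.warning("gene %s has no exon features; skipped", gene.id)

    chosen: list[TranscriptModel] = []
    for gene_id in sorted(by_gene):
        models = by_gene[gene_id]
        if canonical_policy == "flag-else-longest" and gene_id in flagged:
            models = [m for m in models if m.canonical]
        # longest exonic span, tie-broken by transcript id
        models.sort(key=lambda m: (-m.exonic_span, m.transcript))
        chosen.append(models[0])
    return chosen


def extract_introns(transcripts: Iterable[TranscriptModel]) -> pd.DataFrame:
    """Build the intron catalogue from transcript models.

    For consecutive exons ``[a,b)`` and ``[c,d)`` an intron of length
    ``c - b`` is emitted.  Ranks run 5'->3' in transcription order, so
    on the '-' strand the genomically last gap has rank 1.  Transcripts
    with overlapping exons are rejected with a warning; zero-length
    introns (abutting exons) are dropped with a warning.
    """
    records: list[dict] = []
    for tr in transcripts:
        if tr.has_overlapping_exons():
            log.warning("transcript %s has overlapping exons; rejected", tr.transcript)
            continue
        n_gaps = len(tr.exons) - 1
        for gidx in range(n_gaps):
            b = tr.exons[gidx][1]
            c = tr.exons[gidx + 1][0]
            length = c - b
            if length == 0:
                log.warning(
                    "zero-length intron (abutting exons) in %s; dropped", tr.transcript
                )
                continue
            rank = gidx + 1 if tr.strand == "+" else n_gaps - gidx
            records.append(dict(
                species=tr.species, gene=tr.gene, transcript=tr.transcript,
                rank=rank, length=length, chrom=tr.chrom, start=b, end=c,
                strand=tr.strand, log2_length=float(np.log2(length)),
                flag_short=length < SHORT_INTRON_FLAG_BP,
            ))
    if not records:
        return pd.DataFrame(columns=CATALOGUE_COLUMNS)
    return pd.DataFrame.from_records(records)[CATALOGUE_COLUMNS]


def genome_size(fasta_path) -> int:
    """Total bases in a FASTA file (ambiguity characters included);
    transparently reads gzip-compressed input."""
    total = 0
    n_records = 0
    with _open_text(fasta_path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            total += len(rec.seq)
            n_records += 1
    if n_records == 0:
        raise ValueError(f"{fasta_path}: no FASTA records")
    return total


def read_genome(fasta_path) -> dict[str, str]:
    """Read a (possibly gzipped) FASTA into a dict of upper-case strings."""
    with _open_text(fasta_path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def intron_interval(tr: TranscriptModel, rank: int) -> tuple[int, int]:
    """Genomic 0-based half-open interval of the intron with the given
    transcription-order rank."""
    n_gaps = len(tr.exons) - 1
    if not 1 <= rank <= n_gaps:
        raise ValueError(f"rank {rank} out of range for {tr.transcript}")
    gidx = rank - 1 if tr.strand == "+" else n_gaps - rank
    return tr.exons[gidx][1], tr.exons[gidx + 1][0]


def intron_sequence(tr: TranscriptModel, genome: dict[str, str], rank: int) -> str:
    """Intron sequence in transcript orientation (reverse-complemented
    on the '-' strand)."""
    from ._align import encode, reverse_complement, decode

    a, b = intron_interval(tr, rank)
    seq = genome[tr.chrom][a:b]
    if tr.strand == "-":
        seq = decode(reverse_complement(encode(seq)))
    return seq


def write_gff3(transcripts: Iterable[TranscriptModel], path) -> None:
    """Write transcript models as GFF3 (gene/mRNA/exon), 1-based inclusive.

    Canonical transcripts carry a ``canonical=1`` attribute.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for tr in transcripts:
            g0 = tr.exons[0][0]
            g1 = tr.exons[-1][1]
            fh.write(
                f"{tr.chrom}\tintronevo\tgene\t{g0 + 1}\t{g1}\t.\t{tr.strand}\t.\t"
                f"ID={tr.gene}\n"
            )
            canon = ";canonical=1" if tr.canonical else ""
            fh.write(
                f"{tr.chrom}\tintronevo\tmRNA\t{g0 + 1}\t{g1}\t.\t{tr.strand}\t.\t"
                f"ID={tr.transcript};Parent={tr.gene}{canon}\n"
            )
            for k, (a, b) in enumerate(tr.exons, start=1):
                fh.write(
                    f"{tr.chrom}\tintronevo\texon\t{a + 1}\t{b}\t.\t{tr.strand}\t.\t"
                    f"ID={tr.transcript}.e{k};Parent={tr.transcript}\n"
                )


def write_fasta(genome: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in genome:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_catalogue(catalogue: pd.DataFrame, path) -> None:
    catalogue.to_csv(path, sep="\t", index=False)


def read_catalogue(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
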