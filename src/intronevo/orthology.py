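"""Reference-anchored intron orthology via sticky transcript alignment.

Intron positions are transferred between orthologous transcripts by
global alignment of spliced transcripts into which one "sticky"
meta-symbol has been inserted at every exon-exon junction.  Meta-symbols
may only align to meta-symbols and carry a large bonus, so intron
positions attract each other across species; introns whose meta-symbols
end up in the same alignment column are called orthologous.

The orthology is anchored on one reference species: rows are reference
introns (gene, rank), columns are species, cells are the orthologous
intron's length (or missing).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._align import META, StickyScoring, encode, nw_align, reverse_complement
from .annotation import TranscriptModel, intron_interval

log = logging.getLogger(__name__)


@dataclass
class StickyTranscript:
    """Spliced exonic sequence with intron meta-symbols at junctions.

    ``codes`` is the int8-encoded symbol sequence; ``meta_ranks[k]`` is
    the intron rank of the k-th meta-symbol in sequence order (always
    1, 2, ... because the sequence is in transcription orientation).
    Removing the meta-symbols recovers the spliced transcript exactly.
    """

    transcript: str
    codes: np.ndarray
    meta_ranks: np.ndarray

    @property
    def n_introns(self) -> int:
        return int(self.meta_ranks.size)


def make_sticky(tr: TranscriptModel, genome: dict[str, str]) -> StickyTranscript:
    """Build the sticky symbol sequence for a transcript.

    Exons are spliced 5'->3' in transcription order ('-' strand
    transcripts are reverse-complemented), with one meta-symbol at each
    junction carrying the intron rank.
    """
    chrom = genome[tr.chrom]
    exon_codes = []
    for (a, b) in tr.exons:
        if a < 0 or b > len(chrom):
            raise ValueError(
                f"exon {a}-{b} of {tr.transcript} outside contig {tr.chrom}"
            )
        exon_codes.append(encode(chrom[a:b]))
    if tr.strand == "-":
        exon_codes = [reverse_complement(c) for c in exon_codes[::-1]]
    parts = []
    meta = np.array([META], dtype=np.int8)
    for k, ex in enumerate(exon_codes):
        if k > 0:
            parts.append(meta)
        parts.append(ex)
    codes = np.concatenate(parts) if parts else np.empty(0, dtype=np.int8)
    return StickyTranscript(
        transcript=tr.transcript,
        codes=codes,
        meta_ranks=np.arange(1, len(exon_codes), dtype=np.int64),
    )


def sticky_align(
    a: StickyTranscript,
    b: StickyTranscript,
    scoring: StickyScoring = StickyScoring(),
) -> tuple[int, list[tuple[int, int]]]:
    """Globally align two sticky transcripts.

    Returns the optimal score and the ``(rank_a, rank_b)`` pairs whose
    meta-symbols share an alignment column.  Arguments are ordered
    canonically before the DP so the result is symmetric in its inputs.
    """
    if a.codes.size == 0 or b.codes.size == 0:
        raise ValueError("cannot align empty sticky transcripts")
    swap = a.codes.tobytes() > b.codes.tobytes()
    x, y = (b, a) if swap else (a, b)
    score, pairs = nw_align(x.codes, y.codes, scoring)
    xm = {pos: int(r) for pos, r in zip(np.flatnonzero(x.codes == META), x.meta_ranks)}
    ym = {pos: int(r) for pos, r in zip(np.flatnonzero(y.codes == META), y.meta_ranks)}
    matched = [
        (xm[i], ym[j]) for (i, j) in pairs
        if x.codes[i] == META and y.codes[j] == META
    ]
    if swap:
        matched = [(rb, ra) for (ra, rb) in matched]
    return score, sorted(matched)


@dataclass
class OrthologyTable:
    """Reference intron x species matrix of orthologous intron lengths."""

    reference: str
    data: pd.DataFrame  # index "gene:rank", columns species, values length or NaN

    @property
    def species(self) -> list[str]:
        return list(self.data.columns)

    @property
    def genes(self) -> pd.Series:
        return self.data.index.to_series().str.split(":").str[0]

    @property
    def ranks(self) -> pd.Series:
        return self.data.index.to_series().str.split(":").str[1].astype(int)

    def clade_min(self, species: list[str]) -> pd.Series:
        return self.data[species].min(axis=1)

    def clade_median(self, species: list[str]) -> pd.Series:
        return self.data[species].median(axis=1)

    def write(self, path) -> None:
        out = self.data.copy()
        out.index.name = "intron"
        out.to_csv(path, sep="\t", na_rep="NA", float_format="%.0f")

    @classmethod
    def read(cls, path, reference: str) -> "OrthologyTable":
        df = pd.read_csv(path, sep="\t", index_col="intron", na_values="NA")
        return cls(reference=reference, data=df)


def _intron_lengths(tr: TranscriptModel) -> dict[int, int]:
    out = {}
    for rank in range(1, len(tr.exons)):
        a, b = intron_interval(tr, rank)
        out[rank] = b - a
    return out


def build_orthology(
    transcripts: dict[str, list[TranscriptModel]],
    genomes: dict[str, dict[str, str]],
    family_table: pd.DataFrame,
    reference: str,
    min_species: float = 0.8,
    scoring: StickyScoring = StickyScoring(),
) -> OrthologyTable:
    """Assemble the reference-anchored intron orthology.

    Families are kept when they are single-copy in at least
    ``min_species`` (a fraction) of the species; every retained
    non-reference transcript is sticky-aligned to the reference
    orthologue and matched meta-symbols fill the table.  Meta-symbol
    pairing is injective by construction (an alignment column holds at
    most one symbol of each sequence).
    """
    log.info("sticky scoring: %s", scoring)
    species = sorted(transcripts)
    if reference not in species:
        raise ValueError(f"reference species {reference!r} not in cohort")
    by_gene = {
        sp: {tr.gene: tr for tr in models} for sp, models in transcripts.items()
    }

    counts = family_table.groupby(["family_id", "species"]).size()
    rows: dict[str, dict[str, float]] = {}
    for family_id, fam in family_table.groupby("family_id"):
        single = {
            sp: g.gene_id.iloc[0]
            for sp, g in fam.groupby("species")
            if len(g) == 1 and g.gene_id.iloc[0] in by_gene.get(sp, {})
        }
        if len(single) < min_species * len(species):
            continue
        if reference not in single:
            log.warning("family %s lacks a reference gene; skipped", family_id)
            continue
        ref_tr = by_gene[reference][single[reference]]
        ref_sticky = make_sticky(ref_tr, genomes[reference])
        ref_lengths = _intron_lengths(ref_tr)
        for rank in range(1, len(ref_tr.exons)):
            rows[f"{ref_tr.gene}:{rank}"] = {reference: float(ref_lengths[rank])}
        for sp in species:
            if sp == reference or sp not in single:
                continue
            tr = by_gene[sp][single[sp]]
            sticky = make_sticky(tr, genomes[sp])
            if sticky.n_introns == 0 and ref_sticky.n_introns == 0:
                continue
            _, matched = sticky_align(ref_sticky, sticky, scoring)
            sp_lengths = _intron_lengths(tr)
            for (ra, rb) in matched:
                rows[f"{ref_tr.gene}:{ra}"][sp] = float(sp_lengths[rb])
    data = pd.DataFrame.from_dict(rows, orient="index")
    data = data.reindex(columns=species).sort_index()
    data.index.name = "intron"
    return OrthologyTable(reference=reference, data=data)
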