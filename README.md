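# intronevo

Analysis pipeline for studying the evolution of spliceosomal intron
lengths across a vertebrate-like species cohort.  Teleost fishes have
compact, variable genomes in which log-transformed intron lengths are
bimodal: a sharp peak of minimal introns near 76 bp is separated from a
broad long-intron population by an antimode (trough) near 256 bp.  This
package implements, as tested reusable components, the statistics used
to characterise that pattern and to ask whether introns that stayed
long form a non-random, functionally constrained class:

* **Intron cataloguing** (`annotation`): GFF3/GTF parsing, one canonical
  transcript per gene, intron lengths and ranks from exon coordinates.
* **Size distributions** (`distributions`): fixed-bandwidth Gaussian
  kernel densities of log2 length, antimode detection, short-intron
  fractions, annotation-quality filtering (species with >2.5% of
  introns shorter than 32 bp are excluded).
* **Intron orthology** (`orthology`): spliced transcripts carry one
  "sticky" meta-symbol per exon-exon junction; global Needleman-Wunsch
  alignment over the extended alphabet (meta pairs meta with a large
  bonus, meta-base pairing forbidden) transfers intron positions
  between orthologues, building a reference-anchored intron x species
  length matrix.
* **Phylogenetics** (`phylo`): Kimura two-parameter distances
  d = -(1/2)ln(1-2P-Q) - (1/4)ln(1-2Q) from pooled pairwise exon
  alignments, Saitou-Nei neighbour joining with deterministic
  tie-breaking, outgroup rooting.
* **Ancestral sizes** (`ancestral`): Sankoff maximum parsimony over
  states round(10*log2 length) with cost |Δstate|, cumulative
  branch-change tracing, mode lines of ancestral-vs-extant joint
  distributions, minimised-intron (76-100 bp) proportions.
* **Size association** (`association`): plug-in mutual information of
  log2-binned sizes with margin-permutation significance, quantile
  cross-prediction between clades, size-partitioned correlations.
* **Term depletion** (`depletion`): genes ordered by their longest
  minimal-clade intron length; per functional term, lower-tail
  hypergeometric depletion probabilities over all nested gene sets.
* **Sequence conservation** (`conservation`): recursive masked
  Smith-Waterman alignment of orthologous introns, a k-mer repeat
  filter, and a search-space null model (linear fit of log top score
  on log search space from non-orthologous control alignments; a hit
  is conserved when its residual exceeds the 95th control percentile).
* **Synthetic cohorts** (`simulate`): a generator with known ground
  truth — species tree with a contracted clade, two intron classes
  (free introns drift and minimise; retained introns resist), K2P exon
  evolution, planted conserved elements and planted term associations —
  so every stage can be validated by parameter recovery.

## Worked example

```python
from intronevo.pipeline import RunConfig, run_pipeline

art = run_pipeline(RunConfig(outdir="demo_out", seed=1))
print(open("demo_out/report.txt").read())
```

The report for the default cohort (12 species, 200 single-copy
families, ~1,460 introns) includes:

```
## distributions
contracted antimodes (bp): 246, 252, 246, 257, 246
fraction<256bp contracted 0.819 vs background 0.001

## orthology
1461 reference introns x 12 species (100.0% cells filled)

## ancestry
cumulative mean state change: contracted [-25.8, -25.6], background [1.9, 2.0] (10*log2 states)

## conserve
flagged proportions: control_ctl=0.03, control_long=0.07, control_med=0.04,
ctl=0.00, long=1.00, med=1.00, short=0.00, short2=0.00
```

Reading this: every contracted-clade ("teleost-like") species shows the
expected size antimode close to 256 bp and ~82% of its introns below
it, while background species have essentially none; the sticky-
alignment orthology recovered all introns; Sankoff reconstruction
infers a ~2.6 log2-unit loss of mean intron size along the contracted
clade and none elsewhere; and introns long across the contracted clade
carry sequence flagged as conserved in 100% of cases (their planted
elements) versus 0% for the control set (long in the reference but
short across the clade), with non-orthologous control alignments
flagged at roughly the nominal 5%.

A command-line interface mirrors the stages
(`intronevo simulate|catalog|distributions|orthology|tree|ancestry|
associate|deplete|conserve|run-all`); `run-all` takes a single YAML
config and writes all stage artefacts, a report and content hashes.

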