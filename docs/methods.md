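# Methods

This note documents the models and procedures implemented in
`intronevo`, the parameters that matter, what the synthetic-data
generator does and does not emulate, and the numerical choices made
where the design was genuinely open.

## The analysis

The unit of analysis is the spliceosomal intron of a canonical
transcript, identified by its gene and its rank in transcription
(5'→3') order, and characterised by its length on the log2 scale.
Log transformation is used throughout because the probability of an
intron changing in size is plausibly proportional to its length, which
makes log-size approximately normally evolving and makes size classes
visible as modes of the log-density.

**Catalogue.** Annotations (GFF3/GTF) are reduced to one canonical
transcript per gene (policy `flag-else-longest`: a truthy `canonical`
attribute wins, otherwise the longest exonic span, ties broken by
transcript id). Introns are the gaps between consecutive exons;
zero-length gaps are dropped, transcripts with overlapping exons
rejected. Introns shorter than 32 bp are kept but flagged: a species
whose flagged fraction exceeds 2.5% (strict) is excluded from
cross-species statistics, since such catalogues usually reflect
fragmented assemblies.

**Densities and antimodes.** Size densities are Gaussian-kernel
estimates on the log2 scale, fixed bandwidth 0.25 log2 units, grid
2^4..2^20 with 512 points, renormalised to integrate to one on the
grid. Bandwidth 0.25 resolves the 76-bp minimal-intron peak from the
~256-bp antimode without fragmenting the broad long-intron mode. The
antimode is the density minimum strictly between the two highest local
maxima inside a caller-supplied window; a window with fewer than two
peaks reports none. `fraction_below` uses strict `<` at the threshold.

**Intron orthology.** Orthologous intron positions are transferred by
global alignment of "sticky" transcripts: the spliced exonic sequence
with one meta-symbol inserted at each exon-exon junction. Scoring:
base match +1, mismatch −1, linear gap −2 per symbol, meta↔meta +10,
meta↔base forbidden (−2^24, never optimal because two gaps cost −4).
The large meta bonus makes intron positions attract across species
while the forbidden pairing keeps them out of exonic columns; which
meta-symbols share a column defines orthology, independent of their
ranks. Scores are integers, so DP ties exist; the traceback prefers
diagonal, then up, then left, and symmetry of the reported pairs is
guaranteed by ordering the two inputs canonically (lexicographically
by encoded sequence) before the DP. Families are restricted to those
single-copy in at least 80% of species (configurable), anchored on one
reference species.

**Distances and tree.** Kimura two-parameter distances use transition
proportion P and transversion proportion Q over aligned columns where
both symbols are plain bases: d = −½ln(1−2P−Q) − ¼ln(1−2Q); pairs
where either logarithm's argument is non-positive raise a saturation
error. Counts are pooled across families before applying the formula
(robust for short alignments; per-family averaging is a config
option). Pairwise exon alignments reuse the same Needleman-Wunsch core
without meta-symbols. Neighbour joining is the standard Saitou-Nei
agglomeration; when several pairs minimise the Q criterion the
lexicographically smallest label pair is joined, making output
deterministic; negative branch lengths are clamped to zero with a
warning. The tree is rooted by bisecting the branch that separates a
declared outgroup; node ids are assigned in post-order.

**Ancestral sizes.** Lengths are discretised to integral 10·log2
states (round-half-even; 76 bp → 62, 256 bp → 80, 1024 bp → 100), and
ancestral states inferred per intron by Sankoff parsimony with cost
|Δstate| on a lattice spanning the observed states ±10 (linear cost
never favours states outside the observed hull; the margin is a safety
band, asserted in tests). Missing species contribute all-zero cost
vectors. Backtrace ties go to the state closest to the parent's chosen
state, then the smallest; at the root the smallest minimal-cost state
is chosen. This root rule biases the root low by a fraction of the
per-branch noise scale — visible as a small positive cumulative change
at all leaves in no-drift simulations — which is reported, not
corrected. `branch_changes` accumulates, per node, the distance from
the root and the mean over introns of (state − root state).

**Mode lines.** The joint distribution of ancestral vs extant states
(introns > 75 bp on both axes) is histogrammed on the integral state
grid, standardised column-wise (ancestral columns to mean 0, sd 1),
blurred with a Gaussian of sd 6 states truncated at 4 sd (nearest-edge
padding; constant padding drags boundary peaks toward the corners),
and per-column peaks are joined into lines (join tolerance 9 states,
bridging gaps up to 3 columns), then smoothed with a normal kernel of
sd 2 columns. Peak positions within ~2 blur sds of the grid boundary
are edge-biased; tests therefore evaluate line accuracy on interior
columns.

**Size association.** Mutual information uses integral log2(length)
bins (≈14 bins over the observed range, matching the analysis scale;
the plug-in estimator, reported in bits). Significance is by
permutation of one margin with the add-one estimator
p = (1+#{MI_perm ≥ MI_obs})/(n_perm+1); 10,000 permutations by
default. Quantile cross-prediction: among introns whose
reference-clade median exceeds a threshold, the fraction whose
target-clade median exceeds the target clade's own 50th/95th
percentile, with log2 observed/expected against 0.5/0.05.
Size-partitioned correlations: pairs at least 76 bp in both species
and within the reference's 99th percentile are split at the midpoint
of the reference log-size range; Pearson correlations per set, ratio
r_long/r_short, flagged unreliable when |r_short| < 0.05.

**Term depletion.** Each gene is scored by the maximum over its
introns of the minimum length across a clade's species (missing
species ignored). For each term with ≥5 annotated genes and each
threshold (all distinct gene values, downsampled to ≤512), the nested
set k = #{genes ≤ T} is tested for depletion of the term's m members
with the lower-tail hypergeometric P(X ≤ q | N, m, k). No
multiple-testing correction is applied; the number of terms tested is
emitted. Term annotation is a flat gene→term table; ontology-graph
propagation is out of scope.

**Sequence conservation.** Local alignments use affine-gap
Smith-Waterman (match +1, mismatch −1, gap open −4, extend −1,
minimum reported score 20, so a 20-bp exact match is the smallest
reportable hit). The recursive scan reports the optimal alignment,
masks its seed interval with a sentinel symbol that cannot align, and
repeats; seed intervals are therefore disjoint while partner intervals
may overlap. Pairs with search space l1·l2 > 1e8 are skipped. Intron
sets are chosen by clade length profile (long: clade-min ≥ 1024 bp;
med/short: lowest clade-variance 2000 in (256,1024)/(90,256); a second
short set and the control sampled randomly; control: clade-median
< 256 bp but reference length > 1024 bp). Seed sequences matching ≠1-2
genome loci are removed: the locus counter is a 31-mer index voting on
genome diagonals, counting loci whose matching k-mer windows cover
≥50% of the query; k-mers occurring >50 times are ignored so simple
repeats report zero loci. The null model fits log(top score) on
log(seed length × summed partner lengths) by least squares over ≥50
control alignments in which a non-orthologous reference intron of
similar length (nearest length within ±25%, different gene) replaces
the seed; conservation is called when a residual exceeds the 95th
percentile of control residuals. Natural logs are used; the base
cancels in percentile flagging. Sets are repeat-filtered before
maximising over partners, and both counts are logged.

## The synthetic cohort

The generator produces inputs with known truth; its defaults define
the study conditions used by the test suite and the acceptance script.

* **Tree**: ultrametric, depth 1.5; the root splits into an outgroup
  tip and the ingroup at 1.2, which splits into a contracted
  ("teleost-like", 5 species) and a background ("mammal-like") clade
  with random internal topologies. Branch lengths × `subst_rate`
  (0.05/unit) give exon divergences up to ~0.15 substitutions/site —
  comfortably below K2P saturation while leaving a clear phylogenetic
  signal.
* **Families**: 200 single-copy genes, 1 + negative-binomial introns
  per gene (mean 7), exon lengths uniform 80-200 bp, strand random,
  one chromosome per species with genes separated by 500-bp N spacers.
* **Size classes**: class is assigned at the gene level (a retained
  gene's introns are all retained) with retained fraction 0.25, so the
  fraction of retained introns matches. Free introns start at
  log2 size ~ N(9.8, 0.5); retained introns at N(9.5, 1.7) with a
  gene-level factor (between-gene sd √(1.7²−0.4²), within-gene 0.4) so
  genes differ coherently in retained intron size — this makes the
  per-gene length statistic's lower tail dense just above the class
  boundary, as in real data where the long class begins at the
  antimode. First introns get +0.5 log2 (first introns are longer in
  real annotations).
* **Evolution**: log2 sizes evolve as Brownian motion (sd 0.25 per
  √branch length, Euler steps of 0.05 with reflection at the class
  floor each step — endpoint folding would turn strong drift into an
  above-floor pile instead of a floor spike). On branches inside the
  contracted clade (stem included) free introns additionally get drift
  −3 per unit branch length and minimise — jump to just above the
  floor — with rate 0.25 per unit branch length. The jump process
  represents lineage-specific loss of intron sequence; pure drift of
  −3 over the ~1.2-unit contracted path cannot minimise introns that
  started ≥2 kb, while observed teleost genomes do minimise a subset
  of anciently long introns in parallel. Floors: 76 bp globally,
  256 bp for the retained class — the retained floor sits at the class
  boundary so the long class's left edge (and hence the contracted
  antimode) falls near 256 bp. With these defaults the measured
  contracted-clade antimode lies at 207-263 bp across seeds.
* **Sequence**: exons evolve under K2P with ts/tv 2.0 by exact
  per-site transition probabilities. Intron sequence is drawn
  independently per species (emulating neutral sequence diverged
  beyond alignability) except for one conserved element per retained
  intron: a 50-bp master copied into every species at a random offset
  with per-base identity 0.9.
* **Terms**: 40 terms, Poisson-mean-45 members; the first 5 are
  planted, drawing 90% of members from retained genes.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: intron gain/loss and alternative
splicing (positions are fixed, so orthology recovery is easier than in
real genomes); paralogy (families are strictly single-copy);
transposable-element insertions and genome rearrangement;
rate heterogeneity across sites and lineages; intermediate divergence
of intron sequence (real introns are partially alignable at short
distances; here background intron sequence is fully independent, so
conservation calls separate more cleanly than in real data); and an
in-clade reference with intermediate contraction (a zebrafish-like
genome). Because contraction is total inside the synthetic clade, the
size-partitioned correlation contrast is demonstrated against
non-contracted partners.

## Problem sizes

The default cohort used by the test suite and `scripts/acceptance.py`
is 12 species × 200 families (~1,460 orthologous introns); the drift
sweep uses five 8-species/60-family cohorts; MI calibration uses 200
replicates of n = 1000 with 500 permutations; the conservation stage
aligns 60 introns per set against 3 partner species. These sizes give
stable statistics (recovery rates, antimode locations and calibration
rates reproduce across seeds) while keeping a full pipeline run around
a minute on one CPU.

## Known limitations

* Sankoff reconstruction under-infers minimal ancestral states when
  few extant lineages retain them, and the smallest-state root
  tie-break biases root states slightly low; both are properties of
  the method, reported as-is.
* The antimode detector assumes the two major modes are the two
  highest peaks in the window; heavily skewed densities with shoulder
  peaks may need a narrower window.
* The k-mer repeat counter is a stand-in for a full genome aligner:
  it requires exact 31-mer matches, so diverged repeat copies are
  counted as distinct loci.
* Mutual information uses the plug-in estimator; with ~14 bins and
  ≥100 paired introns its positive bias is small, but bias-corrected
  estimators are not implemented.
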