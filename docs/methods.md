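# Methods

This note documents the models, statistics and numerical conventions
implemented in `mi2p`, the design choices made where several conventions
were defensible, and what the synthetic benchmarks do and do not show.

## Problem setting

Given two groups of shotgun metagenomes (cases vs. controls, or responders
vs. non-responders), the goal is (a) to find microbial genes whose
abundance differs consistently between the groups and (b) to ship those
genes with a trained classifier so that a single new metagenome can be
assigned a phenotype.  The discovery side works *subtractively*: instead of
profiling whole metagenomes, it first finds k-mers that differ between the
groups, uses them to pull out the differential sub-metagenome read-by-read,
and only quantifies candidate genes against that signal-bearing background.

## Canonical k-mer counting

Every length-k window over {A,C,G,T} of every read is counted under its
*canonical* form, the lexicographic minimum of the k-mer and its reverse
complement, making all downstream statistics independent of sequencing
strand.  Windows containing any other symbol are skipped (dropped, not
randomized, for determinism).  Counting is in-memory on 2-bit-packed
integer codes (numeric order of codes equals lexicographic order of the
strings, so sorted code arrays double as lexicographically ordered k-mer
lists); this comfortably handles desk-scale cohorts (tens of samples,
10⁴–10⁶ reads each) but deliberately does not compete with disk-based
counters at real cohort scale.

* **k = 21** by default: the usual discriminative odd k for bacterial
  sequence at this scale; configurable.
* **min_prevalence = 2**: a k-mer seen in a single sample cannot carry a
  two-group signal; dropping singletons also removes most sequencing-error
  k-mers.
* Counts are **depth-normalized to counts-per-million** (CPM, per-sample
  read totals) before testing, so unequal sequencing depth cannot
  masquerade as a group difference in a rank test.  A flag restores raw
  counts.

## Differential testing

Each k-mer row (later: each gene row) is tested with a two-sided Wilcoxon
rank-sum test.  U is computed from midranks.  For group sizes n₁, n₂ ≤ 8
with no ties the two-sided p is exact, from the full U null distribution
(p = 2·min tail, capped at 1); otherwise a normal approximation with tie
correction and a 0.5 continuity correction is used.  The two branches agree
within 0.011 absolute at n₁ = n₂ = 8 (the worst case sits at mid-range p;
this is a property of the continuity-corrected approximation itself).  The
row-wise screen is fully vectorized (ranks, tie terms and z-scores computed
matrix-wide); when both groups are ≤ 8 the approximation is replaced by the
exact value on tie-free rows.

Multiple testing uses Benjamini–Hochberg step-up adjusted values
(q-values), q ≤ 0.05 by default at both the k-mer and the gene stage.  Note
that with only a handful of samples per group the smallest achievable exact
p (2/C(n₁+n₂, n₁)) bounds what can survive BH across 10⁵–10⁶ k-mers: below
roughly 8 samples per group the k-mer screen can come up empty on principle,
not from lack of biological signal.

## Read extraction

A read votes once for every window whose canonical k-mer is differential;
it is extracted when it collects at least **min_votes = 2** votes (an
absolute count — requiring two differential windows keeps a single
sequencing error from producing a false vote).  Among extracted reads,
those whose valid windows are *strictly* more than **50%** covered by
abundant k-mers (top **1%** of k-mers by cohort-wide mean CPM) are dropped
as redundant; abundance is defined cohort-wide, with ties broken toward the
lexicographically smaller k-mer so the set is deterministic.  Redundancy is
only evaluated on reads that pass voting, matching the screen-then-reduce
order of the discovery workflow.  Both rules are canonical-k-mer based and
therefore strand-invariant, and kept-read counts are monotone in both
thresholds (fewer with higher min_votes, more with a laxer abundance cap).

## Quantification

Reads are assigned to genes either by the **built-in matcher** — a read is
assigned to every gene with which it shares ≥ 5 canonical 21-mer windows;
deterministic, alignment-free, adequate for exact or near-exact matches —
or from a **SAM file** produced by an external aligner, pooling primary and
secondary alignments of a read into one gene set.  A read aligned to one
gene at several positions is still unique (gene-level set semantics).

Counting follows the unique-plus-apportioned convention used for gene
profiling of gut metagenome catalogs: with U_g the number of reads unique
to gene g, each multi-mapped read r contributes U_g / Σ_{g'∈G_r} U_{g'} to
every g ∈ G_r, falling back to an equal 1/|G_r| split when no gene of the
read has unique support (so no read mass is ever discarded).  Total mass is
conserved exactly: Σ_g raw_g equals the number of assigned reads.  The
apportionment is applied in a single pass (no EM iteration).  Raw counts
are normalized per kilobase of gene per million reads:

    abundance_g = raw_g / (L_g / 1000) / (N / 10⁶)

with N the sample's **total** read count by default (a flag-free argument;
callers may pass mapped-read totals instead).

In the discovery pipeline, candidate genes are quantified against each
sample's **full** read set — the extraction step delineates the
sub-metagenome for (external) assembly, while quantification profiles the
genes in the whole sample.  This also makes training-time features
distributionally identical to prediction-time features, where a query
sample is always mapped in full.

## Marker selection

1. **q-value pre-filter**: per-gene WRS on the RPKM table, BH across genes,
   keep q ≤ 0.05.
2. **Tree-ensemble selection** (default): 100 extremely randomized trees
   are fit on the surviving genes *plus one column-permuted shadow copy of
   each*; a gene is kept when its impurity importance strictly exceeds the
   largest shadow importance.  The more common above-mean-importance rule
   was considered and rejected: impurity importances sum to 1, so the mean
   is identically 1/n and the rule discards roughly half of *any*
   homogeneous feature set — after the q-filter has concentrated the
   candidates to mostly true markers, that halving is arbitrary.  The
   shadow threshold asks the meaningful question (is this gene more
   informative than the best feature known to carry no signal?) and
   degrades gracefully in both regimes.  If nothing beats the shadows the
   selector keeps everything rather than returning an empty model.
3. **L1-based selection** (alternative): nonzero coefficients of an
   L1-penalized logistic regression on standardized features.

## Classifiers and evaluation

Model families: random forest (10/100/1000 trees; **100 by default**,
balancing runtime and accuracy), SVM (default settings, probability
outputs), decision tree, k-nearest-neighbour (20 neighbours), and a neural
network realized as a Bernoulli RBM feature transform (3200 binary hidden
units) followed by a logistic-regression head — the RBM alone is
unsupervised, so some supervised head is required; the logistic head is the
conventional completion and is documented here as an interpretive choice.
Distance- and margin-based families (SVM, KN, NN) see log(1+x)-transformed,
rescaled abundances; tree-based families consume raw RPKM.

Evaluation offers stratified 5-fold CV and LOOCV.  Feature selection is
refit inside every training fold, never on the full table.  Per-fold ROC
curves are interpolated onto a fixed 101-point FPR grid and averaged
vertically (mean TPR per grid FPR); the mean AUC is the mean of fold AUCs.
LOOCV pools held-out case probabilities into a single ROC (a per-fold ROC
is undefined for one-sample folds), and the pooled AUC equals the
Mann–Whitney pairwise concordance of the scores.  When a training fold's
screen selects nothing the fold contributes constant 0.5 scores (chance
level) — under permuted labels this is the pipeline's honest output, since
the in-fold screen finds no genes to train on.  The final shipped predictor
is refit on the full training table after CV.

## Marker repository

The distributable unit is a directory: nucleotide FASTA (optional protein
FASTA), a metadata TSV (gene id, length, enrichment direction, opaque
annotation strings — annotations are stored, never computed), the
serialized predictor, and a JSON manifest carrying a format-version string,
the exact **feature order** the predictor expects, and full provenance
(parameters, seeds, versions, per-stage statistics).  Loading validates
id/metadata/FASTA agreement and predictor feature count and order; silent
feature misalignment is the dominant failure mode of shipped predictors,
hence the explicit manifest.  Save → load → save is byte-identical for the
text artifacts.

## Synthetic cohorts

The generator emulates the *structure* of a two-group shotgun cohort, not
its full biology.  A catalog of uniform-random genes (300–1500 bp) carries
n_markers planted markers, split as evenly as possible between
case-enriched and case-depleted.  Per-gene baseline log-abundance is drawn
once with SD 1.0 (natural log) to give the uneven abundance profile real
metagenomes show; markers sit ±log(fold_change)/2 around their baseline per
group, so the group-mean ratio is exactly the stated fold change.  Per
sample, gene abundances are log-normal around the group mean with SD
`abundance_dispersion`; reads are multinomial across genes (probability ∝
abundance × number of start positions), uniform-random substrings from
either strand with probability ½, with i.i.d. substitution errors and
constant FASTQ qualities (no stage consumes qualities).  Read ids encode
the origin gene, and a truth ledger records markers, directions, labels and
realized per-gene read counts.

Default conditions: 30 + 30 samples, 200 genes, 20 markers, fold-change 4,
100 bp reads, 20 000 reads/sample, substitution rate 0.005, dispersion 0.5.
Dispersion 0.5 was chosen as a realistic between-subject variability for
gut gene abundances (≈ 1.6-fold typical sample-to-sample wobble); the
benchmark problem sizes (2×20 samples for the k-mer-specificity run at
fold 8, 2×15 training + 2×5 held-out samples at fold 16 for the end-to-end
run) keep the full stack in the minutes range on one core.

Not modeled: strain mixtures, operon/GC structure, indels, quality decay,
host reads, compositional coupling beyond the shared multinomial depth.
Consequently, passing benchmarks demonstrates the machinery (calibration
under the null, recovery of planted fold-changes, conservation laws,
determinism) — not performance on real cohorts, where gene redundancy,
strain variation and batch structure are the dominant difficulties.

## Numerical and degenerate-case conventions

* All randomness flows from explicit integer seeds through NumPy
  generators; every stage is byte-deterministic given its seed.
* Ties in the WRS test use midranks and the tie-corrected variance; a row
  with zero variance reports p = 1 and direction "tied".
* Apportionment conservation holds to < 10⁻⁹ relative error per 10⁶ reads.
* Empty inputs fail loudly: empty query read sets, single-class labels,
  zero-gene repositories and fewer than two samples per group are errors,
  not warnings; a build in which no gene survives selection raises
  "no genes surviving selection".
* The CLI distinguishes input errors (exit 2) from validation/pipeline
  errors (exit 3).

## Known limitations

* The built-in mapper is window-matching, not gapped alignment; diverged or
  indel-rich reads should be aligned externally and ingested as SAM.
* The k-mer screen's power collapses below ~8 samples per group (exact-p
  floor under BH, see above).
* Single-pass apportionment does not resolve multi-mapping as well as
  EM-style estimators when unique counts are sparse.
* The RBM network is a faithful family member but is not expected to be
  competitive at desk-scale sample sizes.
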