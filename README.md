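# mi2p — from microbiome to phenotype

`mi2p` discovers **differential microbial marker genes** from two groups of
shotgun metagenomes (e.g. patients vs. healthy controls, immunotherapy
responders vs. non-responders) and uses them to **predict host phenotype**
for new metagenome samples.  It is aimed at computational microbiome
researchers who want a self-contained, testable implementation of the
subtractive, k-mer-driven marker discovery workflow together with the
downstream classifier machinery — without the hundreds of gigabytes of real
cohort data the approach is normally run on.

## What it does

**Discovery ("build")** takes per-sample FASTQ read sets, a two-group label
table and a candidate gene FASTA, and runs:

1. **Canonical k-mer counting** per sample (k = 21 by default; canonical =
   lexicographic minimum of a k-mer and its reverse complement), assembled
   into a k-mer × sample count matrix and depth-normalized to
   counts-per-million.
2. **Differential k-mer screen** — a two-sided Wilcoxon rank-sum (WRS,
   Mann–Whitney U) test per k-mer row, Benjamini–Hochberg adjusted across
   all k-mers, keeping q ≤ 0.05.  Exact p-values by enumeration for group
   sizes ≤ 8 without ties, tie-corrected normal approximation otherwise.
3. **Voting-based read extraction** — a read is extracted when ≥ 2 of its
   k-mer windows are differential; among extracted reads, reads whose
   windows are majority-covered by cohort-wide abundant k-mers (top 1% by
   mean normalized count, typically from abundant common species) are
   dropped as redundant.  This isolates the differential sub-metagenome
   that would normally be fed to an external assembler.
4. **Gene quantification** — reads are mapped onto the candidate genes
   (built-in deterministic k-mer matcher, or SAM from an external aligner);
   a gene's raw count is its unique reads *U_g* plus each multi-mapped
   read's mass split across its genes proportionally to their unique
   counts; raw counts are normalized per kilobase of gene per million
   sample reads (RPKM-style).
5. **Marker selection** — per-gene WRS q ≤ 0.05 pre-filter, then
   tree-ensemble importance selection (a gene must beat the best
   column-permuted "shadow" feature; L1-penalized logistic selection is
   available as an alternative).
6. **Classifier training** — random forest with 100 trees by default; SVM,
   decision tree, k-nearest-neighbour (20 neighbours) and an RBM-based
   neural network (3200 binary hidden units + logistic head) are also
   provided, with leave-one-out and stratified 5-fold cross-validation and
   vertically averaged ROC curves.

The result is a **marker repository**: nucleotide (optionally protein)
FASTA of the marker genes, a metadata table with enrichment direction and
annotations, the trained predictor with its feature order, and a full
provenance record.

**Prediction** maps a query metagenome onto the repository's marker genes,
quantifies them the same way, and reports the predicted phenotype with a
case probability.

A **synthetic-community module** generates two-group cohorts with planted
marker genes (stated fold-changes, log-normal abundance noise, substitution
sequencing errors) so the whole stack is testable against a ground-truth
ledger.

## Worked example

```bash
# 1. simulate a strong-signal cohort: 8 cases + 8 controls, 6000 reads each,
#    200 genes of which 20 are planted markers at fold-change 16
mi2p simulate --out cohort --preset strong --n-case 8 --n-control 8 \
     --reads-per-sample 6000 --seed 3

# 2. discover markers and train the predictor
mi2p build --reads-dir cohort --labels cohort/labels.tsv \
     --genes cohort/genes.fasta --out repo --seed 3

# 3. predict a sample
mi2p predict --reads cohort/case00.fastq --repo repo --out report.json
```

With these inputs, `build` logs each stage:

```
[mi2p INFO] stage 1/6: counting canonical 21-mers in 16 samples
[mi2p INFO] stage 2/6: differential k-mer screen (217525 k-mers)
[mi2p INFO]   12733 differential k-mers, 2176 abundant k-mers
[mi2p INFO] stage 3/6: voting-based read extraction
[mi2p INFO] stage 4/6: quantifying 200 candidate genes
[mi2p INFO] stage 5/6: gene-level q-value pre-filter and feature selection
[mi2p INFO]   200 candidate genes -> 22 markers
[mi2p INFO] stage 6/6: training RF predictor
```

i.e. 12 733 of 217 525 canonical 21-mers are differential at q <= 0.05 and
22 of the 200 candidate genes survive the two-stage screen (the cohort
plants 20 true markers).  The predict step prints one line per query:

```
case00	case	1.0000
```

sample `case00` is predicted `case` with case probability 1.00;
`report.json` additionally carries the per-marker-gene RPKM values (the
classifier's feature vector) and a provenance block.

The same workflow is available as library calls
(`mi2p.build_repository`, `mi2p.predict_sample`), and the selection and
classification layers are scikit-learn estimators
(`WilcoxonSelector`, `TreeImportanceSelector`, `L1Selector`,
`PhenotypeClassifier`) that compose with sklearn pipelines and model
selection.

## Scope

Assembly (e.g. MegaHit), gene prediction (e.g. FragGeneScan), external
alignment (Bowtie 2) and HMM annotation are *not* re-implemented: `build`
expects a candidate gene FASTA from such external tools (or the synthetic
catalog), `predict` optionally ingests an external aligner's SAM, and
annotations are stored as opaque strings.  The in-memory k-mer counter
targets desk-scale cohorts, not the disk-based scale of dedicated counters.
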