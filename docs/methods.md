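# Methods

This note documents the models, conventions and numerical choices
behind `essgene`, in the order the pipeline applies them.

## Feature extraction

Codons are read as non-overlapping in-frame triplets from position 0 of
the supplied CDS, which is assumed to be the coding strand in frame 0
(curated essential-gene collections distribute coding sequences, so no
ORF search is performed). A trailing incomplete triplet is discarded;
any triplet containing a non-ACGT (IUPAC ambiguity) letter is skipped
rather than raising, to tolerate real FASTA dialects. The 64 codon
counts are normalized **by the gene's own total of complete codons**,
giving a per-gene codon frequency distribution; gene length counts all
nucleotides of the CDS including the stop codon, and protein length
counts standard residues excluding a trailing `*`.

The genetic code defaults to NCBI translation table 11 (bacterial) and
is configurable wherever codon statistics are computed. Stop codons
form their own synonymous family; under table 11, methionine (ATG) and
tryptophan (TGG) sit in singleton families. RSCU of every codon in a
family with zero observations is defined as 0, and the `rscu_max`
feature is taken over degenerate (n >= 2) non-stop families only — a
family with a single synonymous codon always has RSCU 1 and carries no
usage-bias information.

**CAI.** Relative adaptedness is computed per amino-acid family:
r_i = X_i / X_max where X_max is the count of the family's most
frequent codon in the reference set, so each observed family's top
codon scores exactly 1 (the classical convention; a global maximum
would make r depend on amino-acid composition rather than synonymous
choice). An unobserved codon in an observed family receives the
pseudo-value 0.5 / X_max so the geometric mean can never hit exactly 0;
entirely unobserved families, Met, Trp and stops are excluded from
scoring. CAI is the geometric mean of r over the gene's scored codon
occurrences, accumulated in log space. The reference set is
configurable: the default is **self-referential** (the gene's own
counts, matching the defining formulas, which use the gene's X_i);
`reference="species"` pools counts per species into a shared table,
closer to the classical "highly expressed reference set" usage. The two
choices change CAI values but nothing else in the layout.

## Corpus input

DNA and protein FASTA records are paired on the first
whitespace-delimited header token by default; a custom regular
expression can be supplied for other header dialects. Records present
in only one file are warned about and skipped; duplicate identifiers
within a file are an error. Orthology cluster membership is consumed as
a two-column (gene_id, cluster_id) table from an external clustering
tool; genes absent from the table become singleton clusters derived
from their own identifier, so they can never spuriously share a
cluster.

## Balancing and splitting

Essentiality corpora are heavily imbalanced toward non-essential genes.
The corpus is balanced **before** splitting by down-sampling the
majority class uniformly at random (seeded, without replacement) to the
minority-class size, globally across species. No over-sampling or class
weighting is used.

The `random` policy shuffles each class separately and allocates
floor(f·n) records to train and validation and the remainder to test,
so the per-partition class ratio stays within one record of the global
ratio. Ten independent seeded splits (repeated random subsampling)
constitute one repeated experiment; this is implemented literally as
described rather than as rotating-fold cross-validation.

The `cluster_aware` policy shuffles whole clusters and fills train,
then validation, then test greedily, closing a partition once its
gene-count target is met. Every cluster therefore lies wholly inside
one partition — including validation, since validation drives early
stopping and the leak argument applies to it equally. Realized
fractions can deviate from the targets with coarse cluster sizes and
are logged; a cluster larger than the whole train target is forced into
train with a warning.

Features are standardized to train-set z-scores (constant features get
scale 1). Standardization is an addition for optimizer stability, not
part of the original protocol; the `Standardizer` records the partition
it was fitted on and refuses to fit on anything but training data.

## Classifier

A feed-forward network: input (89) → affine/ReLU/dropout per hidden
layer → affine to 2 units → softmax. Defaults reproduce the selected
hyper-parameter set: hidden widths 128, 256, 512, 1024, 1024, 1024,
dropout 0.3, at most 100 epochs, Adadelta. The output layer is a
two-unit softmax: this satisfies the sum-to-one probability contract
and is mathematically a sigmoid applied to the logit difference, which
resolves the ambiguity of describing a "sigmoid" output that sums to
one across two units. Implementation is plain NumPy in float32 —
forward, backward and Adadelta (rho 0.95, eps 1e-6, no learning rate to
tune) — which is entirely adequate at this model size on one CPU.
Weights are He-normal from a seeded generator; dropout uses inverted
scaling and is active only during training, so inference is
deterministic.

Early stopping: patience defaults to 10 epochs on validation loss, with
the best-validation weights restored. The untrained network's
validation loss serves as the initial best, so a first epoch that fails
to improve on it already counts as non-improving (this makes patience 0
mean "stop at the first non-improving epoch"). Non-finite losses raise
immediately with the epoch index. The classification threshold for
confusion-based metrics is 0.5, with ties classified positive.

## Metrics

Sn = TP/(TP+FN), Sp = TN/(FP+TN), PPV = TP/(TP+FP),
accuracy = (TP+TN)/total, with the essential class positive. A metric
with a zero denominator is reported as missing (None), never coerced to
0, so aggregates over repetitions are not silently skewed. ROC curves
sweep all distinct scores as thresholds (no intermediate-point
dropping) and AUC is trapezoidal, which makes it equal to the pairwise
concordance statistic P(s_pos > s_neg) + 0.5·P(tie); the test suite
verifies this against a brute-force oracle. AUPR uses the step-wise,
interpolation-free summation convention. Repeated experiments report
per-repetition test metrics, the validation AUC alongside (published
aggregates do not always say which partition they used), means and
standard deviations, and the raw AUC list.

## Ablation

Pairwise Pearson correlations over all 89 features (constant features
correlate 0 and are flagged); every pair with |r| > 0.9 forms an
ablation unit, and overlapping pairs are merged transitively via
union-find — on some corpora the qualifying pairs overlap, and
transitive closure keeps units disjoint. When a unit is ablated **both
(all) members are removed**: removing only one member would be
compensated by its correlate, which is the reason for grouping in the
first place. The model is retrained with reduced input width (rather
than zero-masking, which would leave dead weights and an input-width
mismatch with the standardizer). Baseline and every ablated run share
the same seeded class-stratified 5-fold split; within each fold, 10% of
the training block is held out for early stopping. The empty unit is
the identity and scores delta 0 exactly.

## Synthetic corpus generator

The generator produces the study conditions for all pipeline tests; its
defaults are fixed package choices, not tuning knobs.

* **Codon distributions.** A base distribution over the 61 sense codons
  is drawn once from a symmetric Dirichlet(5). The essential class
  multiplies it by exp(s·z) with z ~ N(0,1) per codon and
  s = `codon_bias_strength` (default 0.6 — a strong, cleanly learnable
  contrast); the non-essential class multiplies the base by
  exp(g·GC(codon)) with g = `gc_shift` (default 0.4), reproducing the
  direction of higher GC in non-essential genes.
* **Lengths.** Log-normal in codon units, essential log-mean 5.75
  (~315 codons) vs non-essential 5.60 (~270), sd 0.35, floor 30 codons
  — essential genes slightly longer, as in Gram-positive collections;
  both means are configurable and equalized in the null preset.
* **Genes.** ATG + body codons sampled from the class distribution + a
  random stop; the protein is the exact table-11 translation, so every
  generated record passes all feature-extraction preconditions.
* **Families.** A fraction `ortholog_family_rate` (default 0.2) of
  genes belong to cross-species families: one ancestor is copied into
  >= 2 species with per-base substitutions at `mutation_rate` (third
  codon positions at the full rate, first/second at a tenth — a crude
  synonymous bias; substitutions creating premature stops are skipped).
  Labels are constant within a family, and family members share a
  cluster id.
* **Leak preset.** `leak_prone_config()` sets family rate 0.6, mutation
  rate 0.01 and `family_label_noise` 0.35: a noisy family's sequences
  are drawn from one class's codon distribution but carry the opposite
  label, so those labels are predictable only by recognizing the family
  itself. Random splits place near-identical family members on both
  sides of the train/test boundary and reward that memorization;
  cluster-aware splits remove it, producing the characteristic AUC drop.
* **Null preset.** `null_signal()` zeroes the codon tilt and GC shift
  and equalizes the length distributions; a classifier on such a corpus
  should sit at chance.

What the generator does **not** emulate: real genome-scale codon-usage
structure (amelioration, strand bias, operon context), realistic
phylogenetic correlation between species, indels or rearrangements in
families, and annotation noise. Passing tests therefore demonstrate
that the pipeline recovers the signals it assumes when they are
present, and reports chance when they are absent — not that any
particular real corpus carries those signals at a given strength.

## Problem sizes used in the automated checks

The training-based checks in `tests/test_acceptance.py` run at the
default corpus scale (3 species × 2,000 genes; 5 species × 2,000 for
the CAI sweep) but with a reduced network — two hidden layers (128,
64), batch 128, at most 40 epochs, patience 8. At this corpus size the
class contrasts are either cleanly present or absent, so the reduced
architecture measures the same qualitative outcomes while keeping the
whole suite under a minute; the full six-layer architecture remains the
library default and its shape and output contracts are covered by unit
tests. The ablation check plants one informative Gaussian feature among
seven noise features (n = 600) rather than using a genomic corpus,
which isolates the procedure's ranking behaviour from feature-extraction
effects.

## Known limitations

* Self-referential CAI makes the feature a measure of internal codon
  homogeneity rather than adaptation to a highly expressed reference
  set; supply a pooled species reference where that reading matters.
* The greedy cluster-aware split can realize fractions far from
  80/10/10 when a few clusters dominate the corpus; sizes are logged
  and the split manifest records the actual assignment.
* Adadelta with default constants converges slowly on very weak
  signals; the epoch budget, not the optimizer, is the binding
  constraint there.
* Down-sampling discards majority-class data; no attempt is made to
  ensemble over multiple down-samples.
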