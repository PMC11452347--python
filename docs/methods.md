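# Methods

## Model and procedure

`vascomm` treats cell–cell communication inference as a co-expression
problem: an ordered ligand–receptor pair (L, R) is a candidate signal
from sender subtype S to receiver subtype V within one region when both
genes are highly expressed in their respective populations. The
interaction score is

    score(L, R | S, V) = m_S(L) · m_V(R),

where `m_G(g)` is the arithmetic mean, over the cells of group G, of the
de-logged normalized expression `exp(x) − 1` (i.e. mean CP10K). The
linear scale — rather than the log scale the matrix is stored on — is
deliberate: products of log-scale averages compress exactly the strong
co-expression the method is after, and the score's interpretation as
"mean ligand transcripts × mean receptor transcripts per 10⁴" only holds
on the linear scale.

A raw product score has no natural threshold, so significance is
calibrated per comparison by a bootstrap null designed to preserve
everything about the data except the identity of the receptor:

1. per iteration, resample cells with replacement independently within
   sender and receiver, and recompute both mean profiles;
2. draw `D` pseudo-receptor genes (D = database size) uniformly without
   replacement from all detected genes, pair each with a ligand drawn
   uniformly from the database's detected ligands, and record the
   product scores;
3. pool over `B = 1000` iterations into a null of `B·D` scores.

Each observed pair then gets the add-one one-sided empirical p-value
`p = (1 + #{null ≥ s}) / (1 + B·D)`, Bonferroni-corrected by the number
of pairs scored in the comparison; a pair is significant when the
corrected p falls below α = 0.01 and its score is positive. The smallest
significant score is reported as the comparison's cutoff. A
`fixed_cutoff` option bypasses calibration and calls any score above a
user-supplied threshold, for reproducing analyses that published a
single dataset-wide cutoff.

Randomness in the null is consumed in a fixed, documented order from one
seeded generator (sender weights, receiver weights, pseudo-receptor
keys, ligand indices), which is what lets an independent loop-based
reference implementation reproduce the whole path exactly in the test
suite.

### Database assembly

The database is an ordered, duplicate-free list of directed pairs:
established reference pairs first (file order, displayed uppercase),
then candidates sorted lexicographically (displayed in original symbol
case). A DE gene becomes a candidate only with positive localization
evidence (plasma membrane, secreted, or extracellular matrix — any
unrecognized annotation collapses conservatively to `other`, never to an
eligible class) and only paired with PPI partners whose edge carries
experimental validation. Candidates are added in **both** orientations
because which member acts as the ligand is unknown a priori; orientation
is resolved empirically by which direction scores significantly. A
candidate that duplicates a reference pair keeps established provenance.

### Specificity filter

For the ME, pairs significant in *every* receiving subtype except ME
pericytes are flagged `excluded_nonspecific` and lose their significant
call: a signal that appears ubiquitously but is missing precisely in the
one subtype profiled by a different modality is most plausibly a
methodological artifact, not biology. The rule is a literal set
comparison — a pair significant in all subtypes *including* pericytes is
retained.

### Differential expression

Two-sided Wilcoxon rank-sum per gene, with the field's marker-gene
gating applied *before* testing (detection fraction, then fold change),
so the multiple-testing adjustment runs over the tested set only.
For pooled sizes n ≤ 20 the exact null is enumerated over all C(n, n_a)
label assignments of the pooled mid-ranks; above that a tie-corrected
normal approximation (no continuity correction) is used. The two gates
are separate parameters because the source analyses used 0.25 for
cluster markers and 0.6 for regional enrichment; 0.6 is the default for
the regional question this package targets.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| min_genes / min_counts | 500 / 750 | QC floors on genes detected and total UMIs per cell (inclusive) |
| max_pct_mito | 15% | mitochondrial-read ceiling (inclusive) |
| min_novelty | 0.4 | genes/UMIs floor; low values mark low-complexity libraries |
| max_doublet_score / max_empty_fdr | 0.25 / 0.01 | external doublet/empty-droplet flags; strictly-above rejects, missing never rejects |
| min_pct / logfc_threshold | 0.25 / 0.6 | DE gates; 2^0.6 ≈ 1.52-fold linear change |
| n_iterations | 1000 | bootstrap iterations for the null |
| alpha | 0.01 | one-sided level after Bonferroni; 0.05 available for looser summaries |
| pseudocount | 1.0 | on the mean-CP10K scale in avg_log2fc, making it antisymmetric and bounded |

All QC thresholds are inclusive on the passing side ("at least", "≤", "≥"
read literally); the doublet and empty-droplet gates are exclusive on the
failing side (> 0.25, > 0.01). Zero-count cells get novelty 0 (rejected)
rather than an undefined ratio.

## The synthetic-data generator

The generator emulates the two-region vascular study design: subtypes
cEC, pericyte, astrocyte and fibroblast in cortex and ME plus ME
tanycytes, 150 cells each by default. Counts are negative binomial with
lognormal per-gene baseline rates (log-mean −0.3, log-sd 0.3) and
lognormal per-cell depths (log-sd 0.25), dispersion 2 — chosen so clean
cells land comfortably on the passing side of the QC defaults (~1,600
UMIs, ~950 genes, novelty ~0.6, < 1% mitochondrial from 13 mt- genes),
the overdispersed regime typical of droplet libraries. Planted markers
and pair members multiply a gene's rate by its fold change within one
(subtype, region). Contaminants are constructed, not sampled, to fail
QC deterministically by class: low-quality cells are binomial-thinned to
~190 UMIs (under both count and gene floors), doublets are exact sums of
two same-region parents with doublet score drawn above 0.25, empties are
draws from the ambient (mean-rate) profile with empty FDR above 0.01.
Reference pairs are the planted pairs plus random decoy pairs up to a
configurable database size (default 200), so null datasets carry a
realistic-sized database.

One master seed drives everything; each stage derives an independent
stream from the seed plus its stage name, so outputs are bit-identical
per (config, seed) and adding a stage never perturbs earlier draws.

What the generator does *not* emulate — gene–gene correlation structure,
batch effects, ambient-RNA contamination of clean cells, realistic gene
symbols and annotation error — bounds what passing tests show: recovery
and calibration results demonstrate the pipeline's statistical logic
under a faithful null and planted-effect model, not robustness to every
artifact of real droplet data.

## Problem sizes and numerical choices

Calibration and recovery studies run at 2,000 genes × ~1,350 cells with
a 200-pair database and 1,000 bootstrap iterations — large enough that
the per-comparison null holds 200,000 draws (minimum attainable
corrected p ≈ 10⁻³ at family size 200) while a 50-replicate study
completes in minutes on one CPU. The family-wise false-call probability
measured over 50 null replicates is compared to the 0.01 level with an
exact binomial bound, and planted-signal recovery (folds 5, 150
cells/subtype) to the 90% target with a one-sided binomial sampling
band, since both are Monte-Carlo estimates of rates.

Other numerical choices: the add-one p-value estimator avoids zero
p-values; the Bonferroni family is the pairs of one (sender, receiver,
region) comparison, each with its own null; empirical-p tail counts use
binary search on the sorted null; score products of a missing gene are
reported as NaN and never significant; the degenerate all-tied Wilcoxon
case returns p = 1; zero-total cells normalize to all-zero columns.

## Known limitations

- Single-gene pairs only; multi-subunit receptor complexes and
  pathway-level communication models are out of scope.
- Doublet and empty-droplet detection are consumed as annotation
  columns, not recomputed; cluster-level QC removal is out of scope
  because clustering is.
- External receiver profiles are ingested as-is on their own scale;
  cross-modality scale calibration is the caller's responsibility and
  the provenance is recorded in the output.
- The bootstrap null's "randomize with replacement" is implemented as a
  within-subtype cell bootstrap with random pseudo-receptor genes; other
  readings (gene-label permutation, count resampling) exist, and the
  choice is documented here rather than settled by any external source.
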