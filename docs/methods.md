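# Methods

`glandscape` re-implements, as a tested pipeline, a plate-based single-cell
RNA-seq analysis whose central question is whether cell clusters are robust
to technical measurement noise. This note documents the models, the
numerical choices, and what the synthetic-data generator does and does not
emulate.

## The analysis in one paragraph

Cells sorted into 96-well plates are sequenced together with ERCC spike-in
transcripts added to every well at a fixed dilution, plus blank wells — some
empty (negative controls), some with a small aliquot of bulk RNA (positive
controls). Cell QC is anchored on those controls. Counts are TMM-normalised,
converted to FPKM for an expression filter, re-normalised to TPM, and a
low-variability filter removes uninformative high-expression genes. A
technical-noise model fitted from the spike-ins is used to simulate
technical replicates of the count matrix; each replicate is re-normalised
and clustered, and the frequency with which every pair of cells co-clusters
across 250 replicates forms the consensus matrix. The cluster number k is
chosen from cluster-wise mean silhouette widths pooled over replicates.
Groupings of cells are scored by stability − promiscuity against the
consensus. Differential expression between groups uses a permutation test
with Benjamini–Hochberg FDR; stem-like clusters are flagged by an
entropy × links score; marker positivity uses a tenth-centile threshold.

## Cell QC

The threshold on per-well biological-gene totals is
`max(negative-control totals) + 1`. Construction fails with a QC-conflict
error if any positive control falls below it, so the rule "exclude all
negatives, include all remaining positives" is enforced rather than assumed.
An explicit override (e.g. a count threshold taken from a sequencing batch,
such as 25,119 fragments) bypasses the control checks. An optional outlier
rule (median ± k·MAD on log10 totals of sample wells, default off) is
provided because plate data often contain wells that pass the control-based
bar yet are clearly atypical; it is off by default because no principled
universal k exists.

## Normalization

TMM follows the canonical published constants: reference cell chosen by
upper-quartile count fraction closest to the across-cell mean; per cell,
log-ratios M and log-abundances A over genes positive in both cell and
reference; double trim of 30% each side by M and 5% each side by A
(rank-based, deterministic under ties); factor = 2^(precision-weighted mean
of retained M) with delta-method binomial weights; factors rescaled to
geometric mean 1. Because the precision weights depend on absolute counts,
factors are invariant to uniform scaling of a cell only up to the weight
shift (a few percent at typical depths); the identity and two-cell scaled
cases are exact.

FPKM uses the TMM-effective library size (library size × TMM factor), which
makes "TMM-normalised, then FPKM" a single coherent operation. The gene
expression filter keeps genes with ≥ 4 FPKM in ≥ 3 cells. TPM is computed
after re-normalisation on the retained gene set, so every cell's TPM column
sums to 10⁶ over those genes. The variability filter drops genes that are
simultaneously in the top decile of mean TPM and below the fifth centile of
coefficient of variation; both centiles use the nearest-rank convention, as
does every other quantile in the package.

Spike-ins are excluded from TMM, from both gene filters and from all
downstream clustering/DE; they feed the noise model only.

## Technical-noise model

From spike-in counts over sample wells, two curves are fitted:

* **Dropout** — detection rate (fraction of wells with count > 0) against
  log2(mean detected count + 1), fitted as a binomial-likelihood logistic
  with slope constrained ≥ 0 (monotone detection). If every spike is
  detected everywhere the fit degenerates to p_detect ≡ 1. Note the observed
  detection rate folds sampling zeros of the count distribution into
  "dropout"; the fitted midpoint is therefore slightly above the purely
  mechanistic one (about +0.2 on the log2 scale under the default simulated
  conditions), which is the behaviour a spike-anchored empirical noise model
  should have.
* **Variance** — least-squares line of log2(variance over detected wells) on
  log2(mean over detected wells), floored at the mean (Poisson floor).
  The mean–variance relation of overdispersed counts is convex in log–log
  space; fitting a line over a two-fold dilution series spanning ~2¹¹
  balances the curvature, and mid-range predictions (e.g. µ = 100) land
  within a few percent of the generative value.

A simulated technical replicate perturbs the observed counts: each positive
entry x is zeroed with probability proportional to 1 − p_detect(x) and
otherwise redrawn from a zero-truncated NB with mean x and fitted variance
(truncated because dropout is handled by the explicit injection step); each
zero entry of gene g is recovered with a probability chosen so that the
expected number of recoveries equals the expected number of injections.
Two balancing choices make the perturbation stationary per gene:

* the injection probability is capped per gene so the expected number of
  injected zeros never exceeds the gene's zero pool (without the cap, genes
  detected in nearly every well but with modest counts would lose detections
  that no recovery could replace);
* recovery values are drawn around the injection-weighted mean of the
  gene's positive entries — the expected value of what dropout removes —
  rather than the plain detected-well mean, keeping the perturbation
  mean-preserving, not just rate-preserving.

Under the default simulated plate, per-gene detection rates across 250
replicates stay within 3 binomial standard errors of the source for ~99% of
genes, and per-gene means are preserved to a median 0.4%. Genes with source
mean below ~1 count retain a visible upward bias (up to ~50% of a tiny
base) because recovered and truncated draws cannot go below 1; this is an
integer-count floor, not a fit artefact. With noise parameters at zero the
replicate distribution collapses exactly onto the source matrix.

## Consensus clustering and k selection

The clusterer inside the replicate loop is deliberately simple and
deterministic: average-linkage hierarchical clustering on the distance
1 − Spearman correlation between cells, tree cut by `maxclust`, cluster ids
relabelled in order of first appearance. The robustness machinery — the
replicate loop, the consensus matrix, silhouette-based k selection — is
agnostic to the clusterer, which is pluggable; a multi-transformation
consensus clusterer could be substituted without touching the rest.

Per replicate, TPM and log2(x+1) are recomputed from the perturbed counts
before clustering, because technical noise acts on counts, not on
normalised values. For each k in the requested range the per-cluster mean
silhouette widths (same distance, singleton clusters scored 0) are pooled
over replicates; the suggested k maximises the pooled median, and the full
distributions are returned so the final k can be chosen by inspection —
with diffuse, noisy populations the silhouette criterion is conservative
and tends toward merging, so the suggestion is a starting point, not a
verdict. Final clusters cut an average-linkage tree on 1 − consensus.

A grouping's score against the consensus matrix is
stability − promiscuity: mean within-group co-clustering frequency minus
mean frequency between members and all non-members. A single group covering
all cells ("ensemble") has promiscuity 0 by convention. Scores live in
[−1, 1]; random groupings score ≈ 0.

## Differential expression

The permuted statistic is |log2 fold change| of group-mean TPM with
pseudocount 1 — a declared, self-contained choice that makes the test
oracle-checkable by exhaustive enumeration at small n. Labels are permuted
jointly across genes, preserving gene–gene correlation for the FDR step.
P-values use the add-one estimator p = (1 + #{|stat*| ≥ |stat|}) / (B + 1),
valid at finite B and bounded below by 1/(B+1). Consequently, with the
supported 250–1000 permutations the classical reporting filter
"fold change > 4 and FDR < 10⁻⁵" cannot fire from permutation p-values
alone; the filter is kept as the default reporting convention, and run
reports additionally tally genes at FDR < 0.05. Note that measured TPM fold
changes are smaller than generative fold changes whenever the perturbed
genes carry an appreciable share of the library (compositional
renormalisation) and are further shrunk by the pseudocount at low
expression.

## Stem scoring

Per-cell entropy is the Shannon entropy of the TPM composition over
retained genes, normalised by ln G to [0, 1]. The link graph projects each
cell onto the segments joining its cluster's medoid (1 − Spearman geometry)
to every other medoid in log2TPM space; the cell supports a link toward the
cluster of its largest scalar projection when that projection lies strictly
between the medoids. A link exists when either direction collects at least
m_min supporting cells (default max(2, 1% of cluster size) — sensitive; a
higher explicit m_min suppresses stray projections in small panels). The
score of a cluster is its link count times the excess of its median entropy
over the minimum cluster-median entropy, so a cluster at minimum entropy or
with no links scores exactly 0. Median (not mean) entropy and the
delta-against-minimum are robustness choices: they make the score invariant
to the entropy offset shared by all clusters.

## Marker binarization

A cell is positive for a gene when its expression is at or above the tenth
centile of expression among cells with at least one transcript of that gene,
i.e. the 90% of expressing cells with the highest expression are included;
ties at the threshold are included. With n expressing cells and distinct
values this yields exactly ⌈0.9 n⌉ positives. The rule is rank-based, hence
invariant to monotone rescaling, so calls agree across counts, TPM and log
scales. Thresholds are always computed per gene over the full matrix and
then applied to any subset, so combination tables and tissue-scoped
selection rules share one threshold per gene.

## The synthetic-data generator

The generator emulates what the analysis assumes about plate data: discrete
populations with marker-gene modules, log-normal per-cell depth (not applied
to spike-ins, which enter at fixed dilution), NB overdispersion
(var = µ + φµ²), logistic mean-dependent dropout, a two-fold spike-in
dilution series spanning ≥ 2¹⁰ at the default 12 spike-ins, and control
wells (blank negatives with Poisson(0.01) background plus full spike
signal; positives as depth-matched pseudo-bulk draws).

Default study conditions: 108 biological genes + 12 spike-ins, 3 populations
× 100 cells, marker modules of 20 genes per population (~18% of the panel,
in line with the between-lineage DE fractions used by standard scRNA-seq
benchmark simulators), marker multiplier 4 (8 in the "well-separated"
recovery experiments), φ = 0.5, dropout midpoint 1.0 / slope 1.5,
size-factor SD 0.25, 3 negative + 3 positive controls. All randomness flows
from one master seed through named substreams, so adding control wells does
not change the cell counts drawn.

What the generator does **not** emulate: read-level structure (no FASTQ, no
UMIs), batch effects, doublets, amplification bias, gene–gene correlation
beyond group structure, or realistic transcriptome scale (tens of genes, not
tens of thousands). Passing tests therefore demonstrate that the
implementation is correct under the model's own assumptions at desk scale —
not that the pipeline's scientific conclusions transfer to any particular
real dataset.

## Problem sizes and determinism

The test and acceptance experiments run at desk scale, chosen so the whole
suite completes in a few minutes on one CPU: 20-seed recovery experiments
use 50 simulated replicates per seed for k selection and 30 for score
ordering (the zero-noise collapse uses the full 250), 500-well spike plates
for noise recovery, and a 2000-gene null for permutation calibration. Every
stochastic step takes an explicit seed; identical configuration and seeds
reproduce every artefact checksum in the run report.

## Known limitations

* The noise model is global (spike-derived), not gene-specific; biological
  overdispersion beyond the spike trend is not simulated back into
  replicates.
* Silhouette-median k selection is conservative for weakly separated
  populations (it prefers merging); the full silhouette distributions are
  exposed for manual choice.
* The stability score uses promiscuity against *all* non-members; a variant
  restricted to the most-associated external cluster would penalise
  fragmented groupings differently.
* Mean preservation of simulated replicates degrades below ~1 count per
  gene (integer floor), and FDR < 10⁻⁵ is unreachable from ≤ 1000
  permutations (estimator floor); both are properties of the methods, not
  bugs, and both are covered above.
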