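# Methods

## Problem and model

Cancer expression cohorts show *regional epigenetic regulation* (RER):
contiguous runs of genes whose expression rises or falls together across
tumors, independent of DNA copy number.  The pipeline detects such regions
from three inputs: a genes-by-samples log-scale expression matrix, an
ordered gene map, and per-(gene, sample) copy-number calls.

The detection statistic is the **transcription correlation score (TCS)**:
for gene *g* with expression profile *x_g*,

    TCS(g) = sum over neighbors h of rho_S(x_g, x_h),

where the neighbors are the up-to-*n* genes on each side of *g* in genomic
order on the same chromosome (a sliding window of 2n + 1 genes) and rho_S
is the Spearman rank correlation on pairwise-complete samples.  Under the
null of independent genes each rho is approximately N(0, 1/(m − 1)) for m
samples, so the TCS distribution is approximately normal with a right tail
of outliers where coordinate regulation exists.  Significance is assessed
empirically: z = (TCS − mean)/sd over all defined scores, with a one-sided
upper-tail normal p value (coordinate regulation only inflates the score).

## Copy-number masking

Dosage changes mimic coordinate regulation: a deletion spanning k genes
shifts all of them in the affected samples and produces genuine
correlation.  Before scoring, every (gene, sample) cell with a non-neutral
copy-number call is set to missing; correlations then use the remaining
pairwise-complete samples.  Masking is per cell, never per gene row, so a
gene aberrant in some samples still contributes its neutral samples.  A
simple threshold caller (loss ≤ −0.3, gain ≥ +0.3 log2 by default) is
included for convenience; externally produced call sets are accepted
unchanged, and any non-neutral call masks (gain vs amplification is not
distinguished).

Undefined correlations (fewer than `min_pairs` complete pairs, default 10,
or a constant profile) are dropped from the TCS sum rather than counted as
zero: zeros would deflate scores exactly in the heavily masked regions the
mask is meant to rescue.

## Region delineation and trimming

Each significant gene seeds a candidate window of itself ± n genes
(clipped at chromosome ends).  Overlapping or book-ended windows merge;
merged regions with fewer than two significant genes are discarded.

Regions are then *trimmed* against the data.  For each member gene a
representative per-sample profile is computed as the median over the other
member genes (excluding the tested gene, so self-correlation cannot retain
it), and the gene is kept when its Spearman correlation with the
representative reaches p < 0.05 (two-sided).  Two boundary rules are
implemented:

* **contiguous** (default): the region becomes the maximal run of
  consecutively kept genes around the significant core (ties broken by
  core-gene count, then length, then leftmost position).
* **extent**: the region spans the first to the last kept gene.

The extent rule is the literal min/max reading, but it is statistically
leaky: a delineated region carries ~n noise genes on each flank, and at
alpha = 0.05 the chance that some outer flank gene correlates spuriously
is ≈ 1 − 0.95^18 ≈ 0.6 per region, dragging boundaries outward.  Measured
on synthetic domain cohorts the extent rule recovered true domain
boundaries to ±1 gene in only ~40% of domains and retained ~2 chance
regions per 500-gene null cohort, while the contiguous rule recovered
100% of boundaries and kept ~0.05 chance regions per null cohort.  The
contiguous rule is therefore the default; both are available.

Regions report two sizes: the full member span and `span_sig`, first to
last significant gene — the latter is the reporting convention.

## FDR by gene-order randomization

The permutation null shuffles the assignment of expression profiles to
genome positions (profiles keep their values, order is destroyed), then
re-runs scoring and delineation.  Null scores are compared against the
TCS cutoff *fixed from the observed data* (the score where the observed
z reaches alpha), not against a cutoff refit on the permuted data:
refitting would flag ~alpha of genes on every permutation by construction
and the estimate would be uninformative.  The FDR is the region-level
ratio (null regions / observed regions) averaged over permutations; the
gene-level ratio is emitted alongside.

## Multiscale scan

Re-running the scan at n = 1..10 produces a gene-by-window significance
matrix.  A broad region that is really two independent sub-domains stays
merged at n = 10 (the windows bridge the few intervening null genes) and
separates into distinct significant blocks once n falls below the gap
width — the basis for sub-region resolution.

## Region-level statistics

* **Region mean expression**: each gene is z-scored across samples
  (population sd, missing ignored); a region's value in a sample is the
  mean z of its significant genes there.
* **Clustering**: Ward linkage on Euclidean distances, applied to region
  rows and sample columns; labels from cutting the region dendrogram at k
  (default 3).  Missing cells are imputed to 0 (the z-score mean) inside
  the distance computation only.
* **Group association**: two-sided Wilcoxon rank-sum per region between
  two sample groups; exact distribution when both groups are ≤ 20 and
  tie-free, normal approximation with tie correction otherwise.
* **Neighbor correlation count**: for one gene, how many of its 20
  nearest neighbors correlate at p < 0.05 (two-sided t-approximation).
* **Gene density**: genes-with-start-inside-regions per Mb of region
  span, against uniform repositioning of each region within its own
  chromosome; add-one permutation p.

## Interval permutation tests

A region is *contained* in a TAD when ≥ 80% of its span lies within a
single TAD.  The null repositions each region uniformly within its own
chromosome, rejecting placements that intersect assembly gaps (bounded
resampling; an impossible placement is an error naming the region).
Window enrichment counts sites whose midpoint falls inside the window
(midpoint membership avoids double counting at edges) and ranks the
observed count against equal-length windows placed genome-wide, with the
chromosome drawn proportional to its placeable length.  Both statistics
use tie-inclusive (≥ observed) counting and add-one estimators, so
p ∈ [1/(N+1), 1] and the percentile is never 0.

## FISH statistics

Chromatin compaction is measured per nucleus as d²/r², the squared
interprobe distance normalized by squared nuclear radius with
r = sqrt(area/π) — invariant under a change of length units (d → s·d,
area → s²·area).  Distributions of d²/r² are compared directly with the
two-sided rank-sum test above (exact for combined n ≤ 40 without ties).
Radial position uses five concentric equal-area shells from periphery
(shell 1) to center (shell 5); for a normalized radial coordinate on a
circular nucleus the equal-area boundaries are sqrt(k/5), k = 1..4, with
boundary values assigned to the outer shell.  The circular model is the
exact analytic counterpart of area-erosion on normalized inputs; real
segmented nuclei are not circular, which is one reason synthetic tests do
not certify behavior on raw microscopy data.

## Synthetic cohorts

`simulate_cohort` draws, for gene g and sample s,

    x[g, s] = baseline(g) + shift · 1[group(s) affected]
              + sqrt(c) · F(d, s) + cna_shift(g, s) + N(0, noise_sd²)

with one standard-normal factor F per domain and sample.  The realized
within-domain correlation is c / (c + noise_sd²); study-condition cohorts
that state "within-domain correlation c" therefore use
noise_sd = sqrt(1 − c).  Copy-number aberrations are additive log-scale
shifts on the spanned genes of a random sample subset, with the exact
affected cells returned as ground truth — the central property being that
their apparent coordinate expression must vanish after masking.  Defaults
(500 genes on one chromosome at 100 kb spacing, 200 samples in two equal
receptor-status groups, unit noise, baseline N(7, 1) log2-intensity-like)
describe a mid-sized microarray cohort.  FISH tables draw nuclear area
from lognormal(log 150 µm², 0.2), d²/r² from a gamma with shape 2 and
mean equal to the `compaction` parameter (a stand-in chosen for
positivity and right skew, recorded in the output header, not a claim
about real measurements), and radial positions from beta(4, 1.5)
(peripheral) or beta(1.5, 4) (central).  TAD tilings use lognormal sizes
(σ = 0.25) around the requested mean with occasional simulated gaps.

What the generator does *not* emulate: probe-level noise and
normalization artifacts, correlated (segmental) baseline structure,
karyotype evolution, non-Gaussian expression tails, or 3D nuclear
geometry.  Passing tests certify the statistical machinery under the
stated generative model, not performance on any particular real cohort.

## Problem sizes and numerical choices

Test and acceptance runs use 100–500-gene cohorts with 120–200 samples,
10 null replicates, 5 FDR permutations, 1000 TAD permutations and 10,000
enrichment windows — sizes at which every Monte-Carlo margin asserted is
several standard errors wide.  The scoring core is exact (Pearson on
average ranks for complete rows, verified to 1e-9 against a brute-force
double loop); z scores use the sample standard deviation (ddof = 1);
permutation estimators are add-one throughout; clustering ties follow
scipy's deterministic linkage order.  All stochastic components take
explicit integer seeds and are bit-reproducible.

## Known limitations

* The empirical-null z score assumes the bulk of TCS values is normal;
  cohorts where most genes sit in coordinated domains would inflate the
  null sd and lose power.
* Neighbor windows count genes, not base pairs: gene-dense and gene-poor
  regions cover very different genomic spans at the same n.
* The FDR's fixed-cutoff convention makes the estimate conservative when
  the observed signal is weak (cutoff barely above the null).
* Probe-to-gene collapsing is out of scope; for real arrays, collapse
  multiple probes per gene beforehand (conventionally the probe with the
  highest median expression).
* The TAD test's chromosome-restricted permutation preserves chromosome
  composition but not local gene density or the TAD landscape itself.
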