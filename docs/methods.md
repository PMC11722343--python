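# Methods

This note documents the models and procedures `tmequant` implements, the
parameters that matter, what the synthetic generators do and do not
emulate, and the numerical conventions chosen where the design was open.

## Coordinate and unit conventions

Cell centroids are micrometers in image convention (origin top-left, y
increasing downward). Every geometric operation uses Euclidean distances
only, so the orientation convention never affects a result; all geometry
is invariant under translation and rotation (verified by test). Densities
are reported per mm^2; a disk of radius r um has area `pi * (r/1000)^2`
mm^2, so 3 neighbors within 100 um correspond to 95.49 cells/mm^2.

## BET triads

Endothelial cells (CD31+ PanCK- in the IMC panel this models) carry a
major-axis length — the longest cell diameter from segmentation, taken as
supplied and never re-derived. A lymphocyte is *in contact* with an EC
when their centroid distance is at most `boundary_multiplier x
major_axis`; the default multiplier is 2 and the boundary is inclusive
(a cell at exactly 2x the axis counts). An EC with at least one contact B
cell and at least one contact T cell anchors one triad; ECs with a single
contact class or none are discarded.

Two counting units are reported because either could be meant by "number
of triads": the EC-centric count (primary; one triad per qualifying EC)
and the number of distinct B x T contact pairs over triad ECs
(`n_triples`). Rates divide the EC-centric count by ROI area; per-ROI,
per-TLS and per-mm^2 figures are all derivable from the outputs. The
T-cell classes default to all CD4/CD8 states plus Tregs (all CD3+) and
are configurable, as is the 1x-axis boundary variant via
`boundary_multiplier=1`.

Detection is exactly equivalent to the O(n^2) all-pairs scan (tested on
random fixtures); the KD-tree is an implementation detail.

## Neighborhood densities

The proximity graph joins cells of one ROI whose centroid distance is
<= 100 um (inclusive, configurable). Anchored density counts
target-phenotype cells within the radius of each anchor (the anchor never
counts itself), divides by the disk area, and averages over anchors per
ROI — the per-anchor mean is the primary aggregate, with a pooled variant
available. TLS membership comes from an explicit `tls_id` column; TLS
area defaults to the convex hull of the member centroids (no mask format
is assumed) with a fixed-radius disk override. The activation/exhaustion
ratio divides activated by exhausted T-cell density within the same TLS;
a zero exhausted density yields a missing value, never infinity.

## Single-cell QC

Cells are kept when detected genes (count > 0) lie in [200, 6500] and the
mitochondrial count fraction is <= 15%. The bounds are phrased as removal
of cells *below/above* them, so boundary cells survive — 200 genes or
exactly 15% mito is kept. Removal reasons are reported per cell with the
priority low_genes > high_genes > high_mito; the filter is idempotent.
"Genes" means genes detected, not UMIs, and the mito criterion is skipped
with a warning (never silently) when no gene carries a mitochondrial flag.

The doublet rule flags cells expressing markers (raw count > 0 by
default; configurable) from two or more distinct lineage sets: epithelial
(SFTPC, SCGB3A1), T (CD3D), B/plasma (CD79A, JCHAIN, MZB1), myeloid
(MARCO, CD163). T and B/plasma are kept as separate lineages — a
CD3D+CD79A+ cell is biologically a T-B doublet. Pan-immune markers
(PTPRC) are excluded from the rule because co-expression with PTPRC is
universal for immune cells and carries no doublet signal.

## Module scores and cell-of-origin

Expression is normalized as log1p of counts scaled to 10,000 per cell
before scoring (standard, configurable). The module score of a cell is
the mean normalized expression over the signature genes minus the mean
over a control pool: for each signature gene, up to `n_ctrl = 100` genes
are sampled (seeded, without replacement) from its expression bin —
`n_bins = 24` equal-count bins over gene-wise mean expression — excluding
the signature genes themselves; the pooled union forms the control set.
Subtracting bin-matched controls removes the component of the signal
explained by expression level, which makes the score invariant to adding
a per-cell constant (tested) and centers it near zero for uninformative
sets. The binning/control defaults are the canonical values for this
scoring family and both are exposed as parameters; agreement with an
independent implementation (scanpy's `score_genes`) is verified in the
test suite by correlation and recovered group separation.

Tumor cells are labeled AT2-like or club-like by the larger of the two
scores (exact ties labeled `tied`). A patient's origin call is the
majority label, requiring at least `min_cells = 20` tumor cells, a
winning fraction of at least `min_majority = 0.6`, and a positive
patient-mean winning score (`min_score = 0`); otherwise the patient is
unassigned. These thresholds are not canonical — they were chosen so that
all three outcomes (AT2-like, club-like, unassigned) are reachable under
realistic mixtures, and all are configurable. A `mean_score` method is
also provided that compares patient-mean AT2 vs club scores instead of
the cell majority; majority is the default.

## CNV cell scores

Input is a cells x genes matrix of CNV values centered at 0 (a `center`
flag subtracts 1 from 1-centered matrices) plus a gene -> chromosome-arm
map. The per-arm score is the mean of squared values over that arm's
genes; the cell score is the unweighted mean over arms. Squaring makes
gains and losses count alike: for i.i.d. Normal(0, sigma) noise
E[score] = sigma^2 (verified within 5% at 10^4 cells x 100 genes), and
one arm shifted by `a` among `k` arms with no noise scores exactly
`a^2/k`. Cluster aggregation is per-cell first, then the cluster mean.

"Elevated" is quantified as cluster mean > reference mean + `k_sigma`
(default 2) reference standard deviations, computed from at least 10
normal-tissue cells. Auxiliary evidence used in practice (nodule-sample
enrichment, mixed marker expression) belongs in annotations, not in the
hard criterion.

## Spot statistics

Spot expression is normalized as log1p of depth-scaled counts (10,000 per
spot). The spatial significance score of a gene is its standard deviation
across spots (ddof = 1); this reading — plain across-spot s.d., not a
variance of a spatially smoothed field — is the only computation the
phrase "spatial standard deviation" directly supports, and a
moving-window residual variant was deliberately not made the default.
Candidate genes are the top n per sample (ties broken lexicographically
by gene id so selections are bit-stable), intersected across samples.

The rank-recovery score ranks a spot's genes by expression (ties by gene
id) and integrates the signature-recovery curve over the top
`top_fraction = 5%` of ranks, normalized by the maximal achievable area —
an AUCell-style statistic in [0, 1], invariant to monotone transforms of
a spot's expression. Coexistence is the Pearson correlation of per-spot
cell-type counts across spots; zero-variance types yield flagged missing
entries.

## Comparison layer

Patient-matched compartment values use the Wilcoxon matched-pairs
signed-rank test: zero differences are dropped (classical convention; the
all-zero case returns p = 1), the exact null distribution is used up to
n = 25 non-zero pairs and the normal approximation with continuity
correction above. Exactness is verified against full 2^n sign
enumeration, and the type-I error at alpha = 0.05 is calibrated within
[0.03, 0.07] under a Gaussian null (n = 12, 10,000 replicates).

Unpaired comparisons run through a variance gate: Levene's test at
alpha = 0.05 routes to Mann-Whitney U when significant, otherwise to
Student's t-test. Using an equality-of-variance statistic as a
*normality* gate is statistically questionable — Levene's test does not
test normality — but it is reproduced deliberately as the convention this
package standardizes on; both branch p-values are always retained in the
result object, and a Shapiro-Wilk gate is available behind
`gate="shapiro"` for users who want an actual normality screen. No
multiple-testing correction is applied by default (per-comparison p-values
are reported); Benjamini-Hochberg adjustment is available as a helper.

## Synthetic data: what it emulates and what it does not

The generators exist to make every detector testable with exact ground
truth, not to be a tissue simulator.

*ROIs* are homogeneous Poisson point patterns per phenotype (defaults of
20–600 cells/mm^2 by phenotype over a 1.5 x 1.5 mm ROI, loosely scaled to
lung IMC fields) with three planted structures: triad ECs (each given one
B and one T cell at uniform angle and radius in (0, 2a]), distractor ECs
(one lymphocyte in contact, the other class placed at (2a, 4a] so
boundary behavior is exercised), and TLS disks (150 um radius, 200 cells:
a B-cell core within 60% of the radius and an activated/exhausted T-cell
ring). Planted geometry is *certifiable*: ECs are mutually separated and
background lymphocytes are rejection-sampled out of a 4x-axis exclusion
disk around every EC, so the planted triad set provably equals the
complete triad set. Real tissue has no exclusion zones, no circular TLSs
and strong spatial inhomogeneity — passing recovery tests demonstrates
correctness of the detector logic and boundary conventions, not
performance on real images.

*Expression* is Gamma-Poisson (negative binomial, dispersion shape 10)
with lognormal library factors (sigma 0.25). The AT2 and club programs
are 10-gene blocks at base means 20 and 8 whose log-means shift by
`program_delta` in program cells; an optional patient purity parameter
links programs to patients. The two program blocks sit at different base
expression strata, and a block of ~200 housekeeping-like genes spans the
upper decades, so the programs fall into different mean-expression bins
and do not contaminate each other's control pools — with both programs in
one bin the measured score difference would systematically exceed the
planted shift, which is a property of bin-matched scoring worth knowing
about on real data too. Mitochondrial fractions follow Beta(2, 38) (mean
5%); doublets co-express two random lineage marker sets. Ambient RNA,
batch effects and realistic gene-gene correlation are not modeled.

*CNV matrices* are Normal(0, sigma = 0.05) noise with additive arm shifts
(default +0.5 on 1q) in a tumor fraction of cells. *Spot grids* are
Poisson counts on a 20 x 20 grid, flat except for spatially variable
genes following a linear gradient in a random direction (log-amplitude 2
by default), plus per-spot cell-type counts in which one pair shares a
latent Poisson component (rate 20), producing a planted positive
correlation around 0.6–0.7.

## Problem sizes and numerical choices

Recovery experiments use 1,000 cells x 1,000 genes for module scoring
(the score difference recovers a planted delta = 1 within a few percent),
10^4 cells x 100 genes for the CNV noise expectation, 50 seeds x (7
triads + 5 distractors) for triad recovery, and 10,000 replicates for
signed-rank calibration; these sizes make the full suite and the
acceptance script each run in well under a minute of compute per stage on
one CPU. All randomness flows from a single integer seed per generator
(`numpy.random.default_rng`); derived stage seeds use `SeedSequence`
spawning. Ties are always broken deterministically (gene id
lexicographic), boundary comparisons are inclusive, and degenerate inputs
(zero totals, empty TLSs, all-zero differences, zero-variance types)
return defined values or explicit errors rather than NaN surprises.

## Known limitations

Per-cell segmentation quality, marker spillover and intensity
normalization are upstream of this package: it starts at segmented cell
tables and count matrices. TLS areas from convex hulls underestimate
concave structures. The EC-centric triad count ignores how many distinct
vessels a lymphocyte touches; the triple count partially compensates.
Module-score behavior depends on the expression binning as noted above.
The comparison layer implements per-comparison inference only; study-wide
error control is the caller's responsibility.
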