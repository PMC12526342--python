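# Methods

This note documents the models and estimators implemented in `aridpop`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical decisions that matter for
reproducing results.

## Data model and conventions

Genotypes are diploid alternate-allele dosages in {0, 1, 2, missing}.
Positions are 1-based and all intervals — gene features, scan windows,
SNP padding — are closed, the native convention of both VCF and GFF3, so
no half-open conversions occur inside the pipeline (the windowed-FST CLI
output additionally emits a BED-compatible 0-based start column).
Chromosome names are opaque strings in natural sort order (PC2 < PC10).
Phase is accepted on input and discarded; no analysis here uses it.
Haploid or polyploid calls are rejected rather than coerced, because
every estimator below assumes diploidy.

## Quality filtering

Thresholds follow standard short-read resequencing practice: per-genotype
DP ≥ 5 and GQ ≥ 20 (inclusive), per-site QUAL ≥ 30 and MAF ≥ 0.05
(inclusive), per-site missingness < 10% and per-sample missingness ≤ 20%
(both strict on the stated side). MAF is computed on non-missing calls
only. Missingness fractions are computed as missing-count / n rather than
1 − called-fraction so that exact-threshold cases (1 missing call in 10)
compare correctly against decimal cutoffs.

LD pruning is the windowed greedy procedure of PLINK's
`--indep-pairwise`: windows of 50 consecutive candidate SNPs advanced by
5, removing one member of any pair with r² > 0.5 until a full pass is
clean. r² is the squared Pearson correlation of dosages over
pairwise-complete entries (composite LD, matching unphased PLINK
behavior). The pair-removal rule — drop the lower-MAF member, ties to the
later site — is deterministic; the reference tool's exact tie-break is
undocumented, so pruned-set sizes can differ slightly from it on real
data while satisfying the same no-high-r²-pair guarantee.

## Clone detection

Relatedness is the method-of-moments IBD estimator of PLINK `--genome`:
per-pair IBS0/1/2 counts over pairwise-complete polymorphic sites are
equated to their expectations given IBD state, using the finite-sample
allele-count corrections of the original estimator, with allele
frequencies taken from the full retained sample set (no founder panel is
assumed). The raw moment estimates can leave the probability simplex;
they are projected back (Euclidean projection) before
PI_HAT = P(IBD=2) + P(IBD=1)/2, so threshold semantics stay bounded.
Pairs with fewer than 100 complete sites are flagged low-confidence but
kept. Clonal groups are connected components of the PI_HAT ≥ 0.95 graph;
each multi-member group retains its minimum-missingness member, ties
broken lexicographically, so the retained set is reproducible.

## Ancestry (sNMF-style factorization)

Genotypes are one-hot encoded (three classes per site; missing cells
carry the site's empirical class frequencies) and factored as X ≈ QG by
alternating nonnegative least squares: Q rows are projected to the
probability simplex and each G row's per-site 3-block renormalized after
every half-step. The NNLS subproblems are solved exactly by cyclic
coordinate descent on the normal equations, vectorized across all
columns — the same fixed points as per-column active-set NNLS at a small
fraction of the cost. Initialization is uniform random from the run seed;
K = 1 uses its closed form (Q = 1, G = class means). The sparsity
parameter of the reference method is effectively 0 here (no extra
regularization); this is the documented default, not a tuned value.

K is selected by the cross-entropy criterion: 5% of observed genotype
cells are masked (re-drawn per replicate together with the
initialization, from a `SeedSequence(seed, K, replicate)` stream), the
model is refitted, and the mean negative log-probability of the true
classes at masked cells is computed with probabilities floored at 1e-10.
**best_K minimizes the per-K mean across replicates.** The per-K minimum
was evaluated and rejected: it rides on mask/initialization noise and is
regularly won by a neighboring K (an observed margin of 0.002 nats), while
the mean tracks the elbow of the replicate cloud; the full table is
returned so either summary can be recomputed.

Cluster labels are the Q-row argmax (1-based; ties to the lowest index),
with an "admixed" flag below 0.5. DAPC takes these labels as given — it
validates rather than re-clusters — using mean-imputed, standardized
dosages, PCA to 40 components (capped at the data rank), and LDA with
pooled within-group covariance for posteriors.

## Diversity

Ho is the heterozygous fraction of non-missing calls per sample. He is
per group: the mean over sites of 2p(1−p) · 2n/(2n−1), Nei's unbiased
small-sample correction on the allele count (this was verified to give
mean F ≈ 0 in a Hardy–Weinberg deme; a diploid-count n/(n−1) factor
over-corrects by ~1/(2n) and leaves a spurious positive F). F = 1 − Ho/He
uses the sample's group-level He — the only reading consistent with
per-group comparisons of a per-sample F; a global-He variant is a trivial
caller-side substitution. The π proxy divides heterozygous calls by *all*
sites in the analyzed matrix (missing included), the only denominator
constant across samples; it therefore never exceeds Ho. Group differences
use one-way ANOVA and Tukey HSD (statsmodels); the all-constant
degenerate case reports F = 0, p = 1 rather than dividing by zero.

## Differentiation

Per site and population pair, the Weir–Cockerham (1984) two-population
diploid variance components are computed from sample sizes, alternate
frequencies and heterozygote fractions:

    a — among-population, b — among-individual, c — within-individual,
    theta = a / (a + b + c)

Genome-wide, per-window and pairwise values use the weighted
(ratio-of-sums) form Σa / Σ(a+b+c), the quantity VCFtools reports;
estimates are left unclipped (slightly negative values are informative).
Sites with non-positive total variance are excluded from ratios. On tiny
hand fixtures the estimator behaves exactly as the algebra dictates: a
fixed difference gives theta = 1, the all-heterozygous two-population site
gives (a, b, c) = (0, −0.25, 0.5), theta = 0; note the estimator subtracts
expected sampling variance, so identical demes give slightly *negative*
point estimates on small fixtures and approach 0 only in expectation.

Windows are 50 kb with a 10 kb step, anchored at position 1 of each
chromosome (anchoring is a convention, recorded in output headers).
Outlier windows are those at or above the empirical 99th percentile
(linear interpolation) of defined window values, computed per comparison.
Outlier SNPs are the SNPs inside outlier windows; genes are collected when
they overlap an outlier SNP ± 2500 bp (closed intervals, deduplicated by
gene id). Padding SNPs rather than windows follows the more specific of
the two conventions in circulation; both differ only at window edges.

## Introgression (ABBA–BABA)

Site patterns use population alternate-allele frequencies
(Dsuite-style), e.g. ABBA = (1−p1)p2p3(1−pO) + p1(1−p2)(1−p3)pO, and
D = (ΣABBA − ΣBABA)/(ΣABBA + ΣBABA). Significance comes from a
delete-one block jackknife over contiguous 1 Mb physical blocks (a
physical block is used because SNP-count blocks depend on ascertainment;
the size is configurable and recorded). Z = D/SE and p is two-sided
normal. The f4-ratio splits P3 into two seeded random halves:
f4(P1,P2;P3a,O) / f4(P1,P3b;P3a,O), a direct admixture-fraction estimate
(it recovers planted fractions within ~0.01 on average at f = 0.15).
Quartets are taken as given — no BBAA-maximizing reordering — with a
warning when BBAA is not the largest sum. Per-chromosome scans jackknife
within the chromosome and flag Z > 2; with few blocks per chromosome the
Z estimate is noisy, so the chromosome carrying the *largest D* is the
more reliable localization readout and is what the recovery suite checks.
This stage should consume the unpruned filtered matrix: LD pruning
removes exactly the correlated sites that carry the signal.

## Phylogeny

Distances are 1 − cosine similarity of dosage vectors over sites
non-missing in both samples (zero-norm vectors give distance 1 with a
warning; a pair sharing no sites is an error). Neighbor joining is the
Saitou–Nei agglomeration with the standard Q criterion, lowest-index
tie-break, three-point termination at a trifurcating root, and negative
branch lengths clipped to zero with the clipped total recorded. On
additive matrices the tree reproduces input path lengths to 1e-9 (tested
against an independent NJ implementation on random matrices). Bootstrap
support resamples SNP columns with replacement, recomputes distance and
tree, and scores each internal edge of the reference tree by the
percentage of replicates containing the same leaf bipartition
(orientation-free canonical form; branch lengths ignored).

## LD decay

All intra-chromosome SNP pairs within 300 kb contribute (distance, r²)
points per sample group; points are averaged in 100 bp bins and a cubic
least-squares B-spline with 8 basis functions is fitted to bin means,
weighted by pair counts. Interior knots are log-spaced in distance:
decay curvature concentrates near zero, and uniform knots under-resolve
the initial drop (log knots cut the half-decay error on a known
exponential from ~9% to ~2-3%). The curve is evaluated on a grid at the
bin width, clipped to [0, 1]; the reference maximum is the fitted value
at the smallest bin — not a global maximum, protecting against smoother
wiggle — and the half-decay distance is the first crossing of half that
value, linearly interpolated, or absent if never crossed.

## Flower-expansion layout

Markers within ε = 1e-4° of each other (transitive closure) are placed at
angles 2πk/m on a circle of radius 5e-3° around their group centroid
(angle 0 north, clockwise, k ordered by sample id), so the centroid is
preserved exactly and the minimum separation is 2R·sin(π/m). For m > 7
the radius grows as R·(1 + (m−7)/14) to keep petals from colliding.
Geometry is planar in degrees — displacements are ≪ 1°, so geodesic
corrections would change nothing visible.

## Synthetic-data generator

Demes follow the Balding–Nichols model: per site an ancestral frequency
p ~ U(0.05, 0.95), deme frequency ~ Beta(p(1−F)/F, (1−p)(1−F)/F), so
Var = p(1−p)F and expected pairwise Weir–Cockerham FST between demes i
and j is ≈ (F_i + F_j)/2 — making recovery targets analytic, which is why
this model was chosen over a coalescent back end (a documented extension
point). Defaults mirror the target study's shape at desk scale: 4 demes,
114 samples (29/29/28/28), drift F = (0.02, 0.03, 0.05, 0.12) with a
low-diversity fourth deme, 15 chromosomes PC1–PC15 of 5 Mb, 10,000 SNPs.
Optional per-deme F_IS introduces a within-deme heterozygote deficit
(genotypes drawn with P(het) = 2p(1−p)(1−F_IS)) so an isolated deme can
show both low Ho and high F. Admixture uses Dirichlet Q rows biased
toward the home deme. Clonal copies flip genotypes at a configurable
error rate and blank cells at a missing rate. Quality fields guarantee
that non-planted sites/cells pass the default filters, and planted
failures (low QUAL, ≥10% missing, MAF < 0.05, extra ALT allele, low
DP/GQ cells) are disjoint across rules and recorded in the truth, so the
filter ledger can be checked exactly.

The quartet generator drifts (((P1,P2),P3),O) with per-branch
Balding–Nichols steps — defaults F = 0.05 (root→internal), 0.10
(internal→(P1,P2) and →P3), 0.03 (tips), 0.30 (outgroup), i.e. moderately
diverged ingroups with a clearly external outgroup — and implements gene
flow by replacing the recipient's frequency with the donor's at a
fraction f of (optionally one-chromosome) sites.

**What the generator does not emulate:** linkage. Sites are independent
draws, so genuine recombination-driven LD decay curves cannot arise from
it; LD-decay recovery is therefore validated on pairs generated from a
known r²(d) curve, and the group-contrast behavior on real data (shorter
half-decay in larger-Nₑ groups) is outside what these tests can show. It
also omits sequencing-read realism (base errors correlated with depth),
reference bias, and any geographic genetic gradient beyond discrete deme
centers. Passing the recovery suite demonstrates estimator correctness
under the stated models, not robustness to artifacts absent from them.

## Problem sizes in the test and acceptance suites

Recovery runs use the scales at which their targets are statistically
crisp while keeping the whole suite fast on one core: FST recovery at
2×100 diploids × 10,000 SNPs; the clone panel at 204 samples × 3,000
SNPs; K selection at 80 samples × 800 SNPs with 5 replicates × K = 1..10;
D-statistic calibration at 100 null and 50 introgressed quartets of
4×20 samples × 10,000 SNPs; bootstrap support with 200 replicates.
These sizes are the package's chosen study conditions for validation;
estimates at larger sizes only tighten.

## Known limitations

- The LD stage applies no extra MAF/missingness filtering of its own;
  it analyzes whatever matrix it is given.
- The f4-ratio uses a single random split of P3; averaging over splits
  would reduce its variance at extra cost.
- DAPC's 40-PC default is taken as given (no a-score optimization).
- `pairwise_relatedness` is O(n² · sites) in memory-light matrix form;
  beyond ~10⁴ samples it would need chunking.
- The orchestration layer (`pipeline.run_all`) proceeds when no GFF3 is
  supplied (FST outliers are reported without gene context) rather than
  refusing to run the scan stage.
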