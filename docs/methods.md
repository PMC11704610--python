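# Methods

## Generative model

Counts are drawn as a Gamma–Poisson mixture per gene and cell: a latent
rate λ ~ Gamma(shape = f, scale = b) and an observed count
Poisson(λ·s), where s is the cell's extrinsic size factor. With s = 1
this is exactly NB in the bursting parameterization (size r = f,
p = 1/(1+b)), so mean = b·f and Fano = 1+b hold in closed form and the
simulator is the distribution the inference stage fits — parameter
recovery tests are therefore well-posed. b = 0 uses the Poisson limit
with rate f (convention: the "mean" of a b = 0 gene is f).

mRNA lifetime is normalized to 1 and assumed unchanged by treatment, so
burst frequencies are per-lifetime and only relative quantities (fold
changes) are interpreted downstream. Time and area units are arbitrary.

**Extrinsic layer.** s = (A/Ā)^η with A lognormal(μ_logA, σ_logA) and
Ā the realized mean area of the cell's condition × replicate block
(using the realized rather than the theoretical mean keeps the factor
centered at 1 in every replicate; with η = 0 the factor is exactly 1).
η = 1 gives the linear count–size correlation that the extrinsic filter
targets. Defaults: η = 1, σ_logA = 0.25 (≈ 25 % area CV, a typical
cultured-cell spread); `area_shift_treated` multiplies treated areas to
construct datasets with a deliberate size confound.

**Technical layer (UMI arm).** Each molecule is captured independently
with the cell's probability β: observed = Binomial(true, β). For
uniform β this maps NB(b, f) → NB(β·b, f) exactly, which is the engine
of the noise-underestimation phenomenology: observed
ΔFano = (1+β·c·b)/(1+β·b) < (1+c·b)/(1+b) for any β < 1, c > 1,
while Δmean is untouched. β defaults to 0.1 (a typical droplet-platform
capture efficiency); `capture_sd = 0` selects the exact uniform-β mode
used by the analytic tests, `capture_sd > 0` a logit-normal β with the
spread mapped from the probability scale by the delta method.

**Treatment.** The treated condition uses (c·b, f/c), c ≥ 1, so
intrinsic means match exactly between conditions; c defaults to 2.
Default experiment size: 200 cells × 3 replicates per condition
(smFISH-scale); analyses that need tighter sampling error pass larger
`n_cells` explicitly.

Ground truth (per-gene parameters, per-cell areas and capture
probabilities) is returned with every dataset but consumed only by
tests, never by analysis stages.

## Noise metrics

Per-gene summaries use the unbiased (n−1) sample variance — cell counts
per replicate are modest (~50 for imaging data) so the bias of the n
denominator would be material. CV² = σ²/μ², Fano = σ²/μ; genes with
μ = 0 are flagged `undefined` rather than dropped. Fold changes are
treated/control ratios computed after replicate averaging (arithmetic
mean of each metric over replicates; a gene must be present in every
replicate — no imputation). Depth normalization divides each cell by
its total count and rescales to 10⁴; fold changes for count matrices
are computed on normalized values, for cell tables on raw spot counts.

QC boundary semantics: minimum thresholds inclusive (≥), maximum
thresholds and the mitochondrial fraction strict (<). The gene coverage
filter (mean ≥ 0.1 and detection ≥ 5 % of cells, per condition,
intersection across conditions) is a configurable stand-in for
pipeline-specific defaults; both thresholds are exposed.

## Rank tests

The paired Wilcoxon signed-rank test drops zero differences
(Wilcoxon's original policy). For n ≤ 25 the p-value is exact, computed
by dynamic programming over the permutation distribution of W⁺
conditional on the observed mid-ranks — valid under ties among |d|,
which scipy's exact method refuses; larger samples use the normal
approximation with continuity correction. The rank-sum test delegates
to `scipy.stats.mannwhitneyu` (exact for small tie-free samples). Both
paths are cross-checked in the tests against brute-force enumeration of
sign patterns / label subsets.

## Extrinsic filter

The permutation test uses |mean(A) − mean(B)| of areas as its statistic
(the simplest location statistic for "are the area distributions
indistinguishable"), with p = (1 + #{≥ observed})/(1 + n_perm). The
default resampling draws labels with replacement (bootstrap-style);
a classical without-replacement mode and an exhaustive-enumeration mode
are provided, and the tests confirm all three agree within Monte-Carlo
error on small groups. α is compared strictly (stop requires p > α).

Percentiles use linear interpolation between order statistics, computed
on the pooled (both-condition) area vector; boundary cells are kept
(inclusive), so all-equal areas are a stable fixed point. Iterative
2/98 trims are recomputed on the pooled survivors each round, mirroring
the initial pooled 5/95 trim. Each round removes the trim tails, so the
retained set shrinks weakly and max_iter = 25 bounds the loop (deeper
recursion would exhaust the ≥ 50 cells/treatment requirement anyway;
falling below it raises a warning flag, an emptied condition is an
error with the iteration trace attached).

Convergence additionally requires |r| < 0.45 for the count-vs-area OLS
in *each* condition separately. The size-corrected metric regresses
count on area per condition and takes the residual variance with
ddof = 1 (not n−2) so corrected σ² ≤ raw σ² holds exactly, at the cost
of a slight downward bias; corrected mean is the raw mean and CV²/Fano
are recomputed from the pair.

## Burst inference

NB fits maximize a single-parameter profile likelihood over log r with
p(r) = r/(r+μ̂) in closed form from the first-moment condition, bounded
bracket ±12 natural-log units around the method-of-moments start
r₀ = μ²/(σ²−μ). This makes the implied mean equal the sample mean by
construction and is derivative-free and robust. Samples with σ² ≤ μ
have no interior optimum and return a flagged Poisson-boundary fit
(b = 0, f = μ — the b = 0 mean convention above); absurdly large r̂
(> 10⁶·μ) is folded into the same boundary rather than reported as an
unstable estimate. Fits require ≥ 25 cells.

Fold changes Δb, Δf are formed per gene × replicate and aggregated as
the mean of per-replicate log₂ values with their SEM; a pooled-counts
fit is emitted alongside (both views are standard). The reciprocity
regression is OLS of log₂Δb on log₂Δf with parameter standard errors;
replicate spread (not fit uncertainty) is the default error source for
the per-gene SEMs.

The homeostasis report classifies each gene with two tolerances
(defaults 0.25 on the log₂ scale): proportional b,f scaling
(|log₂Δb − log₂Δf| ≤ tol) with a moved mean ⇒ *mean_shifted*; stable
mean with opposite-direction b,f ⇒ *homeostatic*; anything else ⇒
*non_reciprocal_outlier*. The accompanying tests are one-sample
signed-rank tests of the per-gene log fold changes against 0 —
equivalent to the paired treated-vs-control test across genes — with
the directional alternatives: mean two-sided, CV²/Fano/b greater,
f less.

## Scoring

χ = median over genes of ((D−E)/E)², S the plain sum of the three χ.
The standard median (central-pair average for even n) is used; genes
with zero or missing reference are excluded pairwise per metric with
counts reported. Ranking ties break lexicographically by method name.
The underestimation report counts genes whose fold change sits strictly
closer to 1 than the reference on the log scale (ties count as
neither) and reports the median of |log₂D| − |log₂E|.

## Pipeline and reproducibility

One global seed is expanded into per-stage substreams via
`numpy.random.SeedSequence` spawn keys, so inserting a stage does not
shift the randomness of the others; the smFISH and UMI generators are
salted separately and per-condition × replicate streams are
independent (with c = 1, treated and control are exchangeable draws).
Identical (config, seed) pairs reproduce outputs bit-identically; the
run manifest records a hash of the scientific configuration (output
directory and log level excluded) plus a sha256 per output file. Floats
serialize with 9 significant digits; tables are TSV/CSV with headers.

## What the synthetic data does and does not show

The generator reproduces the statistical skeleton of a
noise-perturbation experiment: NB marginals with known (b, f), a
size-coupled extrinsic component, reciprocal treated/control parameter
pairs, replicate structure, and binomial capture. It does not emulate
gene–gene correlation structure, cell-cycle or burst-kinetics dynamics
(no promoter-state trajectories), amplification noise beyond binomial
thinning, batch effects, or mappability artifacts. Passing tests
therefore demonstrate correctness of the estimators and algorithms
under the stated model, and the *mechanism* of capture-driven noise
underestimation — not calibrated magnitudes for any particular
platform or cell type: the extrinsic coupling (η = 1) and capture
efficiency (β = 0.1) defaults are field-typical placeholders, not fits
to a specific dataset.

## Problem sizes

Analyses in the test-suite and acceptance script use: n = 10⁵ cells for
moment checks (sampling error ≪ the 3 % tolerance), n = 10³ × 50 seeds
for MLE recovery, 5 replicates × 5000 cells for summary-level fold
changes, 3 × 10⁴ cells per condition for the per-gene 5 % thinning
checks, and 10 seeds × 300 cells for filter convergence — sizes chosen
so that each tolerance sits several sampling standard deviations away
from its pass boundary.
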