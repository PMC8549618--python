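# Methods

`methscales` analyses DNA-methylation differentiation between groups of
individuals at three scales — whole methylome, per chromosome, and local
differentially methylated regions (DMRs) — and relates it to genetic
structure.  The motivating design is a two-river, two-rearing-environment
salmonid sperm-methylome study: whole-genome bisulfite sequencing of
hatchery- and wild-born males from two rivers, where the question is whether
rearing environment leaves methylation marks that parallel across rivers and
are not explained by genotype.  This note records the models, the defaults
and why, the numerical choices, and what the synthetic data does and does
not emulate.

## Methylome preprocessing

Per-sample symmetric-CpG counts (MethPipe-style tables or Bismark coverage
files) are merged per dyad: the plus-strand cytosine at position *p* and the
minus-strand cytosine at *p*+1 are summed and reported at *p*.  Coordinates
are 0-based half-open internally; 1-based dialects are converted on read.
Fraction-encoded inputs are converted to counts by round-half-up of
fraction × coverage (deterministic across platforms).

Cells with coverage below 10× are treated as missing.  For ordination,
methylation is averaged over non-overlapping 1-kb windows (step 1 kb); the
window value is the **unweighted** mean of per-CpG fractions (coverage
weighting is deliberately not applied — "mean methylation" in the windowing
tradition of MethPipe), and a window is kept only when *every* sample has at
least 3 covered CpGs inside it.  This complete-case rule produces the
gap-free matrix that the Euclidean distance requires; the alternative
(pooling CpG counts across samples) would let sample-specific coverage
deserts leak missingness into the distance computation.

## Ordination engine

All multivariate tests run through one stack:

* **Distance**: Euclidean between sample rows.
* **PCoA**: Gower double-centering of −½D², symmetric eigendecomposition,
  coordinates = eigenvectors × √λ.  Axes with λ ≤ 10⁻¹⁰·λ₁ are dropped;
  negative eigenvalues are discarded without Lingoes/Cailliez correction,
  because Euclidean input distances guarantee non-negativity up to rounding.
* **Axis retention**: axes representing at least 3% of the variation
  (inclusive comparison) form the response matrix of the db-RDA.
* **(Partial) RDA**: explanatory factors are centered treatment indicators;
  interactions are elementwise products of centered indicators; the
  intercept is implicit because the response is column-centered.  R² is the
  projected fraction of the total sum of squares; the adjustment is
  Ezekiel's, adjR² = 1 − (1 − R²)(n − 1)/(n − p − 1) with p = rank(X).  For
  partial models, Y and X are residualized on the covariates Z and the
  reported adjusted value is adjR²(X+Z) − adjR²(Z) (the semipartial
  convention used by `vegan::RsquareAdj`; the test suite checks exact
  agreement with vegan).
* **Permutation test**: pseudo-F = (SS_X|Z/p)/(SS_res/(n−p−q−1)); rows of Y
  (or of the reduced-model residuals when covariates are present — the
  standard scheme for constrained ordination) are permuted; p = (1 + #{F* ≥
  F})/(1 + n_perm).  The loop is vectorized by applying all permutations to
  the orthonormal bases in one matrix product, which makes 500-simulation
  calibration runs take seconds.
* **Forward selection**: greedy; at each step the candidate with the lowest
  permutation p (ties broken by larger F) is added if p ≤ 0.05.  Forward
  only — with two candidates (river, environment) stepwise elaborations add
  nothing.
* **Variance partitioning**: fractions from adjusted R² of [X1], [X2],
  [X1+X2]; pure₁ = adjR²(X1+X2) − adjR²(X2), shared = adjR²(X1) + adjR²(X2)
  − adjR²(X1+X2).  Adjusted fractions can be slightly negative by
  construction.

Per-chromosome analysis is this same stack applied to the chromosome-sliced
window matrix; the pipeline reports raw per-chromosome p-values (no
correction across the chromosome models, matching common practice at ~30
models), with an optional Benjamini–Hochberg column that is off by default.

## Per-CpG differential-methylation test and DMR calling

The CpG-level model is a documented re-implementation of the
arcsine/weighted-least-squares dispersion-shrinkage approach for
beta-binomial bisulfite counts (the multifactor variant, which does not
smooth across neighbouring CpGs):

1. transform Y_ij = arcsin(2·X_ij/N_ij − 1);
2. weighted least squares of Y on the design
   `~ environment + river + environment:river` with weights N_ij;
3. per-site residual variance s²_i (df d_i) shrunk toward the genome-wide
   mean residual variance with weight w = d_i/(d_i + d₀), d₀ = 20 (fixed;
   empirical-Bayes moderation of the same flavour as limma/DSS — large
   enough to stabilise 24-sample variances, small enough not to flatten
   genuine heteroscedasticity);
4. Wald statistic per term against a two-sided normal reference.

**Missing-data rule.** Cells below the 10× floor receive zero weight rather
than excluding the whole site; a CpG is tested when every river×environment
cell retains at least two covered samples and positive residual df.  A
strict all-samples-covered rule would discard essentially every CpG at ~15×
mean coverage (P(all 24 samples ≥ 10×) ≈ 0), which no count-based caller
does in practice.

**Region rules** (defaults): flag CpGs with p < 0.01 (ties at the threshold
are not significant); candidate regions are maximal CpG runs that start and
end at flagged CpGs and keep the flagged fraction ≥ 0.4 under greedy
left-to-right extension with trailing unflagged CpGs trimmed; candidates
must span ≥ 100 bp (interval closes 2 bp after the last CpG, covering the
dyad) and contain ≥ 10 CpGs; surviving regions with a genomic gap ≤ 50 bp
are merged; finally only regions with |mean methylation difference| strictly
greater than 0.10 are kept.  Runs live in CpG-index space — genomic distance
enters only through the span and merge rules.  Group means are unweighted
(per CpG, mean over per-sample fractions in the group; then mean over the
region's CpGs).  Direction is *hyper* when the focal (hatchery) group is
more methylated; the hyper:hypo balance is tested with the df = 1
equal-proportions χ².

## Randomization null for DMR counts

False discovery is controlled at the region-count level: environment labels
are permuted within each river (group sizes preserved, rivers independent;
some samples may land in their true group), the full model → caller →
effect-filter chain is re-run per replicate, and the observed count gets the
add-one empirical p = (1 + #{count* ≥ observed})/(1 + n_reps), with a 95%
interval from the empirical 2.5/97.5 percentiles (linear, type-7
interpolation).  The replicate counts pass through the same >10% effect
filter as the observed count (configurable, since a pre-filter count is an
equally defensible null statistic).

## Genetic structure

Variants are filtered to biallelic SNPs with QUAL ≥ 20; genotypes with depth
outside [5×, 100×] are set missing; sites with > 20% missing genotypes (or,
optionally, more than a fixed number of missing individuals) are dropped;
the minor-allele-frequency floor (0.01) is computed from the genotypes that
survive depth masking; C/T and G/A ref/alt pairs are removed because
bisulfite conversion makes them indistinguishable from methylation signal.
Differentiation is Weir & Cockerham's (1984) θ from the variance components
a, b, c, with the overall value as the ratio of sums Σa/Σ(a+b+c) over
informative loci; missing genotypes are excluded per locus and monomorphic
loci are undefined.  Genotype ordination mean-imputes missing dosages (for
the distance only, never for F_ST) and runs the same PCoA → ≥3% axes →
forward selection → partial db-RDA stack.

## Variance partitioning of DMR CpGs

The response is the PCoA of the Euclidean distance between samples over the
CpGs inside a called DMR set, reduced to broken-stick axes: expected
proportion b_k = (1/p)·Σ_{i=k..p} 1/i, axes retained while λ_k/Σλ > b_k,
first failure truncates, floor of one axis.  The genetic explanatory axes
are the leading genotype-PCoA axes reaching 90% cumulative variance, capped
at n − 3 so the model never saturates outright.

**Stability caveat.**  When genetic variation is weak and unstructured (as
in the synthetic cohorts: Balding–Nichols divergence 0.01, no linkage or
relatedness), the genotype eigenvalue spectrum is near-uniform and the 90%
rule retains nearly all n − 1 axes; combined with a one-axis broken-stick
response whose residual variance is tiny, the Ezekiel adjustment becomes
extreme and pure fractions can fall outside [0, 1] (an environment-pure
fraction above 1 simply means the genetic axes explained less than chance on
that response).  Real genotype data concentrates variance in far fewer axes
and does not reach this regime.  Interpret the adjusted fractions
qualitatively near saturation, or pass `response_axes="all"` to
`partition_dmr_variation` to keep residual variance in the denominator —
that unreduced form is also what the constructed-fraction recovery tests
use, because axis subsetting removes residual variance and inflates every
explained fraction.

## Synthetic cohorts

`simulate_cohort` emulates the study design at the CpG-count level (read
simulation, bisulfite conversion error and alignment artifacts are out of
scope):

* 2 rivers × 2 rearing environments × 6 males (configurable);
* CpG positions with geometric spacing (mean 30 bp) along 2 × 300-kb
  chromosomes — genome scaled down ~100× to keep simulation and refitting
  fast while leaving ~20k CpGs and ~600 windows;
* per-CpG baseline methylation Beta(mean 0.70, concentration 3), emulating a
  largely methylated sperm methylome with dispersed per-site levels;
* coverage negative-binomial (mean 15×, size 10); counts beta-binomial with
  φ = 0.05 — the overdispersion model the CpG test assumes;
* 20 planted environment DMRs of 15 CpGs with an additive shift of ±0.25 on
  the proportion scale (hyper:hypo 2:1 in hatchery fish), *identical
  coordinates and directions in both rivers* (parallelism); 20
  river-associated regions of the same geometry.  Effects are additive with
  clamping to [0.01, 0.99] because region-level effects are naturally
  reported as percent-methylation differences; planted regions redraw their
  baseline from U(0.30, 0.65) — differential methylation arises in regions
  of intermediate methylation, and this guarantees the nominal ±0.25 shift
  is never truncated by the clamp;
* genotypes from river-specific Balding–Nichols frequencies at a divergence
  of F_ST = 0.01, identically distributed across environments within a
  river, so environment labels carry no genetic information by construction.

What the generator does **not** emulate: linkage disequilibrium, family
structure/relatedness, spatially autocorrelated methylation, coverage
biases (GC, mappability), bisulfite non-conversion, and C/T SNPs
masquerading as methylation.  Passing recovery tests therefore demonstrate
the statistical machinery under the assumed noise model, not robustness to
these real-data pathologies — the C/T–G/A variant filter, for instance, is
exercised by crafted VCFs rather than by the generator.

`simulate_varpart_matrix` builds samples × CpG matrices whose environment,
genetic-axis and noise components are mutually orthogonalized and rescaled
to exact variance fractions; it is the ground-truth construction for the
variance-partition recovery tests.

## Problem sizes and determinism

Defaults are sized so the full pipeline on the standard cohort runs in
seconds and the 100-replicate randomization on a one-chromosome cohort in
about a minute on one core; the per-CpG fit is batched across sites (one
einsum + batched 4×4 solves), and permutation tests are vectorized across
permutations.  Every stochastic stage takes a seed; the pipeline derives
per-stage sub-seeds from the global seed via CRC-32 of the stage name, so
reruns are bit-identical and any single stage can be reproduced from saved
upstream artifacts.

## Known limitations

* The per-CpG test is a faithful re-implementation of the arcsine/WLS
  dispersion-shrinkage approach, not a bit-compatible clone of any existing
  package; d₀ = 20 is a fixed choice.
* The df = 1 equal-proportions χ² for hyper/hypo enrichment is the standard
  construction; published analyses sometimes report statistics that cannot
  be reproduced from the printed counts by this test.
* Window-level complete-case filtering discards windows with any
  low-coverage sample; at very low coverage this can remove a large genome
  fraction before ordination.
* Adjusted-R² variance fractions degrade near model saturation (see the
  stability caveat above).
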