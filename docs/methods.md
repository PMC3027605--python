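# Methods

This note documents the statistical procedures `metacgh` implements, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions.

## Coordinates and containers

Clones are addressed by chromosome and 1-based basepair midpoint; all bp
intervals are half-open `[start, end)`. Chromosomes are laid head-to-tail
in karyotype order with cumulative offsets (`global_bp`) for genome-wide
plots and tracks. Arm assignment is `position <= centromere -> p, else q`
against a packaged nominal GRCh-era table of chromosome lengths and
centromere midpoints; both are overridable, and no downstream statistic
depends on the build beyond arm labels and chromosome extents. X and Y
clones are loaded but excluded from analysis by default: with male pooled
reference DNA their ratios are confounded with sample sex.

Log2 matrices are samples × clones with NaN for missing measurements.
Replicate spots are collapsed by the mean over non-missing replicates.
Normalization is per-sample median centering — the clone-level counterpart
of subarray median normalization on the physical array, whose print-tip
layout is not recoverable from clone-level data; it removes sample-level
intensity offsets, which is the operative intent.

## Kernel-smoothed recurrence profiles

The gain aggregate at clone c is `Σ_samples max(log2, 0)`; the loss
aggregate uses the negative part. Missing values contribute zero (absent
evidence is not imputed). The kernel-smoothed estimate on grid point x is
the unnormalized Gaussian-weighted sum over clones of the same chromosome,
with kernel width w (standard deviation):

    KSE(x) = Σ_c a_c exp(−(x − p_c)² / 2w²).

The unnormalized sum is used deliberately: it preserves the aggregate-mass
interpretation and is linear in the data (`kse(a+b) = kse(a)+kse(b)`;
duplicating every sample exactly doubles the profile). A Nadaraya–Watson
style normalized variant (divide by the local weight mass; preserves
constants) is available via `normalize=True`; with near-uniform 1 Mb clone
spacing the two differ appreciably only near chromosome ends. Defaults:
kernel width 1 Mb (the array's resolution scale) and grid spacing 50 kb.
Kernel evaluation is truncated beyond 5 kernel widths; each dropped term
has weight < e^(−12.5) ≈ 3.7e-6 and the aggregate truncation error is below
1e-4 of the profile maximum (tested against an exact evaluation).
Smoothing never crosses chromosome boundaries.

**Randomization null.** Each randomized instance permutes the
clone-to-position assignment once, shared across samples — equivalently,
the aggregate vector is permuted over clone positions. This preserves the
between-sample correlation at a locus while destroying genomic location,
which is the quantity under test. (A per-sample independent shuffle is a
configurable alternative.) For m instances the genome-wide maximum (gains)
or minimum (losses) is collected and the threshold is the
`ceil((1−α)(m+1))`-th order statistic — the exact-level randomization
convention, under which a pure-noise profile exceeds the threshold
somewhere in the genome with probability α when `α(m+1)` is an integer
(verified by simulation; α = 1 degenerates to the extreme, so every
profile is "significant" somewhere). Gains and losses get separate
thresholds from separate extremum distributions; this is family-wise error
control per sign. A pointwise empirical-p mode with Bonferroni correction
over grid points is provided as an alternative correction.

## Differential profiles and permutation FDR

For two groups, each tumor's full signed log2 vector is smoothed
individually onto the 50 kb grid (the signed profile, not the sign-split
one: the two-sample statistic below compares full profiles; a sign-split
mode exists behind a flag). Per grid point,

    SNR = |mean_A − mean_B| / (sd_A + sd_B),

with within-group standard deviations on n−1 denominators. If both sds are
zero the SNR is 0 for equal means and +inf otherwise; infinite sentinels
sort above all finite values. The SNR is symmetric in group order,
invariant under adding a constant to every sample and under positive
rescaling of all data, and invariant to row-normalization of the smoother
(the same per-grid factor scales numerator and denominator) — so per-tumor
smoothing defaults to the normalized kernel, which preserves constant
profiles.

Group labels are permuted uniformly with group sizes preserved (default
1000 permutations). For candidate threshold t (the sorted observed SNR
values — an exact step function, not a continuous grid),

    FDR(t) = mean over permutations of #{x : SNR_perm(x) > t}
             / max(1, #{x : SNR_obs(x) > t}),

capped at 1 — a plug-in estimator in the SAM lineage. The raw curve need
not be monotone; it is replaced by the conservative envelope
`FDR*(t) = max_{t' ≥ t} FDR(t')`, which is non-increasing in t and never
smaller than the raw estimate. The q-level threshold is the smallest
observed SNR value with FDR* ≤ q; when the estimate never falls below q the
threshold is reported absent (not an error — asking for regions at an
absent threshold is). Maximal grid runs above the threshold, split at
chromosome boundaries, are reported as bp intervals with peak SNR.

## Shrunken-centroids classification

Training follows the standard nearest-shrunken-centroids construction:
with class centroids x̄_ik, overall centroid x̄_i, pooled within-class sd
s_i, fudge constant s0 (median of the s_i by default; percentile and
explicit override configurable) and m_k = √(1/n_k − 1/n):

    d_ik = (x̄_ik − x̄_i) / (m_k (s_i + s0)),
    d'_ik = sign(d_ik) max(|d_ik| − Δ, 0),
    x̄'_ik = x̄_i + m_k (s_i + s0) d'_ik.

Features with a nonzero shrunken deviation in at least one class are the
selected features; their count is non-increasing in Δ. Prediction
minimizes δ_k(x) = Σ_i (x_i − x̄'_ik)²/(s_i + s0)² − 2 log π_k with class
probabilities ∝ exp(−δ_k/2); discriminant ties break toward the larger
prior, then label order. Priors default to empirical class frequencies.
At Δ = 0, equal priors and s0 = 0 the rule reduces to nearest-centroid in
s_i-standardized coordinates (tested against an independent
implementation; the shrunken centroids themselves are cross-checked
against scikit-learn's `NearestCentroid(shrink_threshold=...)`).

Δ is chosen by stratified k-fold cross-validation (default 10-fold,
degrading to the smallest class size) as the largest Δ whose mean error is
within one standard error of the minimum — the parsimony rule, preferring
sparser signatures. Missing values are imputed before training by the
per-sample chromosome-arm median, keeping local copy-number context.

Arm enrichment of the selected clones is the one-sided hypergeometric
tail: drawing |selected| clones from the array, the probability of at
least the observed count on the arm.

ROC curves rank samples by positive-class probability (or any raw score),
group ties into single steps, and integrate by the trapezoid rule; this
AUC equals the midrank Mann–Whitney U/(n₊ n₋), which the tests assert
exactly.

## Cohort statistics

Group comparisons of categorical characteristics use the Pearson
chi-square without continuity correction, after excluding explicit
"unknown" categories and dropping all-zero rows/columns (df computed on
the reduced table). This choice reproduces the published p-values of the
cohort-characteristics table packaged as a fixture, at printed precision,
across five characteristics. A warning (no exact-test fallback) is emitted
when any expected cell is below 5 — several of those tables trip it.

Logistic regression is a maximum-likelihood GLM fit (IRLS, relative
log-likelihood tolerance 1e-8, max 100 iterations). Complete separation is
detected (single-covariate pre-check plus the fitter's own diagnostic) and
raised as an error naming the covariate; the pipeline records it in the
run report rather than aborting, since near-separation is a property of
strong effects in small cohorts. Effect sizes are odds ratios per
amplification unit, `OR = exp(u·β)` with Wald CI `exp(u(β ± z·SE))`;
the default CI level is 0.90 to match the reporting convention of the
regional-gain analysis this mirrors, with 0.95 available.

## Synthetic cohorts: what they emulate, and what not

A cohort is `log2[s, c] = Σ carried segment amplitudes + offset_s + ε`,
with `offset_s ~ N(0, sample_offset_sd²)` and i.i.d.
`ε ~ N(0, noise_sd²)`; each sample carries each eligible segment with
probability `penetrance` (independent Bernoulli). Draw order is fixed
(offsets, then carriage by sample id and segment list order, then the
noise matrix), so the returned ground truth is reproducible from the seed.

Defaults, chosen once as plausible study conditions: group sizes LM 36 /
PM 37 / M0 25 (the cohort composition of the metastasis-site study design
this generator emulates); noise sd 0.2 log2 (FFPE-grade array noise
scale); sample offset sd 0.05; clone spacing 1 Mb over the 22 autosomes
(2,856 clones, one per complete megabase); shared baseline segments
qualitatively mimicking common colorectal aberrations (gains of 7, 8q,
13q and low-level 20q; losses of 8p, 17p, 18q; penetrance 0.4–0.5); and a
group-specific 20q gain of 0.3 log2 at penetrance 0.8 confined to LM —
the amplitude is a free choice, as no effect-size estimate exists for the
real aberration beyond group profile figures.

Noise is independent across clones by default: that is the simplest model
under which the calibration of the kernel statistics can be verified
exactly (clone exchangeability makes the randomization null exact). An
AR(1)-along-genome option (`ar1_rho`) exists for robustness experiments.
The generator does not model FFPE artifacts, tumor-cell fraction dilution,
replicate spot structure, waviness, or segmentation-scale breakpoint
noise — so passing recovery tests demonstrate the statistical machinery
under its own assumptions, not performance on real arrays.

A covariate generator draws nodal status per group (N+ rates 0.60 / 0.50
/ 0.25 for LM / PM / M0) for exercising the two-covariate regression.

## Pipeline and reproducibility

The pipeline derives each stage's seed deterministically from the master
seed via a seed sequence keyed on (master seed, stage index); stages can
be rerun in isolation and reproduce the full-pipeline outputs, and a rerun
with the same configuration is byte-identical. All outputs are
tab-separated tracks or JSON. Matrix round-trips are bit-exact (`%.17g`
writing, round-trip float parsing).

Test and acceptance simulations run on reduced genomes (4–7 chromosomes,
100–500 kb grids, 99–200 randomizations) — the package's chosen problem
sizes for its self-checks — with tolerances widened accordingly: binomial
3σ bands for calibration rates, ≥90% replicate rates for recovery.

## Known limitations

* Kernel width is fixed, not data-adaptive; no per-width search.
* The FDR estimator is the plug-in ratio; no π₀ estimation.
* The classifier assumes feature-wise (diagonal) dispersion, as the
  centroid model dictates; correlated-clone structure is ignored.
* Absolute copy-number estimates assume diploid reference and no tumor
  cell fraction correction.
* No segmentation (e.g. CBS) — recurrence and differential calls are made
  on smoothed profiles, not segment calls.
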