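# metacgh

Copy-number analysis of primary-tumor array-CGH profiles for predicting the
organ site of colorectal-cancer metastasis.

Primary colorectal tumors that later seed liver metastases tend to carry
characteristic chromosomal copy-number aberrations — most prominently gain
of chromosome arm 20q — that tumors seeding the peritoneum, or never
metastasizing, carry less often. `metacgh` implements the full analysis
chain for asking this question of a cohort of samples × clones log2
tumor/reference ratio matrices (BAC-array CGH at ~1 Mb resolution, groups
such as LM = liver metastases, PM = peritoneal metastases, M0 =
metastasis-free):

1. **Recurrent-aberration detection** (`metacgh.kcsmart`). Per group,
   positive and negative log2 values are summed across tumors per clone and
   smoothed with a Gaussian kernel onto a genomic grid — the kernel-smoothed
   estimate,

   KSE(x) = Σ_c a_c · exp(−(x − p_c)² / 2w²),

   where a_c is the gain (or loss) aggregate at clone position p_c and w the
   kernel width (default 1 Mb). Significance comes from a randomization
   null: clone-to-position assignments are permuted, the genome-wide
   extremum of each randomized KSE is collected, and its (1 − α) point is a
   family-wise-error-corrected threshold.

2. **Differential-aberration detection** (`metacgh.comparative`). Each
   tumor's signed profile is smoothed onto a 50 kb grid and two groups are
   compared per grid point with a signal-to-noise ratio,

   SNR(x) = |mean_A(x) − mean_B(x)| / (sd_A(x) + sd_B(x)),

   with significance from permuting group labels (default 1000 times) and a
   plug-in false-discovery-rate estimate; regions above the 1% (or 5%) FDR
   threshold are significantly differentially aberrant.

3. **Metastasis-site classification** (`metacgh.classifier`). A nearest-
   shrunken-centroids (PAM-style) classifier on clone-level log2 values:
   standardized centroid deviations d_ik are soft-thresholded by Δ, chosen
   by stratified cross-validation (min error + 1 SE rule), leaving a sparse
   clone signature; evaluation includes confusion rates, probability-ranked
   ROC curves and trapezoid AUC, and per-chromosome-arm hypergeometric
   enrichment of the selected clones.

4. **Regional statistics** (`metacgh.stats`). Pearson chi-square tests for
   cohort characteristic tables, and logistic regression of metastasis
   outcome on the mean 20q log2 ratio (odds ratio per 0.1 log2 with Wald
   CIs, optionally adjusted for nodal status). Approximate absolute copy
   number is `2 · 2^(mean log2)`.

5. **Synthetic cohorts** (`metacgh.simulate`). A generator planting shared
   and group-specific aberration segments (amplitude, penetrance, target
   groups) plus Gaussian noise on a ~1 Mb clone map, with the full ground
   truth returned — every stage above is testable without external data.

## Worked example

The packaged demonstration simulates the study design this package targets
(LM n=36, PM n=37, M0 n=25; shared colorectal baseline aberrations; an
LM-specific 20q gain of 0.3 log2 at penetrance 0.8) and runs every stage:

```sh
metacgh demo --out demo_run
```

```json
{
  "differential_region_covers_20q": true,
  "classifier_20q_enriched": true,
  "passed": true
}
```

From `demo_run/report.json` (fixed seed 20496):

* the LM vs PM+M0 comparison finds exactly one 1%-FDR differential region,
  chr20:28,050,000–62,450,000 (peak SNR 0.96) — the planted q arm;
* the LM classifier keeps 27 clones at the cross-validated shrinkage level
  (CV error 0.13) and classifies with accuracy 0.90, sensitivity 0.75,
  specificity 0.98, AUC 0.93; its clone list is overwhelmingly 20q
  (hypergeometric enrichment p ≈ 2e-44);
* the mean-20q log2 score alone gives ROC AUC 0.88, and logistic regression
  yields an odds ratio of 6.6 (90% CI 3.5–12.6) per 0.1 log2 of 20q gain,
  significant independently of nodal status;
* between-group KSE correlations are high for losses (≈0.91) and for the
  groups without the planted gain (PM vs M0 gains ≈0.86), but depressed for
  LM gains (≈0.64) — the planted difference.

`metacgh demo --amplitude 0 --out null_run` is the negative control: with no
planted effect both structural checks fail and the command exits nonzero.

The same stages are available on files (`metacgh simulate`, `kcsmart`,
`compare`, `classify`, `cohort-stats`, `run`) and as library functions; see
`docs/methods.md` for the statistical details and parameter guidance.

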