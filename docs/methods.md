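# Methods

## Problem and data model

Glioblastoma tumors are mechanically heterogeneous. MR elastography (MRE)
yields voxel maps of the shear-modulus magnitude |G*| (kPa) and the shear
phase angle φ (rad) that can be read at surgically navigated biopsy sites,
so each biopsy carries both a transcriptome and an in-vivo stiffness. The
pipeline asks three questions: which genes separate relatively stiff from
relatively soft tumor regions, is that separation stable across patients,
and does the resulting expression signal stratify survival in external
expression-only cohorts.

The in-memory containers are: `StiffnessVolume` (co-registered |G*|, φ and
an integer habitat segmentation — 0 background, 1 NAWM white matter,
2 NAWM gray matter, 3 FLAIR-hyperintense region, 4 contrast-enhancing
tumor, 5 necrosis), `BiopsySample`, `CountMatrix` (genes × samples with
per-sample patient id and stiff/soft label), `SignatureModel`, and
`SurvivalCohort`.

## Stiffness quantification

* **ROI estimator.** The biopsy value is the trimmed mean of nine MRE
  voxels centered on the seed: exactly one maximum and one minimum are
  removed and the remaining seven averaged. Nine voxels cannot form a
  symmetric 3-D neighborhood, so the default reading is the 3×3 in-plane
  patch on the seed's slice; a "9 physically nearest voxels in 3-D"
  alternative (ties broken by physical distance, then lexicographically) is
  a config option. Seeds whose neighborhood leaves the grid fail loudly —
  silently shrinking the ROI would change the estimator.
* **Normalization.** ROI values are divided by the mean over the
  contralateral NAWM white matter: NAWM-WM voxels restricted to the
  hemisphere (first grid axis) opposite the tumor centroid (CE + necrosis,
  falling back to FLAIR). The same operation yields φ_norm.
* **Labeling.** Within each patient, stiff ⇔ |G*|_norm strictly greater
  than the mean of that patient's biopsy values; ties go to soft. With at
  least two non-tied biopsies, every patient gets at least one of each
  label; a single biopsy is an error because the relative rule is undefined.
* **Region statistics.** Per-habitat means, normalized means and percent
  differences versus contralateral NAWM-WM; habitat volumes are label
  counts × voxel volume. Missing habitats are reported as absent, never as
  zero.
* **Nonparametric tests.** The Wilcoxon signed-rank test uses exact
  enumeration for n ≤ 12 without ties or zero differences (all-zero
  differences are degenerate: p = 1, flagged) and a continuity-corrected
  normal approximation otherwise. Spearman's rho is the Pearson correlation
  of mid-ranks; for n ≤ 8 the two-sided p enumerates all n! pairings, above
  that the t-approximation is used.

## Differential expression

A deliberately small, fully documented re-implementation of the standard
bulk RNA-seq skeleton:

* **Size factors** — median-of-ratios over genes expressed in all samples,
  rescaled to geometric mean 1; an optional positive-counts pseudo-reference
  handles matrices with no universally expressed gene.
* **Dispersion** — per gene, normalized counts are projected onto the
  design column space; a method-of-moments estimate of α in
  Var = μ + αμ² (with an n/(n−p) degrees-of-freedom correction) is shrunk
  on the log scale (weight 0.7 on the trend) toward a fitted trend
  α(μ) = a₀ + a₁/μ. Genes without estimable excess variance take the trend
  value and are flagged. α is clipped to [1e-8, 10]. There is no Cox-Reid
  adjustment and no outlier refitting.
* **GLM** — negative-binomial log-link GLM with offset log s_j and fixed
  design `~ patient + label` (patient blocking is the only reading of a
  per-patient stiff/soft contrast). The IRLS loop is batched across genes
  (the design is shared), with working weights μ/(1+αμ). Genes whose
  coefficients diverge (a label class with all-zero counts has no finite
  MLE) are flagged non-converged and excluded from the testing family —
  counted, never silently dropped.
* **Wald test** — z = β/SE on the label coefficient. The plain reference is
  standard normal; `run_de` passes the residual degrees of freedom
  (n − p) and uses a Student-t reference instead, a small-sample correction
  that restores null uniformity at blocked-design sample sizes (e.g. 8
  patients × 3 biopsies gives 15 residual df, where the normal reference is
  measurably liberal) and degenerates to the normal as n grows.
* **BH** — step-up Benjamini–Hochberg at α = 0.05.
* **Stability selection** — the full analysis is re-run P times, each time
  excluding all samples of one patient; the stable set is the genes
  significant with a consistent fold-change sign in *every* iteration,
  partitioned into stiff-/soft-associated by sign. Iterations that lose an
  entire label class are skipped with a warning and recorded.
* **Log transform** — the signature model consumes
  log2(count/size_factor + 1), a monotone stand-in for regularized-log
  transforms whose empirical-Bayes shrinkage is out of scope.
* Batch correction is a deliberate no-op hook: the synthetic data are
  single-batch, and a pluggable pre-step can replace it for real data.

## Enrichment

ORA is a one-sided hypergeometric tail per term (sets intersected with the
universe; odds ratio with Haldane correction reported), BH across terms.
Preranked GSEA ranks genes by the signed Wald statistic (positive = up in
stiff), scores each set with the weighted Kolmogorov–Smirnov running-sum
extremum (weight |stat|), and draws the null by re-sampling each set's
positions uniformly from the ranked list. NES divides ES by the mean |null
ES| of the same sign; p is the one-sided empirical tail with add-one
smoothing. Sets smaller than `min_size` (default 5) after restriction are
skipped and logged.

## Signature model

Sparse PLS-DA via NIPALS on standardized log-normalized expression
(centering/scaling constants from training data only; constant genes
dropped with a warning). Per component, the X weight vector is
soft-thresholded so exactly `keep_x` genes stay nonzero, then normalized;
X and the centered class-indicator matrix are deflated between components.
`keep_x = all` is exactly plain PLS-DA. Prediction projects new samples
with the training constants through the same deflation and assigns the
nearest class centroid in latent space (a "max.dist"-style rule — the
simplest deterministic choice; a Mahalanobis variant would be a
straightforward extension). Tuning runs repeated stratified k-fold CV
(default 5 folds, 100 repeats) over a (components × keep_x) grid and picks
the smallest model within one standard error of the best mean balanced
error rate — a parsimony-first rule matching the goal of a minimal
sufficient signature. Tied loading magnitudes at the threshold break by
gene order; with continuous data ties have measure zero.

## Survival

Kaplan–Meier product-limit curves with median survival = earliest t with
S(t) ≤ 0.5 (absent if never reached; no CI on the median). The log-rank
test uses observed-minus-expected counts with hypergeometric variance. Cox
proportional-hazards regression maximizes the partial likelihood by
Newton–Raphson with Efron tie handling (Breslow available for
cross-checking); categorical covariates are dummy-coded with the most
frequent level as reference; HR = exp(β) with a Wald 95% CI on the log
scale. A warning fires below five events per coefficient; monotone
likelihood surfaces as an error. The numerical engines are lifelines /
statsmodels; the module owns the cohort schema and encodings.

## Synthetic-data generator

The generator emulates the study conditions, and its defaults *are* those
conditions:

| knob | default | meaning |
|---|---|---|
| n_patients, biopsies | 13, 2–7 each | cohort structure |
| NAWM |G*| | 2.7 ± 0.35 kPa (voxel sd) | white-matter baseline at ~50 Hz |
| habitat |G*| factors | CE 0.8, necrosis 0.7, FLAIR 1.0, GM 0.9 | CE 20% and necrosis 30% softer than NAWM |
| habitat φ factors | CE 0.90, necrosis 0.92, FLAIR 0.85 | φ 10/8/15% lower |
| intra_habitat_sd | 0.28 (log scale) | within-habitat spatial spread; calibrated so the cohort median max/min biopsy ratio ≈ 1.6 |
| n_genes / planted | 2000 / 100 at log2FC 2 | desk-scale expression universe |
| dispersion | trend 0.05 + 1/μ, Gamma(4) gene noise | bulk RNA-seq–like mean–dispersion trend |
| patient effect | 0.3 (log sd, per gene × patient) | between-patient expression variation |
| external cohort | n 265, carriers 63/265 | external validation structure |
| true log HR | ln 1.45 | hazard of the expression signal |
| censoring | 25% | independent exponential censoring |
| baseline median | 460 days | non-carrier survival |

Geometry: the brain is a large ellipsoid (gray-matter shell, white-matter
interior); the tumor is nested axis-aligned ellipsoids (necrosis ⊂ CE ⊂
FLAIR) in one hemisphere, leaving the mirror hemisphere as contralateral
NAWM. The within-habitat heterogeneity field is a smoothed lognormal
multiplier re-centered per habitat, so habitat means equal the configured
factors exactly in expectation; the spatial correlation length
(`smoothness_sigma`, default 1 voxel) is a free parameter since real
within-habitat autocorrelation is not characterized. The surgeon's ordinal
consistency grade is simulated uncorrelated with |G*|_norm by default
(matching the observed absence of correlation), with an optional
correlation knob.

Counts are Gamma–Poisson (NB) with log-mean = gene baseline + per-gene ×
patient effect + label effect (planted genes only, 80% up-in-stiff) +
library factor. Gene baselines, dispersions and the planted program derive
from the config seed alone, so the biopsy and external cohorts share one
gene universe. Survival times are exponential with hazard × exp(log HR) for
carriers; censoring is exponential, calibrated to the configured marginal
fraction.

**What passing tests do and do not show.** The generator matches the
study's *statistical* structure (blocked design, NB counts with a
mean–dispersion trend, proportional hazards), not real data's batch
effects, transcript-length or GC biases, segmentation errors,
registration/brain-shift error (beyond the trimmed ROI), or non-proportional
hazards. Green tests demonstrate the machinery is correct and calibrated
under these assumptions, not that real cohorts will reproduce any specific
gene list.

## Numerical choices and problem sizes

IRLS converges at max |Δβ| < 1e-8 (cap 100 iterations); X'WX carries a
1e-10 ridge; η is clipped to ±30; coefficients beyond |β| > 20 (natural
log) mark a gene non-converged. NIPALS converges at 1e-9 on the weight
vector. Test and acceptance simulations run at desk scale — 2000 genes,
8 patients × 3 biopsies, 20 null seeds, 50 signature seeds, 500 survival
replicates at n = 265 — sizes chosen so the full suite completes in about a
minute while keeping Monte-Carlo error well inside the asserted bands.

## Known limitations

* The DE stack is a simplification: no Cox-Reid dispersion adjustment,
  no independent filtering, no LFC shrinkage; its gene lists will differ in
  detail from heavier empirical-Bayes pipelines on real data.
* MRE physical reconstruction (inverting wave images to |G*|/φ), image
  registration, and habitat segmentation are out of scope; synthetic labels
  and a shared voxel space stand in.
* The ordered-logistic / multinomial analyses of surgeon grade and
  radiological class are not implemented.
* `simulate_external_cohort` plants a clean expression shift in carriers;
  real external cohorts mix platforms and batches, where the pluggable
  batch-correction hook would matter.
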