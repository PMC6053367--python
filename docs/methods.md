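# Methods

This note documents the statistical models implemented by `agesplice`, the
synthetic world its tests run in, the numerical choices, and the limitations
a user should know before trusting a green test suite.

## 1. Detecting age-associated features

Every feature (splicing event, gene, transcript, transcript ratio) is fitted
independently by ordinary least squares:

    y_ij = α_i + β¹_i AGE_j + β²_i GENDER_j + Σ_k β_i^{k+2} CF_j^k + ε_ij

- **Usable samples.** Cells equal to the SUPPA sentinel `-1` (gene not
  expressed) or non-finite are excluded per event. Events with fewer than
  `min_samples` (default 50) usable samples, or a zero-variance response, are
  returned as *not tested* rather than given p = 1, so they cannot dilute the
  FDR. A constant gender column (single-sex tissue, e.g. uterus) is dropped
  from the design instead of raising a rank error; any other rank deficiency
  is an error that names the offending columns.
- **Age p-value.** Two-sided t test on β¹. Expression responses are
  log2(x+1)-transformed before fitting (variance stabilization for TPM-like
  data; the transform is a package choice, exposed by using the gene /
  transcript scan entry points).
- **Multiple testing.** Hand-rolled Benjamini–Hochberg step-up (q capped at
  1, monotone from the top), applied across all *tested* features of one scan
  (one tissue, one modality). Verified against a brute-force implementation
  of the step-up definition.

### Hidden confounders

The latent batch-like factors (`n_factors = 20` by default) are a
principal-component surrogate for PEER-style factors, estimated
surrogate-variable style:

1. impute sentinel cells with the feature mean; residualize every feature row
   against `[1, age, gender]`;
2. take the top left singular vectors of the residual matrix as factor
   *loadings* (feature-space directions learned without age contamination);
3. score each factor by projecting the raw row-centered matrix onto its
   loading, preserving the factor's true sample pattern — including any
   chance in-sample correlation with age.

Factors whose Pearson correlation with age reaches p < 0.05 are then
excluded from the design, so genuine ageing signal is not regressed away.

Two tempting simplifications fail measurably and are avoided. Scoring factors
directly from the raw SVD lets strong batch directions mix into
age-correlated components; excluding those leaves shared confounding
unadjusted (null p ≤ 0.05 rates up to ~0.4 on clean data). Scoring factors
from the residual matrix makes them exactly orthogonal to age, which
*structurally hides* a confounder's age-aligned component from the
adjustment — worse still. The exclusion rule itself retains an irreducible
hazard: a genuine batch factor is dropped by chance in ~5% of datasets (per
factor), and the stronger the factor, the worse the resulting inflation in
that dataset. This is a property of the exclusion procedure, not of any
particular implementation; it is why the generator's default factors are
moderate (see §7).

### Permutation null

Ages are shuffled across usable samples (gender and factors fixed) and the
model is refitted exactly for each shuffle, using the Frisch–Waugh–Lovell
decomposition: response and shuffled-age vectors are residualized against the
nuisance design once, after which each shuffle's OLS t statistic is a dot
product. The identity permutation reproduces the observed fit exactly.

Two quantities are reported per event:

- `perm_fraction` — the share of shuffles whose age coefficient reaches
  nominal p ≤ 0.05. Because the t statistic of a randomly shuffled regressor
  is t-distributed *regardless of the response*, this fraction sits near 0.05
  for every event, signal or null; it is a diagnostic of the permutation
  machinery, not a significance measure.
- `perm_pvalue` — the empirical permutation p-value Pr(|t*| ≥ |t_obs|), with
  the standard +1 correction. This is what the significance call uses.

**Significance** = BH q ≤ 0.05 AND `perm_pvalue` ≤ 0.05 (both thresholds
configurable). Direction is the sign of β¹.

## 2. Modality scans and overlap

Transcript ratios are `TR = T_x / Σ_x T_x` within each gene and sample; cells
of gene–samples with zero total are sentinel-masked. The gene scan estimates
its confounders from the gene matrix, the transcript and ratio scans from the
transcript matrix. Overlap of the four modalities' significant gene sets is
reported as the full intersection lattice plus per-modality unique genes.

## 3. Cross-tissue similarity

Tissue similarity is the Jaccard index of per-tissue sets of genes carrying
at least one significant event. `J(∅, ∅)` is defined as 0 so empty tissues
never look similar. Clustering is average-linkage on distance 1 − J (the
linkage method is a package choice, exposed as a flag); trees are exported as
Newick.

## 4. Age prediction

- **Reduction.** Classical metric MDS of samples on Euclidean distances
  (sentinels imputed by feature means), computed by eigendecomposition of the
  double-centered squared-distance Gram matrix. This equals PCA scores up to
  per-axis sign; signs are fixed deterministically (largest-magnitude
  coordinate positive). 30 components for age models.
- **Clock.** LASSO on standardized components; penalty tuned by inner 5-fold
  CV over a log-spaced grid (1e-3 … 10, 9 points); evaluation by repeated
  k-fold CV (default 100 × 10-fold), each sample scored by the mean of its
  out-of-fold predictions, accuracy = Spearman correlation with true age.
  Under a pure null this statistic is slightly *negative*, not zero: when
  the LASSO shrinks to the intercept, a sample's prediction is its training
  fold's mean, which excludes that sample's own age (leave-one-out
  anticorrelation, ≈ −0.17 at n = 100). Interpret near-zero or negative
  accuracies as "no skill".
- **Old/young classification.** L1-penalized logistic regression on the
  age-extreme quartiles, accuracy by repeated stratified CV.
- **Robust events.** The permutation null is stochastic, so the full
  significance pipeline is repeated (default 10 permutation seeds) and events
  significant in ≥ 8 runs are retained.
- **Relative age.** Per fitting round (default 100): bootstrap-resample the
  training cohort, tune the penalty by randomized inner CV, predict all test
  samples, and z-score against that round's training prediction distribution.
  The bootstrap supplies the across-round sampling variation that the paired
  Wilcoxon comparison of two samples' z-scores needs; rounds whose model
  collapses to a constant are skipped. The ordering call is the sign of the
  median z difference.

## 5. Splicing-factor driver detection

Exon-skipping events are classed `up` / `down` (significant, by β¹ sign) or
`stable` (tested, non-significant, nominal p ≥ 0.5 — the buffer zone below
0.5 belongs to no class, keeping the background clearly null). Motifs are
degenerate IUPAC consensuses; occurrences are counted at every (possibly
overlapping) position, `N` in a sequence never matches. The seven regions
around the cassette exon default to 100 nt exonic flanks and 200 nt intronic
windows (configurable); counts are raw per region since region lengths are
fixed. Each (motif, region, contrast ∈ {up-vs-stable, down-vs-stable}) cell
is a two-sided rank-sum test (exact for small tie-free samples), BH-corrected
across the whole scan at FDR ≤ 0.1, and called enriched only when the
changing class carries *more* occurrences. Driver calls intersect enrichment
with the factor's own age-associated expression (log2 transcript-level TPM,
same covariate structure, nominal p ≤ 0.05) and carry a mechanism note
(repressor/activator × up/down). External target lists are compared by a
two-sided Fisher exact test against a stated background; a zero off-diagonal
yields an infinite odds ratio, reported as such.

## 6. Disease contribution

Null model: disease ~ intercept + age + gender + GE components. Alternative:
adds PSI components built **only from significant age-associated events**.
Both are fitted by maximum likelihood; LLR = 2(ℓ_alt − ℓ_null) is referred to
chi-square with df = number of added PSI components. The outcome is binary,
so the default likelihood is binomial (logistic; IRLS, alternative warm-
started from the null fit so nesting holds numerically); a Gaussian-linear
variant sits behind `family="gaussian"` for a strict linear-model reading.
Complete separation is detected (fitted probabilities at 0/1) and handled by
a mildly L2-penalized fallback whose parameters are scored under the
unpenalized likelihood, with the result flagged. The chi-square reference is
asymptotic: keep the total parameter count well below n (the pipeline clips
components to ~n/10 per block at synthetic scale; with ~23 parameters the
test is measurably liberal below n ≈ 300).

## 7. The synthetic world

The generator emulates one GTEx-like tissue per dataset; all stages draw from
deterministic child streams of one seed, so identical configurations give
byte-identical outputs.

- **Cohort**: ages uniform on 20–70 y, gender Bernoulli(0.5), one sample per
  donor.
- **PSI**: `expit(α_i + β_i·(age−45) + γ_i·gender + Σ_k λ_ik f_kj + ε)`,
  with α ~ N(0,1), noise sd 0.5 (logit), gender effects N(0, 0.3). A
  `frac_age_assoc` fraction of events (default 0.2) gets β = ±0.016
  logit/year ≈ a 0.2 PSI shift across the age range at PSI 0.5. Hidden
  factors: 3 by default with loadings N(0, 0.25) — each explains a few
  percent to ~10% of an event's variance, the regime PEER-type factors
  occupy in real data; much stronger defaults would make the exclusion rule's
  5% hazard (see §1) catastrophic, a property documented rather than hidden.
  The raw-PSI linear detection model is deliberately misspecified against
  this bounded generator — monotone trends survive the logit link, which is
  exactly the robustness the scan needs in practice.
- **Missingness**: sentinel `-1` uniformly at random per cell (default 5%),
  plus optional whole-gene-per-sample dropout emulating "gene not expressed".
- **Expression**: log-normal gene totals with planted log2-linear age trends
  for a subset; transcripts share each gene's total via softmax weights, so
  the gene row is the *exact* sum of its transcript rows. "Isoform switch"
  genes keep a flat total while the transcript ratio drifts with age —
  signal visible only to the transcript and ratio scans.
- **Regions/motifs**: i.i.d. uniform nucleotides, no splice-site grammar;
  the planted driver motif receives Poisson(3) extra insertions in its
  configured region for events of its trend class; decoys occur at the
  random-sequence background rate. The driver's splicing factor gets a
  log2-linear age trend whose sign follows repressor logic.
- **Disease**: Bernoulli-logit in standardized age, centered gender, the
  first principal component of log2 gene expression, and the first principal
  component of the age-associated PSI submatrix; `disease_effect = 0` is the
  null world for LLR calibration.

**What a green test does not establish.** The generator has no read-level
noise, no realistic PSI error model (logit-Gaussian is a stand-in; real PSI
noise is beta-binomial-like and depth-dependent), no donor relatedness or
repeated measures, no splice-site grammar, independent factors across PSI and
expression, and one tissue per dataset. Recovery rates measured here bound
what identical effect sizes would yield on real data only loosely.

## 8. Numerical choices

- OLS via `lstsq` after a pivoted-QR rank check; permutations via FWL with a
  per-event RNG substream derived from (master seed, CRC32 of the event ID),
  so results are independent of event iteration order.
- MDS eigenvalues clipped at 0; rank-deficient inputs yield ~0 variance on
  the trailing axes.
- Rank-sum tests fall back to the tie-corrected normal approximation when
  ties or larger samples preclude the exact distribution; two groups with
  all-identical pooled values get p = 1.
- LASSO penalty grid `logspace(-3, 1, 9)`; `alpha = 0` is routed to exact
  least squares.
- All thresholds (FDR 0.05, permutation 0.05, driver FDR 0.1, stable-class
  floor 0.5, ≥ 50 samples, 20 factors, 1000 permutations) live in the
  configuration objects and are logged in the pipeline manifest.

## 9. Known limitations

- The exclusion-rule hazard of §1 means null calibration degrades in worlds
  where single latent factors dominate per-event variance; no implementation
  of the stated procedure avoids this.
- The factor exclusion is applied once per scan (factors are global objects),
  not per event's usable-sample subset.
- The LLR chi-square is asymptotic; at small n / many components prefer
  fewer components or larger cohorts.
- `perm_fraction` is reported for compatibility but must not be used as a
  significance filter (§1); the package's calls use `perm_pvalue`.
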