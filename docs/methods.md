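# Methods

This note documents the models implemented in `orgrowth`, the choices made
where the procedure was genuinely open, and what the synthetic-data
generators do and do not emulate.

## Random-intercept mixed model and likelihood-ratio test

Organoid measurements are nested in cell lines, and genotype is a
line-level (between-cluster) factor, so per-organoid observations are not
independent. The model is

    y_ij = x_ij' beta + b_i + e_ij,
    b_i ~ N(0, sigma_line^2),  e_ij ~ N(0, sigma_resid^2),

with y the log area, log volume, log total-cell count (fold effects are
multiplicative, so size responses are modeled on the log scale) or the raw
labeling index, and i indexing cell lines.

Estimation is full maximum likelihood, not REML: the genotype test
compares models that differ in fixed effects, and REML log-likelihoods are
not comparable across fixed-effect structures. The likelihood is profiled
over lambda = sigma_line^2 / sigma_resid^2. For fixed lambda the
covariance of a line with n_i observations is sigma^2 (I + lambda J), so
beta is the GLS solution computed from per-group sufficient statistics
(O(groups × p²) per evaluation) and sigma_resid^2 = RSS_V / n in closed
form. The outer search is a fixed log-spaced grid (1e-6..1e3, 60 points,
plus the lambda = 0 boundary) refined by golden section on log-lambda to
1e-10 tolerance, falling back to bounded Brent if the grid bracket is
degenerate. The search is fully deterministic. Fits agree with an
independent ML mixed-model implementation (statsmodels `MixedLM`,
`reml=False`) to ~1e-6 in log-likelihood and coefficients on test data,
and collapse to OLS when sigma_line -> 0.

A relative floor of 1e-12·(1 + y'y) on the profiled RSS keeps the
Gaussian likelihood finite for degenerate (perfectly fitted, e.g.
constant) responses; there the LRT statistic is exactly 0.

The genotype LRT uses chi2 = 2·(ll_full − ll_null) against chi-square(1);
negatives beyond −1e-8 raise, smaller ones clamp to 0. The chi-square
reference is asymptotic: under permuted genotype labels (observation
level) the measured type-I error at alpha = 0.05 is ~0.06 over 1000
permutations of the default simulated design (42 organoids, 6 lines) —
slightly anticonservative, as expected at this sample size, and inside
the 0.03–0.07 band the test suite enforces. Permutation at the line level
is not used for calibration: with 6 lines only C(6,3) = 20 labelings
exist.

## Permutation-null enrichment

The null for an overlap between a size-k query and a target set is built
by drawing `n_perm` (default 10,000) uniform size-k samples without
replacement from a gene universe; z = (x − mean)/SD of the null draws
(sample SD, ddof 1), with a two-sided normal-tail p as the primary value
and the empirical p ((#{|null − mu| ≥ |x − mu|} + 1)/(n_perm + 1))
reported alongside. The exact null is hypergeometric, with

    mu = kK/N,   var = mu (1 − K/N) (N − k)/(N − 1),

which `hypergeometric_moments` provides as the closed-form oracle; it is
cross-checked in the tests against `scipy.stats.hypergeom` and against
exhaustive enumeration of all subsets of a 12-gene universe.

Open choices, decided once and recorded here:

- **Universe.** Defaults to all genes in the supplied DE table (all genes
  tested for DE), overridable by file. Enrichment z-scores depend strongly
  on this choice.
- **Direction-reversal null.** A "reversal" is a gene significant (padj
  strictly < alpha, default 0.05) in both contrasts with opposite log2FC
  signs. The null draws random sets of the rescue-significant size and
  counts drawn disease-significant genes as reversals with probability
  1/2 (fair-coin sign assignment). Genes with log2FC exactly 0 are
  excluded with a warning.
- **Identifier normalization.** Case-fold plus whitespace strip; no alias
  or database resolution, ever.
- **PC loadings.** Computed by SVD of the gene-centered log2(x+1) matrix
  with samples as observations; "top-k loading genes" means largest
  absolute loading, ties broken lexicographically by gene id.

## Cell-cycle estimation

The labeling index is pooled as sum(double-positive)/sum(Ki67+) across
sections within an organoid — sections have unequal denominators, so
averaging per-section ratios would weight small sections too heavily —
and organoid values are averaged within a line. T_c = T_s / LI, with T_s a
configuration parameter defaulting to 4.5 h (a typical human
neural-progenitor S-phase length); absolute T_c values are always reported
together with the T_s used, while genotype comparisons use
`relative_cell_cycle`, which is exact and T_s-free because T_s cancels in
the ratio. Absolute marker counts round half to even.

## Morphometry

Areas and volumes are raw foreground counts scaled by physical pixel or
voxel size — no convex hull, no smoothing; masks are upstream inputs. The
"middle" z-plane is the 0-based index floor(n_z/2), a fixed convention.
The area-to-volume calibration is simple OLS (scipy `linregress`), with
F = R²/(1 − R²)·df₂ on (1, n − 2) df; a perfect fit reports F = inf,
p = 0. The gray/white-matter ratio is GM/(GM + WM) on voxel counts, so
the voxel volume cancels.

## Reference z-scores and ordinal summaries

Subject measurements are standardized as z = (value − ref mean)/ref SD
against a (sex, age) reference-norm table; a missing stratum is an error
naming the stratum. The "weighted" combination across subjects is
Stouffer's method, sum(w z)/sqrt(sum w²) — one natural reading of a
weighted z; the weights are the caller's (e.g. sqrt of stratum sizes).
Ordinal (e.g. blinded radiology) scores are summarized as the median of
exactly three readings.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *design* and the *planted statistical
structure* of an organoid overgrowth study, not the biology:

- `gen_morphometry` — 3 lines/genotype × 7 organoids measured at weeks 4,
  9, 13. log-area = log(baseline) + 0.12/week growth + genotype effect
  ramping linearly from 0 (week 4) to log(1.5) (week 13) + line intercept
  (SD 0.10) + residual (SD 0.15); volume = 0.35 × area with multiplicative
  log-normal noise of the same residual SD (the volume-noise scale is the
  package's choice; no separate parameter is defined). The organoid-level
  SDs are free parameters of the simulation, not calibrated to any
  dataset.
- `gen_brdu_ki67` — 3 sections/organoid, Ki67+ counts Poisson around 200,
  double-positives Binomial(Ki67, LI) with default LI 4.5/83 (control) and
  4.5/54 (case), i.e. a 1.54-fold difference; plus PAX6+ and total-nuclei
  columns.
- `gen_expression` — 20,000 genes × 3 samples in each of control, patient
  and rescue groups. Log-normal baseline means (ln-mean 4.0, ln-SD 1.5),
  NB dispersion 0.05, 339 planted DE genes with |log2FC| ≥ 0.25, a
  980-gene disease-annotation set overlapping the DE set by exactly 19,
  rescue reversing each DE gene's sign with probability 0.2, and a batch
  shift (ln-SD 1.0) on a random 5% of genes disjoint from the DE set,
  applied to the rescue-batch samples — so PC1 tracks batch genes and not
  DE genes. The emitted DE tables are truth-derived stand-ins for an
  upstream DE caller's output (DE calling itself is out of scope): planted
  genes get padj < 0.05 by construction. Consequently, recovery tests
  exercise the downstream inference, not DE-calling error.
- `gen_atlas` — 40 labeled profiles (8 structures × 5 ages) of independent
  log-normal expression; the query is one profile with multiplicative
  log-normal noise (SD 0.1 by default), so the true label should rank
  first by Pearson r.

Not emulated: image texture beyond binary ellipsoids, droplet
single-cell artifacts, gene-gene correlation, library-size variation, and
DE-calling uncertainty. Passing tests therefore demonstrate correctness
of the implemented inference under the stated generative assumptions, not
robustness to real-data pathologies.

## Problem sizes used by the standing checks

The test suite and `scripts/acceptance.py` use: 10,000 permutations for
oracle-agreement checks at the 339/980/20,000 scale; 1000 label
permutations for LRT calibration; 500 seeds × 200 permutations (universe
2000, query 100, target 200) for enrichment-null calibration; 100
simulated studies for fold recovery; 100 atlas seeds for mapping. These
sizes give Monte-Carlo error comfortably below the tolerances they are
checked against, and the whole acceptance script completes in well under
a minute on one CPU.

## Known limitations

- The LMM supports a single random intercept (no random slopes or crossed
  factors) and Gaussian responses only.
- chi-square LRT calibration is asymptotic; with very few lines the test
  is mildly anticonservative (measured ~0.06 at nominal 0.05 on the
  default design).
- Enrichment p-values from the normal tail understate extreme tails
  relative to the exact hypergeometric; the empirical permutation p is
  bounded below by 1/(n_perm + 1).
- Gene identifiers are matched by normalized string equality only.
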