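# Methods

`pwcmr` dissects a two-sample Mendelian-randomisation (MR) estimate by
clustering the exposure's genetic instruments on their phenome-wide
association profiles, estimating a causal effect per cluster, and — in a
complementary arm — searching systematically for candidate confounder
traits and conditioning on them in multivariable MR (MVMR). This note
documents the statistical model, the defaults and why they are set where
they are, what the synthetic-data generator does and does not emulate, and
the numerical decisions a maintainer would want to know.

## Model and assumptions

Throughout, per-variant effects are standardised to the SD/SD scale:
`beta_std = z / sqrt(n)` with `z = beta/se` and `se_std = 1/sqrt(n)`, so
`beta_std^2` is the fraction of trait variance the variant explains. Binary
traits are standardised identically (at biobank sample sizes linear and
logistic effect estimates are nearly proportional, so cluster geometry is
insensitive to this shortcut; it remains a known approximation).

The working causal model is: an exposure X receives contributions from K
distinct SNP clusters ("mechanisms"), each with its own total effect
alpha_k on the outcome Y. A cluster may act purely through a heritable
confounder U (SNP -> U -> X, U -> Y); such a cluster's instruments are
valid-looking but their ratio estimates converge on `q_uy/q_ux` (the ratio
of U's effects on Y and X) rather than on a causal effect of X — the
correlated-pleiotropy failure mode of standard IVW. Clustering instruments
by their PheWAS profiles separates such clusters because U-driven SNPs
share associations with U's phenotypic correlates.

### Pipeline stages (clustering arm)

1. **Instrument selection.** Genome-wide significance p < 5e-8, greedy LD
   clumping (window 10,000 kb, r2 >= 0.001 discards; ties at equal p broken
   lexicographically by variant id for determinism). Pairwise LD is an
   input table; an absent pair is treated as r2 = 0, which supports sparse
   LD files but means an incomplete table under-clumps — this is stated
   loudly here because it is silent at run time.
2. **Trait QC.** Remove traits with missing instrument effects, duplicates
   (keep most recent version), effective sample size < 50,000, and
   |rG with exposure| > 0.75 (the absolute value is used: negatively
   aligned near-duplicates are equally redundant).
3. **Trait-wide Steiger filter.** For each instrument and each panel trait,
   a one-sided delta-method z-test of whether the trait's explained
   variance exceeds the exposure's:
   `zeta = (b_t^2 - b_x^2) / sqrt(4 b_t^2 se_t^2 + 4 b_x^2 se_x^2)`,
   removing the SNP if any trait reaches one-sided p < alpha/T (alpha
   default 0.05, T = number of panel traits). The variance of a squared
   estimate is approximated by `Var(b^2) ~= 4 b^2 SE^2`; this is the
   standard first-order result and is accurate at GWAS sample sizes.
4. **Clustering.** Absolute standardised effects, each SNP row scaled to
   unit variance (sd with ddof=1) across traits; k-means (k-means++ init,
   25 restarts, fixed seed) for k in 2..50; k chosen by penalised
   within-cluster sum of squares `AIC(k) = W_k + 2 k d`. The
   spherical-Gaussian log form `n d ln(W_k/(n d)) + 2 k d` is available via
   configuration, but it is scale-invariant and demonstrably over-splits
   whenever the per-cluster SNP count is not much larger than the trait
   count: sample-level overfitting reduces W_k by a few percent per extra
   cluster at any noise scale, which the multiplicative form always
   rewards. The unscaled form stops as soon as the absolute reduction in
   W_k drops below 2d, which is the behaviour wanted for tight, genuinely
   clustered profiles. Empty clusters are impossible by construction
   (scikit-learn reseeds them); duplicated points land together.
5. **Enrichment.** Per cluster j and trait t, the per-SNP average squared
   standardised effect `sigma2[j,t]`, normalised by its across-cluster mean
   to give the enrichment ratio `ER[j,t]`; the mean of ER over clusters is
   exactly 1 per trait (checked to 1e-10). ER uses the standardised, not
   row-normalised, effects, so cluster annotation is independent of the
   clustering transform. Top-10 traits per cluster, ties broken by id.
6. **Per-cluster MR.** IVW per cluster and over all instruments, with
   Cochran's Q (chi-square, L-1 df), the average per-instrument
   heterogeneity Q/(L-1), and a cluster-level Cochran Q across cluster
   estimates. The fixed-effect IVW SE is the default;
   `random_effects=True` applies the multiplicative inflation
   max(1, sqrt(Q/(L-1))).

### Confounder-search arm

Traits with |rG with the outcome| > 0.75 are removed first (missing rG
passes with a warning: only known high-rG traits can be filtered). Each
remaining trait is tested against exposure and outcome by bidirectional MR:
four estimators per direction (IVW, weighted median, simple mode, weighted
mode), ordered by p-value, and the **second most significant** estimate is
selected, so a causal claim is never carried by a single method; exact p
ties are broken by the fixed order IVW > weighted median > weighted mode >
simple mode. Directionality between traits A and B uses

    t_AB = (|a_AB| - |a_BA|) / sqrt(SE_AB^2 + SE_BA^2),  P = Phi(t_AB)

with P > 0.95 calling A->B dominant and P < 0.05 the reverse (heuristic
5% type-I control; the 0.01/0.99 tightening is exposed and can only shrink
the candidate set). The selected method's own alpha and SE feed this test.
A trait dominant on both exposure and outcome, with nominally significant
MR (p < 0.05) on both, is a candidate confounder; exposure->trait plus
trait->outcome dominance marks a mediator; double reverse dominance a
collider. Mediators and colliders are recognised but not conditioned on:
the goal is to correct the exposure's total effect, not to decompose it.

For the candidates, a Z-score matrix over the union of their genome-wide
significant SNPs is built (complete-case by default; HLA 6p21.3,
chr6:25–34 Mb GRCh37, excluded), thinned by rank-based clumping (per-trait
competition ranks of |Z|, per-SNP importance = best rank, greedy clump at
5,000 kb / r2 0.01), and traits with fewer than three surviving instruments
are dropped. Stepwise MVMR (forward selection at p < 0.05/m with backward
pruning; m defaults to the number of candidates) picks the traits with
independent outcome effects. The final joint fit includes the exposure,
trimmed (greedily dropping the trait whose removal most improves it) until
the exposure's conditional F-statistic is at least 10.

**Conditional F convention.** Sanderson–Windmeijer form: the exposure's
instrument effects are regressed on the other exposures' effects with
inverse-variance weights from the *exposure's* standard errors, and
F = Q_x/(L - k), k = #others + 1. With no other exposures this reduces to
the univariable mean instrument strength `mean(beta_x^2/se_x^2)` up to the
L/(L-1) degrees-of-freedom factor. Exposure-side weighting is the only
convention consistent with that reduction, which is why it is used even
though estimation itself weights by outcome SEs.

### Estimator details

* **IVW**: weights `w_i = beta_x_i^2 / se_y_i^2`; identical to weighted
  zero-intercept regression of outcome on exposure effects (verified to
  1e-10 against a least-squares oracle). Instruments with `beta_x = 0` are
  excluded (undefined ratio) rather than failing the fit.
* **Weighted median**: interpolated weighted percentile at 0.5 with ratio
  weights `(beta_x/se_y)^2`; SE from a seeded parametric bootstrap (1,000
  draws of both effect vectors; weights held at point values — resampling
  them as well changes SEs negligibly but costs determinism across
  platforms with differing reduction orders).
* **Modes**: Gaussian-kernel density of the ratios, Silverman bandwidth
  `0.9 min(sd, IQR/1.349) L^{-1/5}` times a tuning factor phi = 1;
  unweighted (simple) or inverse-variance weights (weighted). The argmax is
  located on a 512-point grid and polished by bounded scalar minimisation,
  so it matches a 200,001-point grid oracle to ~1e-4. Bootstrap SEs reuse
  the grid without polish (grid error is far below the SE itself).
* **Difference Z-test**: `z = (a1 - a2)/sqrt(SE1^2 + SE2^2)`; 95% CIs are
  converted to SEs as (upper - lower)/(2 * 1.96).

## Synthetic data

`simulate_study` draws summary statistics directly in standardised-effect
space: observed effect = true effect + N(0, 1/n_gwas), se = 1/sqrt(n_gwas).
This is exact for the large-sample standardised model and fast; only the
coarsening experiment simulates individuals, because binning is a
nonlinearity with no effect-space representation.

Default conditions (chosen once, as a realistic biobank-scale study):

| parameter | default | meaning |
|---|---|---|
| `n_gwas` | 360,000 | per-trait GWAS sample size (UK-Biobank scale) |
| `n_snps_per_cluster` | 30, 30, 30 | instruments per mechanism |
| `alpha_k` | -0.09, -0.09, 0 | total pathway effects on Y (SD/SD) |
| `q_ux`, `q_uy` | 0.6, -0.3 | confounder U's effects on X and Y |
| `loading_mean/sd` | 0.05 / 0.01 | per-SNP pathway loadings (SD units) |
| `traits_per_cluster` | 4 | marker traits per mechanism |
| `marker_loading` | 0.7 | marker effect per unit SNP->X effect |
| `u_proxy_loading` | 0.5 | U's effect on its proxy trait |
| `m_x`, `alpha_m` | 0.08, 0.3 | X->mediator and mediator->Y effects |

The third cluster acts purely through U, so its apparent effect is
`q_uy/q_ux = -0.5` while the genuine clusters carry -0.09; the
inverse-variance-weighted mix makes the naive all-instrument IVW roughly
-0.15, and conditioning on the U-proxy in MVMR returns the exposure
estimate to about -0.09. Marker loadings are defined relative to each
SNP's *exposure* effect so that no marker out-explains the exposure — the
profile a valid instrument shows in real PheWAS data; an earlier
formulation tied to raw pathway loadings made the confounder cluster's
markers exceed the exposure and interacted with the Steiger filter to bias
that cluster's denominators. The mediator's X-loading (0.08) is deliberately
small enough that exposure instruments stay below genome-wide significance
for the mediator trait, keeping its instrument set clean. `alpha_k` is the
**total** pathway effect (the estimand of cluster-specific IVW); when a
mediator is planted the direct effect is derived internally so totals are
preserved.

What the generator does **not** emulate: linkage disequilibrium between
causal effects (the optional block-LD feature writes AR(1) r2 entries to
exercise clumping logic, but marginal effects stay independent), sample
overlap between trait GWAS (noise is independent across traits, whereas a
shared biobank induces correlated errors), minor-allele-frequency and
power spectra, binary traits, palindromic-allele ambiguity and strand
errors, and population stratification. Passing recovery tests therefore
demonstrates correctness of the algorithms under the stated model, not
robustness to those real-data complications.

The coarsening experiment simulates genotypes for n individuals, builds a
continuous exposure with ~7% SNP heritability, quantile-bins it (3 bins
emulates a coarse self-reported body-size proxy), and recomputes GWAS
effects. Attenuation of per-SNP effects — and the consequent inflation of
|IVW| when the coarse proxy serves as exposure — is emergent, not imposed.

## Numerical choices and degenerate inputs

* All randomness flows through `numpy.random.default_rng` with explicit
  seeds; every simulation derives sub-seeds by fixed offsets.
* Zero-variance instrument profiles abort normalisation with the SNP named;
  an all-zero exposure column in MVMR yields estimate 0 with infinite SE
  instead of a rank-deficiency error; genuinely collinear designs raise
  (condition number > 1e12 on the weighted normal matrix).
* Clump tie-breaks, top-N tie-breaks and rank ties (competition ranking,
  ties share the better rank, then variant id) are all deterministic, so
  outputs are invariant to input row order.
* Harmonisation drops palindromic variants when either allele frequency is
  missing or lies in [0.4, 0.6], and flips signs for swapped or
  strand-complemented alleles; irreconcilable allele sets are dropped with
  a reason code.
* P-values are floored at 1e-320 when writing simulated tables to avoid
  log-zero underflow on re-reading.

## Problem sizes used in tests

Replication counts follow the package's own verification design: 50
replicates for end-to-end recovery, 2,000 for type-I calibration, 200 for
the coarsening experiment, 1,000 random instances for the least-squares
oracle. Recovery coverage is judged with 99% family-wise (Bonferroni)
intervals using the delta-method ratio variance
`se_ivw * sqrt(1 + alpha^2)` — the fixed-effect IVW SE omits the
exposure-side noise term, which is material at |alpha| = 0.5 — so that a
replicate-level miss is rare (~2%) and the 90%-of-replicates criterion
detects systematic bias rather than interval-level coin flips.

## Known limitations

* Real candidate traits downstream of a genuine mechanism (rather than of
  a confounder) can satisfy the candidate-confounder truth table — the
  scan deliberately over-calls, mirroring its use as a screen whose
  false positives are neutralised by the subsequent MVMR step.
* The cross-cluster Q test assumes independent cluster estimates; clusters
  share no instruments, but with overlapping GWAS samples their errors
  would correlate, making the test anti-conservative on real data.
* The stepwise procedure's backward-pruning behaviour is configurable
  (`prune=False` disables it); with strongly correlated candidates the
  selected set is order-dependent only within numerical p-value ties.
* Conditional-F trimming is greedy and may not find the globally best
  subset satisfying F >= 10 when candidates interact.
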