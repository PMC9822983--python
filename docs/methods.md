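# Methods

This note documents the models, the synthetic-data generator, numerical
choices and known limitations of `stressbiome`. It records design
decisions in the package's own terms; every empirical number it mentions
is computed by the test suite or `scripts/acceptance.py`.

## Multi-group CFA and the invariance ladder

The two-factor model treats the 0–4 Likert items as continuous and fits
a mean-and-covariance structure per cohort by maximum likelihood. Each
item loads on exactly one factor (ED: a, b, c, f, i, j; SE: d, e, g, h);
Σ_g = Λ_g Φ_g Λ_g' + Θ_g and μ_g = ν_g + Λ_g α_g.

**Identification.** Factor variances are fixed to 1 and factor means to
0 in the reference group (lexicographically first cohort label). Moving
up the ladder, the non-reference group's factor variances are freed at
the weak level (loadings equal) and its factor means at the strong level
(intercepts equal). This yields df = 68 / 76 / 84 / 94 for 10 items and
two groups and 26 / 31 / 36 / 43 for the 7-item reduced scale, which the
test suite asserts.

**Objective and test statistic.** The optimizer minimizes
T(θ) = Σ_g (N_g − 1) F_g directly (S_g uses the N_g − 1 denominator;
Wishart convention), so the reported chi-square T is the optimum of the
objective itself. An N_g-weighted variant is available via
`multiplier="n"`. Optimization is L-BFGS-B with an analytic gradient
(verified against finite differences in the tests); stalled line
searches trigger up to three cold restarts, and a fit is accepted as
converged when the gradient max-norm falls below 1e−3 on the T scale
(curvature there is of order N, so the implied parameter error is
~1e−7). Residual variances are parameterized on the log scale; values
pinned below 1e−6 are reported as bounded with a warning. Negative
chi-square differences between nested fits (possible in finite samples
with this unscaled statistic) are floored at zero with p = 1 and a
warning; no Satorra–Bentler-type scaling is applied.

**Modification indices.** For each active cross-group equality
constraint, the released direction is added to the parameterization and
the score statistic is computed from the analytic gradient and a
finite-difference Hessian at the constrained optimum:
MI = g_j² / (2 s_j), with s_j the Schur complement of the released
direction after projecting out the free parameters. This equals the
expected chi-square drop from releasing that single constraint; the
suite checks agreement with actual refits within 15% for small-to-
moderate releases (the quadratic approximation degrades for very large
ones). Per-item aggregates sum the item's constraint statistics at the
first failing level, with df equal to the number of summed constraints.

**Pruning.** The loop refits the ladder, and while any nested comparison
has p ≤ 0.05, removes the item with the largest per-item aggregate MI at
the first failing level (ties broken by item label order), subject to
every factor retaining at least two items. The stop rule requires the
weak, strong and strict comparisons to all pass. Because the final
ladder performs three dependent tests at α = 0.05 each, the procedure
carries an intrinsic ≈10% chance of removing one extra item from data
that are already invariant (measured on invariant 7-item synthetic data
at n = 2000/group); this bounds the achievable exact-set recovery rate
of any such stepwise scheme.

**Scoring.** SE items are positively worded and are reverse-scored
(4 − response) inside PS totals; the SE factor score sums raw responses.
rRatio = rED/rSE is missing when rSE = 0, and missing item responses
propagate to every score that uses them.

**EFA.** The exploratory path uses a two-step polychoric matrix
(thresholds from inverse-normal marginal proportions, pairwise ML over
bivariate-normal cell probabilities), parallel analysis against the 95th
percentile of eigenvalues from random normal data, minres extraction
(uniquenesses optimized to minimize off-diagonal squared residuals),
varimax pre-rotation and a Promax transform with power 4. Heywood cases
are flagged and clipped, never hidden.

## Microbiome features

**QC order**: sample floor (< 5 total reads) → ASV length window
[251, 254] inclusive → contaminant rule → rare-ASV rule (relative
abundance < 1% in every sample AND count < 10 in every sample). The
default contaminant rule is blank-based: an ASV is a contaminant when
detected in ≥ 90% of negative controls and at higher mean relative
abundance in controls than in study samples. A literal
sample-prevalence rule (drop ASVs present in < 90% of study samples) is
available behind `contaminant_rule="literal_prevalence"`; it is far more
aggressive and not the default because blank-based decontamination is
what a panel of extraction/swab/vial blanks supports.

**CSS.** The scaling factor is the sum of a sample's counts up to the
chosen quantile `l` of its nonzero counts (zeros excluded so that sparse
samples do not collapse the quantile to zero). `l` is chosen adaptively:
the smallest grid quantile at which the median absolute relative
deviation of truncated sums across samples exceeds 0.1, floored at the
median. Normalized values are count/factor × 1000, and log2 factors are
exported as model offsets.

**Diversity** uses scikit-bio estimators (observed features,
bias-corrected Chao1, Shannon in nats, inverse Simpson, ACE with rare
threshold 10) on raw counts. Bray–Curtis uses scipy; optional
rarefaction is a seeded single draw without replacement
(multivariate hypergeometric), applied to Bray–Curtis only — the
phylogenetic (UniFrac) distances are out of scope, so the question of
which distance the original workflow rarefied does not arise here
beyond this config switch.

**PERMANOVA** is sequential (type-I) on the Gower-centered matrix
G = −½ J D² J: terms enter in the stated order, pseudo-F uses the
residual mean square, and p-values come from permutations of the raw
observations (default 999, seeded). The single-term case matches
scikit-bio's one-way PERMANOVA exactly (cross-checked in the tests);
the multi-term sequential partition is implemented here because no
installed package provides it.

**Volatility** is the per-participant T2→T3 distance, modeled by OLS on
the gestational-week difference with a cohort adjustment.

## Zero-inflated Gaussian differential abundance

Per feature, y = log2(count + 1) follows a mixture of a point mass at
zero — probability logistic in log2 library size, slope capped at 0 so
dropout cannot increase with depth — and a Gaussian with mean
Xβ + offset, offset = log2 CSS factor. EM alternates posterior zero
responsibilities with weighted least squares and a weighted logistic
refit; convergence at max parameter change < 1e−6 or 100 iterations
(non-convergence flagged, last iterate returned). Inference uses the
weighted information with variance rescaled to the effective df
(Σ responsibilities − rank). With no zeros the mixture collapses and
coefficients equal OLS to 1e−8 (asserted). No empirical-Bayes variance
moderation is applied — each feature's variance is its own — a
deliberate divergence from moderated pipelines, documented here.
Features detected in < 10% of samples are not modeled (the mixture is
unidentifiable there). BH q-values are computed across features within
each target; significance tiers are q < 0.05 and q < 0.01.

## Microbiome association index

Genus aggregation sums CSS-normalized abundances over ASVs sharing a
genus; unassigned ASVs pool per family as `unclassified_<family>`. The
kinship is K = ZZ'/m over log-transformed (pseudocount = half the
smallest nonzero value), per-genus standardized abundances; constant
genera are dropped, numerical negative eigenvalues clipped at zero.

REML maximizes the restricted likelihood over the three log-variances
(kinship, participant intercept, residual) by L-BFGS-B, with a coarse
grid fallback on non-convergence; a dense 25³ grid search is kept as an
independent oracle. b² = σ²_K/(σ²_K + σ²_participant + σ²_residual):
the participant variance stays in the denominator because "variance
explained" should partition total variance (`b2_denominator`
exposes the alternative). The LRT for σ²_K uses the ½χ²₀ + ½χ²₁
boundary mixture. Cross-validation stratifies folds by participant
(both visits together, preventing within-person leakage); test
predictions are fixed effects plus the kinship BLUP through the
train–test K block (participant effects are zero for unseen people), and
R² = 1 − SSE/SST pooled over folds. Kinship BLUP prediction equals ridge
regression on standardized genus features with penalty σ²_e/σ²_K (dual
identity, asserted numerically).

Stepwise covariate selection is forward, on fixed-effects-only OLS with
block F-tests at entry p < 0.05; its family-wise inflation under the
null (~5% per candidate) is documented by the null test rather than
corrected, matching standard stepwise practice.

## Immune markers

Analyte concentrations are analyzed in natural log (the base only
rescales coefficients). Linear models adjust for BMI and site;
categorical predictors use treatment coding with the largest level as
reference. Partial Spearman residualizes average ranks on the controls'
ranks and correlates by Pearson — with no controls this is exactly plain
Spearman. Below-detection values impute at limit/√2 with flags. k-means
runs on log, per-analyte standardized profiles with n_init = 20 and a
silhouette-maximizing k.

## Networks

SparCC draws Dirichlet(count + 1) fractions per sample (20 inferences,
median estimate; a deterministic posterior-mean mode exists for exact
permutation invariance), solves basis variances from the sparsity
approximation, and iteratively excludes the most correlated pair while
|r| > 0.1, up to 10 pairs. Bootstrap edge calibration permutes each
taxon's counts across samples — destroying co-abundance, preserving
marginals — and declares an edge significant when |r_obs| > 3·SD_boot(r)
and |z_obs| > 3·SD_boot(z) with z = r/SD_boot(r) (the z-score definition
is this package's, stated here because the rule is otherwise
underdetermined; with this definition the two conditions nearly
coincide, and both are evaluated literally). The integrated network
admits cytokine–cytokine edges at |ρ| > 0.65 & q < 0.001, stress edges
at q < 0.05, taxon–taxon edges from the bootstrap-significant SparCC
set, and taxon–cytokine edges at q < 0.005. Modules come from greedy
modularity on |weight|; the bridge score counts distinct neighbor
communities; articulation points are reported. SparCC runs at genus
level by default (ASV level is a caller choice).

## Synthetic-data generator

The generator is first-class, tested code that defines the study
conditions: cohorts of 38 (urban) and 46 (suburban) participants sampled
at T2 and T3; site-conditional covariates with the cohort-summary rates
(urban: obesity 17/38, nulliparity 12/38, age 28.6 ± 5.5, BMI
32.0 ± 8.2, race 12:24:3 Hispanic:NH-Black:NH-White; suburban: 13/46,
19/46, 32.3 ± 3.0, 28.9 ± 6.0, 1:5:36), gestational weeks ~24/29 at T2
and +9 weeks at T3. The obesity flag is drawn at its marginal rate
rather than derived from the simulated BMI; the two are marginally, not
jointly, calibrated. Race/ethnicity is a 3-level label with no finer
structure (it is only a fixed covariate downstream).

Latent (ED, SE) are bivariate normal with correlation −0.4 — a config
knob, not an estimate, since the true latent correlation is unknown —
shared per participant with between-visit correlation 0.7. Items load at
0.8 with unit noise, standardized and cut at fixed thresholds (−1.5,
−0.5, 0.5, 1.5), which keeps all five categories occupied at n ≈ 40 per
cohort. Non-invariance is planted on items e, f, h in the suburban
cohort with loading gaps of 0.5 and intercept gaps of 0.3 whose
directions alternate within factor (e: −, h: +, f: −): a
common-direction shift of half a factor's items is absorbed by the free
factor variance/mean of the non-reference group and leaves the planted
set unidentifiable in population, so alternating directions are required
for planted-truth recovery to be a meaningful check.

ASV counts: 150 ASVs over ~40 genera; log-normal basis abundances with
genus-level covariance (ASVs of a genus share a genus factor), a
participant random intercept with ICC 0.5 linking T2/T3, planted
log-linear taxon–trait effects (default: *B. uniformis*-like vs SE,
magnitude −1.0), multinomial sampling at depths 8000–30000 and
depth-dependent dropout p₀ = logistic(4 − 0.7·log depth). Cytokines: 21
analytes, log-normal with a common immune factor loading +0.6 everywhere
except the CXCL11-like analyte (−0.6), BMI as a log-scale confounder
(0.03 per unit), and a −0.4 coupling of CXCL11 to the planted taxon.

What the generator does **not** emulate: read-level sequencing error,
chimeras, taxonomic misassignment, realistic phylogenetic or
demographic microstructure, batch effects, or item-specific response
styles. Passing recovery tests therefore show the estimators are
correct under their assumed models at study-like sizes — not that the
original biological findings are reproduced.

## Validation battery and problem sizes

Because the study's questionnaire and cytokine tables are not public,
the battery substitutes planted-truth recovery and calibration checks,
with problem sizes chosen as the package's own simulation design:

- **Item-pruning recovery**: 50 replicates at n = 2000 per cohort
  (single-visit rows). The large-sample regime is used because the final
  stage of the iterative procedure — detecting the last non-invariant
  item after the others are removed, partially absorbed by the freed
  factor variance — sits near the significance boundary at a few hundred
  per group; the intrinsic over-removal rate (~10%, see above) is the
  main residual failure mode.
- **b² recovery**: 50 replicates, 168 samples (84 participants × 2),
  100 genera, planted b² = 0.8 with participant ICC; ten-fold
  participant-stratified CV gain compared against 0.25.
- **ZIG**: 20 full-null replicates (no planted effects) for FDR
  calibration; 50 replicates at study size for sign/significance
  recovery of the planted taxon.
- **SparCC**: 20 null replicates (50 taxa × 200 samples) for the mean
  |r| bound; 20 bootstrap replicates (45 taxa × 150 samples, 100
  bootstraps) for the 3·SD rule's false-positive fraction.
- **PERMANOVA / LRT type-I**: 200 replicates each; PERMANOVA calibration
  uses 199 permutations per replicate (the analysis default stays 999;
  at α = 0.05 the coarser permutation grid does not change the
  rejection decision).
- **Oracles**: ZIG = OLS on zero-free data (1e−8); MI vs refit at the
  largest released constraint under a small planted gap (15%); BLUP =
  ridge dual (1e−8); REML vs 25³ grid.

## Known limitations

- The CFA is continuous-ML on ordinal data (no WLSMV); chi-squares are
  slightly inflated by discretization kurtosis, which the invariance
  *differences* mostly cancel but do not remove entirely.
- No scaled/robust difference tests; negative differences floor at 0.
- Only two groups are exercised (more are structurally supported but
  untested); modification indices require exactly two.
- The ZIG model has no variance moderation and its p-values rely on a
  t approximation with effective df.
- SparCC's exclusion heuristic and the bootstrap rule inherit the
  original method's approximations; the z-score component of the edge
  rule is nearly redundant by construction.
- UniFrac (phylogenetic) distances are out of scope; no tree is built.
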