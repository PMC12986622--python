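# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the limitations of the `ricegs` pipeline.

## Statistical models

**Genomic relationship matrix.** VanRaden's first method with in-sample
allele frequencies: with dosage matrix X (n accessions × m SNPs, entries
0/1/2 counting alternate alleles) and pⱼ the observed alternate-allele
frequency, W = X − 2p column-wise and G = WWᵀ / (2Σⱼ pⱼ(1−pⱼ)), the sum
over polymorphic SNPs only (monomorphic columns center to zero and are
excluded from the denominator). In-sample frequencies make 1ᵀG1 = 0
exactly, which the tests assert.

**Variance components.** The single-trait mixed model y = 1μ + g + e with
g ~ N(0, Gσ²g), e ~ N(0, Iσ²e) is fitted by restricted maximum likelihood.
G is eigendecomposed once (O(n³)); in the rotated basis every likelihood,
gradient and average-information evaluation is O(n). Each iteration
proposes an Average-Information (quasi-Newton) update of (σ²g, σ²e),
projected onto the parameter space so that boundary optima (σ²g → 0) are
reached directly; if the projected AI step would lower the restricted
likelihood, an EM step is taken instead. Starting values are
σ²g = σ²e = var(y)/2; components are floored at 10⁻⁸·var(y) so the
heritability ratio σ²g/(σ²g+σ²e) stays finite and inside (0, 1);
convergence is declared when the largest parameter change falls below
tol·var(y) (tol = 10⁻⁶, max 100 iterations; non-convergence is reported in
the result, never raised). A kinship that is numerically a multiple of the
identity triggers an unidentifiability warning — the genetic and residual
variances then share a single degree of freedom and only their sum is
meaningful.

**GBLUP.** Marker effects i.i.d. normal. The default fit is deterministic:
AI-REML on the VanRaden kinship gives (σ²g, σ²e), and the exact ridge
solution g = Xcᵀ(XcXcᵀ + λI)⁻¹(y − ȳ) with λ = 2Σp(1−p)·σ²e/σ²g follows,
where Xc is centered on training means (stored in the fit and re-applied
at prediction). This is algebraically identical to kinship-space BLUP with
matched shrinkage — an identity the acceptance suite verifies to 10⁻⁶. A
Gibbs-sampling mode (normal marker prior, scaled-inverse-χ² priors on both
variances) exists for posterior summaries; the deterministic path is the
default because it admits exact regression tests and is far cheaper.

**Bayesian LASSO.** Park–Casella hierarchy: gⱼ | τⱼ², σ² ~ N(0, τⱼ²σ²);
1/τⱼ² | · ~ Inverse-Gaussian(√(λ²σ²/gⱼ²), λ²); λ² ~ Gamma(shape 1.1,
rate 1.12×10⁻⁷) with the conjugate full conditional
Gamma(shape + m, rate + Στⱼ²/2); σ² ~ scaled-inverse-χ²(df 5, scale 3.5)
parameterized with density ∝ (σ²)^−(df/2+1) exp(−scale/(2σ²)) and the
conjugate update including the marker-effect contribution
(df + n + m, scale + ‖r‖² + Σgⱼ²/τⱼ²); flat prior on μ. The "rate" of the
Gamma hyperprior is a true rate (mean = shape/rate). Default schedule:
15,000 iterations, 5,000 burn-in, thinning 5 → exactly 2,000 retained
draws; marker effects are posterior means. All draws come from one seeded
`numpy` generator, so fits are bit-reproducible. Effects numerically at
zero are floored at 10⁻¹² before the inverse-Gaussian update. Known
limitation: on weak-signal problems with few markers the sampler can drift
into the degenerate full-shrinkage mode that this hierarchy admits (λ²
grows without bound while all effects collapse); the extremely diffuse λ²
hyperprior offers no restraint there. The λ²-fixed option
(`lambda2_fixed`) disables the hyperprior and is used by the shrinkage
ordering tests.

**PC regression.** Principal components of the centered dosage matrix,
keeping the smallest k whose cumulative explained variance reaches the
target (default 0.95); scores are standardized by training SDs and the
loadings + standardization constants travel with the fit, so new samples
are projected, never refit. The regressor backend is pluggable
(OLS and mean built in, LightGBM optional, arbitrary fit/predict objects
registrable) and outside the correctness surface.

**Evaluation.** Accuracy is Pearson's r between observed phenotypes and
GEBVs, computed per validation fold and averaged over the k×repeats folds
(never pooled over concatenated predictions). Partitions are uniform
random with fold sizes differing by at most one; all training statistics
(centering, kinship, PCA) are computed inside each training fold. A model
failure in a fold is recorded as a missing value with a warning and
excluded from the mean. Zero variance in either vector raises rather than
silently scoring 0. Independent validation trains one model per season on
the core set and scores only the season-unique accessions.

**Screening.** Candidates are ranked by GEBV — ascending when lower values
are favourable (internode length, height), descending otherwise (bending
resistance) — with ties broken by accession id so selections are
reproducible. The 9-level ordinal lodging score maps onto four categories
(x ≤ 2 highly resistant; 2 < x < 5 moderately; 5 ≤ x < 7 susceptible;
x ≥ 7 extremely susceptible), and the report compares category proportions
of the selection against the base population, headline quantity being the
combined resistant (HLR+MLR) share.

## Genotype QC

Variant filters run in the fixed order non-biallelic → missing rate → MAF,
each removal attributed to exactly one filter. The missing-rate filter
removes variants with **more than** 20% missing calls by default — the
plain-language reading of the upstream protocol, not the vcftools
`--max-missing 0.2` flag convention (which would keep anything up to 80%
missing); an all-missing variant is always removed here. MAF is computed
over non-missing calls and is invariant to allele labelling.

LD pruning interprets the 52/10/0.5 parameters as a count-based window:
within each window of 52 consecutive variants, while any surviving pair
exceeds r² = 0.5 (strict inequality), the worst pair's lower-MAF member is
removed (ties: the later position); the window slides by 10. This greedy
order is pinned down because the upstream tool's internal order is not
reproducible; an exhaustive re-scan oracle in the test suite confirms the
kept set and that no surviving pair violates the threshold in any window
placement.

Imputation is deterministic and single-site (column mean rounded to the
nearest dosage with ties toward the heterozygote, or column mode) —
complete dosages are all the downstream models need, and phasing-based
imputation is out of scope.

Panel merging matches variants on (chromosome, position): exact
(ref, alt) matches are kept, swapped alleles are kept with dosages flipped
to 2−x, strand-ambiguous A/T and C/G swaps and all other mismatches are
dropped — the conservative standard where the upstream procedure is
unstated. Positions duplicated within a panel are dropped as mismatches.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes, at
desk scale:

* **Genotypes** come from a founder-haplotype mosaic: each accession
  carries two haplotypes copied from a small founder pool (default 16)
  with a per-SNP probability (default 0.02) of switching to a uniformly
  redrawn founder. Neighbouring SNPs usually share a donor, which yields
  blockwise LD that decays with distance and weakens as the switch rate
  grows — a qualitative, tunable stand-in for real LD decay, chosen over
  coalescent simulation for simplicity and seed-reproducibility. A minimum
  MAF (default 0.05) is enforced by redrawing founder alleles at failing
  SNPs for a bounded number of rounds; exhausting the budget is a loud
  generation failure.
* **Phenotypes** are strictly additive: each trait samples a QTL subset
  and normal effects; the two seasons' effect vectors share the configured
  genetic correlation (default 0.7 — a free parameter, since no
  paired-season genetic correlation is reported for these traits), exact
  at ρ = ±1. Gaussian noise is residualized against the genetic values and
  scaled so var(u)/var(y) equals the target h² exactly on the realized
  sample; the realized value is recorded in the ground-truth record. The
  seven default traits carry the published heritability spread
  (0.23–0.77).
* **Membership** splits accessions into a core set phenotyped in both
  seasons plus season-unique sets (defaults 217/98/123 in the analysis
  drivers, matching the study design's 315/340 season totals).
* **Candidates** are drawn from the same founder pool (so marker effects
  transfer), and their ordinal lodging score discretizes a latent
  liability loading −1.0 on the culm-strength breeding value and +0.5 on
  the height breeding value, plus N(0, sd²) noise. Default discretization
  uses fixed Gaussian cut points chosen so the four categories have
  roughly a 31/42/14/12% base mix (the reported base proportions of the
  large rice diversity panel); an equal-frequency rule is available, and
  the rule used is recorded with the output.

Stage seeds derive from the master seed by fixed offsets; identical
config + seed reproduces every output bit-for-bit.

What the generator does **not** emulate: population structure and
admixture, genotyping error and missingness patterns, dominance/epistasis,
genotype-by-environment interaction beyond the single genetic correlation,
and the real LD decay profile. Passing tests therefore demonstrate
correctness of the machinery and qualitative behaviors (accuracy rising
with heritability, screening enrichment in the loaded direction) — not
real-data accuracy levels.

## Problem sizes and numerical choices

The analysis drivers use a 438 × 2,000-SNP panel, and the benchmark suite
uses n = 300–500, m = 1,500–2,000 with 5–10 seeds per claim — sizes chosen
so each pipeline property is measured well clear of sampling noise while a
full run stays interactive on one CPU. The Bayesian LASSO's full 15,000-
iteration schedule is exercised on a small panel (its per-iteration cost is
O(nm)); the CV drivers use a shortened chain for the full trait table,
stated in the script. Singular ridge systems receive a logged 10⁻⁸ jitter.
In `column_mean_rounded` imputation a mean exactly halfway between two
dosages rounds to the heterozygote. PCA ranks are decided with a 10⁻⁹
slack on cumulative explained variance to absorb floating-point noise at
target 1.0.

## Known limitations

* AI-REML handles a single random effect and an intercept only — no
  multi-trait models, fixed covariates, or dominance kinships.
* The Bayesian LASSO's degenerate-mode risk (above) at small m.
* The LD-pruning tie-break, while fully specified and oracle-checked, is
  one of several defensible orders; kept sets are not comparable across
  tools.
* Ordinal-score candidates are scored on liability truth, not on simulated
  field phenotypes; enrichment tests are directional, not calibrated to
  any published enrichment percentage, which depends on real phenotypes.
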