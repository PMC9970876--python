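# Methods

This note records the models, numerical choices and design decisions behind
`discoprofile`, and what the synthetic-data experiments do and do not show.

## Instrument selection and harmonization

Two summary-statistics tables (BMI, continuous s.d. scale; T2D, log-OR scale)
are cross-referenced by SNP id. Harmonization expresses both effects per copy
of a shared effect allele: if the second study reports the opposite allele the
sign is flipped and the frequency complemented. No strand inference is
attempted — non-matching allele sets are dropped, as are indels (alleles are
restricted to single bases at parse time) and palindromic A/T or C/G SNPs with
MAF above 30% (strand-ambiguous). MAF for the palindrome rule comes from the
first study; when one study lacks a frequency the other's is used, and SNPs
with no frequency in either are dropped, since the standardization formula
needs MAF.

Filters: MAF > 1% and P < 5×10⁻⁸ in *both* studies. Clumping is greedy
against a reference panel: repeatedly keep the strongest remaining SNP and
drop neighbours with r² ≥ 0.01 within a symmetric, inclusive 500-kb window
(|Δpos| ≤ 500,000). The ranking statistic is the sum of −log₁₀ p across the
two GWAS (configurable to min-p or BMI-p); this favours strong dual signals
and is deterministic, with residual ties broken by SNP id. After alignment to
the BMI-increasing allele (flipping both effects and swapping alleles when
β_BMI < 0), the label is the sign of the aligned T2D effect; β_T2D exactly 0
is excluded rather than arbitrarily labelled. A replication table contributes
a per-SNP sign-agreement flag after the same allele alignment; SNPs absent
from replication stay unset.

## Phenome scan

Per (SNP, trait) cell: z = β/SE, SE* = 1/√(2·MAF·(1−MAF)·(n + z²)),
β* = z·SE*. The identity β* = z·SE* is asserted exactly throughout. QC drops
studies with n ≤ 500 and, for binary traits, cells with fewer than 25 minor
alleles in the smallest group (2·MAF·n_smallest < 25). Traits matching a
T2D-family name pattern are excluded from the scan to avoid circularity.
When a SNP is missing from a trait table, the best panel proxy with r² ≥ 0.5
within 500 kb substitutes; its effect is re-signed by the sign of the
proxy–index dosage correlation in the panel (the correlation-sign rule is this
package's convention — allele-level alignment between a proxy and an index SNP
is not otherwise defined).

## Profile comparison

Stage one pools each profile's standardized effects per trait with the
Paule–Mandel estimator: τ̂² is the root of the generalized Q equation,
found by bisection to relative tolerance 1e-10 (Q is monotone decreasing in
τ²); τ̂² = 0 whenever Q(0) ≤ k − 1, in which case pooling reduces exactly to
fixed-effect inverse-variance weighting. Missing cells are simply absent from
the pool (meta-analysis tolerates missingness); they are zero-imputed only
for the Boruta matrix, which needs complete input, with a logged count.

The δ-test compares pooled profiles: δ = |β̂_C − β̂_D|,
SE_δ² = SE_C² + SE_D², z = δ/SE_δ, two-sided normal p. Benjamini–Hochberg
FDR at 5% is applied in two families — all per-profile p-values, and all δ
p-values — within each phenotypic domain when a domain map is supplied
(single family by default; the global-vs-per-domain choice is configurable
because either reading is defensible). Stage two receives traits where some
pooled estimate *and* δ pass FDR.

**Boruta.** Each iteration appends permuted shadow copies of every trait,
fits a random-forest classifier of the SNP labels, and scores a hit for every
trait whose Gini importance beats the maximum shadow importance; hit counts
are referred to two-sided binomial tests against 0.5 at the algorithm's
default 0.01 confidence, Bonferroni-adjusted over all traits. Two departures
from the textbook configuration matter at this problem's scale and are
deliberate: (i) "1,000 iterations" is interpreted as the iteration cap, with
early stop once every trait is decided, each iteration fitting one forest of
a configurable tree count; (ii) the shadow pool holds **five** independent
permutations per trait rather than one. With only a few dozen SNP rows, a
pure-noise trait can carry a large fixed in-sample correlation with the
labels and persistently beat a single shadow set; a larger shadow pool raises
the max-shadow reference to a quantile such lucky correlations rarely clear,
restoring type-I control (measured: 20/20 noise-only matrices with zero
confirmations, 20/20 recoveries of a trait whose class means sit 3 s.d.
apart, at the 48+19-row matrix size). A genuinely separating trait dominates
any shadow pool, so power is unaffected.

**Outliers.** Single-linkage clustering (Euclidean on z rows by default,
correlation distance by flag) over each profile's SNPs; the reported
"last-joined" SNP is the leaf whose first merge occurs at the greatest
height — the variant most distal from the rest of its profile.

## Individual-level GRS batteries

GRSs are exact unweighted sums of risk-allele dosages (missing dosages
mean-imputed with a log entry). Phecode status: case requires codes on ≥ 2
distinct days (two-visit rule, toggleable); listed individuals who are not
cases are excluded; phecodes with < 200 cases are skipped. Logistic, linear
(per-individual median over repeated lab measurements, optional rank-based
inverse-normal transform with Blom offsets) and Cox models adjust for age,
sex and ten genetic-PC surrogates. Cox events are deaths whose primary cause
is in the configured code set; other deaths are censored at the death time.
OR/HR comparisons between profiles reuse the δ-test on the log scale, and
CIs parsed from reports convert through log before SE = width/(2×1.96).
Extreme-decile analysis: within individuals with obesity, the top decile of
each profile score (type-7 quantile; ties at the threshold are included,
which inflates the union fraction for discrete allele-count scores above the
19% analytic value that holds for independent continuous scores) is compared
per trait to all other individuals with obesity by Kruskal–Wallis, optionally
within sex strata.

## SMR & HEIDI

The lead instrument is the minimum-p cis-eQTL within ±500 kb of the TSS that
is also genome-wide significant for BMI (ties by position then id; the window
is configurable). SMR: b = β_out/β_eQTL, T = z²_out·z²_eQTL/(z²_out+z²_eQTL)
referred to χ²₁, se = |b|/√T. HEIDI: secondary SNPs with r² to the lead in
[0.05, 0.9] and eQTL significance χ²₁ > 10 (p < 1.57×10⁻³; the cited
method's convention, adopted because no threshold is otherwise specified),
up to 20 strongest by eQTL p. Differences dᵢ = bᵢ − b_lead get a delta-method
covariance from the LD correlations assuming independent eQTL and outcome
samples; the statistic Σ(dᵢ/sd dᵢ)² follows an eigenvalue-weighted χ²
mixture under the null, inverted by Imhof's integral. The oscillatory tail
(asymptotic period 4π/q) is summed over half-period chunks with repeated
averaging of partial sums, giving ~1e-10 accuracy against closed-form χ²
cases; a fixed-seed Monte-Carlo fallback (10⁶ draws) guards pathological
eigenvalue sets. Regions with no qualifying secondary SNP return an undefined
p_HEIDI and the gene fails the screen. The discordant-gene screen requires
FDR-corrected SMR significance for both BMI and T2D (one BH family per
outcome across all gene×tissue tests), p_HEIDI > 0.01 for both, and opposite
SMR effect signs.

## Tissue-of-action score

Specificity is the tissue's share of the gene's summed median TPM (sums to 1
per gene). Epigenetic evidence is the strongest promoter/enhancer mark
overlapping the lead SNP or an r² ≥ 0.8 proxy in a cell line mapped to the
tissue. The combined score, specificity × weight(none 1, enhancer 2,
promoter 3, both 4), is this package's own construction: the source procedure
sorts on the two criteria without printing a formula, so the weights are
config-exposed and both raw criteria are always emitted next to the combined
score. Zero-specificity tissues rank last with a missing log-score.

## Directional decomposition

Instruments for a mediating trait require P < 5×10⁻⁸ for the trait *and* BMI
(genome-wide significance for both is the default where no trait-side
threshold is otherwise specified), are clumped and BMI-aligned, then split by
trait-effect sign. Each group's T2D effect is pooled by fixed-effect IVW
(β̂ = Σwβ/Σw, w = 1/se²); pooling the union of the two groups equals IVW
over all members, an identity asserted in tests. Proteins use a single cis
instrument (strongest dual-significant SNP in the gene region), where the
pool reduces to the Wald estimate.

## Synthetic data: what it emulates and what it does not

Genotypes come from a Gaussian copula: per individual two latent AR(1)
haplotype chains are thresholded to alleles and summed to dosages. Because
two binary variables with unequal frequencies cannot be strongly correlated,
MAF is drawn once per LD block (uniform on the configured range) and the
latent correlation is calibrated by tetrachoric inversion so the realized
dosage correlation of adjacent SNPs matches the configured within-block LD.
Blocks are mutually independent and placed ≥ 500 kb apart so clumping windows
never span blocks.

GWAS summary statistics are generated analytically: true per-SNP effects are
propagated through the empirical block LD to marginal effects, and observed
effects add block-correlated noise at SE = 1/√(2·MAF·(1−MAF)·n) (log-OR
scale with an effective n for the binary trait). Planted effects are
specified per genotype s.d. and converted to per-allele at each causal SNP's
frequency: instruments in the emulated study are ascertained at genome-wide
significance, so planted instruments must be detectable at the configured
sample sizes irrespective of MAF. Exact logistic GWAS at consortium scale is
deliberately avoided. Default sample sizes (500,000 for the continuous
trait, 150,000 effective for the binary one) and planted profile sizes
(12 concordant, 5 discordant in a 40-block world — scaled down from the
study's 48+19 to keep world generation fast; calibration suites use the full
48+19 where profile size itself matters) are the conditions all recovery
tests quote.

The cohort generator draws fresh individuals from the same block parameters;
BMI is the planted genetic score plus Gaussian noise, T2D follows a logistic
liability, linked phecodes follow logistic links to the concordant GRS
(planted log-OR 0.03/allele), one lab carries a planted 0.05 s.d./allele
effect, and survival is exponential with log-hazard linear in the concordant
GRS (planted HR 1.05/allele) under uniform censoring. eQTL scenarios are
generated at the region level: pleiotropy (one causal SNP drives expression
and, through it, both traits), linkage (distinct causal SNPs at r² ≈ 0.5) and
null, on the standardized scale with AR(1) regional LD. The expression atlas
plants one elevated "true tissue" per gene (~5×n_tissues-fold) with a
promoter mark at the lead SNP in that tissue's cell line and occasional stray
enhancers.

Not emulated: realistic human LD maps, population stratification and
relatedness, imputation uncertainty, genome-build issues, multi-allelic
variants, ascertainment quirks of billing-code phenotypes. Passing tests
therefore demonstrate the *statistical machinery* — calibration under the
null, recovery of planted structure, agreement with independent oracles —
not robustness to those real-data complications.

A single global seed fans out to per-stage streams via a fixed CRC32 hash of
stage names, so every stage is independently reproducible and all generators
are byte-deterministic given (seed, config).

## Numerical and testing choices

- Paule–Mandel bisection tolerance 1e-10 (relative); the test oracle is a
  two-stage dense grid search agreeing to 1e-6.
- BH-FDR is delegated to statsmodels and checked against an explicit step-up
  enumeration on vectors of ≤ 12 p-values; single linkage is delegated to
  scipy and checked against an O(n³) agglomeration oracle.
- Simulation suite sizes (e.g., 20 seeds for recovery rates, 200 for HEIDI
  calibration, 1,000 for null uniformity, cohorts of 3,000 with 600-individual
  panels in the coverage loops) are chosen so the whole test suite and the
  acceptance script each finish in minutes on one CPU while leaving the
  binomial noise of the measured rates well inside the asserted margins.
- Degenerate paths raise typed errors (configuration, empty-input,
  degenerate-input) rather than returning silently wrong numbers; drops are
  always counted and logged, never silent.

## Known limitations

- HEIDI's delta-method covariance needs a strong lead instrument; with weak
  instruments the test is only approximate (the screen's dual genome-wide
  significance requirement enforces this in practice).
- The per-domain FDR option reflects the source analysis's reporting
  structure but cannot be verified against it beyond the printed examples.
- The tissue-of-action combination rule is an explicit stand-in (see above);
  rankings under other monotone weightings are invariant only in the absence
  of score ties.
- Binary-trait standardized effects are interpreted on the liability-ish
  scale the standardization formula implies, with no further transformation.
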