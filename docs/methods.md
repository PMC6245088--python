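# Methods

## The model

Two-sample Mendelian randomization treats L independent SNPs as
instrumental variables for an exposure X (here: serum calcium in SD units,
1 SD ≈ 0.5 mg/dL) on a binary outcome Y (log-odds scale). The summary-level
generative model is

    β_Xj ~ N(γ_j, σ²_Xj)                (exposure study)
    β_Yj ~ N(θ γ_j + α_j, σ²_Yj)        (outcome study)

with γ_j the true per-allele exposure effect, θ the causal log-odds ratio
per exposure SD, and α_j a horizontal-pleiotropy effect (zero for a valid
instrument). The two studies are assumed non-overlapping, so the exposure
and outcome errors are independent; linkage between instrument SNPs is
assumed negligible (instruments selected for pairwise independence).

Estimators and their validity conditions:

- **Wald ratio** β̂_j = β_Yj/β_Xj. First-order delta-method SE
  σ_Yj/|β_Xj| by default (the convention of the summary-data MR
  literature); the second-order form adding β²_Yj σ²_Xj/β⁴_Xj is available
  by flag.
- **IVW** θ̂ = Σw_jβ̂_j/Σw_j, w_j = β̂_j's inverse variance. Unbiased when
  all instruments are valid or pleiotropy is balanced.
- **Maximum likelihood**: the bivariate-normal likelihood above maximized
  over (γ_1..γ_L, θ). Accounts for exposure-side noise that the first-order
  IVW ignores.
- **MR-Egger**: weighted least squares of β_Yj on β_Xj with free intercept,
  weights 1/σ²_Yj. The intercept estimates the mean directional-pleiotropy
  effect; the slope is consistent for θ under InSIDE (pleiotropy
  independent of instrument strength) and NOME (negligible exposure-side
  measurement error, monitored by I²GX).
- **Weighted median**: the 50% point of the inverse-variance-weighted,
  sorted ratio distribution (linear interpolation at percentile positions
  s_j = cumulative weight − w_j/2). Consistent while valid instruments
  carry > 50% of total weight.

## Inference conventions

Combined estimates are tested on Student t with L−1 degrees of freedom
(L−2 for the Egger slope and intercept), and CIs use the same quantiles;
per-SNP estimates use normal quantiles. Effects models:

- `fixed`: SE = (Σw_j)^−1/2.
- `random`: multiplicative overdispersion, SE scaled by √(Q/(L−1)) with Q
  Cochran's statistic — *unfloored*. This pairing is what makes the t
  reference exact: for homogeneous normal ratios the combined z and Q are
  independent, so z/√(Q/(L−1)) ~ t(L−1), and the simulation suite confirms
  nominal 5% type-I error at the null. Flooring the factor at 1 would make
  the t-test conservative by roughly an order of magnitude at L = 5.
- `auto` (default): `random` iff Q > L−1 (I² > 0), else `fixed` — the
  common applied convention, and the behaviour equivalent to a floored
  multiplicative model. The case study resolves to fixed effects (I² = 0
  for both outcomes).

MR-Egger SEs use multiplicative overdispersion floored at 1 (never deflated
below the homoscedastic value). A single-SNP instrument yields df = 0; its
p-value and CI are reported as missing rather than fabricated.

The ML optimizer is exact coordinate ascent: given θ, the optimal
γ_j = (β_Xj/σ²_Xj + θβ_Yj/σ²_Yj)/(1/σ²_Xj + θ²/σ²_Yj); given γ, the
optimal θ is the γ-weighted regression through the origin. θ starts at the
IVW estimate, γ at β_X; each step is an exact conditional maximization, so
the objective increases monotonically. Convergence is |Δθ| < 10⁻¹⁰ with a
cap of 200 iterations; non-convergence raises an error carrying the IVW
fallback. The SE inverts the observed information matrix analytically via
its arrowhead structure. In the σ_Xj → 0 limit the ML estimate equals IVW
(verified to 10⁻⁶ in tests), and the through-origin Egger regression equals
fixed-effects IVW exactly (10⁻¹⁰) — the two closed-form identities used as
independent cross-checks.

Weighted-median SEs come from a parametric bootstrap (each ratio resampled
from N(β̂_j, se²_j)), default 10,000 draws under a fixed default seed of 1,
bit-reproducible; ties in the sort are broken by rsid. I²GX is computed as
an I²-type statistic on the exposure effects, either on the raw β_Xj with
precision 1/σ²_Xj, or (default) on the Egger-weighted scale β_Xj/σ_Yj with
measurement SE σ_Xj/σ_Yj; both are invariant to common rescaling of
(β_Xj, σ_Xj).

## Harmonization

Exposure SNPs absent from the outcome table may be substituted through a
user-supplied proxy map (the case study's CASR variant enters this way; LD
between proxy and index SNP is taken as given, not computed). Allele pairs
are aligned by direct match, flip (sign change plus frequency complement),
or one strand complementation before a hard error. Palindromic (A/T, C/G)
SNPs are dropped when the effect-allele frequency is missing or within 0.08
of 0.5 (a conservative default; the case-study instrument contains none);
otherwise strands are resolved by frequency concordance. All rows are then
oriented so β_X ≥ 0 (flipping both betas together), the orientation MR-Egger
requires. Every input SNP ends in exactly one of the harmonized or dropped
(with reason) lists.

## Power

The closed-form normal approximation for a binary outcome is

    power = Φ( √(n · R² · K(1−K)) · |ln OR| − z_{1−α/2} ),

K the case fraction. At the case study's face-value inputs (n = 72,729,
K = 0.616, R² = 0.0071, OR 1.25, α = 0.05) this gives 0.69, not the 80%
reported alongside those inputs in the source analysis; the parameterization
behind the published figure is not recoverable, so the discrepancy is
documented rather than reconciled, and the power tests assert the formula's
internal properties (monotonicity, inversion round-trip) instead. Similarly,
the instrument constants R² = 0.0071 and F ≈ 86 are consumed as given: the
calcium GWAS per-SNP effects needed to recompute them are unpublished, and
the F formula (R²/(1−R²))·((n−k−1)/k) is oracle-tested on its own.

## The synthetic generator

`simulate_summary_stats` draws the generative model above directly at
summary level. Defaults: L = 50; γ_j ~ U(0.04, 0.10) SD/allele with
σ_Xj ~ U(0.009, 0.013), giving per-SNP first-stage F = (γ/σ_X)² roughly
between 10 and 100 — straddling the conventional weak-instrument boundary;
σ_Yj ~ U(0.05, 0.15), typical of a case-control GWAS of tens of thousands.
Pleiotropy regimes (`none`, `balanced(sd)`, `directional(mean, sd)`,
`inside_violating(rho, sd)`) hit a `prop_invalid` fraction of SNPs, on the
outcome side only — sufficient to exercise every estimator contract at
summary level; individual-level confounding, LD and genotype sampling are
deliberately not emulated, so passing calibration says nothing about, e.g.,
winner's-curse selection or sample overlap in real data. A `noiseless` mode
draws the reported SEs but adds no sampling noise, the regime in which the
estimators' consistency claims become exact algebraic statements.
Calibration replicates derive per-replicate seeds from one master seed via
`numpy.random.SeedSequence`, so each replicate is independently
reproducible; estimator failures are counted and reported, never silently
dropped.

One point deserves emphasis for interpreting the weighted-median checks:
with directional pleiotropy present and *any* nonzero ratio noise, the
finite-sample weighted median targets the median of the ratio mixture and
carries positive bias of order half the median ratio SE even when valid
instruments hold a weight majority. Its celebrated robustness is the
vanishing-noise consistency; the suite therefore demonstrates exact
unbiasedness in the noiseless limit, the monotone breakdown as the invalid
fraction crosses ½, and the bias *ordering* (weighted median ≪ IVW) at
realistic noise.

## The case study

The five-SNP calcium instrument is embedded as the published per-SNP OR
(95% CI) cells for both outcomes. Cells are back-derived to (log-OR, SE)
with normal quantiles — the recomputed z-test p-values reproduce the
printed per-SNP p column to its 2-decimal precision (±0.015, the rounding
of 2-decimal OR/CI inputs). Because those cells are ratio-level, the ML
estimate is computed in the vanishing-exposure-noise limit (where it equals
IVW), and MR-Egger is reported as NOT COMPUTABLE — explicit output, not a
silent omission — since it needs the unpublished per-SNP exposure betas; it
is exercised on simulated data instead. Combined estimates from rounded
inputs are reproducible to about ±0.02 on the OR scale: the overall-cancer
combined OR lands at 0.81–0.83 depending on rounding of the dominant CASR
cell against the published 0.83, while the advanced-cancer OR 0.98
(0.57–1.70, p = 0.93), the heterogeneity p-values (0.43/0.81 vs published
0.44/0.80 at I² = 0) and the weighted medians (0.81/0.92 vs 0.80/0.92)
reproduce directly. The pipeline is deterministic end-to-end; the
weighted-median bootstrap seed defaults to 1.

The phenome-screen fixture lists the two published screened-out variants
with their flagged trait classes; its p-values are synthetic placeholders
below the corrected thresholds (the exact look-up p-values are
unpublished), and the per-SNP look-up counts are set to the published
boundary values (859 and 1,060), reproducing the corrected thresholds
5.8×10⁻⁵ and 4.7×10⁻⁵.

## Known limitations

- Ratio-level fixtures cannot support MR-Egger or I²GX for the case study.
- No LD modelling anywhere: instruments are assumed independent, proxies
  are taken on trust.
- The power approximation ignores case-control ascertainment beyond
  K(1−K) and non-collapsibility of the odds ratio.
- Non-linear exposure effects, multivariable MR, mode-based and outlier-
  robust estimators (e.g. MR-PRESSO) are out of scope.
- Monte-Carlo suite sizes (5,000 null replicates at L = 5; 300–1,000
  replicates for recovery and intercept checks) were chosen as the package's
  standing test conditions; all seeds are fixed in the tests.
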