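# Methods

## Scope and estimands

`mrmediate` estimates, from GWAS summary statistics alone, (i) the total
causal effect of an exposure on an outcome, (ii) the direct effect after
conditioning on candidate mediators, and (iii) the share of the exposure's
excess outcome risk that the mediators account for. All computation is on
the additive scale — log odds ratios for binary traits — with odds ratios
produced only at the reporting boundary. The two-sample design assumes the
exposure and outcome associations come from non-overlapping samples of the
same ancestry; no sample-overlap correction is applied.

## Instrument selection

Instruments are SNPs with exposure association p < 5×10⁻⁸, thinned by
greedy clumping: candidates sorted by ascending p (ties broken by genomic
position, then identifier, for determinism), the best accepted, and every
remaining candidate discarded if it lies within the window (default
10,000 kb, closed interval on 1-based positions) of an accepted SNP with
r² > 0.001. A pair whose r² is *unknown* but which lies inside the window
is treated as correlated and dropped — conservative by construction, so
the procedure never admits a dependent pair on incomplete LD information.
On instances small enough to enumerate, the greedy result is provably the
unique set that is pairwise-independent and p-dominant; the test suite
checks this against an exhaustive oracle.

## Harmonization

The first exposure dataset fixes the effect-allele convention per SNP.
Other traits are aligned by direct allele match, allele swap (effect sign
flipped, EAF complemented), strand complement, or complement-plus-swap;
irreconcilable allele sets drop the SNP with an audit reason rather than
keeping it silently. Palindromic SNPs (A/T, C/G) default to
frequency-based inference: orientation is taken from which side of 0.5
each trait's EAF falls, and the SNP is dropped when either EAF lies within
0.5 ± 0.08 (band configurable; a plain `drop` policy is also available).
Harmonization is involutive and invariant to strand-flipping any input
record, both checked as properties.

## Estimators

**Wald ratio / IVW.** Per-SNP ratio β̂ᵧ/β̂ₓ with first-order SE sᵧ/|β̂ₓ|
(exposure-side uncertainty ignored — adequate for strong instruments).
IVW combines ratios with weights β̂ₓ²/sᵧ², equivalent to zero-intercept
WLS of β̂ᵧ on β̂ₓ. Cochran Q is the weighted sum of squared ratio
residuals on J−1 df. The error model defaults to `auto`: the fixed-effect
SE is inflated by √(Q/df) whenever Q/df > 1 (multiplicative random
effects), mirroring common two-sample MR software; `fixed` and always-on
`multiplicative_random` are switchable. Inference is normal for IVW,
median and mode estimators; t with J−2 df for Egger — a stated convention.

**MR-Egger.** Weighted regression *with* intercept after orienting all
instruments to positive exposure effects. The intercept estimates average
directed pleiotropy (p < 0.05 flags it); slope and intercept SEs carry the
√(max(1, Q/(J−2))) overdispersion factor.

**Weighted median.** Weighted 50th percentile of the ratio distribution
(cumulative-weight interpolation); SE by parametric bootstrap (default
1,000 draws from the per-SNP sampling normals, seed logged).

**Mode estimators.** Kernel-density mode of the ratios with a normal
kernel; bandwidth is `bandwidth_factor` (default 1.0) times a MAD-based
Silverman rule, 0.9·(1.4826·MAD)·J^(−1/5), robust to the ratio outliers
the estimator exists to resist. The weighted variant weights kernels by
inverse-variance weights. Density is maximised over a 2,048-point grid
augmented with the observed ratios; SE by the same bootstrap.

**MVMR.** Zero-intercept WLS of β̂ᵧ on the J×K exposure-effect matrix,
weights 1/sᵧ² (outcome SEs only — standard MVMR-IVW). SEs carry
√(max(1, Q/(J−K))) by default (switchable: the convention is not settled,
so the scaling is explicit config). Exposure measurement error is not
corrected but surfaced through a per-exposure conditional F approximation:
each exposure's effects are regressed on the others' and the mean residual
chi-square against its own SEs is reported; values below ~10 warn of
conditionally weak instruments. An identically-zero exposure column is
estimated around rather than treated as collinear: the regression runs on
the informative columns and the zero column receives a null placeholder —
genuine rank deficiency between non-degenerate columns raises an error
naming the offenders. MVMR instruments are the union of each exposure's
instruments re-clumped jointly by smallest p across exposures.

**MR-PRESSO.** Observed statistic: the sum of leave-one-out weighted
squared residuals. The null re-draws both exposure and outcome effects
from their sampling normals around the leave-one-out fits (n_sim = 1,000
default). Rank p-values use the add-one convention (1 + #{sim ≥ obs}) /
(n_sim + 1); per-SNP outlier p-values are Bonferroni-adjusted over J, so
the detection floor is J/(n_sim+1) — n_sim must exceed J/α to flag
anything at level α. The corrected estimate is exactly IVW on the
non-outliers; the distortion p compares the observed raw-vs-corrected
distortion, two-sided, against the distortion from removing equally many
randomly chosen SNPs. Same seed and inputs give a bit-identical result.

**Mediation.** Candidates are screened at α = 0.05 on both the
exposure→mediator and mediator→outcome IVW p-values, unadjusted for the
number of candidates (mirroring common practice when a modest candidate
list is screened); near-misses remain auditable in the screen table, and a
candidate missing either leg is marked `untested`, never silently
excluded. PERM = 100×(OR − OR_adj)/(OR − 1) from point ORs, unrounded
until the reporting layer (2 decimals). The formula presumes a harmful
total effect; OR_total ≤ 1 raises an orientation error instead of
guessing, and OR_adj < 1 yields PERM > 100% with a warning, uncapped.
"Attenuated to null" means the adjusted 95% CI includes OR = 1. No
product-of-coefficients or natural-effects estimands are offered.

**Colocalization.** Per instrument, a ±500 kb region. Per SNP and trait,
the Wakefield log-ABF ½log(1−r) + ½rz² with r = sd²/(sd²+se²); prior
effect SDs 0.15 (continuous) and 0.2 (binary), per-SNP priors
p1 = p2 = 10⁻⁴, p12 = 10⁻⁵ — the canonical single-causal-variant
defaults, all configurable. Hypothesis sums are accumulated in log space
with log-sum-exp; H3 uses the stable complement log1p(−exp(s₁₂−s₁−s₂)).
Overlapping instrument windows are kept as separate regions (one per
instrument), and the study-level summary is the *unweighted* mean of
region PPH4 values, called shared when above 0.75. The log-space route is
tested against a linear-space brute-force enumeration on ≤25-SNP regions.

## Synthetic data generator

The generator emulates a consortium-scale study directly at the summary
level: per SNP, a true exposure effect γⱼ ~ N(0, 0.05), a mediator effect
αγⱼ + ηⱼ with mediator-specific ηⱼ ~ N(0, 0.05), and an outcome log-odds
effect θ_d γⱼ + θ_m(αγⱼ + ηⱼ) plus an optional pleiotropy term applied in
the exposure-increasing orientation (so a non-zero mean is genuinely
directed after instrument orientation). Observed effects are drawn
Normal(truth, se). The mediator-specific ηⱼ is essential: without it the
exposure and mediator effect columns are exactly proportional and the
MVMR direct effect is unidentified — it stands in for the mediator's own
GWAS instruments that a real union design contributes.

Defaults emulate the motivating study's data scales: exposure SE 0.002
(a ~700k-sample anthropometric GWAS), mediator SE 0.004 (~57k), binary
outcome SE 0.008 (~60k cases / ~1M total), α = 0.6, θ_d = 0.15,
θ_m = 0.3, hence total effect 0.33 and analytic mediated share
100·0.18/0.33 ≈ 54.5% on the log-odds scale (58.6% through the OR-scale
PERM formula — the truth record carries both). EAFs are Uniform(0.05,
0.95); allele pairs are drawn non-palindromic so harmonization retains
every SNP; LD blocks are laid out within one clumping window and distinct
loci beyond it, with within-block r² written to the pair panel. Same
config (including seed) reproduces the datasets bitwise.

What the generator does *not* emulate: individual-level sampling (effects
are exactly asymptotically normal), realistic LD decay, winner's curse,
sample overlap, or population stratification. Passing tests therefore
demonstrate correctness of the estimators under their own assumptions,
not robustness to those real-data pathologies. One visible consequence:
because every simulated SNP affects both traits, reverse-direction MR on
forward-causal synthetic data tends to look significant — the outcome's
"instruments" are the exposure's causal SNPs — unlike in real data where
the two GWAS hit largely distinct loci.

## Pipeline and reproducibility

The config-driven pipeline runs instrument selection per trait,
univariable IVW for exposure→mediator, mediator→outcome and
exposure→outcome, the mediator screen, one MVMR per adjustment set, the
PERM report, the sensitivity battery on the primary contrast, configured
colocalization pairs, and reverse MR, writing one TSV per stage plus a
JSON manifest echoing thresholds, seeds and stage counts (no timestamps).
A stage failure is recorded per contrast without aborting unrelated
contrasts; failure of the primary contrast re-raises after reports are
written. All stochastic stages consume config seeds, so re-running an
unchanged config reproduces every report byte for byte.

## Test problem sizes

Simulation-based checks use sizes chosen to make Monte-Carlo error small
relative to the effects asserted while keeping the suite quick: 200
replicates at 100 SNPs for mediation recovery (mean estimates compared to
analytic truth within 4 standard errors of the mean), 200 replicates at
30 SNPs for type-I calibration of the Egger-intercept and PRESSO-global
tests (acceptance band 2–10% at nominal 5%), 500 null simulations per
PRESSO call in calibration runs and 1,000 where outlier detection at
α = 0.05 with J = 30 requires it, and ≤12-SNP instances for the exhaustive
clumping oracle.

## Known limitations

- No proxy-SNP search or remote LD reference: LD must be supplied.
- Wald/IVW ignore exposure-side uncertainty beyond the conditional-F
  diagnostic; no MVMR-Egger, MVMR-median or Steiger filtering.
- PERM is reported without a confidence interval (point ORs only).
- Colocalization assumes at most one causal variant per trait per region;
  no LD-aware fine-mapping.
- Continuous outcomes get exponentiated betas only if the caller asks for
  OR-style labelling; the package does not decide that relabelling itself.
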