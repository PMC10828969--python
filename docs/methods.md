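# Methods

## Liability-threshold model and structural correlations

A binary phenotype is modelled as the indicator that a latent standard
normal liability exceeds a threshold.  Liability decomposes into additive
genetic (A), shared environment (C) and unique environment (E) components
with standardized variances a², c², e² summing to one.  Relatedness enters
only through the latent pair correlation ρ = k_A·a² + c², with k_A = 0.5
for full siblings and 0.25 for half siblings (expected additive sharing),
and C assumed fully shared for every analysed pair regardless of sibling
type.  Maternal and paternal half-siblings therefore share one structural
correlation; they are kept as separate strata only for descriptive output
and stratum-level tetrachoric fits.

Assumptions worth making explicit: no dominance or epistatic variance, no
sex-specific thresholds, no assortative mating, and equal shared-environment
exposure for full and half siblings — the last being the strongest
assumption of the half-sibling design, since half siblings are less likely
to be reared together.

## Orthant probabilities

All likelihoods reduce to bivariate-normal upper-orthant probabilities
P(X > t₁, Y > t₂ | ρ).  These are computed with the Gauss–Legendre scheme
on the arcsine identity due to Genz (the tvpack `BVND` algorithm), with the
separate tail expansion for |ρ| > 0.925; absolute accuracy is ~1e-15 in the
moderate-correlation branch and better than 1e-12 overall, verified against
closed forms (e.g. P(X>0,Y>0|ρ) = 1/4 + asin(ρ)/2π) and against an
independent quasi-Monte-Carlo CDF implementation.  The routine is
vectorised over thresholds and correlations, which makes exhaustive
(t, ρ)-lattice searches feasible as an independent optimizer oracle in the
tests.

## Tetrachoric estimation

For a collapsed exchangeable table the likelihood is multinomial over
{both affected, discordant, neither} with common threshold; the discordant
cell carries a factor 2 because member order is unobserved.  Optimization
is Nelder–Mead on (t, atanh ρ) with multistart ρ ∈ {0, ±0.3} (flat
likelihoods in sparse tables), convergence 1e-8 on the log-likelihood.
Standard errors come from the numerically differentiated observed
information (`statsmodels.tools.numdiff`), mapped to the natural scale by
the delta method.  Degenerate inputs: a table with no affected members
pins ρ to the −1 boundary, perfect concordance pins it to +1; both are
returned flagged non-converged rather than erroring.

The birth-year-adjusted variant replaces the common threshold with member
cutoffs t = β₀ + β₁·(year − 1980) and maximizes the four-outcome pairwise
likelihood on pair-level data.  Pairs are canonicalised (members sorted by
outcome, then year — the likelihood is exchangeable) and collapsed to
unique (outcome, year, year) rows with weights, so cost scales with the
number of distinct cohort combinations, not pairs.  If birth years show no
variation the slope is not identifiable and the collapsed fit is returned
with a warning.  The reference year 1980 is the midpoint of the 1950–2010
cohort range; the centering choice affects only β₀.

The crude (unadjusted) collapsed-table fit is what reproduces the published
stratum correlations (0.18 / 0.15 / 0.07 / 0.10) to two decimals, so that
is the estimator used for those reproduction targets.

## ACE / AE fitting

The joint likelihood sums the stratum likelihoods with ρ replaced by
k_A·a² + c², sharing one threshold model (β₀, β₁) across strata (a single
prevalence model; per-stratum intercepts were considered and rejected as
not identifiable from the printed margins and not part of the published
analysis).  Variance components are optimized on the standardized scale
under a² ≥ 0, c² ≥ 0, a² + c² ≤ 1 with multistart a² ∈ {0.1, 0.3, 0.6};
a component that lands within 1e-6 of zero is re-optimized with that
component fixed (active set) and reported as exactly 0.  95% CIs use the
delta method on the *unconstrained* observed information evaluated at the
(possibly boundary) optimum — the likelihood is evaluable at slightly
negative components since only ρ enters it — which is why a boundary C can
report a lower bound marginally below zero, the familiar shape of biometric
software output.  If the information matrix is numerically singular (flat
ridge) the affected interval is reported as missing rather than degenerate.

ACE is not identifiable from a single relatedness class: the likelihood is
constant along k_A·a² + c² = const (asserted numerically in the tests), so
a single-stratum ACE request raises.  AE from full siblings alone satisfies
a² = min(1, 2ρ̂) exactly, which serves as a structural regression test.
The ACE-vs-AE likelihood-ratio statistic is referred to χ²(1); because c²
sits on its boundary under the null this p-value is conservative (the
boundary reference is a 50:50 mix of χ²(0) and χ²(1)), which is documented
rather than corrected.

The AE heritability from the published *collapsed* counts is ≈ 0.35
(= 2 × 0.177), higher than the published headline of 29% (95% CI 19–39%).
The headline came from a birth-year-adjusted pairwise likelihood on
individual-level data (fitted with biometric SEM software); the printed
collapsed margins do not carry the within-pair cohort structure needed to
reproduce it, so the adjusted route is validated by simulation instead:
the `fit_biometric` pair-level path recovers both a² and β₁ on synthetic
data with a genuine cohort trend, and the crude fit on the same data is
measurably biased upward, consistent with the direction of the 0.35 vs
0.29 gap.

## Synthetic registry generator

The generator emulates the study conditions: clusters of 2–4 children,
additive values built from latent parental draws
(A_child = (A_mother + A_father)/2 + Mendelian deviation of variance 1/2,
so corr(A) is exactly 0.5 / 0.25 for full / half sibs), C drawn once per
cluster (the strictest reading of "fully shared", reducing to pair-level
sharing for the analysed pairs), E per individual, and a birth-year-linear
threshold.  Defaults: a² = 0.29, c² = 0, baseline prevalence 0.0017 at the
1980 reference, cohorts uniform on 1950–2010, threshold slope
+0.01/year (observed prevalence declining for later cohorts, the pattern a
register with fixed follow-up produces), cluster mix
{full₂ 0.50, full₃ 0.25, full₄ 0.086, mixed 0.164} with paternal fraction
0.66 — chosen so the selected strata split ≈ 84/5/11%, matching the
study's 1,748,528 / 117,298 / 226,196 composition.  Mixed clusters are one
full-sib core child plus one half-sibling; the true cluster-size
distribution is unknown (only pair counts are published), so the mix is a
stand-in exposed in configuration, not an inference.  Parents are latent
(ids only, no phenotypes); twins are never generated, and the pair
selector additionally drops flagged co-twins defensively.

What the generator does **not** emulate: mortality, emigration and
censoring, diagnosis dates, sex-specific thresholds, assortative mating,
dominance, or realistic cohort-size skew (a weighting hook exists via the
birth-year range but the default is uniform).  Passing recovery tests
therefore show the estimator chain is correct under the model's own
assumptions — not that those assumptions hold in register data.

A direct bivariate shortcut (`simulate_pair_phenotypes`,
`simulate_study_tables`) draws correlated liability pairs without pedigree
structure for fast estimator tests; the full registry route is exercised
end-to-end at smaller n.

## Numerical and testing choices

Problem sizes were picked to keep the default suite a few minutes long:
the optimizer-vs-lattice oracle uses random tables with ≤ 200 pairs against
an exhaustive 1e-3-resolution grid (agreement within 2e-3); parameter
recovery at the study's full stratum sizes uses 20 replicates via the
bivariate shortcut; registry-level moment checks use 2e4–6e4 clusters with
3-Monte-Carlo-SE bounds.  Under a null truth the nonnegativity constraint
makes a single component's estimator half-normal, so null bias is assessed
on the ACE fit (both components near zero) and tolerances for weakly
identified component splits are set from their sampling SE, while the
well-identified combination 0.5a² + c² is held to ±0.03.

## Known limitations

Half-sibling information is weak at this prevalence (1–2 concordant pairs
per stratum), so c² is essentially unidentified in the real tables — the
ACE interval for C spans zero and the AE/ACE distinction rests on a flat
likelihood.  The LR boundary mixture is not applied.  The pipeline's
`describe`/`tetrachoric`/`fit` stages accept any correctly formatted
collapsed table, but the package deliberately implements no case
ascertainment, register linkage, or histotype/age stratification.
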