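# sibace — sibling-design heritability of a rare binary trait

`sibace` estimates how much of the variation in susceptibility to a rare
binary disease — the motivating application is nervous system tumors
ascertained from nationwide Swedish registers — is attributable to additive
genetic factors (A), shared environment (C) and individual-specific
environment (E), using full- and half-sibling pairs instead of twins.

## The model

Each individual carries a latent standard-normal liability

```
y* = a·A + c·C + e·E,        a² + c² + e² = 1,
```

and is affected iff `y* > t`, where the threshold follows a probit
birth-cohort model `t = β₀ + β₁·(birth_year − 1980)`.  For a sibling pair
the latent correlation is structural:

```
ρ = k_A·a² + c²,   k_A = 0.5 (full sibs), 0.25 (half sibs),
```

with shared environment fully shared for every analysed pair.  A collapsed
pair table (n₁₁ both affected, n₁₀ discordant, n₀₀ neither) has the
exchangeable multinomial likelihood

```
L(t, ρ) = n₁₁·log P₁₁ + n₁₀·log 2P₁₀ + n₀₀·log P₀₀,
P₁₁ = P(X > t, Y > t | ρ),  P₁₀ = Φ̄(t) − P₁₁,  P₀₀ = 1 − 2Φ̄(t) + P₁₁,
```

where orthant probabilities are evaluated with Genz's algorithm to ~1e-12.
Maximizing per stratum gives the tetrachoric correlation; maximizing
jointly with ρ replaced by `k_A·a² + c²` gives the ACE / AE
variance-component fit (heritability = a²).  The descriptive companion is
probandwise concordance `2n₁₁/(2n₁₁ + n₁₀)`.

The package also contains the upstream study design: building family
clusters from shared parents, random selection of one sibling pair per
cluster with paternal half-siblings prioritized in mixed clusters, and a
synthetic registry generator with Mendelian kinship-structured liabilities
for validating every stage.

## Worked example

```python
from sibace import fit_tetrachoric, fit_biometric, probandwise_concordance
from sibace.datasets import selected_pair_tables, pooled_half_table

tables = selected_pair_tables()          # published collapsed counts
full = tables["full"]                    # n11=25, n10=5934, n00=1742569

print(round(probandwise_concordance(full), 3))   # 0.008
fit = fit_tetrachoric(full)
print(round(fit.rho, 2), round(fit.se_rho, 2))   # 0.18 0.03

ae = fit_biometric(tables, model="AE")
print(round(ae.a2, 2), [round(x, 2) for x in ae.ci_a2])  # 0.35 [0.26, 0.45]
```

The concordance (0.008: a sibling of an affected person has a ~0.8% risk)
and the tetrachoric correlation (0.18 ± 0.03 on the liability scale) match
the source study's printed values.  The AE heritability from the collapsed
counts (0.35) is the crude, common-threshold estimate; the study's headline
29% came from a birth-year-adjusted pairwise likelihood on individual-level
data, which the collapsed printed tables cannot reconstruct —
`fit_biometric` performs that adjusted fit when given pair-level data with
birth years (see `docs/methods.md`).

The numbered scripts under `analysis/` run the full narrative — published
descriptives, tetrachoric fits, a synthetic end-to-end registry run, model
fits and a parameter-recovery simulation — writing their tables under
`results/`.  The same stages are available as a CLI
(`sibace simulate | select-pairs | describe | tetrachoric | fit | all`).

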