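# funcrare

Species-level functional rarity analysis for tree communities.

Forest inventories consistently show that most tree species are locally
rare, which raises the question whether those rare species are functionally
expendable or hold trait combinations nobody else in the community has.
`funcrare` implements the standard species-level answer for forest
ecologists working from plot censuses (stems with DBH ≥ 10 cm) and
species × trait tables: it quantifies each species' functional
*specialization*, *originality* and *redundancy* in a multidimensional trait
space, relates these indices to the species' abundance, contribution to
aboveground carbon (AGC) and maximum attained size, and tests whether the
rare specialists are disproportionately the large-statured species.

## The indices

Traits (by default wood density WD, specific leaf area SLA, leaf C/N/P
content, leaf δ¹³C) are screened for normality (Shapiro–Wilk), log-transformed
when right-skewed, rescaled to [0, 1] and z-scored, giving a standardized
functional space in which every axis has mean 0 and unit variance. For
species *i* with coordinate vector **xᵢ** in that space:

- **FSpeS** (functional specialization) = ‖**xᵢ**‖, the Euclidean distance to
  the community centroid. Species far from the centroid hold extreme trait
  combinations.
- **FOriS** (functional originality) = min_{j≠i} ‖**xᵢ** − **xⱼ**‖, the
  distance to the nearest neighbouring species. Isolated species score high.
- **FRedS** (functional redundancy) = 1 − FOriS: a species whose traits are
  closely shared by another species is redundant.

Both distances are divided by their across-species maximum so the indices
live on a 0–1 scale (raw distances are available with `normalize=False`).

Community covariates per species: relative abundance (stem count as % of the
most abundant species' count, with classes abundant > 10 %, nonabundant
5–10 %, rare < 5 %), % contribution to the community AGC stock (per-tree
AGC = 0.5 × 0.0509 ρ D² H, heights from a site-level height–diameter model),
maximum DBH (with "large tree" flag at ≥ 70 cm), and hyperdominance (the
minimal set of top carbon contributors jointly holding > 50 % of AGC).

Because index–abundance clouds are triangular (variance shrinking toward
common species), associations are fitted both by OLS and by quantile
regression near the informative boundary (τ = 0.75/0.90 for FSpeS,
τ = 0.25/0.10 for FRedS), with the quantile fit solved exactly as a linear
program and slope p-values from a seeded pair bootstrap. The rare-species
size gradient — mean maximum DBH above (below) moving FSpeS (FRedS)
thresholds in steps of 0.1 — is tested with 10,000 bootstrap resamples and
a 95 % percentile CI (a permutation null is also available).

A fully parameterized synthetic-community generator (lognormal or log-series
abundances, optional monodominant species, truncated-Weibull diameters,
six correlated traits, and a plantable "distinctiveness" displacement of
rare, large-statured species) makes every stage testable without field data.

## Worked example

```python
import funcrare as fr

cfg = fr.RunConfig(synthetic=fr.default_paper_like_config("mixed", seed=7),
                   bootstrap_B=500, randomization_R=2000, seed=7)
res = fr.run_pipeline(cfg)
m = res["mixed"]

assoc = m["associations"]
print(assoc[assoc.method == "quantile"][["response", "tau", "slope", "p"]])
g = m["size_gradients"]["FSpeS"]
print(f"specialization gradient: slope={g.observed_slope:.1f} cm/unit, "
      f"95% CI [{g.ci_low:.1f}, {g.ci_high:.1f}], significant={g.significant}")
```

prints

```
response  tau     slope        p
   FSpeS 0.75 -0.001843 0.008000
   FSpeS 0.90 -0.003258 0.001996
   FRedS 0.25  0.000758 0.042000
   FRedS 0.10  0.003752 0.001996
specialization gradient: slope=33.5 cm/unit, 95% CI [10.9, 98.5], significant=True
```

Read: the upper envelope of specialization falls with abundance and the
lower envelope of redundancy rises (the triangular pattern — the most
specialized, least redundant species are all rare), and among rare species
the mean maximum diameter climbs by ≈ 34 cm per unit of specialization
threshold, a gradient whose bootstrap CI excludes zero. In this simulated
community 16 of 90 species exceed a specialization of 0.6.

The same analysis runs from CSV files (`inventory.csv`, `traits.csv`,
`wood_density.csv`; dialects documented in `funcrare.cli_io`) through the
command line:

```
funcrare simulate --forest-type mixed --seed 7 --out data/
funcrare run --config cfg.json --out results/
funcrare indices --traits data/traits.csv --out profiles.csv
```

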