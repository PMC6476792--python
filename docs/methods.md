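# Methods

This note documents the models, defaults and numerical choices behind
`funcrare`, and what the synthetic-data tests do and do not establish.

## Trait space

Individual measurements are aggregated to species by the arithmetic mean
(median available via `aggregate="median"`); the analysis is species-level
throughout, and intraspecific variation is deliberately out of scope.
Each trait is screened with the Shapiro–Wilk test (α = 0.05 by default) and
log-transformed (natural log) only when it is simultaneously non-normal,
right-skewed (sample skewness > 0) and strictly positive. The skewness
condition prevents left-skewed or merely heavy-tailed traits from being
logged; leaf δ¹³C, which is negative per mille, can never qualify.
Per-trait overrides pin the decision either way.

After the transform, traits are rescaled to [0, 1] and then centered and
scaled to unit sample standard deviation (n − 1 denominator). The rescaling
is affine and therefore cannot change the final z-scored axes; it is kept
because equal trait weighting is conventionally described on the [0, 1]
scale, and its no-op status is asserted by test (`standardize∘rescale01 ≡
standardize` to 1e-12). Constant traits and missing species-level values
are errors, not imputation targets.

## Functional indices

Specialization is the Euclidean norm of a species' coordinates (the
centroid of a z-scored space is the origin); originality is the nearest-
neighbour Euclidean distance; redundancy is the exact complement
1 − originality. Raw distances in a k-axis z-scored space are unbounded, so
the bounded indices are obtained by dividing by the across-species maximum:
the most extreme species scores exactly 1 and the complement identity is
meaningful. `normalize=False` exposes raw distances. Nearest-neighbour ties
need no tie-break (the minimum is unique as a value), and exact duplicate
species get originality 0 / redundancy 1.

Correctness is defined against independently coded double-loop oracles
(distance recomputation per pair, no shared code) at 1e-10 on random
communities up to 50 species × 6 axes, plus rotation- and scale-invariance
properties.

## Community statistics

All statistics pool the plots of one forest type. Relative abundance is the
stem count as a percentage of the most abundant species' count; classes use
> 10 % (abundant), 5–10 % inclusive on both ends (nonabundant), < 5 % (rare).
Tree aboveground biomass uses the moist-tropical D²H form
AGB [kg] = 0.0509 ρ D² H (ρ in g/cm³, D in cm, H in m) with a 50 % carbon
fraction; both constants are configurable and cancel in the percentage
contributions, which is property-tested. Heights come from a forest-type
height–diameter model — power H = aD^b (default a = 3.5, b = 0.55, giving
≈ 23 m at D = 30 cm) or Weibull H = a(1 − exp(−bD^c)) — either supplied or
least-squares fitted to the measured heights present in the inventory;
measured heights always take precedence for their own stems. Hyperdominants
are the minimal descending-contribution prefix strictly exceeding 50 % of
AGC, ties broken lexicographically by species id so the set is
deterministic. Species with maximum DBH ≥ 70 cm are flagged as holding
large trees.

## Association statistics

OLS fits use the standard closed-form estimator with a two-sided t-test on
the slope; a constant response is handled as an exact flat fit (slope 0,
R² = 0). Quantile regression minimizes the check loss
Σ ρ_τ(y − a − bx), ρ_τ(u) = u(τ − 1{u<0}), solved exactly as a linear
program (HiGHS); optimality is verified against exhaustive enumeration of
all two-point lines on small instances (the LP optimum passes through at
least two observations). Because the relevant data are heteroscedastic
triangular clouds, slope inference uses a seeded (x, y)-pair bootstrap
(B = 2000 by default) with a two-sided percentile p-value, floored at
1/(B + 1); resamples with a degenerate design are redrawn. The default
suite fits each index against relative abundance, AGC contribution and
maximum size by OLS, plus upper-quantile (0.75, 0.90) fits for
specialization and lower-quantile (0.25, 0.10) fits for redundancy against
relative abundance. A leave-one-out OLS diagnostic (drop each species,
refit) is provided for influence checks on dominant species.

## Size gradient

Restricted to rare species (< 5 % relative abundance), the profile records
the mean of species maximum DBH above (specialization) or below
(redundancy) each threshold of a 0.1-step grid on [0, 1]; thresholds with no
qualifying species are dropped, and the gradient is the OLS slope of mean
size against threshold (≥ 3 retained thresholds required). Significance:

- **bootstrap** (default): resample rare species with replacement, 10,000
  replicates, 95 % percentile CI; significant if the CI excludes 0. This
  follows the percentile-CI reading of "bootstrapped randomizations".
- **permutation**: shuffle maximum sizes across rare species with the index
  fixed; p = (1 + #{|null| ≥ |obs|})/(R + 1).

Replicates whose profile retains fewer than 3 thresholds are redrawn (count
logged). Both modes are vectorized (the qualifying-species masks are matrix
operations), making 10,000 replicates essentially instant.

## Synthetic communities

The generator emulates a 5-plot, DBH ≥ 10 cm census of a species-rich
tropical forest:

- **Abundance**: lognormal SAD (σ = 1.5) by default — chosen because the
  per-species quantity analysed is abundance relative to the *most*
  abundant species, and an iid log-series draw routinely produces a single
  overwhelming dominant that compresses all relative abundances toward
  zero; log-series is available as an option, and a monodominant scenario
  assigns a configurable stem share f to one species (0.45 in the default
  monodominant configuration, 90/82 species in the mixed/monodominant
  defaults).
- **Size**: species maximum potential DBH is lognormal (median 55 cm,
  σ_log = 0.7, i.e. a realistic ~17–174 cm 5–95 % span from understory
  treelets to emergents), optionally rank-coupled to abundance (ρ = 0.3 by
  default); stem diameters are 10 + Weibull(0.9) with scale (Dmax − 10)/3.
- **Traits**: six traits from a correlated latent Gaussian with a
  leaf-economics-like correlation structure; SLA/LNC/LPC are exponentiated
  (hence right-skewed, and reliably selected for log transformation by the
  automatic rule), WD/LCC/δ¹³C stay symmetric. Four individuals per species
  with intraspecific noise at 30 % of the interspecific sd.
- **Distinctiveness effect**: every species that is both rare and in the
  top quartile of potential size is displaced by δ = 4 latent standard
  deviations along a seeded random direction, sign-flipped to point away
  from the trait centroid. δ was set so that roughly 15 of 90 species
  exceed a normalized specialization of 0.6 — the magnitude of specialist
  scarcity reported for real mixed tropical forest — and the displaced
  fraction defaults to 1 so the planted effect is the clean intersection
  "rare ∧ large". δ = 0 with zero couplings restores full exchangeability
  of traits and sizes across abundance classes (the testable null, checked
  with a multivariate energy-distance permutation test).

What the generator does *not* emulate: spatial structure within plots,
growth and mortality, phylogenetic signal, trait–wood-density coupling
(wood density for the carbon allometry is drawn independently by default so
carbon and trait effects stay separable), and measurement error in DBH.
Passing tests therefore demonstrate that the pipeline detects the planted
statistical structure at study-scale sample sizes, not that any particular
field community has that structure.

## Problem sizes and numerical choices

Simulation-based checks use 90-species communities over 100–200 seeds with
R = 1000 resampling replicates — enough for rates with ~3–5 % Monte-Carlo
error while keeping the whole suite inside a few minutes; the pipeline
default remains R = 10,000. Bootstrap/permutation draws, community
generation and the pair bootstrap are all driven by explicit
`numpy.random.default_rng` seeds, and every stage is bit-identical under a
fixed seed (asserted down to written CSV/JSON bytes). Percentile CIs use
numpy's default linear interpolation. Degenerate inputs (constant traits,
constant predictors, < 2 species, empty thresholds, R < 100) raise errors
rather than returning NaN.

## Known limitations

- The complement identity forces redundancy to be interpreted relative to
  the single nearest neighbour; clusters of three or more similar species
  are not distinguished from pairs.
- Max-normalization makes the indices community-relative: adding one
  extreme species rescales everyone. Cross-community comparisons should use
  raw distances.
- The pair bootstrap for quantile slopes is approximate at boundary
  quantiles with small n; its null rejection rate is calibration-tested at
  n = 60–90 but not guaranteed below that.
- Height–diameter fitting assumes the measured-height subset is
  representative of the forest type.
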