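"""Synthetic tropical-forest communities with controllable functional rarity.

The generator emulates the statistical structure the analysis assumes: a
species-abundance distribution with few abundant and many rare species
(lognormal by default, optionally log-series, with or without a planted
monodominant species), stem diameters from a Weibull distribution shifted to the 10 cm
census threshold with a per-species scale tied to the species' maximum
potential size, six correlated resource-acquisition traits with right-skewed
SLA/LNC/LPC, and a tunable "distinctiveness" effect delta that displaces a
subset of rare, large-statured species outward in standardized trait space.

With ``delta = 0`` and ``abundance_size_coupling = 0`` the traits and sizes
are exchangeable across abundance classes — the testable null.  The truth
record returned alongside the tables identifies the displaced species so
recovery of the planted effect can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .trait_space import DEFAULT_TRAITS

# latent (pre-transform) trait model: SLA/LNC/LPC live on a log scale and are
# exponentiated on output, which produces their right skew
LATENT_MEAN = {
    "WD": 0.60, "SLA": np.log(12.0), "LCC": 470.0,
    "LNC": np.log(22.0), "LPC": np.log(1.0), "d13C": -30.5,
}
LATENT_SD = {
    "WD": 0.12, "SLA": 0.35, "LCC": 25.0,
    "LNC": 0.28, "LPC": 0.35, "d13C": 1.3,
}
# leaf-economics-like correlation structure on the latent scale
_LATENT_CORR = {
    ("SLA", "LNC"): 0.55, ("SLA", "LPC"): 0.40, ("LNC", "LPC"): 0.55,
    ("WD", "SLA"): -0.35, ("WD", "LNC"): -0.25, ("WD", "LPC"): -0.20,
    ("d13C", "SLA"): -0.30, ("d13C", "WD"): 0.15,
    ("LCC", "SLA"): -0.25, ("LCC", "LNC"): -0.20,
}


def latent_correlation(traits=DEFAULT_TRAITS) -> np.ndarray:
    k = len(traits)
    corr = np.eye(k)
    for (a, b), r in _LATENT_CORR.items():
        if a in traits and b in traits:
            i, j = traits.index(a), traits.index(b)
            corr[i, j] = corr[j, i] = r
    # guard: project to the nearest PSD matrix if the filled-in entries clash
    w, v = np.linalg.eigh(corr)
    if w.min() < 1e-10:
        w = np.clip(w, 1e-10, None)
        corr = v @ np.diag(w) @ v.T
        d = np.sqrt(np.diag(corr))
        corr = corr / np.outer(d, d)
    return corr


@dataclass
class SyntheticConfig:
    """All knobs of the community generator; defaults are the mixed-forest
    study conditions (5 one-hectare plots, ~90 species, DBH >= 10 census)."""

    seed: int = 0
    n_species: int = 90
    n_plots: int = 5
    stems_per_plot: int = 450
    sad_family: str = "lognormal"          # "lognormal" | "logseries"
    sad_param: float = 1.5                 # lognormal sigma, or log-series p
    monodominance_fraction: float = 0.0    # f: stem share of species 1
    # size structure: species max potential DBH (cm) is lognormal; per-tree
    # DBH = 10 + Weibull(shape, scale=(Dmax-10)/3)
    dbh_weibull_shape: float = 0.9
    max_size_meanlog: float = float(np.log(55.0))
    max_size_sdlog: float = 0.7
    abundance_size_coupling: float = 0.3   # rho_as on the latent Gaussian scale
    # traits
    traits: tuple[str, ...] = DEFAULT_TRAITS
    skewed_traits: tuple[str, ...] = ("SLA", "LNC", "LPC")
    n_individuals: int = 4
    intraspecific_sd: float = 0.3          # fraction of the interspecific sd
    # distinctiveness effect: delta standardized units applied to a fraction
    # of (rare AND top-quartile max potential size) species
    delta: float = 4.0
    displaced_fraction: float = 1.0
    # wood density used for carbon allometry (independent of the trait table
    # by default so carbon and trait effects stay separable)
    wd_mean: float = 0.60
    wd_sd: float = 0.12
    couple_wd: bool = False
    # true height-diameter law for optionally emitted measured heights
    hd_a: float = 3.5
    hd_b: float = 0.55
    measured_height_fraction: float = 0.1
    forest_type: str = "mixed"

    def validate(self) -> None:
        if self.n_species < 2:
            raise ValueError("need at least 2 species")
        if not 0 <= self.monodominance_fraction < 1:
            raise ValueError("monodominance fraction must be in [0, 1)")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if not 0 <= self.displaced_fraction <= 1:
            raise ValueError("displaced_fraction must be in [0, 1]")
        if self.sad_family not in ("logseries", "lognormal"):
            raise ValueError("sad_family must be 'logseries' or 'lognormal'")
        if self.n_plots < 1 or self.stems_per_plot < 1 or self.n_individuals < 1:
            raise ValueError("plots, stems and individuals must be positive")


def default_paper_like_config(forest_type: str = "mixed", seed: int = 0) -> SyntheticConfig:
    """Study-scale configurations: 5 plots, 90 species (mixed) or 82 species
    with a monodominant stem share (monodominant)."""
    if forest_type == "mixed":
        cfg = SyntheticConfig(seed=seed, n_species=90, forest_type="mixed")
    elif forest_type == "monodominant":
        cfg = SyntheticConfig(seed=seed, n_species=82,
                              monodominance_fraction=0.45,
                              forest_type="monodominant")
    else:
        raise ValueError("forest_type must be 'mixed' or 'monodominant'")
    cfg.validate()
    return cfg


def _species_weights(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.sad_family == "logseries":
        w = stats.logser.rvs(cfg.sad_param, size=cfg.n_species,
                             random_state=rng).astype(float)
    else:
        w = np.exp(rng.normal(0.0, cfg.sad_param, cfg.n_species))
    if cfg.monodominance_fraction > 0:
        f = cfg.monodominance_fraction
        rest = w[1:].sum()
        w[0] = f / (1.0 - f) * rest
    return w


def _allocate_stems(weights: np.ndarray, total: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Multinomial allocation of `total` stems by weight, >= 1 per species."""
    n = weights.size
    if total < n:
        raise ValueError("fewer stems than species")
    counts = np.ones(n, dtype=int)
    extra = rng.multinomial(total - n, weights / weights.sum())
    return counts + extra


def generate_community(cfg: SyntheticConfig):
    """Draw one community.

    Returns ``(inventory, trait_table, wd, truth)``: a stem-level inventory
    DataFrame (plot, tree, species, dbh_cm, height_m, forest_type), an
    individual-level trait DataFrame, a wood-density Series indexed by
    species, and a truth dict recording the displaced species and all
    effect parameters.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_species
    species = np.array([f"S{i + 1:03d}" for i in range(n)])

    # --- abundances -------------------------------------------------------
    weights = _species_weights(cfg, rng)
    total_stems = cfg.n_plots * cfg.stems_per_plot
    counts = _allocate_stems(weights, total_stems, rng)

    # --- max potential size, optionally coupled to abundance --------------
    logw = np.log(weights)
    if np.ptp(logw) > 0:
        z_ab = (logw - logw.mean()) / logw.std()
    else:
        z_ab = np.zeros(n)
    rho = cfg.abundance_size_coupling
    z_size = rho * z_ab + np.sqrt(max(0.0, 1 - rho ** 2)) * rng.standard_normal(n)
    dmax = np.exp(cfg.max_size_meanlog + cfg.max_size_sdlog * z_size)
    dmax = np.maximum(dmax, 15.0)

    # --- stem diameters and plot assignment -------------------------------
    scale = (dmax - 10.0) / 3.0
    sp_index = np.repeat(np.arange(n), counts)
    dbh = 10.0 + scale[sp_index] * rng.weibull(cfg.dbh_weibull_shape,
                                               sp_index.size)
    dbh = np.round(dbh, 1)
    dbh = np.maximum(dbh, 10.0)
    plots = rng.integers(1, cfg.n_plots + 1, sp_index.size)
    height = np.full(sp_index.size, np.nan)
    if cfg.measured_height_fraction > 0:
        m = rng.random(sp_index.size) < cfg.measured_height_fraction
        height[m] = cfg.hd_a * dbh[m] ** cfg.hd_b * np.exp(
            rng.normal(0.0, 0.08, m.sum()))
    inventory = pd.DataFrame({
        "plot": [f"P{p}" for p in plots],
        "tree": [f"t{i + 1:05d}" for i in range(sp_index.size)],
        "species": species[sp_index],
        "dbh_cm": dbh,
        "height_m": np.round(height, 2),
        "forest_type": cfg.forest_type,
    })

    # --- species-level latent traits --------------------------------------
    traits = cfg.traits
    mu = np.array([LATENT_MEAN[t] for t in traits])
    sd = np.array([LATENT_SD[t] for t in traits])
    corr = latent_correlation(traits)
    chol = np.linalg.cholesky(corr)
    latent = mu + (rng.standard_normal((n, len(traits))) @ chol.T) * sd

    # --- plant the distinctiveness effect ----------------------------------
    rel_ab = 100.0 * counts / counts.max()
    rare = rel_ab < 5.0
    large_potential = dmax >= np.quantile(dmax, 0.75)
    eligible = np.flatnonzero(rare & large_potential)
    displaced = np.array([], dtype=int)
    if cfg.delta > 0 and cfg.displaced_fraction > 0 and eligible.size:
        k = max(1, int(round(cfg.displaced_fraction * eligible.size)))
        displaced = np.sort(rng.choice(eligible, size=k, replace=False))
        for s in displaced:
            u = rng.standard_normal(len(traits))
            u /= np.linalg.norm(u)
            # outward: flip the direction if it points toward the trait centroid
            centered = (latent[s] - mu) / sd
            if u @ centered < 0:
                u = -u
            latent[s] += cfg.delta * u * sd

    # --- individual-level measurements and output transforms ---------------
    reps = np.repeat(np.arange(n), cfg.n_individuals)
    noise = rng.standard_normal((reps.size, len(traits))) * (
        cfg.intraspecific_sd * sd)
    values = latent[reps] + noise
    cols = {}
    for j, t in enumerate(traits):
        v = values[:, j]
        if t in cfg.skewed_traits:
            v = np.exp(v)
        elif t != "d13C":
            # physical positivity floor for non-log positive traits
            v = np.maximum(v, 0.05 * abs(LATENT_MEAN[t]))
        cols[t] = v
    trait_table = pd.DataFrame({
        "species": species[reps],
        "individual": np.tile(np.arange(1, cfg.n_individuals + 1), n),
        **cols,
    })

    # --- wood density for the carbon allometry ------------------------------
    if cfg.couple_wd:
        wd_vals = np.maximum(latent[:, traits.index("WD")], 0.2)
    else:
        wd_vals = np.maximum(rng.normal(cfg.wd_mean, cfg.wd_sd, n), 0.2)
    wd = pd.Series(wd_vals, index=pd.Index(species, name="species"), name="wd")

    truth = {
        "seed": cfg.seed,
        "delta": cfg.delta,
        "abundance_size_coupling": cfg.abundance_size_coupling,
        "species": species.tolist(),
        "stem_counts": counts.tolist(),
        "max_potential_dbh": dmax.tolist(),
        "rare_species": species[rare].tolist(),
        "eligible_species": species[eligible].tolist(),
        "displaced_species": species[displaced].tolist(),
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(cfg).items()},
    }
    return inventory, trait_table, wd, truth


def energy_distance_test(x: np.ndarray, y: np.ndarray, n_perm: int = 199,
                         seed: int | np.random.Generator | None = None) -> float:
    """Two-sample multivariate energy-distance permutation test (p-value).

    Used to verify that, under delta = 0, trait vectors are exchangeable
    across abundance classes.
    """
    x = np.atleast_2d(np.asarray(x, float))
    y = np.atleast_2d(np.asarray(y, float))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nx, ny = len(x), len(y)
    pooled = np.vstack([x, y])
    from scipy.spatial.distance import squareform, pdist
    d = squareform(pdist(pooled))

    def estat(ix, iy):
        return (2 * d[np.ix_(ix, iy)].mean() - d[np.ix_(ix, ix)].mean()
                - d[np.ix_(iy, iy)].mean())

    obs = estat(np.arange(nx), np.arange(nx, nx + ny))
    count = 0
    idx = np.arange(nx + ny)
    for _ in range(n_perm):
        perm = rng.permutation(idx)
        if estat(perm[:nx], perm[nx:]) >= obs:
            count += 1
    return (1.0 + count) / (n_perm + 1.0)
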