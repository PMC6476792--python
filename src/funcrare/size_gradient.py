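"""Threshold sweep of rare-species maximum size along a functional index.

Among rare species (relative abundance < 5%), the mean of the species
maximum DBH is computed for species whose index lies above (specialization)
or below (redundancy) each threshold of a 0.1-step grid on [0, 1].  The
slope of mean-maximum-DBH against threshold summarizes the size gradient; its
significance is assessed by 10,000 resampling replicates with a 95%
percentile confidence interval (bootstrap over species), or alternatively by
a permutation null that shuffles maximum sizes across species.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .association_stats import ols_fit

DEFAULT_STEP = 0.1
DEFAULT_R = 10_000


@dataclass
class ThresholdProfile:
    index_name: str
    direction: str                 # "above" | "below"
    thresholds: np.ndarray         # retained thresholds only
    mean_max_dbh: np.ndarray       # cm, per retained threshold
    counts: np.ndarray             # qualifying species per retained threshold

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, float)
        self.mean_max_dbh = np.asarray(self.mean_max_dbh, float)
        self.counts = np.asarray(self.counts, int)
        if np.any(np.diff(self.thresholds) <= 0):
            raise ValueError("thresholds must be strictly increasing")
        if np.any(self.counts < 1):
            raise ValueError("retained thresholds must have >= 1 species")


@dataclass
class RandomizationResult:
    observed_slope: float          # cm per index unit
    replicate_slopes: np.ndarray
    ci_low: float
    ci_high: float
    p: float
    mode: str                      # "bootstrap" | "permutation"
    seed: int | None
    R: int
    n_redrawn: int = 0
    profile: ThresholdProfile | None = field(default=None, repr=False)

    @property
    def significant(self) -> bool:
        """Bootstrap: 95% CI excludes zero; permutation: p < 0.05."""
        if self.mode == "bootstrap":
            return not (self.ci_low <= 0.0 <= self.ci_high)
        return self.p < 0.05


def _grid(direction: str, step: float) -> np.ndarray:
    n = int(round(1.0 / step))
    full = np.round(np.arange(0, n + 1) * step, 10)
    # the extreme end of the sweep (no species above 1 / below 0) is dropped
    return full[:-1] if direction == "above" else full[1:]


def _qualify(index: np.ndarray, thresholds: np.ndarray, direction: str) -> np.ndarray:
    """Boolean matrix (n_thresholds, n_species) of qualifying species."""
    if direction == "above":
        return index[None, :] > thresholds[:, None]
    return index[None, :] < thresholds[:, None]


def threshold_profile(
    index: np.ndarray,
    maxdbh: np.ndarray,
    rare_mask: np.ndarray,
    direction: str = "above",
    index_name: str = "FSpeS",
    step: float = DEFAULT_STEP,
) -> ThresholdProfile:
    """Mean maximum DBH of rare species beyond each index threshold.

    Thresholds with zero qualifying species are dropped from the profile.
    """
    if direction not in ("above", "below"):
        raise ValueError("direction must be 'above' or 'below'")
    index = np.asarray(index, float)
    maxdbh = np.asarray(maxdbh, float)
    rare_mask = np.asarray(rare_mask, bool)
    idx = index[rare_mask]
    dbh = maxdbh[rare_mask]
    if idx.size == 0:
        raise ValueError("no rare species in the community")
    if np.any(idx < 0) or np.any(idx > 1):
        raise ValueError("index values must lie in [0, 1]")
    grid = _grid(direction, step)
    q = _qualify(idx, grid, direction)
    counts = q.sum(axis=1)
    keep = counts >= 1
    means = (q[keep] @ dbh) / counts[keep]
    return ThresholdProfile(index_name, direction, grid[keep], means, counts[keep])


def profile_slope(profile: ThresholdProfile) -> float:
    """OLS slope (cm per index unit) of mean maximum DBH against threshold."""
    if profile.thresholds.size < 3:
        raise ValueError("slope needs >= 3 retained thresholds")
    return ols_fit(profile.thresholds, profile.mean_max_dbh).slope


def _slopes_for_samples(idx_mat: np.ndarray, dbh_mat: np.ndarray,
                        direction: str, step: float) -> np.ndarray:
    """Vectorized profile slopes for R resampled (index, maxdbh) datasets.

    ``idx_mat`` and ``dbh_mat`` are (R, n) matrices.  Replicates with fewer
    than 3 retained thresholds return NaN (caller redraws them).
    """
    grid = _grid(direction, step)
    R = idx_mat.shape[0]
    T = grid.size
    means = np.empty((R, T))
    counts = np.empty((R, T))
    for t, thr in enumerate(grid):
        q = idx_mat > thr if direction == "above" else idx_mat < thr
        c = q.sum(axis=1)
        counts[:, t] = c
        with np.errstate(invalid="ignore"):
            means[:, t] = np.where(c > 0, (q * dbh_mat).sum(axis=1) / np.maximum(c, 1),
                                   np.nan)
    valid = counts > 0
    nt = valid.sum(axis=1)
    # masked per-replicate OLS slope of means against grid
    x = np.where(valid, grid[None, :], 0.0)
    y = np.where(valid, means, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        xbar = x.sum(axis=1) / nt
        ybar = y.sum(axis=1) / nt
        sxy = (x * y).sum(axis=1) - nt * xbar * ybar
        sxx = (x * x).sum(axis=1) - nt * xbar ** 2
        slopes = sxy / sxx
    slopes[nt < 3] = np.nan
    return slopes


def randomization_test(
    index: np.ndarray,
    maxdbh: np.ndarray,
    rare_mask: np.ndarray,
    direction: str = "above",
    mode: str = "bootstrap",
    R: int = DEFAULT_R,
    seed: int | np.random.Generator | None = None,
    step: float = DEFAULT_STEP,
    index_name: str = "FSpeS",
) -> RandomizationResult:
    """Resampling significance test for the threshold-gradient slope.

    ``mode="bootstrap"``: rare species are resampled with replacement and the
    profile slope recomputed per replicate; the 95% CI is the 2.5/97.5
    percentile of replicate slopes and the gradient is significant if the CI
    excludes 0.  ``mode="permutation"``: maximum DBH values are shuffled
    across rare species (index values fixed) to build a null slope
    distribution; p = (1 + #{|null| >= |observed|}) / (R + 1).  Replicates
    whose profile retains fewer than 3 thresholds are redrawn.
    """
    if R < 100:
        raise ValueError("R < 100 gives unstable percentile estimates")
    if mode not in ("bootstrap", "permutation"):
        raise ValueError("mode must be 'bootstrap' or 'permutation'")
    profile = threshold_profile(index, maxdbh, rare_mask, direction,
                                index_name, step)
    obs = profile_slope(profile)
    idx = np.asarray(index, float)[np.asarray(rare_mask, bool)]
    dbh = np.asarray(maxdbh, float)[np.asarray(rare_mask, bool)]
    n = idx.size
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seed_val = seed if isinstance(seed, (int, np.integer)) else None

    slopes = np.full(R, np.nan)
    n_redrawn = 0
    pending = np.arange(R)
    max_rounds = 1000
    for _ in range(max_rounds):
        if not pending.size:
            break
        m = pending.size
        if mode == "bootstrap":
            pick = rng.integers(0, n, size=(m, n))
            idx_mat = idx[pick]
            dbh_mat = dbh[pick]
        else:
            perms = np.argsort(rng.random((m, n)), axis=1)
            idx_mat = np.broadcast_to(idx, (m, n))
            dbh_mat = dbh[perms]
        s = _slopes_for_samples(idx_mat, dbh_mat, direction, step)
        slopes[pending] = s
        pending = pending[np.isnan(s)]
        n_redrawn += pending.size
    if pending.size:
        raise RuntimeError("could not obtain valid replicate profiles "
                           "(fewer than 3 retained thresholds in most resamples)")

    lo, hi = np.percentile(slopes, [2.5, 97.5])
    if mode == "permutation":
        p = (1.0 + np.sum(np.abs(slopes) >= abs(obs))) / (R + 1.0)
    else:
        # bootstrap analogue of a two-sided test: how central is 0
        frac = np.mean(slopes < 0) + 0.5 * np.mean(slopes == 0)
        p = max(min(1.0, 2 * min(frac, 1 - frac)), 1.0 / (R + 1.0))
    return RandomizationResult(obs, slopes, float(lo), float(hi), float(p),
                               mode, seed_val, R, n_redrawn, profile)
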