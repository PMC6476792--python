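"""Construction of the standardized multidimensional trait space.

Raw trait measurements (possibly several individuals per species) are turned
into a species x axes matrix in which every axis has mean 0 and unit sample
standard deviation.  The processing order is: aggregate individuals to species
means, log-transform right-skewed traits, rescale each trait to [0, 1], then
center and scale.  The rescaling step is affine and therefore a no-op with
respect to the final z-scored space; it is retained because equal trait
weighting is conventionally stated on the [0, 1] scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

#: canonical trait set: wood density (g/cm3), specific leaf area (mm2/mg),
#: leaf carbon / nitrogen / phosphorus content (mg/g), leaf d13C (permil).
DEFAULT_TRAITS = ("WD", "SLA", "LCC", "LNC", "LPC", "d13C")

TRAIT_UNITS = {
    "WD": "g/cm3",
    "SLA": "mm2/mg",
    "LCC": "mg/g",
    "LNC": "mg/g",
    "LPC": "mg/g",
    "d13C": "permil",
}

#: traits that are strictly positive by physical definition (d13C is not:
#: plant values are negative per mille).
POSITIVE_TRAITS = frozenset({"WD", "SLA", "LCC", "LNC", "LPC"})


class TraitTableError(ValueError):
    """Raised when a trait table violates its invariants."""


@dataclass
class TraitTable:
    """Species (or individual) x trait measurements with per-trait metadata.

    Parameters
    ----------
    data
        One row per (species, individual) or per species.  Must contain a
        ``species`` column; an ``individual`` column is optional.  Remaining
        columns are traits.
    traits
        Ordered trait names used downstream.
    transforms
        Per-trait transform flag, ``"none"`` or ``"log"``.
    units
        Per-trait unit strings (metadata only).
    """

    data: pd.DataFrame
    traits: tuple[str, ...] = DEFAULT_TRAITS
    transforms: dict[str, str] = field(default_factory=dict)
    units: dict[str, str] = field(default_factory=lambda: dict(TRAIT_UNITS))

    def __post_init__(self) -> None:
        if "species" not in self.data.columns:
            raise TraitTableError("trait table needs a 'species' column")
        missing = [t for t in self.traits if t not in self.data.columns]
        if missing:
            raise TraitTableError(f"trait columns missing from table: {missing}")
        self.traits = tuple(self.traits)
        for t in self.traits:
            self.transforms.setdefault(t, "none")
        self.validate()

    def validate(self) -> None:
        for t in self.traits:
            col = self.data[t]
            vals = col.dropna().to_numpy(dtype=float)
            if not np.all(np.isfinite(vals)):
                raise TraitTableError(f"non-finite values in trait {t!r}")
            if t in POSITIVE_TRAITS and np.any(vals <= 0):
                raise TraitTableError(f"trait {t!r} must be strictly positive")
            if self.transforms.get(t) == "log" and np.any(vals <= 0):
                raise TraitTableError(
                    f"trait {t!r} flagged 'log' but has non-positive values"
                )
            # every species must contribute at least one measurement
            per_species = col.notna().groupby(self.data["species"]).sum()
            empty = per_species[per_species == 0]
            if len(empty):
                raise TraitTableError(
                    f"species {list(empty.index)} have no values for trait {t!r}"
                )

    @property
    def species(self) -> list:
        return list(pd.unique(self.data["species"]))

    def is_species_level(self) -> bool:
        return self.data["species"].is_unique


@dataclass
class FunctionalSpace:
    """Species x standardized trait axes; centroid at the origin by construction.

    ``params`` records, per trait, the applied transform and the rescale /
    standardize constants (min, max, mean, sd) so any run is reproducible.
    """

    species: list
    axes: np.ndarray  # shape (n_species, k), z-scored columns
    trait_names: tuple[str, ...]
    params: dict[str, dict]

    def __post_init__(self) -> None:
        self.axes = np.asarray(self.axes, dtype=float)
        if self.axes.ndim != 2 or self.axes.shape[0] != len(self.species):
            raise ValueError("axes must be (n_species, k)")
        if len(self.species) < 2:
            raise ValueError("a functional space needs at least 2 species")
        if np.isnan(self.axes).any():
            raise ValueError("functional space contains missing entries")

    @property
    def n_species(self) -> int:
        return self.axes.shape[0]

    @property
    def k(self) -> int:
        return self.axes.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.axes, index=pd.Index(self.species, name="species"),
                            columns=list(self.trait_names))


def aggregate_to_species(table: TraitTable, statistic: str = "mean") -> TraitTable:
    """Collapse individual-level measurements to one row per species.

    The species value for each trait is the arithmetic mean (or median) of
    the sampled individuals' values, skipping missing measurements.
    """
    if statistic not in ("mean", "median"):
        raise ValueError("statistic must be 'mean' or 'median'")
    grouped = table.data.groupby("species", sort=True)[list(table.traits)]
    agg = grouped.mean() if statistic == "mean" else grouped.median()
    for t in table.traits:
        if agg[t].isna().any():
            bad = list(agg.index[agg[t].isna()])
            raise TraitTableError(f"species {bad} have no values for trait {t!r}")
    out = agg.reset_index()
    return TraitTable(out, traits=table.traits,
                      transforms=dict(table.transforms), units=dict(table.units))


def shapiro_wilk(values: np.ndarray) -> tuple[float, float]:
    """Shapiro-Wilk normality test (W, p) via the Royston approximation."""
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("Shapiro-Wilk needs n >= 3")
    if v.size > 5000:
        raise ValueError("Shapiro-Wilk p-values unreliable for n > 5000")
    if np.ptp(v) == 0:
        raise ValueError("Shapiro-Wilk undefined for a constant vector")
    res = stats.shapiro(v)
    return float(res.statistic), float(res.pvalue)


def select_transforms(
    table: TraitTable,
    alpha: float = 0.05,
    overrides: dict[str, str] | None = None,
) -> TraitTable:
    """Flag right-skewed non-normal positive traits for log transformation.

    A trait is flagged ``log`` iff its species-level distribution fails the
    Shapiro-Wilk test at ``alpha``, has positive sample skewness, and is
    strictly positive.  ``overrides`` pins a trait to ``"log"`` or ``"none"``
    regardless of the automatic rule.
    """
    if not table.is_species_level():
        table = aggregate_to_species(table)
    overrides = overrides or {}
    flags: dict[str, str] = {}
    for t in table.traits:
        vals = table.data[t].to_numpy(dtype=float)
        if t in overrides:
            if overrides[t] not in ("log", "none"):
                raise ValueError(f"override for {t!r} must be 'log' or 'none'")
            if overrides[t] == "log" and np.any(vals <= 0):
                raise TraitTableError(
                    f"cannot log-transform {t!r}: non-positive values present"
                )
            flags[t] = overrides[t]
            continue
        if np.any(vals <= 0) or np.ptp(vals) == 0:
            flags[t] = "none"
            continue
        _, p = shapiro_wilk(vals)
        skew = stats.skew(vals, bias=False)
        flags[t] = "log" if (p < alpha and skew > 0) else "none"
    return TraitTable(table.data.copy(), traits=table.traits,
                      transforms=flags, units=dict(table.units))


def rescale01(values: np.ndarray) -> np.ndarray:
    """Affine rescale so that min -> 0 and max -> 1."""
    v = np.asarray(values, dtype=float)
    lo, hi = v.min(), v.max()
    if hi == lo:
        raise ValueError("cannot rescale a constant vector (zero range)")
    return (v - lo) / (hi - lo)


def standardize(values: np.ndarray) -> np.ndarray:
    """Center to mean 0 and scale to unit sample sd (n-1 denominator)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("standardize needs n >= 2")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot standardize a constant vector")
    return (v - v.mean()) / sd


def build_functional_space(
    table: TraitTable,
    alpha: float = 0.05,
    overrides: dict[str, str] | None = None,
    aggregate: str = "mean",
    auto_transform: bool = True,
    rescale: bool = True,
) -> FunctionalSpace:
    """Run the full preprocessing pipeline and return the standardized space.

    Order: aggregate to species -> select/apply log transforms -> rescale to
    [0, 1] -> center and scale.  All per-trait constants are recorded in
    ``FunctionalSpace.params``.
    """
    species_table = (
        table if table.is_species_level() else aggregate_to_species(table, aggregate)
    )
    if auto_transform:
        species_table = select_transforms(species_table, alpha=alpha,
                                          overrides=overrides)
    df = species_table.data.sort_values("species").reset_index(drop=True)
    species = df["species"].tolist()
    if len(species) < 2:
        raise TraitTableError("need at least 2 species to build a space")

    cols = []
    params: dict[str, dict] = {}
    for t in species_table.traits:
        raw = df[t].to_numpy(dtype=float)
        if np.ptp(raw) == 0:
            raise TraitTableError(f"trait {t!r} is constant across species")
        transform = species_table.transforms.get(t, "none")
        x = np.log(raw) if transform == "log" else raw
        rec = {"transform": transform, "min": float(x.min()), "max": float(x.max())}
        if rescale:
            x = rescale01(x)
        rec["mean"] = float(x.mean())
        rec["sd"] = float(x.std(ddof=1))
        cols.append(standardize(x))
        params[t] = rec
    axes = np.column_stack(cols)
    return FunctionalSpace(species=species, axes=axes,
                           trait_names=species_table.traits, params=params)
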