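"""Per-species community statistics from a forest inventory.

From a stem table (DBH >= 10 cm census, pooled over the plots of one forest
type) this module derives each species' relative abundance (% of the most
abundant species' stem count), abundance class, contribution to the
community aboveground-carbon (AGC) stock, maximum attained DBH, and
hyperdominance (membership of the smallest set of top contributors jointly
holding >50% of AGC).

Tree AGC uses the moist-tropical-forest allometry
``AGB [kg] = coef * rho * D^2 * H`` (rho wood density in g/cm3, D in cm,
H in m; default coef 0.0509) with biomass assumed 50% carbon.  Heights come
from a site/forest-type height-diameter model (power ``H = a*D^b`` or
Weibull ``H = a*(1 - exp(-b*D^c))``) unless a stem carries a measured height.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

#: DBH (cm) at and above which a species counts as holding "large trees".
LARGE_TREE_DBH = 70.0
#: census cut-off: stems below this DBH (cm) are not inventoried.
MIN_CENSUS_DBH = 10.0

DEFAULT_AGB_COEF = 0.0509
DEFAULT_CARBON_FRACTION = 0.5


class InventoryError(ValueError):
    """Raised when an inventory table violates the census invariants."""


def validate_inventory(inv: pd.DataFrame) -> pd.DataFrame:
    """Check census invariants: DBH >= 10 cm and unique (plot, tree) keys."""
    required = {"plot", "tree", "species", "dbh_cm"}
    missing = required - set(inv.columns)
    if missing:
        raise InventoryError(f"inventory missing columns: {sorted(missing)}")
    if len(inv) == 0:
        raise InventoryError("empty inventory")
    dbh = inv["dbh_cm"].to_numpy(dtype=float)
    if not np.all(np.isfinite(dbh)):
        raise InventoryError("non-numeric or non-finite DBH values")
    bad = inv.index[dbh < MIN_CENSUS_DBH]
    if len(bad):
        raise InventoryError(
            f"DBH below the {MIN_CENSUS_DBH:g} cm census threshold at rows "
            f"{list(bad[:10])}"
        )
    if inv.duplicated(subset=["plot", "tree"]).any():
        dups = inv[inv.duplicated(subset=["plot", "tree"], keep=False)]
        raise InventoryError(
            f"duplicate (plot, tree) keys: {dups[['plot', 'tree']].values[:5].tolist()}"
        )
    return inv


@dataclass
class HDModel:
    """Height-diameter model, site and forest-type specific (not per species).

    ``form="power"``: H = a * D**b.  ``form="weibull"``: H = a * (1 - exp(-b * D**c)).
    """

    form: str = "power"
    a: float = 3.5
    b: float = 0.55
    c: float | None = None
    forest_type: str | None = None

    def __post_init__(self) -> None:
        if self.form not in ("power", "weibull"):
            raise ValueError("form must be 'power' or 'weibull'")
        if self.a <= 0 or self.b <= 0:
            raise ValueError("height-diameter parameters must be positive")
        if self.form == "weibull":
            if self.c is None:
                self.c = 1.0
            if self.c <= 0:
                raise ValueError("height-diameter parameters must be positive")

    def predict(self, dbh) -> np.ndarray:
        d = np.asarray(dbh, dtype=float)
        if np.any(d < MIN_CENSUS_DBH):
            raise ValueError(f"DBH below {MIN_CENSUS_DBH:g} cm")
        if self.form == "power":
            return self.a * d ** self.b
        return self.a * (1.0 - np.exp(-self.b * d ** self.c))


def estimate_height(dbh, model: HDModel, measured=None) -> np.ndarray:
    """Model heights, with any measured height taking precedence."""
    h = model.predict(dbh)
    if measured is not None:
        m = np.asarray(measured, dtype=float)
        h = np.where(np.isfinite(m), m, h)
    return h


def fit_hd_model(dbh, height, form: str = "power",
                 forest_type: str | None = None) -> HDModel:
    """Least-squares fit of a height-diameter model to measured stems."""
    d = np.asarray(dbh, dtype=float)
    h = np.asarray(height, dtype=float)
    ok = np.isfinite(d) & np.isfinite(h)
    d, h = d[ok], h[ok]
    if d.size < 3:
        raise ValueError("need at least 3 measured heights to fit an H-D model")
    if form == "power":
        # linear in log-log space gives a robust starting point and is the
        # classical fit for this form
        slope, intercept = np.polyfit(np.log(d), np.log(h), 1)
        popt, _ = curve_fit(lambda x, a, b: a * x ** b, d, h,
                            p0=[np.exp(intercept), slope], maxfev=10000)
        return HDModel("power", a=float(popt[0]), b=float(popt[1]),
                       forest_type=forest_type)
    popt, _ = curve_fit(lambda x, a, b, c: a * (1 - np.exp(-b * x ** c)),
                        d, h, p0=[h.max() * 1.2, 0.05, 1.0], maxfev=10000)
    return HDModel("weibull", a=float(popt[0]), b=float(popt[1]),
                   c=float(popt[2]), forest_type=forest_type)


def relative_abundance(inv: pd.DataFrame) -> pd.Series:
    """Stem count of each species as a % of the most abundant species' count."""
    validate_inventory(inv)
    counts = inv.groupby("species").size()
    return 100.0 * counts / counts.max()


def classify_abundance(ra) -> np.ndarray:
    """Map relative abundance (%) to abundant (>10), nonabundant ([5, 10]),
    rare (<5).  Both boundaries belong to the middle class."""
    ra = np.atleast_1d(np.asarray(ra, dtype=float))
    out = np.where(ra > 10, "abundant", np.where(ra >= 5, "nonabundant", "rare"))
    return out


def tree_agc(dbh, wd, height, carbon_fraction: float = DEFAULT_CARBON_FRACTION,
             coefficient: float = DEFAULT_AGB_COEF) -> np.ndarray:
    """Aboveground carbon (kg) of a tree: carbon_fraction * coef * rho * D^2 * H."""
    d = np.asarray(dbh, dtype=float)
    rho = np.asarray(wd, dtype=float)
    h = np.asarray(height, dtype=float)
    if np.any(d <= 0) or np.any(rho <= 0) or np.any(h <= 0) \
            or carbon_fraction <= 0 or coefficient <= 0:
        raise ValueError("all allometry inputs must be positive")
    return carbon_fraction * coefficient * rho * d ** 2 * h


def species_agc_contribution(
    inv: pd.DataFrame,
    wd: pd.Series,
    model: HDModel,
    carbon_fraction: float = DEFAULT_CARBON_FRACTION,
    coefficient: float = DEFAULT_AGB_COEF,
) -> pd.Series:
    """% of the community AGC stock contributed by each species."""
    validate_inventory(inv)
    missing = sorted(set(inv["species"]) - set(wd.index))
    if missing:
        raise InventoryError(f"species missing wood density: {missing}")
    measured = inv["height_m"] if "height_m" in inv.columns else None
    h = estimate_height(inv["dbh_cm"], model,
                        measured.to_numpy(dtype=float) if measured is not None else None)
    rho = wd.reindex(inv["species"]).to_numpy(dtype=float)
    agc = tree_agc(inv["dbh_cm"].to_numpy(dtype=float), rho, h,
                   carbon_fraction, coefficient)
    per_species = pd.Series(agc, index=inv["species"].values).groupby(level=0).sum()
    return 100.0 * per_species / per_species.sum()


def max_dbh(inv: pd.DataFrame) -> pd.DataFrame:
    """Per-species maximum DBH (cm) and the 'large tree' (>= 70 cm) flag."""
    validate_inventory(inv)
    mx = inv.groupby("species")["dbh_cm"].max()
    return pd.DataFrame({"max_dbh_cm": mx, "large": mx >= LARGE_TREE_DBH})


def classify_hyperdominant(contributions: pd.Series) -> pd.Series:
    """Flag the minimal descending-contribution prefix holding > 50% of AGC.

    Species are sorted by contribution descending, ties broken by species id;
    species are flagged in order until the cumulative contribution first
    exceeds 50%.
    """
    total = float(contributions.sum())
    if not np.isclose(total, 100.0, atol=1e-6):
        raise ValueError(f"contributions must sum to 100, got {total}")
    order = contributions.loc[
        sorted(contributions.index, key=lambda s: (-contributions[s], str(s)))
    ]
    cum = order.cumsum()
    n_flag = int(np.searchsorted(cum.to_numpy(), 50.0, side="right")) + 1
    n_flag = min(n_flag, len(order))
    flags = pd.Series(False, index=contributions.index)
    flags[order.index[:n_flag]] = True
    return flags


def community_stats(
    inv: pd.DataFrame,
    wd: pd.Series,
    model: HDModel,
    carbon_fraction: float = DEFAULT_CARBON_FRACTION,
    coefficient: float = DEFAULT_AGB_COEF,
) -> pd.DataFrame:
    """Full per-species statistics table for one (pooled) forest type.

    Columns: ``species, n_stems, rel_abund_pct, agc_pct, max_dbh_cm, class,
    hyperdominant, large``.
    """
    validate_inventory(inv)
    counts = inv.groupby("species").size().rename("n_stems")
    ra = relative_abundance(inv).rename("rel_abund_pct")
    agc = species_agc_contribution(inv, wd, model, carbon_fraction,
                                   coefficient).rename("agc_pct")
    mx = max_dbh(inv)
    out = pd.concat([counts, ra, agc, mx], axis=1)
    out["class"] = classify_abundance(out["rel_abund_pct"].to_numpy())
    out["hyperdominant"] = classify_hyperdominant(out["agc_pct"])
    out.index.name = "species"
    return out.reset_index()
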