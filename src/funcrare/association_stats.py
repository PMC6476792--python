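"""OLS and quantile regressions of functional indices on community covariates.

Triangular predictor-response clouds (variance of the response shrinking
along the predictor) carry their signal in the boundary of the scatter, not
in its center, so quantile regressions near the relevant boundary are fitted
alongside ordinary least squares: upper quantiles (0.75, 0.90) for
specialization and lower quantiles (0.25, 0.10) for redundancy.

The quantile fit minimizes the check loss sum_i rho_tau(y_i - a - b x_i),
rho_tau(u) = u (tau - 1{u<0}), solved exactly as a linear program.  Because
the slope's sampling distribution under heteroscedastic triangular data is
awkward analytically, the slope p-value comes from a seeded (x, y)-pair
bootstrap (two-sided, percentile-based).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linprog

DEFAULT_UPPER_TAUS = (0.75, 0.90)   # specialization envelope
DEFAULT_LOWER_TAUS = (0.25, 0.10)   # redundancy envelope


@dataclass
class RegressionResult:
    predictor: str
    response: str
    method: str          # "ols" | "quantile"
    tau: float | None
    slope: float
    intercept: float
    p: float | None
    r2: float | None
    n: int

    def to_dict(self) -> dict:
        return {
            "response": self.response, "predictor": self.predictor,
            "method": self.method, "tau": self.tau, "slope": self.slope,
            "intercept": self.intercept, "p": self.p, "R2": self.r2,
            "n": self.n,
        }


def check_loss(y: np.ndarray, yhat: np.ndarray, tau: float) -> float:
    """Asymmetric absolute (pinball) loss defining the tau-th quantile fit."""
    u = np.asarray(y, float) - np.asarray(yhat, float)
    return float(np.sum(u * (tau - (u < 0))))


def ols_fit(x, y, predictor: str = "x", response: str = "y") -> RegressionResult:
    """Ordinary least squares with a two-sided t-test on the slope."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("OLS needs n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor")
    if np.ptp(y) == 0:
        # a constant response is fit exactly by a flat line
        return RegressionResult(predictor, response, "ols", None,
                                0.0, float(y[0]), 1.0, 0.0, x.size)
    res = stats.linregress(x, y)
    return RegressionResult(predictor, response, "ols", None,
                            float(res.slope), float(res.intercept),
                            float(res.pvalue), float(res.rvalue ** 2), x.size)


def _quantile_line(x: np.ndarray, y: np.ndarray, tau: float) -> tuple[float, float]:
    """Exact LP solution of the 1-covariate quantile regression.

    Variables: intercept a = a+ - a-, slope b = b+ - b-, residual splits
    u, v >= 0 with y - a - b x = u - v; objective tau*sum(u) + (1-tau)*sum(v).
    """
    n = x.size
    # columns: a+, a-, b+, b-, u (n), v (n)
    c = np.concatenate([[0.0, 0.0, 0.0, 0.0], np.full(n, tau), np.full(n, 1 - tau)])
    A_eq = np.zeros((n, 4 + 2 * n))
    A_eq[:, 0] = 1.0
    A_eq[:, 1] = -1.0
    A_eq[:, 2] = x
    A_eq[:, 3] = -x
    A_eq[:, 4:4 + n] = np.eye(n)
    A_eq[:, 4 + n:] = -np.eye(n)
    res = linprog(c, A_eq=A_eq, b_eq=y, bounds=(0, None), method="highs")
    if not res.success:
        raise RuntimeError(f"quantile regression LP failed: {res.message}")
    a = res.x[0] - res.x[1]
    b = res.x[2] - res.x[3]
    return float(b), float(a)


def quantile_fit(
    x, y, tau: float,
    predictor: str = "x", response: str = "y",
    p_method: str = "pair-bootstrap", B: int = 2000,
    seed: int | np.random.Generator | None = None,
) -> RegressionResult:
    """Linear quantile regression with a bootstrap slope p-value.

    ``p_method="none"`` skips inference (p is None); otherwise B seeded
    (x, y)-pair resamples give a two-sided percentile p-value for the slope.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 10:
        raise ValueError("quantile regression needs n >= 10")
    if not 0 < tau < 1:
        raise ValueError("tau must be in (0, 1)")
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: constant predictor")
    slope, intercept = _quantile_line(x, y, tau)

    p = None
    if p_method == "pair-bootstrap":
        rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
        n = x.size
        slopes = np.empty(B)
        for b in range(B):
            while True:
                idx = rng.integers(0, n, n)
                if np.ptp(x[idx]) > 0:
                    break
            slopes[b], _ = _quantile_line(x[idx], y[idx], tau)
        # two-sided percentile p: how central is 0 in the bootstrap distribution
        frac_below = np.mean(slopes < 0) + 0.5 * np.mean(slopes == 0)
        p = float(min(1.0, 2 * min(frac_below, 1 - frac_below)))
        p = max(p, 1.0 / (B + 1))
    elif p_method != "none":
        raise ValueError("p_method must be 'pair-bootstrap' or 'none'")
    return RegressionResult(predictor, response, "quantile", tau,
                            slope, intercept, p, None, x.size)


def run_association_suite(
    profiles: pd.DataFrame,
    comm_stats: pd.DataFrame,
    upper_taus=DEFAULT_UPPER_TAUS,
    lower_taus=DEFAULT_LOWER_TAUS,
    p_method: str = "pair-bootstrap",
    B: int = 2000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Fit the full regression table for one community.

    Six OLS fits (FSpeS and FRedS against relative abundance, AGC
    contribution, and maximum size) plus quantile fits of each index on
    relative abundance: upper quantiles for FSpeS, lower for FRedS.
    Returns a tidy frame ``response,predictor,method,tau,slope,p,R2,n``.
    """
    ps = set(profiles["species"])
    cs = set(comm_stats["species"])
    if ps != cs:
        raise ValueError(f"species sets differ: only-profiles={sorted(ps - cs)[:5]}, "
                         f"only-stats={sorted(cs - ps)[:5]}")
    merged = profiles.merge(comm_stats, on="species").sort_values("species")
    predictors = {"rel_abund_pct": "relative_abundance",
                  "agc_pct": "agc_contribution",
                  "max_dbh_cm": "max_size"}
    rng = np.random.default_rng(seed)
    rows: list[RegressionResult] = []
    for resp in ("FSpeS", "FRedS"):
        y = merged[resp].to_numpy()
        for col, name in predictors.items():
            x = merged[col].to_numpy()
            rows.append(ols_fit(x, y, predictor=name, response=resp))
        taus = upper_taus if resp == "FSpeS" else lower_taus
        x = merged["rel_abund_pct"].to_numpy()
        for tau in taus:
            rows.append(quantile_fit(x, y, tau, predictor="relative_abundance",
                                     response=resp, p_method=p_method, B=B,
                                     seed=rng))
    return pd.DataFrame([r.to_dict() for r in rows])


def leave_one_out_slopes(x, y) -> pd.DataFrame:
    """Influence diagnostic: drop each point, refit OLS, report the slopes.

    Used to confirm that a single dominant species does not drive an
    association (columns: dropped index, slope, p).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    rows = []
    for i in range(x.size):
        keep = np.arange(x.size) != i
        r = ols_fit(x[keep], y[keep])
        rows.append({"dropped": i, "slope": r.slope, "p": r.p})
    return pd.DataFrame(rows)
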