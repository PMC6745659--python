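"""Fitting phenology and fecundity inputs from field-style tabular data.

Quadrat emergence counts (seedlings or vegetative tillers, recorded at a
handful of evaluation dates) are turned into cumulative emergence curves
and fitted with the two-parameter Weibull CDF. Plant-level panicle or seed
counts versus emergence date are fitted with a log-linear exponential
regression; a panicle-ratio adjustment then converts a garden-grown panicle
regression into field-level seeds per plant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .lifecycle import EmergenceDistribution, FecundityParams

EMERGENCE_COLUMNS = ("date", "count", "cohort", "site")


@dataclass(frozen=True)
class FecundityFit:
    """Result of the exponential regression ``y = a * exp(b*x)``."""

    a_hat: float
    b_hat: float
    r_squared: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("r_squared must be in [0, 1]")


def _weibull_cdf(x: np.ndarray, k: float, lam: float) -> np.ndarray:
    return 1.0 - np.exp(-((np.maximum(x, 0.0) / lam) ** k))


def read_emergence_csv(path) -> pd.DataFrame:
    """Read a delimited emergence table with columns date, count, cohort, site."""
    df = pd.read_csv(path)
    missing = set(EMERGENCE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"emergence table missing columns: {sorted(missing)}")
    return df


def fit_weibull_emergence(
    dates: np.ndarray,
    counts: np.ndarray,
    cumulative: bool = False,
    method: str = "ls",
) -> tuple[float, float]:
    """Fit the Weibull emergence curve; returns ``(k_hat, lambda_hat)``.

    Parameters
    ----------
    dates, counts
        Evaluation dates (DASS) and per-interval emergence counts (or the
        cumulative counts if ``cumulative=True``); at least three distinct
        dates are required.
    method
        ``"ls"`` (default): least squares of the Weibull CDF against the
        cumulative emergence proportions. ``"mle"``: maximum likelihood for
        the interval-censored counts (multinomial over the inter-date
        emergence probabilities).
    """
    x = np.asarray(dates, dtype=float)
    c = np.asarray(counts, dtype=float)
    if x.size != c.size:
        raise ValueError("dates and counts must have equal length")
    if np.unique(x).size < 3:
        raise ValueError("need at least 3 distinct evaluation dates")
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    order = np.argsort(x)
    x, c = x[order], c[order]
    cum = c if cumulative else np.cumsum(c)
    if np.any(np.diff(cum) < 0):
        raise ValueError("cumulative counts must be non-decreasing")
    total = cum[-1]
    if total <= 0 or np.count_nonzero(np.diff(cum)) == 0 and cum[0] == total:
        raise ValueError("degenerate data: all emergence at a single date")
    prop = cum / total

    # moment-flavored starting point: scale near the median date
    lam0 = float(np.interp(0.632, prop, x, left=x[0], right=x[-1]))
    k0 = 3.0
    # individuals emerging after the last evaluation are unobserved, so the
    # observed proportions estimate the CDF conditional on emergence by the
    # last date; fit that conditional curve
    if method == "ls":

        def cond_cdf(xx, k, lam):
            c = _weibull_cdf(xx, k, lam)
            return c / max(_weibull_cdf(np.asarray([x[-1]]), k, lam)[0], 1e-12)

        popt, _ = optimize.curve_fit(
            cond_cdf, x, prop, p0=(k0, lam0),
            bounds=((1e-6, 1e-6), (np.inf, np.inf)), maxfev=20_000,
        )
        return float(popt[0]), float(popt[1])
    if method == "mle":
        interval = np.diff(np.concatenate([[0.0], cum]))

        def nll(theta):
            k, lam = np.exp(theta)
            edges = _weibull_cdf(x, k, lam)
            p = np.diff(np.concatenate([[0.0], edges]))
            # emergence after the last evaluation is unobserved; condition on
            # having emerged by the last date
            p = p / edges[-1]
            p = np.clip(p, 1e-300, None)
            return -float(np.sum(interval * np.log(p)))

        res = optimize.minimize(
            nll, x0=np.log([k0, lam0]), method="Nelder-Mead",
            options=dict(xatol=1e-8, fatol=1e-10, maxiter=10_000),
        )
        k, lam = np.exp(res.x)
        return float(k), float(lam)
    raise ValueError("method must be 'ls' or 'mle'")


def fit_weibull_from_table(
    table: pd.DataFrame, cohort: str, site: str | None = None, **kwargs
) -> tuple[float, float]:
    """Fit one site-cohort series of an emergence table."""
    df = table[table["cohort"] == cohort]
    if site is not None:
        df = df[df["site"] == site]
    if df.empty:
        raise ValueError(f"no rows for cohort {cohort!r} (site {site!r})")
    grouped = df.groupby("date", as_index=False)["count"].sum().sort_values("date")
    return fit_weibull_emergence(
        grouped["date"].to_numpy(), grouped["count"].to_numpy(), **kwargs
    )


def fit_exponential_fecundity(x: np.ndarray, y: np.ndarray) -> FecundityFit:
    """Log-linear least squares of ``ln(y)`` on ``x``.

    R^2 is computed on the log scale (the scale of the fit).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.any(y <= 0):
        raise ValueError("y must be strictly positive for a log-linear fit")
    ln_y = np.log(y)
    res = stats.linregress(x, ln_y)
    fitted = res.intercept + res.slope * x
    ss_res = float(np.sum((ln_y - fitted) ** 2))
    ss_tot = float(np.sum((ln_y - ln_y.mean()) ** 2))
    # a response with no variance is fit exactly by the constant term
    r2 = 1.0 if ss_tot == 0.0 and ss_res < 1e-20 else 1.0 - ss_res / max(ss_tot, 1e-300)
    return FecundityFit(
        a_hat=float(np.exp(res.intercept)),
        b_hat=float(res.slope),
        r_squared=float(min(max(r2, 0.0), 1.0)),
    )


def adjust_fecundity(
    panicle_regression: FecundityFit,
    field_panicles_per_plant: float,
    fauba_panicles_per_plant: float,
    seeds_per_panicle: float,
    max_seeds: float,
) -> FecundityParams:
    """Convert a garden panicle regression into field seeds per plant.

    The intercept is scaled by the field/garden panicle ratio (correcting
    for growing conditions) and by the seeds counted per panicle; the decay
    rate is unchanged.
    """
    if min(
        field_panicles_per_plant, fauba_panicles_per_plant, seeds_per_panicle
    ) <= 0:
        raise ValueError("panicle and seed counts must be positive")
    a_field = (
        panicle_regression.a_hat
        * (field_panicles_per_plant / fauba_panicles_per_plant)
        * seeds_per_panicle
    )
    return FecundityParams(a=a_field, b=panicle_regression.b_hat, max_seeds=max_seeds)


def emergence_distribution_from_fit(k_hat: float, lambda_hat: float) -> EmergenceDistribution:
    return EmergenceDistribution(shape_k=k_hat, scale_lambda=lambda_hat)
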