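"""Rosin-Rammler modelling of bolus particle-area distributions.

After mastication, the areas of the individual bolus particles are pooled
into a cumulative *area-weighted* distribution: sorting the particles by
area, the curve value at particle *i* is the fraction of the total
particle area contributed by particles no larger than particle *i*.  The
two-parameter Rosin-Rammler law

    C_area(x) = 1 - exp(-(x / x50)^b * ln 2)

is then fitted by nonlinear least squares.  ``x50`` is the median particle
area in mm^2 (the area below which half of the total particle area lies)
and ``b`` is the dimensionless breadth exponent; a larger ``b`` means a
narrower spread.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "CumulativeAreaDistribution",
    "RosinRammlerFit",
    "build_cumulative",
    "rr_cdf",
    "rr_quantile",
    "fit_rosin_rammler",
    "summarize_by_class",
]

LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class CumulativeAreaDistribution:
    """Particle areas (mm^2, ascending) with cumulative area fractions."""

    areas: np.ndarray
    c_area: np.ndarray

    def __post_init__(self) -> None:
        areas = np.asarray(self.areas, dtype=float)
        c = np.asarray(self.c_area, dtype=float)
        if areas.ndim != 1 or c.shape != areas.shape:
            raise ValueError("areas and c_area must be 1-D arrays of equal length")
        if areas.size == 0:
            raise ValueError("empty distribution")
        if np.any(np.diff(areas) < 0):
            raise ValueError("areas must be sorted ascending")
        if np.any(np.diff(c) < -1e-12):
            raise ValueError("c_area must be non-decreasing")
        if c[0] < -1e-12 or c[-1] > 1.0 + 1e-9:
            raise ValueError("c_area must lie in [0, 1]")
        object.__setattr__(self, "areas", areas)
        object.__setattr__(self, "c_area", c)

    def __len__(self) -> int:
        return int(self.areas.size)


@dataclass(frozen=True)
class RosinRammlerFit:
    x50: float
    b: float
    rss: float
    converged: bool
    class_scope: str = "all"
    n_particles: int = 0


def build_cumulative(areas) -> CumulativeAreaDistribution:
    """Area-weighted undersize cumulative distribution of particle areas.

    Areas are sorted ascending; the cumulative fraction at particle *i* is
    ``sum(a_1..a_i) / sum(a)``.  Ties are kept as separate points.
    """
    a = np.sort(np.asarray(areas, dtype=float))
    if a.size == 0:
        raise ValueError("need at least one particle area")
    if np.any(~np.isfinite(a)) or np.any(a <= 0):
        raise ValueError("particle areas must be positive and finite")
    c = np.cumsum(a) / a.sum()
    c[-1] = 1.0
    return CumulativeAreaDistribution(areas=a, c_area=c)


def rr_cdf(x, x50: float, b: float):
    """Rosin-Rammler cumulative area fraction at area ``x`` (mm^2)."""
    if not (x50 > 0 and b > 0):
        raise ValueError("x50 and b must be positive")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("x must be non-negative")
    out = 1.0 - np.exp(-np.power(x / x50, b) * LN2)
    return out if out.ndim else float(out)


def rr_quantile(c, x50: float, b: float):
    """Inverse of :func:`rr_cdf`: the area at cumulative fraction ``c``."""
    if not (x50 > 0 and b > 0):
        raise ValueError("x50 and b must be positive")
    c = np.asarray(c, dtype=float)
    if np.any((c < 0) | (c >= 1)):
        raise ValueError("c must lie in [0, 1)")
    out = x50 * np.power(-np.log1p(-c) / LN2, 1.0 / b)
    return out if out.ndim else float(out)


def _weighted_median(areas: np.ndarray, c: np.ndarray) -> float:
    idx = int(np.searchsorted(c, 0.5))
    return float(areas[min(idx, areas.size - 1)])


def fit_rosin_rammler(
    dist: CumulativeAreaDistribution,
    init: tuple[float, float] | None = None,
    tol: float = 1e-10,
    max_iter: int = 500,
    class_scope: str = "all",
) -> RosinRammlerFit:
    """Least-squares Rosin-Rammler fit of a cumulative area distribution.

    Minimises ``sum((c_area - C(x; x50, b))^2)`` over ``(x50, b)`` with
    both parameters kept positive through a log re-parameterisation.
    Default initial values: the empirical area-weighted median for ``x50``
    and ``b = 1.5``.

    Raises
    ------
    ValueError
        If the distribution has fewer than 3 distinct areas.
    """
    x = dist.areas
    c = dist.c_area
    if np.unique(x).size < 3:
        raise ValueError("need at least 3 distinct particle areas to fit")
    if init is None:
        x50_0 = max(_weighted_median(x, c), 1e-9)
        b_0 = 1.5
    else:
        x50_0, b_0 = init
        if not (x50_0 > 0 and b_0 > 0):
            raise ValueError("init values must be positive")

    def resid(theta):
        x50, b = np.exp(theta)
        return c - (1.0 - np.exp(-np.power(x / x50, b) * LN2))

    sol = least_squares(
        resid,
        x0=np.log([x50_0, b_0]),
        method="lm",
        xtol=tol,
        ftol=tol,
        gtol=tol,
        max_nfev=max_iter * 3,
    )
    x50_hat, b_hat = np.exp(sol.x)
    return RosinRammlerFit(
        x50=float(x50_hat),
        b=float(b_hat),
        rss=float(np.sum(sol.fun**2)),
        converged=bool(sol.status > 0),
        class_scope=class_scope,
        n_particles=len(dist),
    )


def summarize_by_class(particles: pd.DataFrame, min_particles: int = 3) -> pd.DataFrame:
    """Fit the size law per colour class and for all particles pooled.

    ``particles`` needs columns ``area_mm2`` and ``class`` (values
    "black"/"white").  Returns one row per scope in {all, black, white}
    with the fitted parameters; scopes with fewer than ``min_particles``
    particles are flagged (``fitted=False``) and carry NaN parameters.
    """
    if not {"area_mm2", "class"}.issubset(particles.columns):
        raise ValueError("particles must have 'area_mm2' and 'class' columns")
    rows = []
    scopes = {
        "all": particles,
        "black": particles[particles["class"] == "black"],
        "white": particles[particles["class"] == "white"],
    }
    for scope, sub in scopes.items():
        areas = sub["area_mm2"].to_numpy(dtype=float)
        if areas.size >= min_particles and np.unique(areas).size >= 3:
            fit = fit_rosin_rammler(build_cumulative(areas), class_scope=scope)
            rows.append(
                dict(
                    class_scope=scope,
                    x50_mm2=fit.x50,
                    b=fit.b,
                    rss=fit.rss,
                    n_particles=fit.n_particles,
                    converged=fit.converged,
                    fitted=True,
                )
            )
        else:
            rows.append(
                dict(
                    class_scope=scope,
                    x50_mm2=np.nan,
                    b=np.nan,
                    rss=np.nan,
                    n_particles=int(areas.size),
                    converged=False,
                    fitted=False,
                )
            )
    return pd.DataFrame(rows)
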