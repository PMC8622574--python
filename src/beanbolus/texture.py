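"""PEF processing arithmetic, texture profile analysis and response surfaces.

Pulsed electric field (PEF) treatment delivers energy as a train of short
high-voltage pulses.  Two derived quantities characterise a treatment:
the specific energy input (pulse energy x pulse count / treated mass,
kJ/kg) and the treatment time (pulse count x pulse width).

Texture profile analysis (TPA) extracts mechanical parameters from a
double-compression ("two-bite") force curve following the standard
Bourne conventions: hardness is the peak force of the first compression;
cohesiveness the ratio of the total force-time areas of the second and
first cycles; springiness the ratio of the compression-stroke durations;
chewiness their product; resilience the withdrawal/compression area
ratio within the first cycle.

A quadratic response-surface model (main effects, two-way interactions,
quadratic terms of field strength, specific energy and calcium
concentration) is fitted by ordinary least squares with per-coefficient
t-test p-values, screening-style (no multiplicity adjustment).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TPAParams",
    "RSMFit",
    "specific_energy",
    "treatment_time",
    "compute_tpa",
    "build_design_matrix",
    "fit_least_squares",
    "prediction_profile",
]


@dataclass(frozen=True)
class TPAParams:
    hardness: float  # N
    cohesiveness: float
    springiness: float
    chewiness: float  # N
    resilience: float


@dataclass(frozen=True)
class RSMFit:
    """OLS quadratic response-surface fit."""

    terms: tuple[str, ...]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    p_values: np.ndarray
    residuals: np.ndarray
    factors: tuple[str, ...]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "estimate": self.coefficients,
                "se": self.standard_errors,
                "p": self.p_values,
            }
        )

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coefficients


def specific_energy(pulse_energy_j: float, pulse_count: int, total_mass_kg: float) -> float:
    """Specific energy input in kJ/kg: pulse energy x pulse count / mass."""
    if not total_mass_kg > 0:
        raise ValueError("total mass must be positive")
    if pulse_energy_j < 0 or pulse_count < 0:
        raise ValueError("pulse energy and count must be non-negative")
    return pulse_energy_j * pulse_count / total_mass_kg / 1000.0


def treatment_time(pulse_count: int, pulse_width_us: float) -> float:
    """Total treatment time in ms: pulse count x pulse width."""
    if pulse_count < 0 or pulse_width_us < 0:
        raise ValueError("pulse count and width must be non-negative")
    return pulse_count * pulse_width_us / 1000.0


def _cycles(force: np.ndarray, threshold: float) -> list[slice]:
    """Contiguous runs where force exceeds the trigger threshold."""
    above = force > threshold
    runs = []
    start = 0 if above[0] else None
    for e in np.flatnonzero(np.diff(above.astype(int))):
        if above[e + 1]:
            start = e + 1
        else:
            runs.append(slice(start, e + 1))
            start = None
    if start is not None:
        runs.append(slice(start, above.size))
    return runs


def compute_tpa(time, force, threshold: float = 0.049) -> TPAParams:
    """TPA parameters from a double-compression force-time curve.

    ``time`` in seconds, ``force`` in Newton.  Cycle boundaries are found
    by trigger-threshold crossings (default 0.049 N); exactly two cycles
    must be present.  Areas are force-time integrals (trapezoidal); each
    cycle is split into compression and withdrawal at its peak.
    """
    t = np.asarray(time, dtype=float)
    f = np.asarray(force, dtype=float)
    if t.shape != f.shape or t.ndim != 1:
        raise ValueError("time and force must be 1-D arrays of equal length")
    if np.any(f < 0):
        raise ValueError("force must be non-negative")
    runs = [r for r in _cycles(f, threshold) if r.stop - r.start >= 3]
    if len(runs) < 2:
        raise ValueError("double-compression curve requires two cycles above threshold")
    c1, c2 = runs[0], runs[1]

    def extend_run(sl: slice) -> slice:
        """Grow a threshold-triggered run along the monotone approach to
        zero force on both sides, so stroke durations and areas are not
        biased by the trigger level."""
        start, stop = sl.start, sl.stop
        while start > 0 and 0 <= f[start - 1] < f[start]:
            start -= 1
        while stop < f.size and 0 <= f[stop] < f[stop - 1]:
            stop += 1
        return slice(start, stop)

    def cycle_stats(sl: slice):
        sl = extend_run(sl)
        tt, ff = t[sl], f[sl]
        peak_idx = int(np.argmax(ff))
        area = float(np.trapezoid(ff, tt))
        area_comp = float(np.trapezoid(ff[: peak_idx + 1], tt[: peak_idx + 1]))
        area_with = float(np.trapezoid(ff[peak_idx:], tt[peak_idx:]))
        dur_comp = float(tt[peak_idx] - tt[0])
        return float(ff[peak_idx]), area, area_comp, area_with, dur_comp

    peak1, area1, comp1, with1, dur1 = cycle_stats(c1)
    _, area2, _, _, dur2 = cycle_stats(c2)
    if area1 <= 0 or dur1 <= 0 or comp1 <= 0:
        raise ValueError("degenerate first compression cycle")
    cohesiveness = area2 / area1
    springiness = dur2 / dur1
    return TPAParams(
        hardness=peak1,
        cohesiveness=cohesiveness,
        springiness=springiness,
        chewiness=peak1 * cohesiveness * springiness,
        resilience=with1 / comp1,
    )


def build_design_matrix(
    inputs: pd.DataFrame | np.ndarray,
    factors: tuple[str, str, str] = ("field_strength", "energy", "calcium"),
    center: bool = False,
) -> tuple[np.ndarray, list[str]]:
    """Full quadratic design matrix in three factors.

    Columns: intercept, the three main effects, the three two-way
    interactions, and the three quadratic terms (10 columns).  Raw-scale
    by default; ``center=True`` subtracts factor means first.
    """
    if isinstance(inputs, pd.DataFrame):
        X0 = inputs.loc[:, list(factors)].to_numpy(dtype=float)
    else:
        X0 = np.asarray(inputs, dtype=float)
        if X0.ndim == 1:
            X0 = X0[None, :]
    if X0.shape[1] != 3:
        raise ValueError("expected exactly three input factors")
    if center:
        X0 = X0 - X0.mean(axis=0)
    x1, x2, x3 = X0.T
    names = [
        "intercept",
        factors[0],
        factors[1],
        factors[2],
        f"{factors[0]}*{factors[1]}",
        f"{factors[0]}*{factors[2]}",
        f"{factors[1]}*{factors[2]}",
        f"{factors[0]}^2",
        f"{factors[1]}^2",
        f"{factors[2]}^2",
    ]
    X = np.column_stack(
        [np.ones_like(x1), x1, x2, x3, x1 * x2, x1 * x3, x2 * x3, x1**2, x2**2, x3**2]
    )
    return X, names


def fit_least_squares(
    X: np.ndarray,
    y,
    terms: list[str] | None = None,
    factors: tuple[str, ...] = ("field_strength", "energy", "calcium"),
) -> RSMFit:
    """OLS fit with standard errors and two-sided t-test p-values.

    Solves the normal equations via QR (``numpy.linalg.lstsq``); standard
    errors come from the residual variance and the inverse Gram matrix.
    Raises on rank deficiency.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if n < k:
        raise ValueError("need at least as many runs as model terms")
    if np.linalg.matrix_rank(X) < k:
        raise ValueError("design matrix is rank deficient")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - k
    if dof > 0:
        sigma2 = float(resid @ resid) / dof
        cov = sigma2 * np.linalg.inv(X.T @ X)
        se = np.sqrt(np.diag(cov))
        with np.errstate(divide="ignore", invalid="ignore"):
            tvals = np.where(se > 0, beta / se, np.inf)
        p = 2.0 * stats.t.sf(np.abs(tvals), dof)
    else:  # exact interpolation: no residual dof
        se = np.full(k, np.nan)
        p = np.full(k, np.nan)
    if terms is None:
        terms = [f"b{i}" for i in range(k)]
    return RSMFit(
        terms=tuple(terms),
        coefficients=beta,
        standard_errors=se,
        p_values=p,
        residuals=resid,
        factors=tuple(factors),
    )


def prediction_profile(
    fit: RSMFit,
    vary: str,
    grid,
    fixed: dict[str, float],
) -> pd.DataFrame:
    """Cross-section of the fitted surface along one factor.

    Evaluates the model over ``grid`` for factor ``vary`` while holding
    the remaining factors at the values in ``fixed``.
    """
    if vary not in fit.factors:
        raise ValueError(f"unknown factor {vary!r}; expected one of {fit.factors}")
    grid = np.asarray(grid, dtype=float)
    rows = []
    for g in grid:
        vals = {vary: g, **{f: fixed[f] for f in fit.factors if f != vary}}
        rows.append([vals[f] for f in fit.factors])
    X, _ = build_design_matrix(np.asarray(rows), factors=tuple(fit.factors))
    return pd.DataFrame({vary: grid, "predicted": fit.predict(X)})
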