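"""In vitro digestion kinetics and starch fraction accounting.

Starch hydrolysis during the small-intestinal phase is described by a
fractional conversion model,

    S(t) = Sf + (S0 - Sf) * exp(-ks * t),

where S0 and Sf are the D-glucose released (mg) at the start and end of
the intestinal phase and ks (1/min) is the digestion rate constant; the
curve rises monotonically from S0 to the plateau Sf.  Protein hydrolysis
(L-serine equivalents, mg) is adequately described by a zero-order model
P(t) = P0 + kp*t fitted by ordinary least squares.

Starch fractions are computed from the glucose released after 20 and
120 min of intestinal digestion (G20, G120) and the total starch (TS):

    RDS% = G20 * 0.9 * 100 / TS
    SDS% = (G120 - G20) * 0.9 * 100 / TS
    RS%  = 100 - RDS% - SDS%

where 0.9 = 162/180 converts glucose mass to anhydroglucose (starch)
mass.  Rapidly digestible starch (RDS) is hydrolysed within 20 min,
slowly digestible starch (SDS) between 20 and 120 min, and resistant
starch (RS) leaves the small intestine undigested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "GLUCOSE_TO_STARCH",
    "DigestaTimeSeries",
    "StarchKineticsFit",
    "ProteinKineticsFit",
    "StarchFractions",
    "FitDiagnostics",
    "fractional_conversion",
    "fit_fractional_conversion",
    "fit_zero_order",
    "starch_fractions",
    "gastric_endpoints",
    "fit_diagnostics",
    "adjusted_r2",
]

#: molecular-mass ratio of anhydroglucose in starch to free glucose (162/180)
GLUCOSE_TO_STARCH = 162.0 / 180.0


@dataclass(frozen=True)
class DigestaTimeSeries:
    """A digestion time course: analyte mass (mg) sampled at times (min)."""

    t: np.ndarray
    value: np.ndarray
    phase: str = "intestinal"  # gastric | intestinal
    analyte: str = "glucose"  # glucose | serine

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        v = np.asarray(self.value, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("t and value must be 1-D arrays of equal length")
        if np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise ValueError("timepoints must be non-negative and strictly increasing")
        if np.any(~np.isfinite(v)):
            raise ValueError("values must be finite")
        if self.phase not in ("gastric", "intestinal"):
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.analyte not in ("glucose", "serine"):
            raise ValueError(f"unknown analyte {self.analyte!r}")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "value", v)

    def __len__(self) -> int:
        return int(self.t.size)


@dataclass(frozen=True)
class StarchKineticsFit:
    S0: float
    Sf: float
    ks: float
    adj_r2: float
    converged: bool

    def predict(self, t):
        return fractional_conversion(t, self.S0, self.Sf, self.ks)


@dataclass(frozen=True)
class ProteinKineticsFit:
    P0: float
    kp: float
    adj_r2: float

    def predict(self, t):
        return self.P0 + self.kp * np.asarray(t, dtype=float)


@dataclass(frozen=True)
class StarchFractions:
    G20: float
    G120: float
    total_starch: float
    RDS: float
    SDS: float
    RS: float


@dataclass(frozen=True)
class FitDiagnostics:
    adj_r2: float
    residuals: pd.DataFrame
    parity: pd.DataFrame


def fractional_conversion(t, S0: float, Sf: float, ks: float):
    """Evaluate S(t) = Sf + (S0 - Sf) * exp(-ks * t)."""
    if ks <= 0:
        raise ValueError("ks must be positive")
    if Sf < S0:
        raise ValueError("Sf must be >= S0")
    t = np.asarray(t, dtype=float)
    out = Sf + (S0 - Sf) * np.exp(-ks * t)
    return out if out.ndim else float(out)


def _init_fractional(t: np.ndarray, v: np.ndarray) -> tuple[float, float, float]:
    S0_0 = max(v[0], 1e-6)
    Sf_0 = max(v[-1], S0_0 * 1.001)
    # log-linear regression of ln(Sf_0 + eps - v) on t for the rate
    eps = 0.05 * max(Sf_0 - S0_0, 1e-6)
    resid = Sf_0 + eps - v
    ok = resid > 0
    if ok.sum() >= 2:
        slope = np.polyfit(t[ok], np.log(resid[ok]), 1)[0]
        ks_0 = max(-slope, 1e-4)
    else:
        ks_0 = 0.01
    return S0_0, Sf_0, ks_0


def fit_fractional_conversion(
    series: DigestaTimeSeries,
    init: tuple[float, float, float] | None = None,
    tol: float = 1e-12,
    max_iter: int = 500,
) -> StarchKineticsFit:
    """Fit the fractional conversion model to an intestinal glucose series.

    Parameters are estimated by nonlinear least squares with positivity
    enforced via a log re-parameterisation.  Requires at least 4 points
    and an overall rising trend.  Non-convergence is surfaced through the
    ``converged`` flag, never by silent defaults.
    """
    t, v = series.t, series.value
    if len(series) < 4:
        raise ValueError("need at least 4 timepoints")
    if v[-1] <= v[0]:
        raise ValueError("series does not increase; fractional conversion model not applicable")
    if init is None:
        S0_0, Sf_0, ks_0 = _init_fractional(t, v)
    else:
        S0_0, Sf_0, ks_0 = init
        if min(S0_0, Sf_0, ks_0) <= 0:
            raise ValueError("init values must be positive")

    def resid(theta):
        S0, Sf, ks = np.exp(theta)
        return v - (Sf + (S0 - Sf) * np.exp(-ks * t))

    sol = least_squares(
        resid,
        x0=np.log([S0_0, Sf_0, ks_0]),
        method="lm",
        xtol=tol,
        ftol=tol,
        gtol=tol,
        max_nfev=max_iter * 4,
    )
    S0, Sf, ks = (float(x) for x in np.exp(sol.x))
    pred = Sf + (S0 - Sf) * np.exp(-ks * t)
    return StarchKineticsFit(
        S0=S0,
        Sf=Sf,
        ks=ks,
        adj_r2=adjusted_r2(v, pred, n_params=3),
        converged=bool(sol.status > 0),
    )


def fit_zero_order(series: DigestaTimeSeries) -> ProteinKineticsFit:
    """Closed-form OLS fit of P(t) = P0 + kp*t (serine, intestinal phase)."""
    t, v = series.t, series.value
    if len(series) < 3:
        raise ValueError("need at least 3 timepoints")
    kp, P0 = np.polyfit(t, v, 1)
    pred = P0 + kp * t
    return ProteinKineticsFit(
        P0=float(P0), kp=float(kp), adj_r2=adjusted_r2(v, pred, n_params=2)
    )


def starch_fractions(G20: float, G120: float, total_starch: float) -> StarchFractions:
    """RDS/SDS/RS percentages from intestinal glucose release.

    The three fractions always sum to 100%: the resistant fraction is the
    complement of the digestible fractions.
    """
    if not total_starch > 0:
        raise ValueError("total_starch must be positive")
    if G20 < 0:
        raise ValueError("G20 must be non-negative")
    if G120 < G20:
        raise ValueError("G120 must be >= G20")
    if GLUCOSE_TO_STARCH * G120 > total_starch * (1 + 1e-9):
        raise ValueError("digested starch (0.9*G120) exceeds total starch")
    rds = G20 * GLUCOSE_TO_STARCH * 100.0 / total_starch
    sds = (G120 - G20) * GLUCOSE_TO_STARCH * 100.0 / total_starch
    rs = 100.0 - rds - sds
    return StarchFractions(
        G20=float(G20),
        G120=float(G120),
        total_starch=float(total_starch),
        RDS=float(rds),
        SDS=float(sds),
        RS=float(rs),
    )


def gastric_endpoints(series: DigestaTimeSeries) -> tuple[float, float]:
    """The sampled values at 0 and 120 min of the gastric phase.

    No kinetic model is fitted in the gastric phase; the two endpoints are
    reported for descriptive comparison only.
    """
    if series.phase != "gastric":
        raise ValueError("gastric_endpoints expects a gastric-phase series")
    out = []
    for tp in (0.0, 120.0):
        hit = np.isclose(series.t, tp)
        if not hit.any():
            raise ValueError(f"series is missing the {tp:g} min timepoint")
        out.append(float(series.value[hit][0]))
    return out[0], out[1]


def adjusted_r2(observed, predicted, n_params: int) -> float:
    """Adjusted R^2 = 1 - (1 - R^2)(n - 1)/(n - p - 1).

    ``n_params`` counts all fitted parameters including the intercept;
    p = n_params - 1 is the number of regression degrees of freedom, so a
    straight line (2 parameters) divides by n - 2 and the fractional
    conversion model (3 parameters) by n - 3.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    n = obs.size
    p = n_params - 1
    if n <= p + 1:
        raise ValueError("adjusted R^2 undefined: too few observations")
    ss_res = float(np.sum((obs - pred) ** 2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else -np.inf
    r2 = 1.0 - ss_res / ss_tot
    return float(1.0 - (1.0 - r2) * (n - 1) / (n - p - 1))


def fit_diagnostics(fit, series: DigestaTimeSeries) -> FitDiagnostics:
    """Goodness-of-fit report: adjusted R^2, residual and parity tables."""
    if hasattr(fit, "converged") and not fit.converged:
        raise ValueError("diagnostics require a converged fit")
    pred = np.asarray(fit.predict(series.t), dtype=float)
    n_params = 3 if isinstance(fit, StarchKineticsFit) else 2
    resid = series.value - pred
    residuals = pd.DataFrame({"t_min": series.t, "residual_mg": resid})
    parity = pd.DataFrame({"observed_mg": series.value, "predicted_mg": pred})
    return FitDiagnostics(
        adj_r2=adjusted_r2(series.value, pred, n_params=n_params),
        residuals=residuals,
        parity=parity,
    )
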