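"""Chewer-group classification and cross-metric correlations.

Participants masticate three bean samples (A, B, C); each records a
total chewing duration per sample.  A participant who stays strictly
below the reference median duration of every sample is a "fast" chewer,
strictly above every median a "slow" chewer, and anything mixed (or
exactly on a median) is "inconsistent".  The three labels partition the
panel.

The reference medians default to the within-panel per-sample medians.
With an odd panel size the sample median is itself one participant's
duration, which caps the number of strictly-faster participants at
(n-1)/2; panels designed around known group thresholds should therefore
pass those thresholds explicitly via ``medians`` (the synthetic panel
generator returns them).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["classify_chewers", "pearson_r", "correlation_report"]

#: metrics included in the default correlation report, when present
DEFAULT_CORR_METRICS = (
    "duration_s",
    "x50_mm2",
    "b",
    "amylase_cu_per_ml",
    "ks_per_min",
    "kp_mg_per_min",
    "RDS",
    "SDS",
    "RS",
)


def classify_chewers(
    durations: pd.DataFrame,
    medians: pd.Series | dict | None = None,
) -> tuple[pd.Series, pd.Series]:
    """Label each participant fast / slow / inconsistent.

    Parameters
    ----------
    durations:
        participants x samples table of chewing durations (s); the index
        identifies participants, columns the samples.
    medians:
        optional per-sample reference medians; computed from ``durations``
        (midpoint of the two central order statistics for even counts)
        when omitted.

    Returns
    -------
    (labels, medians):
        labels indexed like ``durations`` with values in
        {"fast", "slow", "inconsistent"}, and the medians used.
    """
    if durations.shape[0] < 2:
        raise ValueError("need at least 2 participants")
    if durations.isna().any().any():
        missing = durations.index[durations.isna().any(axis=1)].tolist()
        raise ValueError(f"missing durations for participants: {missing}")
    if (durations <= 0).any().any():
        raise ValueError("durations must be positive")
    if medians is None:
        med = durations.median(axis=0)
    else:
        med = pd.Series(medians, dtype=float).reindex(durations.columns)
        if med.isna().any():
            raise ValueError("medians must cover every sample column")
    below = durations.lt(med, axis=1).all(axis=1)
    above = durations.gt(med, axis=1).all(axis=1)
    labels = pd.Series("inconsistent", index=durations.index, name="chewer_class")
    labels[below] = "fast"
    labels[above] = "slow"
    return labels, med


def pearson_r(x, y) -> float:
    """Sample Pearson correlation coefficient.

    Computed directly from the covariance formula
    r = sum((x-xbar)(y-ybar)) / sqrt(sum((x-xbar)^2) sum((y-ybar)^2)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    dx = x - x.mean()
    dy = y - y.mean()
    sx = float(dx @ dx)
    sy = float(dy @ dy)
    if sx == 0 or sy == 0:
        raise ValueError("zero variance: correlation undefined")
    r = float(dx @ dy) / np.sqrt(sx * sy)
    return float(np.clip(r, -1.0, 1.0))


def correlation_report(
    records: pd.DataFrame,
    metrics: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Symmetric Pearson correlation matrix across participant metrics.

    Uses pairwise-complete observations; the diagonal is exactly 1.
    ``records`` holds one row per participant with per-participant
    (sample-averaged) metrics as columns.
    """
    if metrics is None:
        metrics = tuple(c for c in DEFAULT_CORR_METRICS if c in records.columns)
        if not metrics:
            metrics = tuple(records.select_dtypes("number").columns)
    if records.shape[0] < 3:
        raise ValueError("need at least 3 participants")
    k = len(metrics)
    out = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            pair = records[[metrics[i], metrics[j]]].dropna()
            out[i, j] = out[j, i] = pearson_r(
                pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy()
            )
    return pd.DataFrame(out, index=list(metrics), columns=list(metrics))
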