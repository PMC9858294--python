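"""Between-region correlation networks and model-data agreement scores.

The central object is the region x region matrix of Pearson correlations
between monthly time series (death counts, temperature-normalised
residuals, or model expectations).  A region's mean correlation with all
others — its "correlation degree" — summarises how tightly it is wired
into the national network; a sudden departure of a region's degree from
its historical baseline is the proposed surveillance signal for an
emerging local source of risk.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .data_io import MonthlyPanel, ValidationError


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric Pearson-correlation matrix with unit diagonal."""

    region_ids: list[str]
    values: np.ndarray
    n_obs: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.region_ids),) * 2:
            raise ValidationError("correlation matrix shape mismatch")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValidationError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-10):
            raise ValidationError("correlation matrix diagonal must be 1")
        if np.any(v < -1 - 1e-12) or np.any(v > 1 + 1e-12):
            raise ValidationError("correlations must lie in [-1, 1]")


def correlation_matrix(
    panel: MonthlyPanel,
    normalise: str = "none",
    method: str = "pearson",
) -> CorrelationMatrix:
    """Pairwise correlations between the panel's region time series.

    ``normalise="per-region-mean"`` divides each series by its mean first
    (turning counts into rates relative to the period average); Pearson
    correlation is invariant to this positive rescaling, so the option
    only matters for derived exports, not for the correlations themselves.
    A Spearman variant is available but off by default.
    """
    if panel.n_months < 3:
        raise ValidationError("need at least 3 months for correlations")
    x = panel.values.astype(float)
    if normalise == "per-region-mean":
        means = x.mean(axis=1, keepdims=True)
        if np.any(means == 0):
            raise ValidationError("zero-mean region cannot be mean-normalised")
        x = x / means
    elif normalise != "none":
        raise ValidationError(f"unknown normalise mode {normalise!r}")
    sd = x.std(axis=1)
    if np.any(sd == 0):
        bad = [panel.region_ids[i] for i in np.nonzero(sd == 0)[0]]
        raise ValidationError(f"zero-variance series for region(s) {bad}")
    if method == "pearson":
        values = np.corrcoef(x)
    elif method == "spearman":
        values, _ = stats.spearmanr(x, axis=1)
        values = np.atleast_2d(values)
    else:
        raise ValidationError(f"unknown method {method!r}")
    values = np.clip((values + values.T) / 2, -1.0, 1.0)
    np.fill_diagonal(values, 1.0)
    return CorrelationMatrix(region_ids=list(panel.region_ids), values=values,
                             n_obs=panel.n_months)


def offdiag_summary(corr: CorrelationMatrix) -> dict:
    """Mean +/- sd of the upper-triangle correlations and per-region degrees.

    The degree of region i is the mean of its n-1 correlations with the
    other regions; the sd is the population standard deviation over the
    n(n-1)/2 distinct pairs.
    """
    v = corr.values
    n = len(corr.region_ids)
    iu, ju = np.triu_indices(n, k=1)
    upper = v[iu, ju]
    degrees = (v.sum(axis=1) - 1.0) / (n - 1)
    return {
        "mean": float(upper.mean()),
        "sd": float(upper.std()),
        "degrees": dict(zip(corr.region_ids, degrees.astype(float))),
    }


def _upper(values: np.ndarray) -> np.ndarray:
    n = values.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    return values[iu, ju]


def model_data_agreement(
    model_corr: CorrelationMatrix, data_corr: CorrelationMatrix
) -> float:
    """Pearson r between the upper triangles of two correlation matrices.

    The headline score for how well a fitted model reconstructs the
    observed between-region correlation network.
    """
    if model_corr.region_ids != data_corr.region_ids:
        raise ValidationError("correlation matrices cover different regions")
    if len(model_corr.region_ids) < 3:
        raise ValidationError("need >= 3 regions (>= 3 pairs) to correlate")
    a, b = _upper(model_corr.values), _upper(data_corr.values)
    return float(np.corrcoef(a, b)[0, 1])


def deaths_agreement(observed: MonthlyPanel, expected: np.ndarray) -> float:
    """Pearson r between observed counts and model expectations, all cells."""
    exp = np.asarray(expected, dtype=float)
    if exp.shape != observed.values.shape:
        raise ValidationError("observed/expected shape mismatch")
    return float(np.corrcoef(observed.values.ravel(), exp.ravel())[0, 1])


def degree_anomaly(
    current: CorrelationMatrix,
    baseline: Sequence[CorrelationMatrix],
) -> np.ndarray:
    """Z-score of each region's correlation degree against an ensemble.

    ``baseline`` is an ensemble of at least 10 correlation matrices (for
    example from rolling historical windows); the score is
    ``(degree_now - mean_ensemble) / sd_ensemble`` per region.  Regions
    whose ensemble degree has zero spread get NaN (undefined), not +/-inf.
    """
    baseline = list(baseline)
    if len(baseline) < 10:
        raise ValidationError("baseline ensemble needs >= 10 matrices")
    for b in baseline:
        if b.region_ids != current.region_ids:
            raise ValidationError("ensemble member covers different regions")
    n = len(current.region_ids)

    def degrees(c: CorrelationMatrix) -> np.ndarray:
        return (c.values.sum(axis=1) - 1.0) / (n - 1)

    ens = np.array([degrees(b) for b in baseline])  # (n_ens, n)
    mu = ens.mean(axis=0)
    sd = ens.std(axis=0, ddof=1)
    cur = degrees(current)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (cur - mu) / sd
    z[sd == 0] = np.nan
    return z


def rolling_baseline(
    panel: MonthlyPanel, window: int = 36, stride: int = 1
) -> list[CorrelationMatrix]:
    """Correlation matrices over rolling windows, for the anomaly baseline."""
    if panel.n_months < window + 9 * stride:
        raise ValidationError(
            "panel too short for a >= 10-member rolling baseline"
        )
    out = []
    for start in range(0, panel.n_months - window + 1, stride):
        sub = MonthlyPanel(
            region_ids=list(panel.region_ids),
            months=panel.months[start:start + window],
            values=panel.values[:, start:start + window],
            kind=panel.kind,
        )
        out.append(correlation_matrix(sub))
    return out


def edge_list(corr: CorrelationMatrix, threshold: float = 0.8):
    """Upper-triangle edges with |weight| >= threshold, for graph export."""
    n = len(corr.region_ids)
    rows = []
    for i in range(n):
        for j in range(i + 1, n):
            w = corr.values[i, j]
            if abs(w) >= threshold:
                rows.append((corr.region_ids[i], corr.region_ids[j], float(w)))
    return rows
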