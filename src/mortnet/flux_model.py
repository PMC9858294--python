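"""Gravity models of inter-region traveller flux.

Three nested descriptions of the daily commuter matrix ``c_ij`` (flow from
region j into region i) are fitted by least squares on log residuals,
which is maximum likelihood under log-normal multiplicative noise:

* distance only:          ``c_ij ~ kappa * exp(-d_ij / d0) + b0``
* GDP only (inflows):     ``c_i: ~ kappa * GDP_i``
* combined gravity:       ``c_ij ~ kappa * pop_j * GDP_i * exp(-d_ij / d0)``

Zero entries (no commuters between a pair) are excluded from the pairwise
fits; the inflow fit requires every total inflow to be positive.  On top of
the commuter flux an "episodic" component with the same gravity form but
its own scale and (longer) decay length models irregular travel; the total
flux is their sum.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .data_io import DistanceMatrix, FluxMatrix, RegionTable, ValidationError


@dataclass(frozen=True)
class GravityParams:
    """Fitted gravity-model parameters.

    ``kappa`` absorbs the units of population, GDP and persons/day, so its
    numerical value is dataset-scale-dependent; ``d0`` (km) is not.
    """

    kappa: float
    d0: float
    b0: float | None = None  # only for the distance-only form
    kappa_e: float | None = None  # episodic counterparts, when estimated
    d0_e: float | None = None
    n_pairs_used: int | None = None
    rms_log_residual: float | None = None

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValidationError("kappa must be >= 0")
        if self.d0 <= 0:
            raise ValidationError("d0 must be > 0")


def _positive_offdiag_mask(flux: FluxMatrix) -> np.ndarray:
    mask = flux.values > 0
    np.fill_diagonal(mask, False)
    return mask


def fit_distance_decay(flux: FluxMatrix, dist: DistanceMatrix) -> GravityParams:
    """Fit ``c(d) = kappa * exp(-d/d0) + b0`` to positive entries.

    Minimises sum of squared log residuals over strictly positive
    off-diagonal entries; ``b0`` is constrained non-negative.
    """
    mask = _positive_offdiag_mask(flux)
    n_used = int(mask.sum())
    if n_used == 0:
        raise ValidationError("all flux entries are zero; nothing to fit")
    if n_used < 10:
        raise ValidationError(f"need >= 10 positive entries, found {n_used}")
    c = flux.values[mask]
    d = dist.values[mask]
    logc = np.log(c)

    # data-driven deterministic start: ignore b0, regress log c on d
    slope, intercept = np.polyfit(d, logc, 1)
    d0_init = -1.0 / slope if slope < 0 else np.ptp(d) if np.ptp(d) > 0 else 100.0
    kappa_init = float(np.exp(intercept))
    b0_init = max(float(np.min(c)) * 0.1, 1e-8)

    def neg_ll(theta):
        kappa, d0, b0 = np.exp(theta[0]), np.exp(theta[1]), theta[2]
        resid = logc - np.log(kappa * np.exp(-d / d0) + b0)
        return float(resid @ resid)

    res = minimize(
        neg_ll,
        x0=np.array([np.log(kappa_init), np.log(max(d0_init, 1.0)), b0_init]),
        method="TNC",
        bounds=[(None, None), (None, None), (0.0, None)],
        options={"maxfun": 2000},
    )
    kappa, d0, b0 = float(np.exp(res.x[0])), float(np.exp(res.x[1])), float(res.x[2])
    rms = float(np.sqrt(res.fun / n_used))
    return GravityParams(kappa=kappa, d0=d0, b0=b0,
                         n_pairs_used=n_used, rms_log_residual=rms)


def fit_gdp_linear(flux: FluxMatrix, regions: RegionTable) -> float:
    """Fit ``c_i: = kappa * GDP_i`` to total inflows; returns kappa.

    The least-squares optimum in log space is closed-form:
    ``log kappa = mean(log c_i: - log GDP_i)``.  Every inflow must be
    positive because the totals sum over all origin regions.
    """
    inflow = flux.values.sum(axis=1)
    if np.any(inflow <= 0):
        bad = [flux.region_ids[i] for i in np.nonzero(inflow <= 0)[0]]
        raise ValidationError(f"zero total inflow for region(s) {bad}")
    return float(np.exp(np.mean(np.log(inflow) - np.log(regions.gdps))))


def gravity_flux(
    regions: RegionTable, dist: DistanceMatrix, kappa: float, d0: float
) -> np.ndarray:
    """Dense gravity prediction ``kappa * pop_j * GDP_i * exp(-d_ij/d0)``."""
    pred = kappa * regions.populations[None, :] * regions.gdps[:, None] \
        * np.exp(-dist.values / d0)
    np.fill_diagonal(pred, 0.0)
    return pred


def fit_gravity(
    flux: FluxMatrix, dist: DistanceMatrix, regions: RegionTable
) -> GravityParams:
    """Fit the combined gravity model ``kappa * pop_j * GDP_i * exp(-d/d0)``.

    Least squares on log residuals over positive off-diagonal entries.  The
    log model is linear in (log kappa, 1/d0), so a linear regression gives
    the start; a bounded quasi-Newton polish in (log kappa, log d0) space
    then handles the (rare) case where the regression slope is non-negative.
    """
    mask = _positive_offdiag_mask(flux)
    n_used = int(mask.sum())
    if n_used == 0:
        raise ValidationError("all flux entries are zero; nothing to fit")
    if n_used < 10:
        raise ValidationError(f"need >= 10 positive entries, found {n_used}")
    c = flux.values[mask]
    d = dist.values[mask]
    mass = (regions.populations[None, :] * regions.gdps[:, None])[mask]
    y = np.log(c) - np.log(mass)  # = log kappa - d/d0 + noise

    slope, intercept = np.polyfit(d, y, 1)
    if slope < 0:
        x0 = np.array([intercept, np.log(-1.0 / slope)])
    else:  # distance-increasing data; start from a weak decay
        x0 = np.array([float(np.mean(y)), np.log(max(np.ptp(d), 1.0) * 10)])

    def neg_ll(theta):
        resid = y - (theta[0] - d / np.exp(theta[1]))
        return float(resid @ resid)

    res = minimize(neg_ll, x0=x0, method="TNC", options={"maxfun": 2000})
    kappa, d0 = float(np.exp(res.x[0])), float(np.exp(res.x[1]))
    rms = float(np.sqrt(res.fun / n_used))
    return GravityParams(kappa=kappa, d0=d0,
                         n_pairs_used=n_used, rms_log_residual=rms)


def episodic_flux(
    regions: RegionTable, dist: DistanceMatrix, kappa_e: float, d0_e: float
) -> FluxMatrix:
    """Episodic-travel matrix ``e_ij = kappa_e * pop_j * GDP_i * exp(-d/d0_e)``.

    ``d0_e`` is expected to exceed the commuter decay length: irregular
    trips are less distance-limited than daily commutes.  The distance-free
    limit is reached by passing ``d0_e = inf``.
    """
    if kappa_e < 0:
        raise ValidationError("kappa_e must be >= 0")
    if not d0_e > 0:
        raise ValidationError("d0_e must be > 0")
    decay = np.exp(-dist.values / d0_e) if np.isfinite(d0_e) else np.ones_like(dist.values)
    values = kappa_e * regions.populations[None, :] * regions.gdps[:, None] * decay
    np.fill_diagonal(values, 0.0)
    return FluxMatrix(region_ids=list(regions.region_ids), values=values,
                      kind="episodic")


def total_flux(commuter: FluxMatrix, episodic: FluxMatrix) -> FluxMatrix:
    """Total traveller flux ``f_ij = c_ij + e_ij``."""
    if commuter.values.shape != episodic.values.shape:
        raise ValidationError("commuter/episodic shape mismatch")
    if commuter.region_ids != episodic.region_ids:
        raise ValidationError("commuter/episodic region sets differ")
    return FluxMatrix(
        region_ids=list(commuter.region_ids),
        values=commuter.values + episodic.values,
        kind="total",
    )


def gravity_fit_summary(params: GravityParams) -> dict:
    """JSON-friendly view of a fit, for the CLI output files."""
    return {k: v for k, v in dataclasses.asdict(params).items() if v is not None}
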