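"""Synthetic study systems with known ground truth.

Generates the full input set the pipeline expects — a region table with
heterogeneous populations and GDPs on a ~1000 km planar extent, seasonal
sinusoidal temperatures with a latitude gradient, a commuter matrix
scattered log-normally around the gravity law, and monthly death counts
Poisson-sampled from the flux-temperature forward model — so that every
fitting stage has a parameter-recovery test surface without external
downloads.  Every operation is a pure function of its inputs and a seed:
one global seed streams to per-component seeds by fixed offsets.

The default ground-truth parameters are chosen so that the infective
(winter, SIR-driven) and non-infective (summer, warm-arm) components of
mortality have comparable magnitude on top of the region baselines,
exercising both halves of the model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import (DistanceMatrix, FluxMatrix, MonthlyPanel, RegionTable,
                      StationReadings, ValidationError, distance_matrix)
from .flux_model import episodic_flux, total_flux
from .sir_network import (FullModelParams, expected_deaths, mixing_matrices,
                          patient_zero_distribution)
from .temperature_model import BiphasicParams, biphasic_lambda

# fixed offsets deriving per-component seed streams from the global seed
_SEED_REGIONS, _SEED_TEMPS, _SEED_COMMUTERS, _SEED_PANEL, _SEED_STATIONS, \
    _SEED_BIPHASIC = 1, 2, 3, 4, 5, 6


def _rng(seed: int, offset: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), offset]))


@dataclass
class SyntheticTruth:
    """A complete synthetic study system with its generating parameters."""

    regions: RegionTable
    temperatures: MonthlyPanel
    commuter_flux: FluxMatrix
    true_biphasic: dict[str, BiphasicParams]
    true_model: FullModelParams
    seed: int
    # filled by generate_mortality_panel for test introspection
    patient_zeros: np.ndarray | None = None
    true_lambda: np.ndarray | None = None


# ---------------------------------------------------------------------------
# Regions
# ---------------------------------------------------------------------------

def generate_regions(n: int, seed: int) -> RegionTable:
    """n regions over a ~1000 km extent (9 deg of latitude, 8 of longitude).

    Populations are log-uniform in [1e5, 1e7] persons; GDP is population
    times a log-normal per-capita productivity (sigma = 0.3, scale 25
    currency units/person — the gravity fits absorb the units).
    """
    if n < 2:
        raise ValidationError("need at least 2 regions")
    rng = _rng(seed, _SEED_REGIONS)
    lats = rng.uniform(38.0, 47.0, size=n)
    lons = rng.uniform(8.0, 16.0, size=n)
    pops = 10.0 ** rng.uniform(5.0, 7.0, size=n)
    gdps = pops * 25.0 * rng.lognormal(mean=0.0, sigma=0.3, size=n)
    return RegionTable(
        region_ids=[f"R{i:02d}" for i in range(n)],
        names=[f"Region {i}" for i in range(n)],
        populations=pops, gdps=gdps, lats=lats, lons=lons,
    )


# ---------------------------------------------------------------------------
# Temperatures
# ---------------------------------------------------------------------------

def generate_temperatures(
    regions: RegionTable, n_months: int, seed: int,
    noise_sd: float = 1.0, start_year: int = 2011,
) -> MonthlyPanel:
    """Seasonal sinusoidal monthly temperatures with a latitude gradient.

    T_im = base_i + A_i cos(2 pi (month - July)/12) + eps, with base_i
    falling linearly from 18 degC at the southern edge (lat 38) to 10 degC
    at the northern edge (lat 47), amplitude A_i uniform in [8, 12] degC
    and eps ~ Normal(0, noise_sd).
    """
    if n_months < 12:
        raise ValidationError("need at least 12 months")
    rng = _rng(seed, _SEED_TEMPS)
    base = 18.0 - (regions.lats - 38.0) * (8.0 / 9.0)
    amp = rng.uniform(8.0, 12.0, size=regions.n)
    months = [(start_year + k // 12, k % 12 + 1) for k in range(n_months)]
    cal = np.array([m for _, m in months], dtype=float)
    season = np.cos(2 * np.pi * (cal[None, :] - 7.0) / 12.0)
    values = base[:, None] + amp[:, None] * season \
        + rng.normal(0.0, noise_sd, size=(regions.n, n_months))
    return MonthlyPanel(region_ids=list(regions.region_ids), months=months,
                        values=values, kind="temperature")


# ---------------------------------------------------------------------------
# Commuter flux
# ---------------------------------------------------------------------------

def generate_commuters(
    regions: RegionTable,
    kappa: float = 3e-9,
    d0: float = 150.0,
    sigma: float = 0.3,
    zero_fraction: float = 0.1,
    seed: int = 0,
    dist: DistanceMatrix | None = None,
) -> FluxMatrix:
    """Commuter matrix scattered log-normally around the gravity law.

    c_ij = kappa * pop_j * GDP_i * exp(-d_ij/d0) * LogNormal(0, sigma);
    the ``zero_fraction`` longest-distance ordered pairs are set to exactly
    zero, mimicking the absent long-range entries of real commuter
    matrices (excluded from the pairwise fits).  The default ``kappa``
    gives daily outflow fractions of a few percent for the default region
    generator; ``d0 = 150`` km is a typical commuting decay length.
    """
    if kappa <= 0 or d0 <= 0 or sigma < 0 or not 0 <= zero_fraction < 1:
        raise ValidationError("invalid commuter-generator arguments")
    rng = _rng(seed, _SEED_COMMUTERS)
    if dist is None:
        dist = distance_matrix(regions)
    mean = kappa * regions.populations[None, :] * regions.gdps[:, None] \
        * np.exp(-dist.values / d0)
    noise = rng.lognormal(mean=0.0, sigma=sigma, size=mean.shape) \
        if sigma > 0 else np.ones_like(mean)
    values = mean * noise
    np.fill_diagonal(values, 0.0)
    n = regions.n
    n_off = n * (n - 1)
    n_zero = int(round(zero_fraction * n_off))
    if n_zero > 0:
        off = np.argwhere(~np.eye(n, dtype=bool))
        d_off = dist.values[off[:, 0], off[:, 1]]
        longest = off[np.argsort(-d_off, kind="stable")[:n_zero]]
        values[longest[:, 0], longest[:, 1]] = 0.0
    return FluxMatrix(region_ids=list(regions.region_ids), values=values,
                      kind="commuter")


# ---------------------------------------------------------------------------
# Ground-truth model parameters
# ---------------------------------------------------------------------------

def default_true_model(
    regions: RegionTable, dist: DistanceMatrix | None = None,
    d0_e: float = 400.0, episodic_outflow: float = 0.02,
) -> FullModelParams:
    """Forward-model truth emulating winter-dominant, synchronised mortality.

    Baselines rho0_i = 5e-4 * pop_i (about 500 deaths/month per million);
    the warm arm reaches ~3e-4 * pop_i at 25 degC.  Transmission is strong
    enough in the cold season (beta ~ 0.7/day at 8 degC against recovery
    gamma = 0.15/day, saturating at the 1/dt ceiling below ~5 degC) that
    winter epidemics sweep a large, population-proportional share of every
    region within the 30-day month, while summer epidemics
    (beta ~ 0.04/day at 25 degC) die out.  With mu = 1.2e-3 the infective
    winter deaths are then comparable to the baseline in every region, so
    total mortality peaks in winter everywhere and the regional series are
    strongly positively correlated — the phenomenology the correlation
    network analysis is about.  The episodic flux scale is set so its mean
    daily outflow fraction is ``episodic_outflow`` with decay length
    ``d0_e`` (longer than the 150 km commuter decay); the flux carries the
    epidemic into non-seeded regions within days, synchronising them.
    """
    if dist is None:
        dist = distance_matrix(regions)
    unit = episodic_flux(regions, dist, kappa_e=1.0, d0_e=d0_e)
    unit_frac = unit.values.sum(axis=0) / regions.populations
    kappa_e = episodic_outflow / float(np.mean(unit_frac))
    a_h = 0.10
    b_h = float(np.log(3e-4) - a_h * 25.0)
    return FullModelParams(
        a_h=a_h, b_h=b_h, rho0=5e-4 * regions.populations,
        kappa_e=kappa_e, d0_e=d0_e, mu=1.2e-3,
        a_beta=0.10, b_beta=0.5, gamma=0.15,
    )


def default_true_biphasic(
    regions: RegionTable, seed: int
) -> dict[str, BiphasicParams]:
    """Per-region U-shaped truth for the biphasic recovery harness.

    Arm slopes and the minimum location vary across regions; the curve
    level is set so monthly expectations stay in roughly [800, 2500] over
    the seasonal temperature range.
    """
    rng = _rng(seed, _SEED_BIPHASIC)
    out = {}
    for rid in regions.region_ids:
        a_c = rng.uniform(0.03, 0.06)
        a_h = rng.uniform(0.08, 0.12)
        tm = rng.uniform(16.0, 20.0)
        lam0 = rng.uniform(900.0, 1100.0)
        b_c = float(np.log(lam0 / 2) + a_c * tm)
        b_h = float(np.log(lam0 / 2) - a_h * tm)
        out[rid] = BiphasicParams(a_c=float(a_c), b_c=b_c,
                                  a_h=float(a_h), b_h=b_h)
    return out


def generate_biphasic_counts(
    truth_biphasic: dict[str, BiphasicParams],
    temps: MonthlyPanel, seed: int,
) -> MonthlyPanel:
    """Poisson counts around the per-region biphasic curves."""
    rng = _rng(seed, _SEED_BIPHASIC + 100)
    lam = np.vstack([
        biphasic_lambda(temps.values[i], truth_biphasic[rid])
        for i, rid in enumerate(temps.region_ids)
    ])
    return MonthlyPanel(region_ids=list(temps.region_ids),
                        months=list(temps.months),
                        values=rng.poisson(lam).astype(float), kind="deaths")


# ---------------------------------------------------------------------------
# Assembly and the forward mortality panel
# ---------------------------------------------------------------------------

def make_truth(
    n_regions: int = 20, n_months: int = 108, seed: int = 0,
    true_model: FullModelParams | None = None,
    commuter_kwargs: dict | None = None,
) -> SyntheticTruth:
    """Build a complete synthetic system (without the mortality panel)."""
    regions = generate_regions(n_regions, seed)
    dist = distance_matrix(regions)
    temps = generate_temperatures(regions, n_months, seed)
    commuters = generate_commuters(regions, seed=seed, dist=dist,
                                   **(commuter_kwargs or {}))
    if true_model is None:
        true_model = default_true_model(regions, dist)
    return SyntheticTruth(
        regions=regions, temperatures=temps, commuter_flux=commuters,
        true_biphasic=default_true_biphasic(regions, seed),
        true_model=true_model, seed=seed,
    )


def generate_mortality_panel(truth: SyntheticTruth, seed: int) -> MonthlyPanel:
    """Poisson monthly death counts from the flux-temperature forward model.

    For each month a patient zero is drawn with probability proportional
    to GDP, the 30-day network epidemic is integrated, the mortality
    expectation lambda = warm arm + baseline + mu R(30) is formed and
    counts are sampled as Poisson(lambda).  The drawn patient-zero
    sequence and the exact lambdas are recorded on ``truth`` for test
    introspection.
    """
    rng = _rng(seed, _SEED_PANEL)
    regions = truth.regions
    dist = distance_matrix(regions)
    episodic = episodic_flux(regions, dist, truth.true_model.kappa_e,
                             truth.true_model.d0_e)
    flux = total_flux(truth.commuter_flux, episodic)
    mix = mixing_matrices(flux, regions)
    p0 = patient_zero_distribution(regions)
    M = truth.temperatures.n_months
    lam = np.empty((regions.n, M))
    i0s = rng.choice(regions.n, size=M, p=p0)
    for m in range(M):
        lam[:, m] = expected_deaths(
            truth.temperatures.values[:, m], int(i0s[m]), flux,
            truth.true_model, regions, mix=mix,
        )
    truth.patient_zeros = i0s
    truth.true_lambda = lam
    counts = rng.poisson(lam).astype(float)
    return MonthlyPanel(region_ids=list(regions.region_ids),
                        months=list(truth.temperatures.months),
                        values=counts, kind="deaths")


# ---------------------------------------------------------------------------
# Daily station files (only to exercise the raw-data reader)
# ---------------------------------------------------------------------------

def fabricate_station_readings(
    regions: RegionTable, n_months: int, seed: int,
    stations_per_region: int = 3, start_year: int = 2011,
) -> StationReadings:
    """Synthetic GHCN-Daily-style readings near each region's capital.

    Three stations per region within ~0.3 deg of the capital report daily
    temperatures around the regional seasonal cycle; one station per
    region reports only TMAX/TMIN to exercise the midpoint fallback.  The
    model path never needs daily data — this exists to test the reader
    and the inverse-distance monthly aggregation on their own format.
    """
    rng = _rng(seed, _SEED_STATIONS)
    base = 18.0 - (regions.lats - 38.0) * (8.0 / 9.0)
    rows = []
    for ri in range(regions.n):
        for s in range(stations_per_region):
            sid = f"ST{ri:02d}{s}"
            slat = regions.lats[ri] + rng.uniform(0.02, 0.3) * rng.choice([-1, 1])
            slon = regions.lons[ri] + rng.uniform(0.02, 0.3) * rng.choice([-1, 1])
            tavg_only_missing = s == stations_per_region - 1
            for k in range(n_months):
                year, month = start_year + k // 12, k % 12 + 1
                n_days = pd.Period(f"{year}-{month:02d}").days_in_month
                season = np.cos(2 * np.pi * (month - 7.0) / 12.0)
                mean_t = base[ri] + 10.0 * season
                for day in range(1, n_days + 1):
                    t = mean_t + rng.normal(0.0, 2.0)
                    spread = rng.uniform(3.0, 6.0)
                    rows.append({
                        "STATION": sid, "LATITUDE": slat, "LONGITUDE": slon,
                        "DATE": f"{year:04d}-{month:02d}-{day:02d}",
                        "TAVG": np.nan if tavg_only_missing else round(t, 2),
                        "TMAX": round(t + spread, 2),
                        "TMIN": round(t - spread, 2),
                    })
    frame = pd.DataFrame(rows)
    frame["DATE"] = pd.to_datetime(frame["DATE"])
    return StationReadings(frame=frame)
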