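"""Tabular I/O and derived geometry for the regional mortality pipeline.

The pipeline works on four kinds of tabular input: a static region table
(population, GDP, capital coordinates), daily weather-station readings,
an origin-destination commuter matrix, and monthly panels (deaths or
temperatures) with regions as rows and ``YYYY-MM`` columns.  This module
reads and writes those formats, validates their invariants, and builds the
derived geometric quantities: the inter-capital great-circle distance
matrix and the inverse-distance station weighting that turns daily station
readings into one mean temperature per region per month.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0


class ValidationError(ValueError):
    """Raised when an input table violates a documented invariant."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionTable:
    """Static attributes of the regions under study.

    Attributes
    ----------
    region_ids : list of str
        Unique short keys, in a fixed order shared by every derived matrix.
    names : list of str
    populations : ndarray, persons
    gdps : ndarray, currency units (scale-free; fits absorb the units)
    lats, lons : ndarray, degrees of the main administrative centre
    """

    region_ids: list[str]
    names: list[str]
    populations: np.ndarray
    gdps: np.ndarray
    lats: np.ndarray
    lons: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.region_ids)
        if n < 2:
            raise ValidationError("a region table needs at least 2 regions")
        if len(set(self.region_ids)) != n:
            dupes = {r for r in self.region_ids if self.region_ids.count(r) > 1}
            raise ValidationError(f"duplicate region_ids: {sorted(dupes)}")
        for name, arr in (("population", self.populations), ("gdp", self.gdps)):
            arr = np.asarray(arr, dtype=float)
            bad = np.nonzero(~(arr > 0))[0]
            if bad.size:
                raise ValidationError(
                    f"non-positive {name} for region(s) "
                    f"{[self.region_ids[i] for i in bad]}"
                )
        for arr, lo, hi, what in (
            (self.lats, -90.0, 90.0, "latitude"),
            (self.lons, -180.0, 360.0, "longitude"),
        ):
            a = np.asarray(arr, dtype=float)
            if not np.all(np.isfinite(a)) or a.min() < lo or a.max() > hi:
                raise ValidationError(f"invalid {what} values")

    @property
    def n(self) -> int:
        return len(self.region_ids)

    def index_of(self, region_id: str) -> int:
        return self.region_ids.index(region_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region_id": self.region_ids,
                "name": self.names,
                "population": self.populations,
                "gdp": self.gdps,
                "lat": self.lats,
                "lon": self.lons,
            }
        )


@dataclass(frozen=True)
class DistanceMatrix:
    """Great-circle distances in km between main administrative centres."""

    region_ids: list[str]
    values: np.ndarray  # (n, n), symmetric, zero diagonal

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.region_ids),) * 2:
            raise ValidationError("distance matrix shape mismatch")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValidationError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValidationError("distance matrix diagonal must be zero")


@dataclass(frozen=True)
class StationReadings:
    """Daily temperature readings from weather stations (long format)."""

    frame: pd.DataFrame  # STATION, LATITUDE, LONGITUDE, DATE, TAVG, TMAX, TMIN


@dataclass
class MonthlyPanel:
    """A region x month matrix of death counts or mean temperatures."""

    region_ids: list[str]
    months: list[tuple[int, int]]  # ordered (year, calendar month)
    values: np.ndarray  # (n_regions, n_months)
    kind: str  # "deaths" | "temperature"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.region_ids), len(self.months)):
            raise ValidationError("panel shape mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("panel contains non-finite cells")
        if self.kind == "deaths":
            v = self.values
            if np.any(v < 0) or np.any(v != np.round(v)):
                raise ValidationError("death counts must be non-negative integers")
        elif self.kind not in ("temperature", "residual"):
            raise ValidationError(f"unknown panel kind {self.kind!r}")

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    @property
    def n_months(self) -> int:
        return len(self.months)

    def month_labels(self) -> list[str]:
        return [f"{y:04d}-{m:02d}" for y, m in self.months]

    def row(self, region_id: str) -> np.ndarray:
        return self.values[self.region_ids.index(region_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.region_ids, columns=self.month_labels()
        )


@dataclass(frozen=True)
class FluxMatrix:
    """Directed persons/day flows; entry [i, j] is the flow from j into i."""

    region_ids: list[str]
    values: np.ndarray  # (n, n), non-negative, zero diagonal
    kind: str  # "commuter" | "episodic" | "total"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.region_ids),) * 2:
            raise ValidationError("flux matrix shape mismatch")
        if np.any(v < 0):
            raise ValidationError("flux entries must be non-negative")
        if np.any(np.diag(v) != 0):
            raise ValidationError("flux diagonal must be zero")
        if self.kind not in ("commuter", "episodic", "total"):
            raise ValidationError(f"unknown flux kind {self.kind!r}")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_REGION_COLUMNS = ["region_id", "name", "population", "gdp", "lat", "lon"]


def read_region_table(path) -> RegionTable:
    """Read a region table CSV (region_id,name,population,gdp,lat,lon)."""
    df = pd.read_csv(path, dtype={"region_id": str, "name": str})
    missing = [c for c in _REGION_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"region table missing columns {missing}")
    return RegionTable(
        region_ids=df["region_id"].tolist(),
        names=df["name"].tolist(),
        populations=df["population"].to_numpy(dtype=float),
        gdps=df["gdp"].to_numpy(dtype=float),
        lats=df["lat"].to_numpy(dtype=float),
        lons=df["lon"].to_numpy(dtype=float),
    )


def write_region_table(regions: RegionTable, path) -> None:
    regions.to_frame().to_csv(path, index=False)


def read_station_readings(path) -> StationReadings:
    """Read GHCN-Daily-style CSV (STATION,LATITUDE,LONGITUDE,DATE,TAVG,TMAX,TMIN)."""
    df = pd.read_csv(path, dtype={"STATION": str})
    needed = ["STATION", "LATITUDE", "LONGITUDE", "DATE"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValidationError(f"station file missing columns {missing}")
    for c in ("TAVG", "TMAX", "TMIN"):
        if c not in df.columns:
            df[c] = np.nan
    df["DATE"] = pd.to_datetime(df["DATE"], format="%Y-%m-%d")
    no_temp = df[["TAVG", "TMAX", "TMIN"]].isna().all(axis=1)
    if no_temp.any():
        raise ValidationError(
            f"{int(no_temp.sum())} station rows carry no temperature field"
        )
    return StationReadings(frame=df)


def read_flux_matrix(path, regions: RegionTable, kind: str = "commuter") -> FluxMatrix:
    """Read a long-format OD matrix CSV (origin_id,destination_id,commuters_per_day).

    Pairs absent from the file are zero flux.  Row convention: the stored
    matrix entry [i, j] holds the flow from origin j to destination i.
    """
    df = pd.read_csv(path, dtype={"origin_id": str, "destination_id": str})
    needed = ["origin_id", "destination_id", "commuters_per_day"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValidationError(f"OD matrix missing columns {missing}")
    idx = {r: i for i, r in enumerate(regions.region_ids)}
    values = np.zeros((regions.n, regions.n))
    for _, row in df.iterrows():
        o, d = row["origin_id"], row["destination_id"]
        if o not in idx or d not in idx:
            raise ValidationError(f"OD pair ({o}, {d}) names unknown region")
        if o == d:
            continue
        values[idx[d], idx[o]] = float(row["commuters_per_day"])
    return FluxMatrix(region_ids=list(regions.region_ids), values=values, kind=kind)


def write_flux_matrix(flux: FluxMatrix, path) -> None:
    rows = []
    n = len(flux.region_ids)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            rows.append(
                (flux.region_ids[j], flux.region_ids[i], flux.values[i, j])
            )
    pd.DataFrame(
        rows, columns=["origin_id", "destination_id", "commuters_per_day"]
    ).to_csv(path, index=False)


def read_monthly_panel(path, kind: str) -> MonthlyPanel:
    """Read a wide-format panel CSV: rows = regions, columns = YYYY-MM."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    months = []
    for c in df.columns:
        y, m = str(c).split("-")
        months.append((int(y), int(m)))
    return MonthlyPanel(
        region_ids=df.index.tolist(),
        months=months,
        values=df.to_numpy(dtype=float),
        kind=kind,
    )


def write_monthly_panel(panel: MonthlyPanel, path) -> None:
    panel.to_frame().to_csv(path)


# ---------------------------------------------------------------------------
# Derived geometry
# ---------------------------------------------------------------------------

def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km (Earth radius 6371 km); broadcasts."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def distance_matrix(regions: RegionTable) -> DistanceMatrix:
    """Pairwise great-circle distances between region capitals.

    Raises on coincident capitals of distinct regions (degenerate geometry
    that would break inverse-distance weighting and the gravity fits).
    """
    d = haversine_km(
        regions.lats[:, None], regions.lons[:, None],
        regions.lats[None, :], regions.lons[None, :],
    )
    np.fill_diagonal(d, 0.0)
    off = ~np.eye(regions.n, dtype=bool)
    if np.any(d[off] <= 0):
        i, j = np.argwhere((d <= 0) & off)[0]
        raise ValidationError(
            f"regions {regions.region_ids[i]!r} and {regions.region_ids[j]!r} "
            "have coincident capitals"
        )
    d = (d + d.T) / 2  # enforce exact symmetry against float asymmetry
    return DistanceMatrix(region_ids=list(regions.region_ids), values=d)


def _station_daily_temperature(df: pd.DataFrame) -> pd.Series:
    """Daily temperature per row: TAVG when present, else (TMAX+TMIN)/2."""
    tavg = df["TAVG"]
    mid = (df["TMAX"] + df["TMIN"]) / 2.0
    return tavg.where(tavg.notna(), mid)


def monthly_temperature(
    stations: StationReadings, regions: RegionTable, k: int = 3
) -> MonthlyPanel:
    """Region-month mean temperatures from the k nearest stations.

    For each region the k stations closest to the capital are selected
    (ties broken by station id); each station contributes its monthly mean
    of daily temperatures, weighted by the inverse of its distance to the
    capital.  Months are calendar months present in the data; every region
    must have at least one usable reading per selected station per month.
    """
    df = stations.frame.copy()
    df["temp"] = _station_daily_temperature(df)
    df["ym"] = list(zip(df["DATE"].dt.year, df["DATE"].dt.month))
    months = sorted(set(df["ym"]))

    meta = df.groupby("STATION")[["LATITUDE", "LONGITUDE"]].first()
    if len(meta) < k:
        raise ValidationError(f"need >= {k} stations, found {len(meta)}")
    # station x month mean of daily temperatures
    sm = df.groupby(["STATION", "ym"])["temp"].mean()

    values = np.empty((regions.n, len(months)))
    for ri in range(regions.n):
        dist = haversine_km(
            regions.lats[ri], regions.lons[ri],
            meta["LATITUDE"].to_numpy(), meta["LONGITUDE"].to_numpy(),
        )
        order = sorted(zip(dist, meta.index))  # ties broken by station id
        chosen = order[:k]
        gaps = []
        for mi, ym in enumerate(months):
            wsum = 0.0
            tsum = 0.0
            for d_s, sid in chosen:
                if (sid, ym) not in sm.index or np.isnan(sm.loc[(sid, ym)]):
                    gaps.append((regions.region_ids[ri], ym, sid))
                    continue
                w = 1.0 / max(d_s, 1e-9)  # guard a station on the capital
                wsum += w
                tsum += w * float(sm.loc[(sid, ym)])
            if wsum == 0.0:
                raise ValidationError(
                    f"region {regions.region_ids[ri]!r} has no usable readings "
                    f"for month {ym}"
                )
            values[ri, mi] = tsum / wsum
        if gaps:
            raise ValidationError(
                f"missing station-months for region {gaps[0][0]!r}: "
                f"{[(g[2], g[1]) for g in gaps[:5]]}..."
            )
    return MonthlyPanel(
        region_ids=list(regions.region_ids),
        months=months,
        values=values,
        kind="temperature",
    )
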