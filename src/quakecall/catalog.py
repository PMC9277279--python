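"""Earthquake-catalog selection and station-epicentre geometry.

Catalogs are pandas DataFrames with columns ``event_id, origin_time
(tz-aware UTC), magnitude, depth_km, lat, lon``; stations carry
``station_id, lat, lon, deploy_start, deploy_end, sample_rate_hz``.

The selection chain mirrors a typical seismic-disturbance study design:
keep events above a magnitude floor inside a study box and period, drop
anything belonging to a swarm (another event within +/- 8 h), then take a
stratified-random subset with at least one event per week so the sample
covers the deployment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "EARTH_RADIUS_KM",
    "filter_catalog",
    "isolate_singular",
    "stratified_weekly_sample",
    "epicentre_distance_km",
    "read_catalog_csv",
    "write_catalog_csv",
    "read_stations_csv",
]

#: IUGG mean Earth radius.
EARTH_RADIUS_KM = 6371.0088

CATALOG_COLUMNS = ["event_id", "origin_time", "magnitude", "depth_km", "lat", "lon"]


def filter_catalog(events: pd.DataFrame,
                   bbox: tuple[float, float, float, float],
                   period: tuple[pd.Timestamp, pd.Timestamp],
                   min_magnitude: float = 3.0) -> pd.DataFrame:
    """Keep events with magnitude strictly above ``min_magnitude`` whose
    epicentre lies in the closed ``bbox`` (lat_min, lat_max, lon_min,
    lon_max) and whose origin time lies in the closed ``period``.

    Input order is preserved; an empty catalog passes through empty.
    """
    lat_min, lat_max, lon_min, lon_max = bbox
    if lat_min > lat_max or lon_min > lon_max:
        raise ValueError("bbox must be ordered (lat_min <= lat_max, lon_min <= lon_max)")
    t0, t1 = pd.Timestamp(period[0]), pd.Timestamp(period[1])
    if t0 > t1:
        raise ValueError("period must be ordered")
    if events.empty:
        return events.copy()
    keep = (
        (events["magnitude"] > min_magnitude)
        & events["lat"].between(lat_min, lat_max)
        & events["lon"].between(lon_min, lon_max)
        & (events["origin_time"] >= t0)
        & (events["origin_time"] <= t1)
    )
    return events.loc[keep].copy()


def isolate_singular(events: pd.DataFrame, isolation_hours: float = 8.0) -> pd.DataFrame:
    """Drop swarm members: keep only events with no other event strictly
    within ``isolation_hours`` of their origin time.

    The exclusion is symmetric — both members of a close pair are dropped —
    and the boundary is open: a gap of exactly ``isolation_hours`` counts
    as isolated.
    """
    if events.empty:
        return events.copy()
    t = events["origin_time"].to_numpy(dtype="datetime64[ns]").astype("int64") / 3.6e12
    gaps = np.abs(t[:, None] - t[None, :])
    np.fill_diagonal(gaps, np.inf)
    keep = gaps.min(axis=1) >= isolation_hours
    return events.loc[keep].copy()


def stratified_weekly_sample(events: pd.DataFrame, n: int,
                             period: tuple[pd.Timestamp, pd.Timestamp],
                             seed: int = 0) -> pd.DataFrame:
    """Stratified-random subset of size ``n`` with >= 1 event per non-empty week.

    Weeks are consecutive 7-day strata anchored at the period start. One
    event is drawn uniformly from each non-empty stratum, then the quota is
    filled by uniform sampling without replacement from the remainder.
    """
    if n > len(events):
        raise ValueError(f"requested n={n} exceeds the {len(events)} available events")
    t0 = pd.Timestamp(period[0])
    week = ((events["origin_time"] - t0).dt.total_seconds() // (7 * 86400)).astype(int)
    n_nonempty = week.nunique()
    if n < n_nonempty:
        raise ValueError(f"n={n} cannot cover all {n_nonempty} non-empty weeks")
    rng = np.random.default_rng(seed)
    chosen: list = []
    for _, idx in sorted(events.groupby(week).groups.items()):
        chosen.append(rng.choice(np.asarray(idx)))
    remaining = events.index.difference(chosen)
    extra = n - len(chosen)
    if extra > 0:
        chosen.extend(rng.choice(np.asarray(remaining), size=extra, replace=False))
    picked = events.loc[sorted(chosen, key=list(events.index).index)]
    return picked.sort_values("origin_time").copy()


def epicentre_distance_km(station, event) -> float:
    """Great-circle (haversine) distance, station to epicentre, in km.

    Spherical Earth of radius 6371.0088 km; at regional scales the
    difference from an ellipsoidal geodesic (< 0.5%) is immaterial here.
    Accepts any two objects with ``lat``/``lon`` attributes or mappings.
    """
    def _coords(obj):
        try:
            return float(obj["lat"]), float(obj["lon"])
        except (TypeError, KeyError, IndexError):
            return float(obj.lat), float(obj.lon)

    lat1, lon1 = _coords(station)
    lat2, lon2 = _coords(event)
    for lat, lon in ((lat1, lon1), (lat2, lon2)):
        if not (-90.0 <= lat <= 90.0) or not (-180.0 <= lon <= 180.0):
            raise ValueError(f"invalid coordinates ({lat}, {lon})")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlmb = np.radians(lon2 - lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlmb / 2) ** 2
    return float(2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a)))


def read_catalog_csv(path) -> pd.DataFrame:
    cat = pd.read_csv(path, parse_dates=["origin_time"])
    missing = set(CATALOG_COLUMNS) - set(cat.columns)
    if missing:
        raise ValueError(f"catalog CSV missing columns: {sorted(missing)}")
    return cat


def write_catalog_csv(events: pd.DataFrame, path) -> None:
    out = events.copy()
    out["origin_time"] = out["origin_time"].dt.strftime("%Y-%m-%dT%H:%M:%S.%f%z")
    out.to_csv(path, index=False)


def read_stations_csv(path) -> pd.DataFrame:
    st = pd.read_csv(path, parse_dates=["deploy_start", "deploy_end"])
    bad = st["deploy_start"] >= st["deploy_end"]
    if bad.any():
        raise ValueError("station deploy_start must precede deploy_end")
    return st
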