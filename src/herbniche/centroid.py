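"""Suitable-range centroids and range-shift (migration) distances.

A suitability raster is binarised at a probability threshold into the
"total suitable region"; its area-weighted centre of gravity is tracked
across climate scenarios, with great-circle (haversine) distances on a
spherical Earth of radius 6371.0 km.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptyDomainError
from .geodata import EARTH_RADIUS_KM, RasterGrid, cell_area_grid


@dataclass
class Centroid:
    lon: float
    lat: float
    scenario: str = ""
    threshold_used: float | None = None


def binarize(suitability: RasterGrid, threshold: float = 0.04) -> np.ndarray:
    """Boolean suitable-range mask: p >= threshold on valid cells."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    return suitability.mask & (suitability.values >= threshold)


def centroid_of_mask(
    mask: np.ndarray, grid: RasterGrid, scenario: str = "", threshold: float | None = None
) -> Centroid:
    """Area-weighted centroid of the masked cells (cos-latitude weighting)."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != grid.values.shape:
        raise ValueError("mask shape does not match grid")
    if not mask.any():
        raise EmptyDomainError("empty suitable range: no cells above threshold")
    w = cell_area_grid(grid)[mask]
    rows, cols = np.nonzero(mask)
    lon = float(np.average(grid.lon_centers()[cols], weights=w))
    lat = float(np.average(grid.lat_centers()[rows], weights=w))
    return Centroid(lon=lon, lat=lat, scenario=scenario, threshold_used=threshold)


def range_centroid(
    suitability: RasterGrid, threshold: float = 0.04, scenario: str = ""
) -> Centroid:
    return centroid_of_mask(
        binarize(suitability, threshold), suitability, scenario=scenario, threshold=threshold
    )


def haversine_km(a, b) -> float:
    """Great-circle distance in km between (lon, lat) points, R = 6371.0 km."""
    lon1, lat1 = np.radians(np.asarray(a, dtype=float))
    lon2, lat2 = np.radians(np.asarray(b, dtype=float))
    h = (
        np.sin((lat2 - lat1) / 2) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2
    )
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0))))


def initial_bearing_deg(a, b) -> float:
    """Initial great-circle azimuth from a to b, degrees clockwise from north."""
    lon1, lat1 = np.radians(np.asarray(a, dtype=float))
    lon2, lat2 = np.radians(np.asarray(b, dtype=float))
    dlon = lon2 - lon1
    x = np.sin(dlon) * np.cos(lat2)
    y = np.cos(lat1) * np.sin(lat2) - np.sin(lat1) * np.cos(lat2) * np.cos(dlon)
    return float(np.degrees(np.arctan2(x, y)) % 360.0)


def migration_table(baseline: Centroid, scenarios: list[Centroid]) -> pd.DataFrame:
    """Per-scenario centroid coordinates, distance from the baseline
    centroid (not chained between periods), and initial bearing.

    A scenario coincident with the baseline gets distance 0 and an
    undefined (NaN) bearing.
    """
    rows = []
    a = (baseline.lon, baseline.lat)
    for c in scenarios:
        b = (c.lon, c.lat)
        d = haversine_km(a, b)
        rows.append(
            {
                "scenario": c.scenario,
                "lon": c.lon,
                "lat": c.lat,
                "distance_km": d,
                "bearing_deg": initial_bearing_deg(a, b) if d > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=["scenario", "lon", "lat", "distance_km", "bearing_deg"])
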