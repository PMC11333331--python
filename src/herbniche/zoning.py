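"""Suitability zoning: natural-breaks classification, class areas, and
scenario change statistics.

The pipeline default classifies suitability with the fixed grade edges
0.2 / 0.4 / 0.6 (no / low / medium / high); an optimal Fisher–Jenks
natural-breaks mode is available for data-driven grading.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geodata import RasterGrid, cell_area_grid

DEFAULT_BREAKS = (0.2, 0.4, 0.6)
CLASS_LABELS = {0: "no", 1: "low", 2: "medium", 3: "high"}


def jenks_breaks(values, k: int) -> list[float]:
    """Optimal 1-D classification into k classes (Fisher–Jenks).

    Minimises the total within-class sum of squared deviations by dynamic
    programming over the sorted values.  Returns the k−1 break values,
    each the smallest member of the upper class, so classification with
    left-closed/right-open intervals reproduces the optimal partition.
    """
    x = np.sort(np.asarray(values, dtype=float).ravel())
    if k < 2:
        raise ValueError("k must be >= 2")
    distinct = np.unique(x)
    if len(distinct) < k:
        raise ValueError(f"need at least {k} distinct values, got {len(distinct)}")
    n = len(x)
    # prefix sums for O(1) within-class SSD of x[i:j]
    c1 = np.concatenate([[0.0], np.cumsum(x)])
    c2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def ssd(i: int, j: int) -> float:  # cost of segment x[i:j], j exclusive
        m = j - i
        s = c1[j] - c1[i]
        return (c2[j] - c2[i]) - s * s / m

    INF = np.inf
    # cost[c][j]: best cost of splitting x[:j] into c+1 classes
    prev = np.array([INF] + [ssd(0, j) for j in range(1, n + 1)])
    split = np.zeros((k, n + 1), dtype=int)
    for c in range(1, k):
        cur = np.full(n + 1, INF)
        for j in range(c + 1, n + 1):
            best, arg = INF, -1
            for i in range(c, j):
                v = prev[i] + ssd(i, j)
                if v < best:
                    best, arg = v, i
            cur[j] = best
            split[c, j] = arg
        prev = cur
    breaks_idx = []
    j = n
    for c in range(k - 1, 0, -1):
        i = split[c, j]
        breaks_idx.append(i)
        j = i
    breaks_idx.reverse()
    return [float(x[i]) for i in breaks_idx]


@dataclass
class SuitabilityClassMap:
    class_grid: RasterGrid     # integer codes, nodata preserved
    breaks: tuple[float, ...]
    areas_km2: dict[int, float]

    @property
    def labels(self) -> dict[int, str]:
        return {c: CLASS_LABELS.get(c, str(c)) for c in sorted(self.areas_km2)}


def classify(
    suitability: RasterGrid, breaks=DEFAULT_BREAKS
) -> SuitabilityClassMap:
    """Grade a [0, 1] suitability raster into len(breaks)+1 classes.

    Intervals are left-closed/right-open except the last, which includes 1,
    so a value exactly on a break belongs to the upper class (p = 0.2 is
    "low").  Nodata cells stay nodata.
    """
    breaks = tuple(sorted(float(b) for b in breaks))
    m = suitability.mask
    vals = suitability.values[m]
    if len(vals) and (vals.min() < 0 or vals.max() > 1):
        raise ValueError("suitability values must lie in [0, 1]")
    codes = np.searchsorted(np.asarray(breaks), suitability.values, side="right")
    out = np.where(m, codes.astype(float), suitability.nodata)
    class_grid = suitability.copy_with(out, name=f"{suitability.name}_class")
    return SuitabilityClassMap(
        class_grid=class_grid,
        breaks=breaks,
        areas_km2=class_areas(class_grid, n_classes=len(breaks) + 1),
    )


def class_areas(class_grid: RasterGrid, n_classes: int | None = None) -> dict[int, float]:
    """Latitude-corrected area (km²) per class code."""
    areas = cell_area_grid(class_grid)
    m = class_grid.mask
    codes = class_grid.values[m].astype(int)
    cell_a = areas[m]
    present = sorted(set(codes.tolist()))
    all_codes = range(n_classes) if n_classes else present
    return {c: float(cell_a[codes == c].sum()) for c in all_codes}


def change_statistics(
    baseline: dict[int, float], scenario: dict[int, float]
) -> dict[int, float | None]:
    """Percent area change per class; undefined (None) where baseline is 0."""
    out: dict[int, float | None] = {}
    for c in baseline:
        base = baseline[c]
        scen = scenario.get(c, 0.0)
        out[c] = None if base == 0 else round((scen - base) / base * 100.0, 2)
    return out


def areas_table(named_areas: dict[str, dict[int, float]]) -> pd.DataFrame:
    """Scenario × class area table (km²) for reporting."""
    df = pd.DataFrame(named_areas).T
    df.columns = [CLASS_LABELS.get(c, str(c)) for c in df.columns]
    return df
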