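"""Two-epoch EQI change: differencing, significance classes, area tables.

Change between epochs is the per-pixel difference dEQI = EQI(year2) -
EQI(year1), classified into three significance levels at fixed thresholds
(default +/-0.05, from the regional ecological-quality evaluation standard):

    dEQI <= -0.05          -> significantly decreased
    -0.05 < dEQI <= 0.05   -> no significant change
    dEQI > 0.05            -> significantly increased

Area summaries report, for every zone, ecosystem type and (zone, type)
stratum, each class's share both of the total valid study area and within
the group — the two denominators published change figures alternate
between.  The same tabulation applied to a level grid yields the
level-proportion tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import Grid, assert_aligned
from .stratification import MASK_CODE, StratumMap

__all__ = [
    "CHANGE_NAMES",
    "ChangeResult",
    "delta_eqi",
    "classify_change",
    "summarize",
]

#: change-class codes
DECREASED, NO_CHANGE, INCREASED = 1, 2, 3
CHANGE_NAMES = {DECREASED: "decreased", NO_CHANGE: "no-change", INCREASED: "increased"}
CHANGE_NODATA = 255


def delta_eqi(eqi1: Grid, eqi2: Grid) -> Grid:
    """Per-pixel EQI difference year2 - year1; nodata if either is nodata."""
    if not assert_aligned([eqi1, eqi2]):
        raise ValueError("epoch EQI grids are not aligned")
    valid = eqi1.valid_mask() & eqi2.valid_mask()
    out = np.where(valid, eqi2.values - eqi1.values, eqi1.nodata)
    return eqi1.with_values(out)


def classify_change(delta: Grid, thresholds: tuple[float, float] = (-0.05, 0.05)) -> Grid:
    """Three-level significance classification of a dEQI grid.

    Boundary membership follows the published convention: the lower
    threshold belongs to "decreased", the upper to "no-change".
    """
    lower, upper = thresholds
    if not lower < upper:
        raise ValueError(f"thresholds must satisfy lower < upper, got {thresholds}")
    valid = delta.valid_mask()
    cls = np.full(delta.shape, NO_CHANGE, dtype=np.uint8)
    cls[delta.values <= lower] = DECREASED
    cls[delta.values > upper] = INCREASED
    out = np.where(valid, cls, CHANGE_NODATA).astype(np.uint8)
    return Grid(values=out, transform=delta.transform, crs=delta.crs, nodata=CHANGE_NODATA)


def _cell_weights(grid: Grid, weighting: str) -> np.ndarray:
    if weighting == "pixel-count":
        return np.ones(grid.shape)
    if weighting == "cell-area":
        # cosine-of-latitude rule for geographic-CRS rasters: cell area is
        # proportional to cos(latitude of the cell-row center)
        rows = np.arange(grid.shape[0])
        _, lat = grid.transform.cell_center(rows, 0)
        w = np.cos(np.deg2rad(np.asarray(lat, dtype=np.float64)))
        return np.repeat(np.clip(w, 0.0, None)[:, None], grid.shape[1], axis=1)
    raise ValueError(f"unknown area weighting {weighting!r}")


def summarize(classes: Grid, strata: StratumMap, class_names: dict[int, str] | None = None,
              weighting: str = "pixel-count") -> dict[str, pd.DataFrame]:
    """Class-share tables over the study area, zones, types and strata.

    Returns four DataFrames keyed ``"total"``, ``"zone"``, ``"type"`` and
    ``"stratum"``.  Each row carries the class pixel count (or area weight),
    its percentage of the total valid study area (``percent_of_total``) and
    its percentage within the row's group (``percent_within``); within each
    group the latter sums to 100.
    """
    if not assert_aligned([classes, strata.codes]):
        raise ValueError("class grid and stratum map are not aligned")
    class_names = class_names or CHANGE_NAMES

    valid = classes.valid_mask() & (strata.codes.values != MASK_CODE)
    w = _cell_weights(classes, weighting)

    df = pd.DataFrame({
        "code": strata.codes.values[valid].astype(np.int64),
        "cls": classes.values[valid].astype(np.int64),
        "weight": w[valid],
    }).merge(strata.legend, on="code")
    total_w = df["weight"].sum()

    def table(group_cols: list[str]) -> pd.DataFrame:
        g = df.groupby(group_cols + ["cls"], as_index=False)["weight"].sum()
        g["percent_of_total"] = 100.0 * g["weight"] / total_w
        if group_cols:
            within = g.groupby(group_cols)["weight"].transform("sum")
        else:
            within = total_w
        g["percent_within"] = 100.0 * g["weight"] / within
        g["class"] = g["cls"].map(lambda c: class_names.get(c, str(c)))
        cols = group_cols + ["class", "weight", "percent_of_total", "percent_within"]
        return g.rename(columns={"weight": "pixel_count"})[
            [c if c != "weight" else "pixel_count" for c in cols]]

    return {
        "total": table([]),
        "zone": table(["zone"]),
        "type": table(["ecosystem_type"]),
        "stratum": table(["zone", "ecosystem_type"]),
    }


@dataclass
class ChangeResult:
    """dEQI grid, significance grid and the per-group share tables."""

    delta: Grid
    sig: Grid
    thresholds: tuple[float, float]
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)

    def export_tables(self, directory, prefix: str = "change") -> None:
        from pathlib import Path
        directory = Path(directory)
        for key, tab in self.tables.items():
            tab.to_csv(directory / f"{prefix}_{key}.csv", index=False)
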