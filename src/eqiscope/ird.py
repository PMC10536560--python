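"""Indicator relative density (IRD) and z-score standardization.

The IRD scales each indicator pixel by a reference value taken from its own
stratum: IRD = F / Fmax, where Fmax is the stratum maximum of the indicator
for that year (or, optionally, an upper percentile as an outlier guard).
With the max reference, IRD lies in [0, 1] for nonnegative indicators and
each stratum attains 1 at its reference pixel.

IRDs from different indicators live on different scales, so each IRD field
is standardized to zero mean and unit standard deviation with the z-score
transform Z = (x - mean) / sigma before weighting.  Sigma is the population
(divide-by-n) standard deviation.  Stored standardization parameters can be
re-applied to another year, which keeps two epochs on one scale for change
analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import Grid, assert_aligned
from .stratification import MASK_CODE, StratumMap

__all__ = [
    "ReferenceTable",
    "StandardizationParams",
    "compute_reference",
    "compute_ird",
    "standardize",
]


@dataclass
class ReferenceTable:
    """Per-stratum reference values Fmax for one indicator-year.

    ``values`` maps stratum code -> reference value; ``method`` records how
    the reference was computed (``"max"`` or ``"percentile"`` with ``q``).
    """

    indicator: str
    year: int
    values: dict[int, float]
    method: str = "max"
    q: float | None = None

    def to_frame(self, legend: pd.DataFrame | None = None) -> pd.DataFrame:
        df = pd.DataFrame({
            "indicator": self.indicator,
            "year": self.year,
            "code": list(self.values),
            "reference": list(self.values.values()),
            "method": self.method if self.q is None else f"{self.method} q={self.q}",
        })
        if legend is not None:
            df = df.merge(legend, on="code", how="left")
        return df

    def to_csv(self, path: str | Path, legend: pd.DataFrame | None = None) -> None:
        self.to_frame(legend).to_csv(path, index=False)


@dataclass
class StandardizationParams:
    """Mean and population standard deviation of one IRD field."""

    mean: float
    std: float
    population: str = "all-valid-pixels"
    indicator: str = ""
    year: int | None = None

    def to_dict(self) -> dict:
        return {"mean": self.mean, "std": self.std, "population": self.population,
                "indicator": self.indicator, "year": self.year}

    @classmethod
    def from_dict(cls, d: dict) -> "StandardizationParams":
        return cls(**d)

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def compute_reference(indicator: Grid, strata: StratumMap, method: str = "max",
                      q: float = 0.99, indicator_name: str = "", year: int = 0) -> ReferenceTable:
    """Per-stratum reference value of an indicator.

    ``method="max"`` (the default) takes the stratum maximum; ``"percentile"``
    takes the q-th upper quantile of the stratum's valid pixels, guarding the
    reference against single-pixel outliers.  A nonpositive reference is an
    error: the relative density is undefined for it.
    """
    if method not in {"max", "percentile"}:
        raise ValueError(f"unknown reference method {method!r}")
    if not assert_aligned([indicator, strata.codes]):
        raise ValueError("indicator and stratum map are not aligned")

    codes = strata.codes.values
    valid = indicator.valid_mask() & (codes != MASK_CODE)
    refs: dict[int, float] = {}
    empty: list[int] = []
    for code in strata.stratum_codes:
        vals = indicator.values[valid & (codes == code)]
        if vals.size == 0:
            empty.append(int(code))
            continue
        refs[int(code)] = float(np.max(vals) if method == "max" else np.quantile(vals, q))
    if empty:
        raise ValueError(f"strata with no valid pixels for {indicator_name or 'indicator'}: {empty}")
    bad = [c for c, r in refs.items() if r <= 0]
    if bad:
        raise ValueError(
            f"nonpositive reference for {indicator_name or 'indicator'} in strata {bad}: "
            "relative density is undefined")
    return ReferenceTable(indicator=indicator_name, year=year, values=refs, method=method,
                          q=q if method == "percentile" else None)


def compute_ird(indicator: Grid, strata: StratumMap, refs: ReferenceTable) -> Grid:
    """Indicator relative density: per-pixel F / Fmax within each stratum."""
    if not assert_aligned([indicator, strata.codes]):
        raise ValueError("indicator and stratum map are not aligned")
    codes = strata.codes.values
    present = set(np.unique(codes[codes != MASK_CODE]).tolist())
    missing = sorted(present - set(refs.values))
    if missing:
        raise ValueError(f"no reference value for strata {missing}")

    ref_grid = np.zeros(indicator.shape)
    for code, r in refs.values.items():
        ref_grid[codes == code] = r

    valid = indicator.valid_mask() & (codes != MASK_CODE)
    out = np.full(indicator.shape, indicator.nodata, dtype=np.float64)
    out[valid] = indicator.values[valid] / ref_grid[valid]
    return indicator.with_values(out)


def standardize(ird: Grid, params: StandardizationParams | None = None) -> tuple[Grid, StandardizationParams]:
    """Z-score an IRD grid; returns the standardized grid and the params used.

    When ``params`` is None the mean and population standard deviation are
    estimated from all valid pixels of the grid (the standardization
    population); otherwise the supplied parameters are applied unchanged —
    this is how a baseline year's scale is imposed on a later year.
    """
    valid = ird.valid_mask()
    x = ird.values[valid]
    if params is None:
        if x.size < 2:
            raise ValueError("standardization needs at least 2 valid pixels")
        mean = float(np.mean(x))
        std = float(np.std(x))  # population sigma (ddof=0)
        if std == 0.0:
            raise ValueError("zero variance: cannot standardize a constant field")
        params = StandardizationParams(mean=mean, std=std)
    elif params.std <= 0:
        raise ValueError("supplied standardization sigma must be positive")

    out = np.full(ird.shape, ird.nodata, dtype=np.float64)
    out[valid] = (x - params.mean) / params.std
    return ird.with_values(out), params


def standardize_per_stratum(ird: Grid, strata: StratumMap,
                            params: dict[int, StandardizationParams] | None = None,
                            ) -> tuple[Grid, dict[int, StandardizationParams]]:
    """Z-score each stratum against its own mean and sigma.

    Alternative pooling to the default study-area-wide standardization:
    every stratum is centered and scaled separately, which removes
    between-stratum level differences from the index.
    """
    codes = strata.codes.values
    out = np.full(ird.shape, ird.nodata, dtype=np.float64)
    used: dict[int, StandardizationParams] = {}
    for code in strata.stratum_codes:
        sel = (codes == code) & ird.valid_mask()
        sub = ird.with_values(np.where(sel, ird.values, ird.nodata))
        try:
            z, p = standardize(sub, None if params is None else params[int(code)])
        except ValueError as exc:
            raise ValueError(f"stratum {int(code)}: {exc}") from exc
        out[sel] = z.values[sel]
        used[int(code)] = p
    return ird.with_values(out), used
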