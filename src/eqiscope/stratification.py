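"""Strata construction: (eco-geographical zone x vegetation ecosystem type).

Reference populations for indicator relative densities are the strata formed
by joining an eco-geographical-zone map with a vegetation ecosystem-type map.
The ecosystem-type map comes from reclassifying a first-level land-use/
land-cover (LULC) product into six vegetation types — cultivated land,
forest, grassland, shrub, wetland, tundra — plus a non-vegetation mask.
Stratum code 0 is reserved for masked (non-vegetation / nodata) pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .grid import Grid, assert_aligned

__all__ = [
    "VEGETATION_TYPES",
    "NON_VEGETATION",
    "MASK_CODE",
    "EcosystemTypeScheme",
    "StratumMap",
    "reclassify_lulc",
    "build_strata",
]

VEGETATION_TYPES = ("cultivated land", "forest", "grassland", "shrub", "wetland", "tundra")
NON_VEGETATION = "non-vegetation"
MASK_CODE = 0

#: ecosystem-type codes used in reclassified grids (1-based, mask = 0)
TYPE_CODES = {name: i + 1 for i, name in enumerate(VEGETATION_TYPES)}


@dataclass
class EcosystemTypeScheme:
    """Total mapping from first-level LULC class codes to ecosystem types."""

    mapping: dict[int, str]

    def __post_init__(self) -> None:
        allowed = set(VEGETATION_TYPES) | {NON_VEGETATION}
        bad = {t for t in self.mapping.values() if t not in allowed}
        if bad:
            raise ValueError(f"unknown ecosystem types in scheme: {sorted(bad)}; "
                             f"allowed: {sorted(allowed)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "EcosystemTypeScheme":
        raw = yaml.safe_load(Path(path).read_text())
        return cls({int(k): str(v) for k, v in raw.items()})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump({int(k): v for k, v in self.mapping.items()}))


@dataclass
class StratumMap:
    """Integer-coded partition of the analysis grid into strata.

    ``codes.values`` holds stratum identifiers (0 = masked); ``legend`` maps
    each nonzero identifier to its (zone, ecosystem-type) pair.
    """

    codes: Grid
    legend: pd.DataFrame  # columns: code, zone, ecosystem_type
    zone_labels: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        present = set(np.unique(self.codes.values)) - {MASK_CODE}
        listed = set(self.legend["code"])
        if present - listed:
            raise ValueError(f"stratum codes missing from legend: {sorted(present - listed)}")
        pairs = list(zip(self.legend["zone"], self.legend["ecosystem_type"]))
        if len(pairs) != len(set(pairs)):
            raise ValueError("legend (zone, type) pairs must be unique")

    @property
    def stratum_codes(self) -> np.ndarray:
        """Sorted nonzero codes present in the legend."""
        return np.sort(self.legend["code"].to_numpy())

    def export_legend(self, path: str | Path) -> None:
        self.legend.to_csv(path, index=False)


def reclassify_lulc(lulc: Grid, scheme: EcosystemTypeScheme) -> Grid:
    """Reclassify first-level LULC codes into ecosystem-type codes.

    Non-vegetation classes and nodata pixels map to the mask code 0.
    Unmapped codes are an error (the scheme must be total over the input).
    """
    valid = lulc.valid_mask()
    codes = lulc.values.astype(np.int64, copy=False)
    present = np.unique(codes[valid])
    unmapped = sorted(set(present.tolist()) - set(scheme.mapping))
    if unmapped:
        raise ValueError(f"LULC codes without an ecosystem-type mapping: {unmapped}")

    lut_size = int(present.max()) + 1 if present.size else 1
    lut = np.full(lut_size, MASK_CODE, dtype=np.uint8)
    for code, name in scheme.mapping.items():
        if 0 <= code < lut_size:
            lut[code] = TYPE_CODES.get(name, MASK_CODE)
    out = np.zeros(lulc.shape, dtype=np.uint8)
    out[valid] = lut[codes[valid]]
    return Grid(values=out, transform=lulc.transform, crs=lulc.crs, nodata=MASK_CODE)


def build_strata(zones: Grid, ecotypes: Grid,
                 zone_labels: dict[int, str] | None = None) -> StratumMap:
    """Join a zone map with an ecosystem-type map into a stratum map.

    A pixel gets a stratum only if it has both a valid zone and a vegetation
    ecosystem type; everything else is masked (code 0).  The legend
    enumerates only (zone, type) pairs that actually co-occur, coded 1..S in
    (zone, type) sort order.
    """
    if not assert_aligned([zones, ecotypes]):
        raise ValueError("zone and ecosystem-type grids are not aligned on one geometry")

    z = zones.values.astype(np.int64, copy=False)
    t = ecotypes.values.astype(np.int64, copy=False)
    ok = zones.valid_mask() & (t != MASK_CODE)

    pairs = np.stack([z[ok], t[ok]], axis=1)
    uniq, inverse = np.unique(pairs, axis=0, return_inverse=True)

    codes = np.zeros(zones.shape, dtype=np.int32)
    codes[ok] = inverse + 1

    labels = zone_labels or {}
    type_names = {v: k for k, v in TYPE_CODES.items()}
    legend = pd.DataFrame({
        "code": np.arange(1, len(uniq) + 1, dtype=np.int32),
        "zone": [labels.get(int(zj), str(int(zj))) for zj, _ in uniq],
        "ecosystem_type": [type_names[int(tk)] for _, tk in uniq],
    })
    code_grid = Grid(values=codes, transform=zones.transform, crs=zones.crs, nodata=MASK_CODE)
    return StratumMap(codes=code_grid, legend=legend, zone_labels=labels)
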