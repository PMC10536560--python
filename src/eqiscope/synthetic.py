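"""Synthetic two-epoch scenarios for end-to-end testing without downloads.

The generator emulates the statistical structure the assessment assumes:
three positively co-varying vegetation indicators (LAI-, FVC- and GPP-like,
on their physical scales) over contiguous eco-geographical zones and
land-cover patches, with sub-annual series whose maximum value composite
recovers a known annual field, nodata regions, and a second epoch identical
to the first outside planted change regions.

Construction, per pixel: a Gaussian copula with a target inter-indicator
correlation matrix (plus an optional per-stratum common shift that creates
between-stratum contrast) yields three coupled quantiles, mapped linearly
onto each indicator's physical range.  Zones and land-cover patches are
Voronoi cells of seeded random points, so strata have contiguous spatial
support.  Planted change regions perturb year-2 values toward (increase) or
away from (decrease) the stratum reference, with each stratum's year-1
reference pixel held fixed so the per-year reference value — and hence the
sign of the planted EQI change — is stable by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.special import ndtr

from .grid import Grid, GridStack, GridTransform
from .stratification import (EcosystemTypeScheme, StratumMap, build_strata,
                             reclassify_lulc, MASK_CODE)

__all__ = ["ChangeRegion", "ScenarioConfig", "Scenario", "generate_scenario"]

#: physical value ranges of the emulated indicators
INDICATOR_RANGES = {"lai": (0.0, 7.0), "fvc": (0.0, 1.0), "gpp": (0.0, 3000.0)}

#: first-level land-cover codes used by the default synthetic scheme
DEFAULT_SCHEME = EcosystemTypeScheme({
    10: "cultivated land", 20: "forest", 30: "grassland", 40: "shrub",
    50: "wetland", 60: "tundra", 70: "non-vegetation",
})


@dataclass(frozen=True)
class ChangeRegion:
    """Rectangular planted-change region with a signed EQI offset scale.

    ``eqi_offset`` > 0 pulls year-2 indicator values toward the stratum
    reference (quality increase); < 0 scales them down (quality decrease).
    The perturbation strength is 1 - exp(-|offset|) of the available range.
    """

    row0: int
    row1: int
    col0: int
    col1: int
    eqi_offset: float

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.row0:self.row1, self.col0:self.col1] = True
        return m


@dataclass
class ScenarioConfig:
    """Study conditions for one synthetic two-epoch scenario."""

    shape: tuple[int, int] = (200, 200)
    cell_size: float = 1000.0
    origin: tuple[float, float] = (0.0, 0.0)  # top-left corner (x0, y0)
    crs: str = "SYNTH:LOCAL-1KM"
    years: tuple[int, int] = (2016, 2020)
    n_zones: int = 6
    n_patches: int = 30
    #: probability of each first-level land-cover code over patches
    lulc_class_probs: dict[int, float] = field(default_factory=lambda: {
        10: 0.20, 20: 0.22, 30: 0.22, 40: 0.12, 50: 0.06, 60: 0.06, 70: 0.12})
    target_correlation: np.ndarray = field(
        default_factory=lambda: np.array([[1.0, 0.7, 0.7],
                                          [0.7, 1.0, 0.7],
                                          [0.7, 0.7, 1.0]]))
    stratum_effect_sd: float = 0.4
    nodata_fraction: float = 0.02
    n_periods: dict[str, int] = field(default_factory=lambda: {"lai": 4, "fvc": 12, "gpp": 12})
    change_regions: tuple[ChangeRegion, ...] = (
        ChangeRegion(20, 50, 20, 50, +0.5),
        ChangeRegion(130, 160, 130, 160, -0.5),
    )
    seed: int = 0

    def __post_init__(self) -> None:
        R = np.asarray(self.target_correlation, dtype=np.float64)
        if R.shape != (3, 3) or not np.allclose(R, R.T) or not np.allclose(np.diag(R), 1.0):
            raise ValueError("target correlation must be a symmetric 3x3 matrix with unit diagonal")
        if np.linalg.eigvalsh(R).min() <= 0:
            raise ValueError("target correlation matrix must be positive definite")
        self.target_correlation = R

    @property
    def transform(self) -> GridTransform:
        return GridTransform(x0=self.origin[0], y0=self.origin[1],
                             dx=self.cell_size, dy=self.cell_size)


@dataclass
class Scenario:
    """Generated fixture: everything the assessment pipeline consumes.

    ``annual`` holds the ground-truth annual fields whose maximum value
    composite over ``stacks`` is exact by construction.
    """

    config: ScenarioConfig
    zones: Grid
    zone_labels: dict[int, str]
    lulc: dict[int, Grid]                      # year -> first-level LULC grid
    scheme: EcosystemTypeScheme
    stacks: dict[str, dict[int, GridStack]]    # indicator -> year -> sub-annual stack
    annual: dict[str, dict[int, Grid]]         # indicator -> year -> annual truth

    def strata(self, year: int) -> StratumMap:
        eco = reclassify_lulc(self.lulc[year], self.scheme)
        return build_strata(self.zones, eco, self.zone_labels)

    def write(self, directory: str | Path) -> Path:
        """Write grids as ASCII rasters plus a YAML manifest; returns manifest path."""
        from .grid import write_ascii_grid
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_ascii_grid(self.zones, directory / "zones.asc")
        manifest: dict = {
            "crs": self.config.crs, "seed": self.config.seed,
            "years": list(self.config.years),
            "zones": "zones.asc", "zone_labels": {int(k): v for k, v in self.zone_labels.items()},
            "scheme": "scheme.yaml", "lulc": {}, "indicators": {},
        }
        self.scheme.to_yaml(directory / "scheme.yaml")
        for year, g in self.lulc.items():
            name = f"lulc_{year}.asc"
            write_ascii_grid(g, directory / name)
            manifest["lulc"][int(year)] = name
        for ind, by_year in self.stacks.items():
            manifest["indicators"][ind] = {}
            for year, stack in by_year.items():
                entries = []
                for ts, sl in zip(stack.timestamps, stack.slices):
                    name = f"{ind}_{year}_t{ts:02d}.asc"
                    write_ascii_grid(sl, directory / name)
                    entries.append({"path": name, "timestamp": int(ts)})
                manifest["indicators"][ind][int(year)] = entries
        path = directory / "manifest.yaml"
        path.write_text(yaml.safe_dump(manifest, sort_keys=False))
        return path


def _voronoi_labels(shape: tuple[int, int], n: int, rng: np.random.Generator) -> np.ndarray:
    """Label each pixel with its nearest seed point: contiguous patches."""
    rows = rng.uniform(0, shape[0], size=n)
    cols = rng.uniform(0, shape[1], size=n)
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    d2 = (rr[..., None] - rows) ** 2 + (cc[..., None] - cols) ** 2
    return np.argmin(d2, axis=-1)


def _nodata_blobs(shape, fraction: float, rng: np.random.Generator) -> np.ndarray:
    """A few random disks covering roughly ``fraction`` of the grid."""
    mask = np.zeros(shape, dtype=bool)
    if fraction <= 0:
        return mask
    target = fraction * shape[0] * shape[1]
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    while mask.sum() < target:
        r0, c0 = rng.uniform(0, shape[0]), rng.uniform(0, shape[1])
        radius = rng.uniform(2, max(3.0, 0.04 * min(shape)))
        mask |= (rr - r0) ** 2 + (cc - c0) ** 2 <= radius ** 2
    return mask


def _seasonal_stack(annual: Grid, n_periods: int, rng: np.random.Generator,
                    year: int) -> GridStack:
    """Sub-annual slices whose maximum value composite equals ``annual``.

    One peak slice reproduces the annual field exactly; the others are the
    annual field scaled by sub-unit seasonal factors with per-pixel jitter,
    so MVC recovers the annual truth while the series still varies.
    """
    factors = np.sort(rng.uniform(0.3, 0.95, size=n_periods))
    peak = int(rng.integers(0, n_periods))
    slices = []
    valid = annual.valid_mask()
    for t in range(n_periods):
        if t == peak:
            vals = annual.values.copy()
        else:
            jitter = rng.uniform(0.8, 1.0, size=annual.shape)
            vals = np.where(valid, annual.values * factors[t] * jitter, annual.nodata)
        slices.append(annual.with_values(vals))
    return GridStack(slices=slices, timestamps=list(range(n_periods)), year=year)


def generate_scenario(config: ScenarioConfig) -> Scenario:
    """Deterministically generate a full two-epoch scenario from a config."""
    rng = np.random.default_rng(config.seed)
    shape = tuple(config.shape)
    t = config.transform
    nodata = -9999.0

    # --- zone and land-cover geometry: contiguous Voronoi patches
    zone_ids = _voronoi_labels(shape, config.n_zones, rng) + 1
    zones = Grid(values=zone_ids.astype(np.int32), transform=t, crs=config.crs, nodata=0)
    zone_labels = {i + 1: f"zone-{i + 1}" for i in range(config.n_zones)}

    patch = _voronoi_labels(shape, config.n_patches, rng)
    codes = np.array(list(config.lulc_class_probs))
    probs = np.array(list(config.lulc_class_probs.values()), dtype=np.float64)
    patch_codes = rng.choice(codes, size=config.n_patches, p=probs / probs.sum())
    # planted changes are vegetation-quality signals, so any land-cover patch
    # touching a change region must carry a vegetation class
    scheme = DEFAULT_SCHEME
    veg_codes = [c for c in codes if scheme.mapping[int(c)] != "non-vegetation"]
    veg_probs = np.array([config.lulc_class_probs[int(c)] for c in veg_codes])
    region_mask = np.zeros(shape, dtype=bool)
    for region in config.change_regions:
        region_mask |= region.mask(shape)
    for pi in np.unique(patch[region_mask]):
        if scheme.mapping[int(patch_codes[pi])] == "non-vegetation":
            patch_codes[pi] = rng.choice(veg_codes, p=veg_probs / veg_probs.sum())
    lulc_vals = patch_codes[patch].astype(np.int32)
    lulc1 = Grid(values=lulc_vals, transform=t, crs=config.crs, nodata=-1)
    lulc = {config.years[0]: lulc1, config.years[1]: lulc1.with_values(lulc_vals.copy())}

    eco = reclassify_lulc(lulc1, scheme)
    strata = build_strata(zones, eco, zone_labels)
    scodes = strata.codes.values

    # --- year-1 annual indicator fields via a Gaussian copula
    names = list(INDICATOR_RANGES)
    L = np.linalg.cholesky(config.target_correlation)
    npix = shape[0] * shape[1]
    z = rng.standard_normal((npix, 3)) @ L.T
    if config.stratum_effect_sd > 0:
        n_strata = int(scodes.max())
        shift = rng.normal(0, config.stratum_effect_sd, size=n_strata + 1)
        shift[0] = 0.0
        z = z + shift[scodes.ravel()][:, None]
        z = z / np.sqrt(1 + config.stratum_effect_sd ** 2)
    u = ndtr(z).reshape(shape[0], shape[1], 3)

    annual1: dict[str, Grid] = {}
    for idx, name in enumerate(names):
        lo, hi = INDICATOR_RANGES[name]
        vals = lo + (hi - lo) * u[..., idx]
        vals = np.where(scodes == MASK_CODE, vals * 0.05, vals)  # sparse non-vegetation signal
        annual1[name] = Grid(values=vals, transform=t, crs=config.crs, nodata=nodata)

    # --- year-2 fields: identical outside planted regions
    annual2: dict[str, Grid] = {}
    planted = np.zeros(shape, dtype=bool)
    for name in names:
        vals = annual1[name].values.copy()
        # per-stratum reference value and reference pixel (held fixed)
        ref_val = np.zeros(shape)
        ref_pixel = np.zeros(shape, dtype=bool)
        for code in strata.stratum_codes:
            sel = scodes == code
            stratum_vals = np.where(sel, vals, -np.inf)
            flat = int(np.argmax(stratum_vals))
            ref_val[sel] = vals.flat[flat]
            ref_pixel.flat[flat] = True
        for region in config.change_regions:
            lam = 1.0 - np.exp(-abs(region.eqi_offset))
            m = region.mask(shape) & ~ref_pixel
            planted |= m
            if region.eqi_offset > 0:
                vals = np.where(m, vals + lam * np.clip(ref_val - vals, 0, None), vals)
            else:
                vals = np.where(m, vals * (1.0 - lam), vals)
        annual2[name] = annual1[name].with_values(vals)

    # --- nodata holes and sub-annual stacks
    stacks: dict[str, dict[int, GridStack]] = {name: {} for name in names}
    annual: dict[str, dict[int, Grid]] = {name: {} for name in names}
    for name in names:
        for year, src in ((config.years[0], annual1), (config.years[1], annual2)):
            holes = _nodata_blobs(shape, config.nodata_fraction, rng)
            vals = np.where(holes, nodata, src[name].values)
            g = Grid(values=vals, transform=t, crs=config.crs, nodata=nodata)
            annual[name][year] = g
            stacks[name][year] = _seasonal_stack(g, config.n_periods[name], rng, year)

    return Scenario(config=config, zones=zones, zone_labels=zone_labels, lulc=lulc,
                    scheme=scheme, stacks=stacks, annual=annual)
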