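"""Pipeline orchestration: manifest in, full artifact directory out.

The assessment runs as a fixed sequence of stages — compose, stratify, ird,
weights, eqi, classify, change, report — each of which reads its inputs
from and writes its outputs to one artifact directory, so the stages can be
run in one shot (:func:`run_pipeline`) or individually from the CLI with
bit-identical results.  Every intermediate (references, standardization
parameters, weights, PCA audit trail, breaks) is serialized, and a run log
records the resolved configuration, its hash, library versions and the
seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import __version__
from .change import CHANGE_NAMES, ChangeResult, classify_change, delta_eqi, summarize
from .eqi import (FIXED_BREAK_PRESETS, LEVEL_NAMES, EQIResult, classify,
                  compute_eqi, jenks_breaks)
from .grid import (Grid, GridStack, assert_aligned, max_value_composite,
                   read_ascii_grid, resample_to, write_ascii_grid)
from .ird import (StandardizationParams, compute_ird, compute_reference,
                  standardize, standardize_per_stratum)
from .stratification import (EcosystemTypeScheme, MASK_CODE, StratumMap,
                             build_strata, reclassify_lulc)
from .weighting import WeightSet, average_weights, pca_weights

logger = logging.getLogger("eqiscope")

INDICATORS = ("lai", "fvc", "gpp")


class RunConfig(BaseModel):
    """Validated configuration of one assessment run.

    Defaults follow the published method: stratum-maximum references,
    global per-year z-scoring, rho = 0.85, five Jenks classes pooled over
    both epochs, significance thresholds +/-0.05.
    """

    manifest: Path
    output_dir: Path
    reference_method: Literal["max", "percentile"] = "max"
    reference_q: float = Field(0.99, gt=0, le=1)
    standardization: Literal["per-year", "shared-baseline"] = "per-year"
    standardization_population: Literal["global", "per-stratum"] = "global"
    rho: float = Field(0.85, gt=0, le=1)
    weights_in: Optional[dict[str, float]] = None
    loading_scale: Literal["unit", "sqrt_eigenvalue"] = "unit"
    signed_loadings: bool = False
    pca_sample_size: Optional[int] = Field(None, gt=0)
    break_mode: Literal["jenks", "fixed"] = "jenks"
    fixed_breaks: Optional[tuple[float, float, float, float]] = None
    break_preset: Optional[str] = None
    n_classes: int = Field(5, ge=2)
    jenks_sample_size: int = Field(100_000, gt=0)
    jenks_pooled_years: bool = True
    change_thresholds: tuple[float, float] = (-0.05, 0.05)
    area_weighting: Literal["pixel-count", "cell-area"] = "pixel-count"
    seed: int = 0

    @field_validator("change_thresholds")
    @classmethod
    def _ordered(cls, v):
        if not v[0] < v[1]:
            raise ValueError(f"change thresholds must be ordered, got {v}")
        return v

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        cfg = cls(**raw)
        # resolve relative paths against the config file location
        base = Path(path).parent
        if not cfg.manifest.is_absolute():
            cfg.manifest = base / cfg.manifest
        if not cfg.output_dir.is_absolute():
            cfg.output_dir = base / cfg.output_dir
        return cfg

    def resolved_breaks(self) -> Optional[tuple[float, ...]]:
        if self.break_mode != "fixed":
            return None
        if self.break_preset is not None:
            try:
                return FIXED_BREAK_PRESETS[self.break_preset]
            except KeyError:
                raise ValueError(f"unknown break preset {self.break_preset!r}; "
                                 f"known: {sorted(FIXED_BREAK_PRESETS)}")
        if self.fixed_breaks is None:
            raise ValueError("break_mode 'fixed' needs fixed_breaks or break_preset")
        return self.fixed_breaks

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


class Manifest:
    """Parsed scenario manifest: zones, LULC, scheme and indicator stacks."""

    def __init__(self, path: str | Path):
        path = Path(path)
        self.base = path.parent
        raw = yaml.safe_load(path.read_text())
        self.years: tuple[int, int] = tuple(int(y) for y in raw["years"])
        self.zones = read_ascii_grid(self.base / raw["zones"])
        self.zone_labels = {int(k): str(v) for k, v in raw.get("zone_labels", {}).items()}
        self.scheme = EcosystemTypeScheme.from_yaml(self.base / raw["scheme"])
        self.lulc = {int(y): read_ascii_grid(self.base / p) for y, p in raw["lulc"].items()}
        self.stacks: dict[str, dict[int, GridStack]] = {}
        for ind, by_year in raw["indicators"].items():
            self.stacks[ind] = {}
            for year, entries in by_year.items():
                slices = [read_ascii_grid(self.base / e["path"]) for e in entries]
                ts = [int(e["timestamp"]) for e in entries]
                self.stacks[ind][int(year)] = GridStack(slices=slices, timestamps=ts,
                                                        year=int(year))


def _require_aligned(grids: list[Grid], stage: str) -> None:
    if len(grids) >= 2 and not assert_aligned(grids):
        raise RuntimeError(f"stage {stage!r}: input grids are not aligned on the analysis grid")


def apply_complete_case(grids: list[Grid]) -> list[Grid]:
    """Mask every pixel that is nodata in any of the grids (complete-case rule)."""
    valid = np.ones(grids[0].shape, dtype=bool)
    for g in grids:
        valid &= g.valid_mask()
    return [g.with_values(np.where(valid, g.values, g.nodata)) for g in grids]


def restrict_strata(strata: StratumMap, valid: np.ndarray) -> StratumMap:
    """Stratum map limited to observed pixels; unobserved strata drop out.

    Complete-case masking can leave a (small) stratum with no valid pixel at
    all; such a stratum has no reference population and no assessable
    pixels, so it is removed from the legend rather than failing the run.
    """
    codes = np.where(valid, strata.codes.values, MASK_CODE)
    present = np.unique(codes[codes != MASK_CODE])
    legend = strata.legend[strata.legend["code"].isin(present)].reset_index(drop=True)
    grid = Grid(values=codes, transform=strata.codes.transform,
                crs=strata.codes.crs, nodata=MASK_CODE)
    return StratumMap(codes=grid, legend=legend, zone_labels=strata.zone_labels)


# ---------------------------------------------------------------------------
# stages: each reads/writes only the artifact directory

def stage_compose(config: RunConfig) -> None:
    """MVC each indicator-year stack, resample onto the analysis grid."""
    man = Manifest(config.manifest)
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    reference = man.zones  # analysis grid: the zone/LULC (coarsest) geometry
    write_ascii_grid(reference, out / "zones.asc")
    man.scheme.to_yaml(out / "scheme.yaml")
    meta = {"years": list(man.years), "zone_labels": man.zone_labels}
    (out / "compose.json").write_text(json.dumps(meta, indent=2))
    for year in man.years:
        lulc = man.lulc[year]
        if not lulc.same_geometry(reference):
            lulc = resample_to(lulc, reference)
        write_ascii_grid(lulc, out / f"lulc_{year}.asc")
        for ind in INDICATORS:
            annual = max_value_composite(man.stacks[ind][year])
            if not annual.same_geometry(reference):
                annual = resample_to(annual, reference)
            write_ascii_grid(annual, out / f"composite_{ind}_{year}.asc")


def _load_meta(out: Path) -> dict:
    return json.loads((out / "compose.json").read_text())


def _load_strata(out: Path, year: int) -> StratumMap:
    codes = read_ascii_grid(out / f"strata_{year}.asc", dtype=np.int32)
    legend = pd.read_csv(out / f"strata_legend_{year}.csv")
    return StratumMap(codes=codes, legend=legend)


def stage_stratify(config: RunConfig) -> None:
    """Reclassify LULC and join with zones into per-year stratum maps."""
    out = config.output_dir
    meta = _load_meta(out)
    zones = read_ascii_grid(out / "zones.asc", dtype=np.int32)
    labels = {int(k): v for k, v in meta["zone_labels"].items()}
    scheme = EcosystemTypeScheme.from_yaml(out / "scheme.yaml")
    for year in meta["years"]:
        lulc = read_ascii_grid(out / f"lulc_{year}.asc", dtype=np.int32)
        eco = reclassify_lulc(lulc, scheme)
        strata = build_strata(zones, eco, labels)
        write_ascii_grid(strata.codes, out / f"strata_{year}.asc")
        strata.export_legend(out / f"strata_legend_{year}.csv")


def stage_ird(config: RunConfig) -> None:
    """References, indicator relative densities and z-scores per year."""
    out = config.output_dir
    meta = _load_meta(out)
    years = meta["years"]
    params_store: dict = {}
    for year in years:
        strata = _load_strata(out, year)
        composites = [read_ascii_grid(out / f"composite_{ind}_{year}.asc") for ind in INDICATORS]
        _require_aligned(composites + [strata.codes], "ird")
        composites = apply_complete_case(composites)
        strata = restrict_strata(strata, composites[0].valid_mask())
        for ind, grid in zip(INDICATORS, composites):
            refs = compute_reference(grid, strata, method=config.reference_method,
                                     q=config.reference_q, indicator_name=ind, year=year)
            refs.to_csv(out / f"reference_{ind}_{year}.csv", legend=strata.legend)
            ird = compute_ird(grid, strata, refs)
            write_ascii_grid(ird, out / f"ird_{ind}_{year}.asc")
            reuse = config.standardization == "shared-baseline" and year != years[0]
            if config.standardization_population == "per-stratum":
                z, params = standardize_per_stratum(
                    ird, strata, params_store[ind] if reuse else None)
                payload = {str(c): p.to_dict() for c, p in params.items()}
            else:
                z, params = standardize(ird, params_store[ind] if reuse else None)
                params.indicator, params.year = ind, year
                payload = params.to_dict()
            if not reuse:
                params_store[ind] = params
            (out / f"zparams_{ind}_{year}.json").write_text(json.dumps(payload, indent=2))
            write_ascii_grid(z, out / f"z_{ind}_{year}.asc")


def _year_observations(out: Path, year: int, sample_size: Optional[int],
                       seed: int) -> np.ndarray:
    z_grids = [read_ascii_grid(out / f"z_{ind}_{year}.asc") for ind in INDICATORS]
    valid = np.ones(z_grids[0].shape, dtype=bool)
    for g in z_grids:
        valid &= g.valid_mask()
    X = np.stack([g.values[valid] for g in z_grids], axis=1)
    if sample_size is not None and X.shape[0] > sample_size:
        rng = np.random.default_rng(seed)
        X = X[rng.choice(X.shape[0], size=sample_size, replace=False)]
    return X


def stage_weights(config: RunConfig) -> WeightSet:
    """Per-year PCA weights and their cross-year arithmetic mean."""
    out = config.output_dir
    meta = _load_meta(out)
    if config.weights_in is not None:
        names = tuple(config.weights_in)
        ws = WeightSet(names=names, weights=np.array(list(config.weights_in.values())),
                       provenance={"method": "user-supplied"})
        ws.dump(out / "weights.json")
        return ws
    per_year = []
    for year in meta["years"]:
        X = _year_observations(out, year, config.pca_sample_size, config.seed)
        ws, pca = pca_weights(X, rho=config.rho, names=INDICATORS,
                              loading_scale=config.loading_scale,
                              signed=config.signed_loadings)
        ws.provenance["year"] = year
        ws.dump(out / f"weights_{year}.json")
        (out / f"pca_{year}.json").write_text(json.dumps(pca.to_dict(), indent=2))
        per_year.append(ws)
    final = average_weights(per_year)
    final.dump(out / "weights.json")
    return final


def stage_eqi(config: RunConfig) -> None:
    """Weighted sum of the standardized IRDs per year."""
    out = config.output_dir
    meta = _load_meta(out)
    weights = WeightSet.load(out / "weights.json")
    for year in meta["years"]:
        z_grids = [read_ascii_grid(out / f"z_{ind}_{year}.asc") for ind in INDICATORS]
        eqi = compute_eqi(z_grids, weights)
        write_ascii_grid(eqi, out / f"eqi_{year}.asc")


def stage_classify(config: RunConfig) -> None:
    """Break estimation (Jenks or fixed) and five-level classification."""
    out = config.output_dir
    meta = _load_meta(out)
    eqi_grids = {year: read_ascii_grid(out / f"eqi_{year}.asc") for year in meta["years"]}
    fixed = config.resolved_breaks()
    if fixed is not None:
        breaks, source = tuple(fixed), "fixed"
    else:
        if config.jenks_pooled_years:
            values = np.concatenate([g.valid_values() for g in eqi_grids.values()])
        else:
            values = eqi_grids[meta["years"][0]].valid_values()
        breaks = jenks_breaks(values, config.n_classes,
                              sample_size=config.jenks_sample_size, seed=config.seed)
        source = "jenks"
    for year, g in eqi_grids.items():
        levels = classify(g, breaks)
        write_ascii_grid(levels, out / f"levels_{year}.asc")
        result = EQIResult(eqi=g, breaks=tuple(breaks), levels=levels, break_source=source)
        result.dump_breaks(out / f"breaks_{year}.json")
        strata = _load_strata(out, year)
        tables = summarize(levels, strata, class_names=LEVEL_NAMES,
                           weighting=config.area_weighting)
        for key, tab in tables.items():
            tab.to_csv(out / f"levels_{year}_{key}.csv", index=False)
    (out / "breaks.json").write_text(json.dumps(
        {"breaks": list(breaks), "break_source": source,
         "pooled_years": config.jenks_pooled_years}, indent=2))


def stage_change(config: RunConfig) -> ChangeResult:
    """Two-epoch differencing, significance classes and area tables."""
    out = config.output_dir
    meta = _load_meta(out)
    y1, y2 = meta["years"]
    eqi1 = read_ascii_grid(out / f"eqi_{y1}.asc")
    eqi2 = read_ascii_grid(out / f"eqi_{y2}.asc")
    delta = delta_eqi(eqi1, eqi2)
    write_ascii_grid(delta, out / "delta_eqi.asc")
    sig = classify_change(delta, config.change_thresholds)
    write_ascii_grid(sig, out / "change_classes.asc")
    strata = _load_strata(out, y1)
    tables = summarize(sig, strata, class_names=CHANGE_NAMES, weighting=config.area_weighting)
    result = ChangeResult(delta=delta, sig=sig, thresholds=config.change_thresholds,
                          tables=tables)
    result.export_tables(out)
    return result


def stage_report(config: RunConfig) -> dict:
    """Machine-readable summary of the run's headline numbers."""
    out = config.output_dir
    breaks = json.loads((out / "breaks.json").read_text())
    weights = json.loads((out / "weights.json").read_text())
    total = pd.read_csv(out / "change_total.csv")
    summary = {
        "weights": weights["weights"],
        "breaks": breaks["breaks"],
        "change_percent": dict(zip(total["class"], total["percent_of_total"])),
    }
    (out / "report.json").write_text(json.dumps(summary, indent=2))
    return summary


STAGES = (("compose", stage_compose), ("stratify", stage_stratify), ("ird", stage_ird),
          ("weights", stage_weights), ("eqi", stage_eqi), ("classify", stage_classify),
          ("change", stage_change), ("report", stage_report))


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in order; returns the report summary.

    Writes the resolved configuration and a run log (config hash, versions,
    seed, stage timings) next to the outputs for auditability.
    """
    config.output_dir.mkdir(parents=True, exist_ok=True)
    (config.output_dir / "config_resolved.yaml").write_text(
        yaml.safe_dump(json.loads(json.dumps(config.model_dump(mode="json"))), sort_keys=True))
    timings = {}
    summary = {}
    for name, fn in STAGES:
        t0 = time.perf_counter()
        try:
            res = fn(config)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        timings[name] = round(time.perf_counter() - t0, 3)
        logger.info("stage %s done in %.2fs", name, timings[name])
        if name == "report":
            summary = res
    log = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "eqiscope_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "stage_seconds": timings,
    }
    (config.output_dir / "run_log.json").write_text(json.dumps(log, indent=2))
    return summary
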