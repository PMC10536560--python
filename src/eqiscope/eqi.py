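"""Ecosystem quality index: weighted sum of standardized IRDs, five-level
classification by Jenks natural breaks.

EQI = sum_i omega_i * Z_i per pixel, over the standardized indicator
relative densities.  The continuous index is cut into five ordered quality
levels — excellent, good, moderate, low, poor — at breaks chosen by the
Jenks natural-breaks optimization (exact dynamic programming minimizing the
within-class sum of squared deviations), or at user-supplied fixed breaks.

Interval convention (matching the published level definitions): classes are
lower-open and upper-closed, so a value equal to a break belongs to the
class *below* it; only values strictly above the top break are "excellent".
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .grid import Grid, assert_aligned
from .weighting import WeightSet

__all__ = [
    "LEVEL_NAMES",
    "FIXED_BREAK_PRESETS",
    "EQIResult",
    "compute_eqi",
    "jenks_breaks",
    "classify",
]

#: class codes 1..5 from worst to best
LEVEL_NAMES = {1: "poor", 2: "low", 3: "moderate", 4: "good", 5: "excellent"}

#: named fixed-break presets; `brr-2016-2020` reproduces the published
#: Belt-and-Road five-level thresholds from an EQI grid
FIXED_BREAK_PRESETS = {"brr-2016-2020": (-0.97, -0.25, 0.44, 1.19)}

LEVEL_NODATA = 255


def compute_eqi(z_grids: list[Grid], weights: WeightSet) -> Grid:
    """Weighted sum of standardized IRD grids; complete-case pixels only."""
    if len(z_grids) != len(weights.names):
        raise ValueError(f"{len(z_grids)} grids but {len(weights.names)} weights")
    if len(z_grids) >= 2 and not assert_aligned(z_grids):
        raise ValueError("standardized IRD grids are not aligned")
    first = z_grids[0]
    valid = np.ones(first.shape, dtype=bool)
    for g in z_grids:
        valid &= g.valid_mask()
    acc = np.zeros(first.shape)
    for w, g in zip(weights.weights, z_grids):
        acc += w * np.where(valid, g.values, 0.0)
    out = np.where(valid, acc, first.nodata)
    return first.with_values(out)


# ---------------------------------------------------------------------------
# Jenks natural breaks (exact Fisher dynamic program)

def _interval_cost(P: np.ndarray, Q: np.ndarray, i: int, j: int) -> float:
    """Within-class SSE of sorted values v[i..j] inclusive, from prefix sums."""
    s = P[j + 1] - P[i]
    q = Q[j + 1] - Q[i]
    cnt = j - i + 1
    return q - s * s / cnt


def _solve_level(P, Q, nxt, lo, hi, jlo, jhi, cost_row, choice_row, n):
    """Divide-and-conquer argmin for one DP level over suffix starts lo..hi.

    ``cost_row[i]`` becomes min_j SSE(i, j) + nxt[j+1] for j in a window
    known (by Monge monotonicity of the SSE cost) to lie in [jlo, jhi];
    ties prefer the smaller j, making the first class as small as possible.
    """
    if lo > hi:
        return
    mid = (lo + hi) // 2
    best, bestj = np.inf, -1
    for j in range(max(jlo, mid), jhi + 1):
        c = _interval_cost(P, Q, mid, j) + nxt[j + 1]
        if c < best:
            best, bestj = c, j
    cost_row[mid] = best
    choice_row[mid] = bestj
    _solve_level(P, Q, nxt, lo, mid - 1, jlo, bestj, cost_row, choice_row, n)
    _solve_level(P, Q, nxt, mid + 1, hi, bestj, jhi, cost_row, choice_row, n)


def jenks_class_bounds(values, k: int) -> list[tuple[float, float]]:
    """Optimal k-class partition of a 1-D distribution: (min, max) per class.

    Exact Jenks natural breaks: contiguous classes of the sorted values
    minimizing the total within-class sum of squared deviations from class
    means, found by dynamic programming with divide-and-conquer speedup
    (the SSE interval cost satisfies the concave Monge condition, so the
    optimal split index is monotone).  Among equal-cost optima the partition
    whose first class is smallest (then second, ...) is returned.
    """
    v = np.sort(np.asarray(values, dtype=np.float64).ravel())
    if v.size and not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    if k < 2:
        raise ValueError("need at least 2 classes")
    n_distinct = np.unique(v).size
    if n_distinct < k:
        raise ValueError(f"need at least {k} distinct values for {k} classes, got {n_distinct}")
    n = v.size

    P = np.concatenate([[0.0], np.cumsum(v)])
    Q = np.concatenate([[0.0], np.cumsum(v * v)])

    # cost[q][i]: optimal cost of splitting v[i:] into q classes (suffix DP)
    cost = np.full(n + 1, np.inf)
    cost[:n] = [_interval_cost(P, Q, i, n - 1) for i in range(n)]  # q = 1
    choices: list[np.ndarray] = []
    depth = sys.getrecursionlimit()
    if depth < 2 * int(np.log2(n + 1)) + 100:
        sys.setrecursionlimit(2 * int(np.log2(n + 1)) + 100)
    for q in range(2, k + 1):
        new_cost = np.full(n + 1, np.inf)
        choice = np.full(n + 1, -1, dtype=np.int64)
        # with q classes left, the first class may end at j in [i, n - q]
        hi = n - q
        _solve_level(P, Q, cost, 0, hi, 0, hi, new_cost, choice, n)
        cost = new_cost
        choices.append(choice)

    bounds: list[tuple[float, float]] = []
    i = 0
    for q in range(k, 1, -1):
        j = int(choices[q - 2][i])
        bounds.append((float(v[i]), float(v[j])))
        i = j + 1
    bounds.append((float(v[i]), float(v[n - 1])))
    return bounds


def jenks_breaks(values, k: int, sample_size: int | None = None,
                 seed: int | None = None) -> tuple[float, ...]:
    """Jenks natural-breaks cut points: the maxima of classes 1..k-1.

    Used with the lower-open / upper-closed convention of :func:`classify`.
    For very large inputs a seeded uniform subsample of ``sample_size``
    values keeps the dynamic program tractable; the sample is drawn without
    replacement and the seed should be recorded in run provenance.
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    if sample_size is not None and v.size > sample_size:
        rng = np.random.default_rng(seed)
        v = rng.choice(v, size=sample_size, replace=False)
    bounds = jenks_class_bounds(v, k)
    return tuple(b[1] for b in bounds[:-1])


def classify(eqi: Grid, breaks) -> Grid:
    """Cut a continuous EQI grid into k = len(breaks)+1 ordered levels.

    Lower-open, upper-closed intervals: value <= breaks[0] -> class 1 (poor),
    breaks[-2] < value <= breaks[-1] -> class k-1, value > breaks[-1] ->
    class k (excellent).  Nodata propagates.
    """
    breaks = tuple(float(b) for b in breaks)
    if any(b >= c for b, c in zip(breaks, breaks[1:])):
        raise ValueError(f"breaks must be strictly increasing, got {breaks}")
    valid = eqi.valid_mask()
    # searchsorted left: count of breaks < value... we need "value <= b" in lower class
    lvl = np.searchsorted(np.asarray(breaks), eqi.values, side="left") + 1
    out = np.where(valid, lvl, LEVEL_NODATA).astype(np.uint8)
    return Grid(values=out, transform=eqi.transform, crs=eqi.crs, nodata=LEVEL_NODATA)


@dataclass
class EQIResult:
    """Continuous EQI, its class breaks, and the five-level grid."""

    eqi: Grid
    breaks: tuple[float, ...]
    levels: Grid
    break_source: str = "jenks"  # or "fixed"

    def dump_breaks(self, path: str | Path) -> None:
        counts = {LEVEL_NAMES.get(int(c), str(int(c))): int(n)
                  for c, n in zip(*np.unique(self.levels.values[self.levels.valid_mask()],
                                             return_counts=True))}
        Path(path).write_text(json.dumps(
            {"breaks": list(self.breaks), "break_source": self.break_source,
             "class_counts": counts}, indent=2))
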