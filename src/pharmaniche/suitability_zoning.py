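"""Suitability classification, zonal areas, and scenario comparison.

Suitability maps are cut into four zones — unsuitable [0, 0.1), low
[0.1, 0.3), moderate [0.3, 0.6), high [0.6, 1.0] — either with these fixed
breaks (the default) or with Fisher–Jenks natural breaks computed from the
data.  Zonal areas use latitude-corrected cell areas on degree grids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_geo import GridSpec, RasterLayer, cell_areas_km2

__all__ = [
    "CLASS_NAMES",
    "ClassMap",
    "classify_fixed_breaks",
    "jenks_breaks",
    "class_areas",
    "change_rate",
    "scenario_compare",
]

CLASS_NAMES = {0: "unsuitable", 1: "low", 2: "moderate", 3: "high"}
DEFAULT_BREAKS = (0.1, 0.3, 0.6)


@dataclass
class ClassMap:
    spec: GridSpec
    classes: np.ma.MaskedArray  # integer codes 0..n_classes-1
    breaks: tuple[float, ...]

    @property
    def n_classes(self) -> int:
        return len(self.breaks) + 1


def classify_fixed_breaks(suitability: RasterLayer,
                          breaks=DEFAULT_BREAKS) -> ClassMap:
    """Classify by half-open intervals; the top class is closed at 1."""
    breaks = tuple(float(b) for b in breaks)
    if any(b2 <= b1 for b1, b2 in zip(breaks, breaks[1:])):
        raise ValueError("breaks must be strictly increasing")
    if breaks and not (0 < breaks[0] and breaks[-1] < 1):
        raise ValueError("breaks must lie strictly inside (0, 1)")
    vals = suitability.values
    finite = vals.compressed()
    if finite.size and (finite.min() < 0 or finite.max() > 1):
        raise ValueError("suitability values must lie in [0, 1]")
    codes = np.ma.masked_all(vals.shape, dtype=float)
    filled = np.ma.filled(vals, np.nan)
    with np.errstate(invalid="ignore"):
        c = np.digitize(filled, breaks, right=False)
    codes = np.ma.masked_array(c.astype(float), mask=np.ma.getmaskarray(vals))
    return ClassMap(suitability.spec, codes, breaks)


def jenks_breaks(values, n_classes: int, max_n: int = 2000,
                 seed: int = 0) -> list[float]:
    """Fisher–Jenks natural breaks: the dynamic program minimizing the
    within-class sum of squared deviations.

    Returns the ``n_classes − 1`` ascending thresholds (upper bounds of the
    lower classes, taken as the midpoint between adjacent data values so the
    half-open classification convention reproduces the optimal partition).
    Inputs longer than ``max_n`` are subsampled for tractability.
    """
    x = np.sort(np.asarray(values, dtype=float))
    if np.unique(x).size < n_classes:
        raise ValueError("need at least as many distinct values as classes")
    if n_classes < 1:
        raise ValueError("n_classes must be positive")
    if x.size > max_n:
        rng = np.random.default_rng(seed)
        x = np.sort(rng.choice(x, size=max_n, replace=False))
    n = x.size

    # prefix sums give SSE of any contiguous run in O(1)
    s1 = np.concatenate([[0.0], np.cumsum(x)])
    s2 = np.concatenate([[0.0], np.cumsum(x**2)])

    def sse(i: int, j: int) -> float:  # run x[i:j], j exclusive
        m = j - i
        s = s1[j] - s1[i]
        return (s2[j] - s2[i]) - s * s / m

    INF = np.inf
    # cost[k][j]: optimal SSE of splitting x[:j] into k classes
    prev = np.array([0.0] + [sse(0, j) for j in range(1, n + 1)])
    argsplit = np.zeros((n_classes, n + 1), dtype=int)
    for k in range(2, n_classes + 1):
        cur = np.full(n + 1, INF)
        for j in range(k, n + 1):
            best, arg = INF, k - 1
            for i in range(k - 1, j):
                c = prev[i] + sse(i, j)
                if c < best:
                    best, arg = c, i
            cur[j] = best
            argsplit[k - 1, j] = arg
        prev = cur

    # backtrack the split points
    splits = []
    j = n
    for k in range(n_classes, 1, -1):
        i = argsplit[k - 1, j]
        splits.append(i)
        j = i
    splits.reverse()
    return [float((x[i - 1] + x[i]) / 2) for i in splits]


@dataclass
class AreaReport:
    table: pd.DataFrame  # index = class name, columns area_km2, fraction_pct
    total_km2: float


def class_areas(cmap: ClassMap, degrees: bool = True,
                class_names: dict[int, str] | None = None) -> AreaReport:
    """Zonal areas in km² and percent of the total valid area."""
    names = class_names or CLASS_NAMES
    areas = cell_areas_km2(cmap.spec, degrees=degrees)
    valid = ~np.ma.getmaskarray(cmap.classes)
    total = float(areas[valid].sum())
    rows = []
    codes = np.ma.filled(cmap.classes, -1).astype(int)
    for code in range(cmap.n_classes):
        a = float(areas[(codes == code) & valid].sum())
        rows.append({"class": names.get(code, str(code)), "area_km2": a,
                     "fraction_pct": 100.0 * a / total if total else 0.0})
    return AreaReport(pd.DataFrame(rows).set_index("class"), total)


def change_rate(current_area: float, future_area: float) -> float:
    """Percent change 100·(future − current)/current."""
    if current_area <= 0:
        raise ValueError("current area must be positive")
    return 100.0 * (future_area - current_area) / current_area


@dataclass
class ScenarioComparison:
    areas: pd.DataFrame          # class × (current, future, change_rate_pct)
    transitions: pd.DataFrame    # current class × future class cell counts


def scenario_compare(current: ClassMap, future: ClassMap,
                     degrees: bool = True) -> ScenarioComparison:
    """Per-class current/future areas, change rates, and the cell-level
    class-transition matrix (rows sum to current class counts)."""
    if not current.spec.aligned_with(future.spec):
        raise ValueError("scenario grids are not aligned")
    cur_rep = class_areas(current, degrees)
    fut_rep = class_areas(future, degrees)
    tab = pd.DataFrame({
        "current_km2": cur_rep.table["area_km2"],
        "future_km2": fut_rep.table["area_km2"],
    })
    tab["change_rate_pct"] = [
        change_rate(c, f) if c > 0 else np.nan
        for c, f in zip(tab["current_km2"], tab["future_km2"])
    ]
    k = max(current.n_classes, future.n_classes)
    cc = np.ma.filled(current.classes, -1).astype(int)
    fc = np.ma.filled(future.classes, -1).astype(int)
    both = (cc >= 0) & (fc >= 0)
    trans = np.zeros((k, k), dtype=int)
    np.add.at(trans, (cc[both], fc[both]), 1)
    names = [CLASS_NAMES.get(i, str(i)) for i in range(k)]
    return ScenarioComparison(tab, pd.DataFrame(trans, index=names, columns=names))
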