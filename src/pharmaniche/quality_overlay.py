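"""Fuzzy-overlay quality zoning.

Each regression model is evaluated cell-wise over the environmental stack to
give a predicted concentration raster; rasters are min–max normalized to
[0, 1] and combined — together with the habitat-suitability layer — by a
fuzzy overlay operator (AND = min, OR = max, SUM = 1 − Π(1−v), PRODUCT = Πv,
GAMMA = SUM^γ·PRODUCT^(1−γ)).  Cells classified unsuitable are masked out of
the final quality map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_geo import EnvStack, RasterLayer
from .quality_models import RegressionModel
from .suitability_zoning import ClassMap

__all__ = [
    "OverlayConfig",
    "QualityMap",
    "predict_factor_raster",
    "minmax_normalize",
    "fuzzy_overlay",
    "mask_by_class",
    "compose_zoning",
    "FACTOR_SUBSETS",
]

#: factor subsets used for the three zoning maps: medicinal quality uses the
#: marker common-peak areas plus index components and effective compound
#: groups; edible quality uses the nutritional items; comprehensive uses all.
FACTOR_SUBSETS = {
    "medicinal": [
        "lobetyolin", "atractylenolide III", "syringin",
        "polysaccharides", "oligosaccharides", "alcohol extract",
        "peak 1 area", "peak 4 area", "peak 5 area", "peak 6 area",
        "peak 9 area", "peak 10 area", "peak 11 area", "peak 12 area",
        "peak 14 area", "peak 15 area", "peak 19 area",
    ],
    "edible": [
        "amino acid", "protein", "fat", "dietary fiber",
        "total nutrient elements",
    ],
}

METHODS = ("fuzzy_and", "fuzzy_or", "fuzzy_sum", "fuzzy_product", "fuzzy_gamma")


@dataclass
class OverlayConfig:
    method: str = "fuzzy_gamma"
    gamma: float | None = 0.9

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown overlay method {self.method!r}")
        if self.method == "fuzzy_gamma":
            if self.gamma is None or not (0 <= self.gamma <= 1):
                raise ValueError("fuzzy_gamma requires gamma in [0, 1]")


@dataclass
class QualityMap:
    layer: RasterLayer
    provenance: dict = field(default_factory=dict)


def predict_factor_raster(model: RegressionModel, stack: EnvStack) -> RasterLayer:
    """Cell-wise evaluation of a linear model over the stack; masked wherever
    any required covariate is masked."""
    for name in model.coefficients:
        if name not in stack:
            raise ValueError(f"stack missing covariate layer {name!r}")
    spec = stack.spec
    out = np.full((spec.nrows, spec.ncols), model.intercept)
    mask = np.zeros_like(out, dtype=bool)
    for name, coef in model.coefficients.items():
        l = stack[name]
        out = out + coef * np.ma.filled(l.values, 0.0)
        mask |= l.mask
    return RasterLayer(model.response, spec, np.ma.masked_array(out, mask=mask))


def minmax_normalize(layer: RasterLayer) -> RasterLayer:
    """(v − min)/(max − min) over valid cells; min → 0, max → 1."""
    vals = layer.values
    finite = vals.compressed()
    if np.unique(finite).size < 2:
        raise ValueError("cannot normalize a constant layer")
    lo, hi = float(finite.min()), float(finite.max())
    return RasterLayer(layer.name, layer.spec, (vals - lo) / (hi - lo))


def fuzzy_overlay(layers: list[RasterLayer], config: OverlayConfig) -> QualityMap:
    """Cell-wise fuzzy combination of aligned [0,1] membership layers."""
    if len(layers) < 2:
        raise ValueError("need at least 2 layers to overlay")
    spec = layers[0].spec
    for l in layers[1:]:
        if not l.spec.aligned_with(spec):
            raise ValueError(f"layer {l.name!r} is not aligned")
    stack = np.ma.stack([l.values for l in layers])
    finite = stack.compressed()
    if finite.size and (finite.min() < -1e-12 or finite.max() > 1 + 1e-12):
        raise ValueError("overlay inputs must lie in [0, 1]")
    stack = np.ma.clip(stack, 0.0, 1.0)
    m = config.method
    if m == "fuzzy_and":
        vals = stack.min(axis=0)
    elif m == "fuzzy_or":
        vals = stack.max(axis=0)
    elif m == "fuzzy_sum":
        vals = 1.0 - (1.0 - stack).prod(axis=0)
    elif m == "fuzzy_product":
        vals = stack.prod(axis=0)
    else:  # fuzzy_gamma
        fsum = 1.0 - (1.0 - stack).prod(axis=0)
        fprod = stack.prod(axis=0)
        g = config.gamma
        vals = fsum**g * fprod**(1.0 - g)
    layer = RasterLayer("quality", spec, vals)
    prov = {"inputs": [l.name for l in layers], "method": m}
    if m == "fuzzy_gamma":
        prov["gamma"] = config.gamma
    return QualityMap(layer, prov)


def mask_by_class(q: QualityMap, cmap: ClassMap,
                  excluded: set[int] = frozenset({0})) -> QualityMap:
    """Mask quality cells whose suitability class is excluded (default:
    the unsuitable class)."""
    if not q.layer.spec.aligned_with(cmap.spec):
        raise ValueError("quality and class grids are not aligned")
    codes = np.ma.filled(cmap.classes, -1).astype(int)
    bad = np.isin(codes, list(excluded)) | np.ma.getmaskarray(cmap.classes)
    vals = np.ma.masked_array(q.layer.values,
                              mask=np.ma.getmaskarray(q.layer.values) | bad)
    prov = dict(q.provenance)
    prov["excluded_classes"] = sorted(excluded)
    return QualityMap(RasterLayer(q.layer.name, q.layer.spec, vals), prov)


def compose_zoning(models: list[RegressionModel], stack: EnvStack,
                   suitability: RasterLayer, cmap: ClassMap,
                   subset: str = "comprehensive",
                   config: OverlayConfig | None = None) -> QualityMap:
    """Full zoning composition: predict each subset factor → normalize →
    overlay with the suitability layer → mask unsuitable cells."""
    config = config or OverlayConfig()
    if subset == "comprehensive":
        wanted = [m.response for m in models]
    elif subset in FACTOR_SUBSETS:
        wanted = FACTOR_SUBSETS[subset]
    else:
        raise ValueError(f"unknown subset {subset!r}")
    chosen = [m for m in models if m.response in wanted]
    if not chosen:
        raise ValueError(f"no models available for subset {subset!r}")
    layers = [minmax_normalize(predict_factor_raster(m, stack)) for m in chosen]
    layers.append(suitability)
    q = fuzzy_overlay(layers, config)
    q = mask_by_class(q, cmap)
    q.provenance["subset"] = subset
    q.layer.name = f"quality_{subset}"
    return q
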