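"""Synthetic study scenes with known ground truth.

Emulates the study design end to end: spatially autocorrelated continuous
climate layers (some pairs deliberately collinear with |r| > 0.8), one
integer-coded soil layer, presence points sampled from a known Gibbs
suitability surface, 20-peak chromatograms with retention-time jitter, and
functional-factor concentration tables generated from sparse linear models
of the environmental covariates plus Gaussian noise.  Every generator is a
pure function of its parameters and seed, so each downstream stage has a
recovery test against recorded truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage

from .io_geo import EnvStack, GridSpec, OccurrenceSet, RasterLayer

__all__ = [
    "SyntheticTruth",
    "gen_env_stack",
    "gen_occurrences",
    "gen_future_stack",
    "gen_chromatograms",
    "gen_functional_factor_table",
    "default_scene",
    "DEFAULT_PEAK_TEMPLATES",
]


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the generators, for recovery tests."""

    true_weights: dict[str, float] = field(default_factory=dict)
    collinear_pairs: list[tuple[str, str]] = field(default_factory=list)
    peak_templates: list[tuple[float, float, float]] = field(default_factory=list)
    factor_models: dict[str, dict] = field(default_factory=dict)
    seed: int = 0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["collinear_pairs"] = [tuple(p) for p in d["collinear_pairs"]]
        d["peak_templates"] = [tuple(p) for p in d["peak_templates"]]
        return cls(**d)


def _smooth_field(rng: np.random.Generator, nrows: int, ncols: int,
                  smoothness: float) -> np.ndarray:
    """Standardized Gaussian-filtered white noise (mean 0, sd 1)."""
    z = rng.standard_normal((nrows, ncols))
    if smoothness > 1:
        z = ndimage.gaussian_filter(z, sigma=smoothness, mode="reflect")
    z = (z - z.mean()) / z.std()
    return z


def gen_env_stack(nrows: int = 100, ncols: int = 100, n_continuous: int = 12,
                  n_categorical: int = 1, smoothness: float = 8.0,
                  collinear_pairs: int = 2, seed: int = 0,
                  cellsize: float = 0.01, xll: float = 100.0, yll: float = 34.0,
                  ) -> tuple[EnvStack, SyntheticTruth]:
    """Generate an aligned environmental stack with planted collinearity.

    Continuous layers are smoothed white noise standardized over the grid;
    each planted collinear pair is built as ``y = 0.95 x + 0.1 ε`` (then
    restandardized), which gives empirical |r| ≈ 0.99.  Categorical layers
    are Voronoi patches with integer codes.
    """
    if nrows < 8 or ncols < 8:
        raise ValueError("grid dimensions must be at least 8")
    if n_continuous < 2:
        raise ValueError("need at least 2 continuous layers")
    if collinear_pairs > n_continuous // 2:
        raise ValueError("collinear_pairs may not exceed n_continuous/2")

    rng = np.random.default_rng(seed)
    spec = GridSpec(ncols, nrows, xll, yll, cellsize)
    layers: list[RasterLayer] = []
    truth = SyntheticTruth(seed=seed)

    n_base = n_continuous - collinear_pairs
    bases = [_smooth_field(rng, nrows, ncols, smoothness) for _ in range(n_base)]
    for i, z in enumerate(bases):
        layers.append(RasterLayer(f"env{i + 1:02d}", spec, np.ma.asarray(z)))
    for k in range(collinear_pairs):
        partner = bases[k]
        eps = _smooth_field(rng, nrows, ncols, smoothness)
        mix = 0.95 * partner + 0.1 * eps
        mix = (mix - mix.mean()) / mix.std()
        name = f"env{n_base + k + 1:02d}"
        layers.append(RasterLayer(name, spec, np.ma.asarray(mix)))
        truth.collinear_pairs.append((f"env{k + 1:02d}", name))
    for j in range(n_categorical):
        n_patches = 6
        centers = rng.uniform(0, 1, size=(n_patches, 2)) * [nrows, ncols]
        rr, cc = np.mgrid[0:nrows, 0:ncols]
        d = (rr[..., None] - centers[:, 0]) ** 2 + (cc[..., None] - centers[:, 1]) ** 2
        codes = np.argmin(d, axis=-1).astype(float)
        layers.append(
            RasterLayer(f"soil{j + 1:02d}", spec, np.ma.asarray(codes), kind="categorical")
        )
    return EnvStack(layers), truth


def gen_occurrences(stack: EnvStack, truth: SyntheticTruth, n_points: int = 200,
                    seed: int = 0) -> OccurrenceSet:
    """Sample presence cells ∝ exp(Σ w·x) without replacement.

    One point is placed uniformly inside each sampled cell.  The exponential
    (Gibbs) form means a maximum-entropy fit with linear features is
    correctly specified for this truth.
    """
    for name in truth.true_weights:
        if name not in stack:
            raise ValueError(f"truth references unknown layer {name!r}")
    rng = np.random.default_rng(seed)
    spec = stack.spec
    valid = ~stack.shared_mask()
    rows, cols = np.nonzero(valid)
    n_valid = rows.size
    if n_points > n_valid:
        raise ValueError(f"n_points={n_points} exceeds {n_valid} valid cells")

    eta = np.zeros(n_valid)
    for name, w in truth.true_weights.items():
        eta += w * np.asarray(stack[name].values)[rows, cols]
    p = np.exp(eta - eta.max())
    p /= p.sum()
    idx = rng.choice(n_valid, size=n_points, replace=False, p=p)
    points = []
    for i in idx:
        r, c = rows[i], cols[i]
        lon = spec.xllcorner + (c + rng.uniform()) * spec.cellsize
        lat = spec.yllcorner + (spec.nrows - 1 - r + rng.uniform()) * spec.cellsize
        points.append((float(lon), float(lat)))
    return OccurrenceSet("synthetic", points)


def gen_future_stack(stack: EnvStack, deltas: dict[str, float],
                     seed: int = 0) -> EnvStack:
    """Apply additive shifts to named layers (an emulated climate scenario)."""
    unknown = set(deltas) - set(stack.names)
    if unknown:
        raise ValueError(f"deltas reference unknown layers: {sorted(unknown)}")
    out = []
    for l in stack.layers:
        nl = l.copy()
        if l.name in deltas:
            nl.values = nl.values + deltas[l.name]
        out.append(nl)
    return EnvStack(out)


#: 20 peak templates (retention time min, mean area, area CV) spanning a
#: 0–50 min gradient, areas right-skewed as in real chromatograms.
DEFAULT_PEAK_TEMPLATES: list[tuple[float, float, float]] = [
    (2.5, 8.0, 0.25), (4.8, 15.0, 0.20), (6.9, 5.0, 0.30), (9.1, 22.0, 0.15),
    (11.4, 12.0, 0.25), (13.6, 30.0, 0.20), (15.9, 7.0, 0.30), (18.2, 18.0, 0.20),
    (20.4, 10.0, 0.25), (22.7, 25.0, 0.15), (25.0, 14.0, 0.20), (27.2, 6.0, 0.30),
    (29.5, 20.0, 0.20), (31.8, 9.0, 0.25), (34.0, 16.0, 0.20), (36.3, 11.0, 0.25),
    (38.6, 28.0, 0.15), (41.0, 8.5, 0.30), (43.5, 13.0, 0.20), (46.0, 19.0, 0.20),
]


def gen_chromatograms(n_samples: int, truth: SyntheticTruth,
                      rt_jitter_sd: float = 0.05, baseline_noise_sd: float = 0.02,
                      seed: int = 0, t_max: float = 50.0, dt: float = 0.01,
                      peak_sigma: float = 0.08) -> pd.DataFrame:
    """Simulate HPLC traces: Gaussian peaks + jitter + baseline noise.

    Peak areas get per-sample log-normal multipliers (unit median, CV from
    the template) and retention times get Gaussian jitter.  Returns a long
    table with columns sample, time, signal.
    """
    if rt_jitter_sd < 0 or baseline_noise_sd < 0:
        raise ValueError("jitter/noise standard deviations must be non-negative")
    templates = truth.peak_templates or DEFAULT_PEAK_TEMPLATES
    if not templates:
        raise ValueError("peak templates must be non-empty")
    for rt, _, _ in templates:
        if not (0 <= rt <= t_max):
            raise ValueError("retention times must lie within the gradient")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, t_max + dt / 2, dt)
    frames = []
    for s in range(n_samples):
        signal = np.zeros_like(t)
        for rt, area, cv in templates:
            sigma_ln = np.sqrt(np.log(1 + cv**2))
            mult = np.exp(rng.normal(-sigma_ln**2 / 2, sigma_ln))
            rt_s = rt + rng.normal(0, rt_jitter_sd)
            a = area * mult
            signal += a / (peak_sigma * np.sqrt(2 * np.pi)) * np.exp(
                -0.5 * ((t - rt_s) / peak_sigma) ** 2
            )
        if baseline_noise_sd > 0:
            signal += rng.normal(0, baseline_noise_sd, size=t.size)
        frames.append(pd.DataFrame({"sample": f"S{s + 1}", "time": t, "signal": signal}))
    return pd.concat(frames, ignore_index=True)


def gen_functional_factor_table(stack: EnvStack, occ: OccurrenceSet,
                                truth: SyntheticTruth, seed: int = 0) -> pd.DataFrame:
    """Concentration table: factor = intercept + Σ coef·layer + noise, per sample."""
    from .io_geo import extract_values

    for fm in truth.factor_models.values():
        for name in fm["coefficients"]:
            if name not in stack:
                raise ValueError(f"factor model references unknown layer {name!r}")
    rng = np.random.default_rng(seed)
    tab = extract_values(stack, occ)
    tab = tab[tab["valid"]].reset_index(drop=True)
    out = tab[["longitude", "latitude"]].copy()
    for fname, fm in truth.factor_models.items():
        y = np.full(len(tab), float(fm["intercept"]))
        for lname, coef in fm["coefficients"].items():
            y = y + coef * tab[lname].to_numpy()
        sd = float(fm.get("noise_sd", 0.0))
        if sd > 0:
            y = y + rng.normal(0, sd, size=y.size)
        out[fname] = y
    return out


def default_scene(seed: int = 0, nrows: int = 100, ncols: int = 100,
                  n_points: int = 200):
    """The default synthetic study: 12+1 layers, 2 collinear pairs, 200 presences.

    The generating suitability surface loads on three informative layers with
    weights ≥ 1 in absolute value so the maxent recovery property holds.
    """
    stack, truth = gen_env_stack(nrows=nrows, ncols=ncols, seed=seed)
    truth.true_weights = {"env03": 1.5, "env04": -1.0, "env05": 1.0}
    truth.peak_templates = list(DEFAULT_PEAK_TEMPLATES)
    occ = gen_occurrences(stack, truth, n_points=n_points, seed=seed + 1)
    return stack, truth, occ
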