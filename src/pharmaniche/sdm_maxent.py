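"""Maximum-entropy species distribution model, written from scratch.

The model is the Gibbs distribution q(x) ∝ exp(λ·f(x)) over the fitting
sample (presences ∪ background) that minimizes the L1-regularized negative
mean presence log-likelihood

    L(λ) = −mean_presence[λ·f(x)] + log Z(λ) + Σ_j β_j |λ_j|,

fitted by cyclic coordinate descent with soft-thresholding.  Coordinate
descent is chosen deliberately: crediting the objective improvement of each
accepted single-feature update to that feature's source layer is exactly how
percent contribution is defined.  Feature classes are linear + quadratic for
continuous covariates and one indicator per category for categorical ones,
each min–max scaled to [0,1] on the training sample; β_j defaults to
``reg_multiplier · sd(f_j over background) / sqrt(n_presences)``.

Suitability output defaults to the cloglog transform
``1 − exp(−e^H · q(x))`` where H is the entropy of the fitted distribution;
the logistic transform ``q e^H / (1 + q e^H)`` is available by flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import rankdata

from .io_geo import EnvStack, OccurrenceSet, RasterLayer, extract_values

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureExpansion",
    "MaxEntModel",
    "fit_maxent",
    "predict_suitability",
    "auc",
    "auc_grade",
    "train_test_split",
    "percent_contribution",
    "permutation_importance",
    "jackknife_gains",
    "response_curve",
    "fit_replicates",
    "sample_background",
]


@dataclass(frozen=True)
class FeatureDef:
    layer: str
    kind: str            # linear | quadratic | indicator
    category: float | None
    vmin: float
    vmax: float

    def raw(self, col: np.ndarray) -> np.ndarray:
        if self.kind == "linear":
            v = col
        elif self.kind == "quadratic":
            v = col**2
        else:
            return (col == self.category).astype(float)
        if self.vmax > self.vmin:
            return (v - self.vmin) / (self.vmax - self.vmin)
        return np.zeros_like(v)


@dataclass
class FeatureExpansion:
    """Deterministic covariate → feature map with training-data scaling."""

    definitions: list[FeatureDef]
    layer_kinds: dict[str, str]

    @classmethod
    def from_training(cls, df: pd.DataFrame, layer_kinds: dict[str, str]
                      ) -> "FeatureExpansion":
        defs: list[FeatureDef] = []
        for name, kind in layer_kinds.items():
            col = df[name].to_numpy(dtype=float)
            if not np.all(np.isfinite(col)):
                raise ValueError(f"non-finite covariate values in layer {name!r}")
            if kind == "categorical":
                for cat in np.unique(col):
                    defs.append(FeatureDef(name, "indicator", float(cat), 0.0, 1.0))
            else:
                defs.append(FeatureDef(name, "linear", None,
                                       float(col.min()), float(col.max())))
                defs.append(FeatureDef(name, "quadratic", None,
                                       float((col**2).min()), float((col**2).max())))
        return cls(defs, dict(layer_kinds))

    @property
    def layers(self) -> list[str]:
        seen: list[str] = []
        for d in self.definitions:
            if d.layer not in seen:
                seen.append(d.layer)
        return seen

    def build(self, df: pd.DataFrame) -> np.ndarray:
        cols = []
        for d in self.definitions:
            if d.layer not in df.columns:
                raise ValueError(f"missing covariate layer {d.layer!r}")
            cols.append(d.raw(df[d.layer].to_numpy(dtype=float)))
        return np.column_stack(cols) if cols else np.empty((len(df), 0))


@dataclass
class MaxEntModel:
    features: FeatureExpansion
    lam: np.ndarray
    beta: np.ndarray
    log_Z: float
    entropy_H: float
    n_presence: int
    n_sample: int
    gain: float
    layer_gain_credit: dict[str, float] = field(default_factory=dict)
    converged: bool = True
    n_iter: int = 0
    replicate_id: int = 0

    def raw_scores(self, df: pd.DataFrame) -> np.ndarray:
        """Raw Gibbs probabilities q(x) = exp(λ·f(x) − log Z), training normalizer."""
        F = self.features.build(df)
        return np.exp(F @ self.lam - self.log_Z)

    def transform(self, raw: np.ndarray, output: str = "cloglog") -> np.ndarray:
        if output == "raw":
            return raw
        qh = raw * np.exp(self.entropy_H)
        if output == "cloglog":
            return 1.0 - np.exp(-qh)
        if output == "logistic":
            return qh / (1.0 + qh)
        raise ValueError(f"unknown output {output!r}")

    def predict(self, df: pd.DataFrame, output: str = "cloglog") -> np.ndarray:
        return self.transform(self.raw_scores(df), output)


def _objective(eta: np.ndarray, n_p: int, lam: np.ndarray, beta: np.ndarray) -> float:
    return -float(eta[:n_p].mean()) + float(logsumexp(eta)) + float(beta @ np.abs(lam))


def fit_maxent(presences: pd.DataFrame, background: pd.DataFrame,
               layer_kinds: dict[str, str] | None = None,
               reg_multiplier: float = 1.0, max_iter: int = 500,
               tol: float = 1e-5, seed: int = 0,
               features: FeatureExpansion | None = None) -> MaxEntModel:
    """Fit the regularized maxent model by cyclic coordinate descent.

    ``presences`` and ``background`` are covariate tables (one column per
    layer).  The fitting sample is their union; the objective is
    non-increasing across accepted updates and fitting stops when a full
    cycle improves the penalized gain by less than ``tol``.
    """
    if len(presences) < 5:
        raise ValueError("need at least 5 presences")
    if layer_kinds is None:
        layer_kinds = {c: "continuous" for c in presences.columns}
    union = pd.concat([presences[list(layer_kinds)], background[list(layer_kinds)]],
                      ignore_index=True)
    if features is None:
        features = FeatureExpansion.from_training(union, layer_kinds)
    F = features.build(union)
    n_p = len(presences)
    N, m = F.shape

    # drop all-constant features (zero variance on the sample)
    keep = F.std(axis=0) > 0
    if not keep.all():
        dropped = [features.definitions[j] for j in np.nonzero(~keep)[0]]
        for d in dropped:
            logger.warning("dropping constant feature %s:%s", d.layer, d.kind)
        features = FeatureExpansion(
            [d for j, d in enumerate(features.definitions) if keep[j]],
            features.layer_kinds)
        F = F[:, keep]
        m = F.shape[1]

    Fb = features.build(background[list(layer_kinds)])
    sd_bg = Fb.std(axis=0) if len(background) else F.std(axis=0)
    beta = reg_multiplier * np.maximum(sd_bg, 1e-6) / np.sqrt(n_p)

    lam = np.zeros(m)
    eta = np.zeros(N)
    fbar_p = F[:n_p].mean(axis=0)
    obj = _objective(eta, n_p, lam, beta)
    credit: dict[str, float] = {layer: 0.0 for layer in layer_kinds}
    n_cycles = 0
    converged = False
    for n_cycles in range(1, max_iter + 1):
        obj_start = obj
        for j in range(m):
            w = np.exp(eta - eta.max())
            w /= w.sum()
            fj = F[:, j]
            Eq = float(w @ fj)
            Vq = float(w @ fj**2) - Eq**2
            g = Eq - fbar_p[j]
            h = max(Vq, 1e-10)
            # proximal Newton target with soft-thresholding
            z = lam[j] - g / h
            target = np.sign(z) * max(abs(z) - beta[j] / h, 0.0)
            delta = target - lam[j]
            if delta == 0.0:
                continue
            for _ in range(30):
                lam_try = lam[j] + delta
                eta_try = eta + delta * fj
                lam_new = lam.copy()
                lam_new[j] = lam_try
                obj_try = _objective(eta_try, n_p, lam_new, beta)
                if obj_try <= obj + 1e-12:
                    break
                delta *= 0.5
            else:
                continue
            if obj_try < obj:
                credit[features.definitions[j].layer] += obj - obj_try
                lam[j] = lam_try
                eta = eta_try
                obj = obj_try
        if obj_start - obj < tol:
            converged = True
            break

    log_Z = float(logsumexp(eta))
    logq = eta - log_Z
    q = np.exp(logq)
    H = float(-(q @ logq))
    gain = float(np.log(N) + eta[:n_p].mean() - log_Z)
    return MaxEntModel(features=features, lam=lam, beta=beta, log_Z=log_Z,
                       entropy_H=max(H, 0.0), n_presence=n_p, n_sample=N,
                       gain=gain, layer_gain_credit=credit,
                       converged=converged, n_iter=n_cycles)


def predict_suitability(model: MaxEntModel, stack: EnvStack,
                        output: str = "cloglog") -> RasterLayer:
    """Suitability raster on the stack grid; masked cells stay masked."""
    for layer in model.features.layers:
        if layer not in stack:
            raise ValueError(f"stack missing model layer {layer!r}")
    tab = stack.valid_table()
    vals = model.predict(tab, output=output)
    grid = np.ma.masked_all((stack.spec.nrows, stack.spec.ncols))
    grid[tab["row"].to_numpy(), tab["col"].to_numpy()] = vals
    return RasterLayer(f"suitability_{output}", stack.spec, grid)


def auc(scores_presence, scores_background) -> float:
    """Area under the ROC curve = Mann–Whitney statistic / (n₁·n₂), ties ½."""
    a = np.asarray(scores_presence, dtype=float)
    b = np.asarray(scores_background, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both score lists must be non-empty")
    ranks = rankdata(np.concatenate([a, b]))
    u = ranks[: a.size].sum() - a.size * (a.size + 1) / 2
    return float(u / (a.size * b.size))


def auc_grade(value: float) -> str:
    """The conventional AUC quality gates for presence–background models."""
    if value < 0.6:
        return "fails"
    if value < 0.7:
        return "poor"
    if value <= 0.9:
        return "good"
    return "excellent"


def train_test_split(occ: OccurrenceSet, test_fraction: float = 0.25,
                     seed: int = 0) -> tuple[OccurrenceSet, OccurrenceSet]:
    """Random disjoint split; test size = round(n · fraction), must be ≥ 1."""
    if not (0 < test_fraction < 1):
        raise ValueError("test_fraction must lie in (0, 1)")
    n = len(occ)
    n_test = round(n * test_fraction)
    if n_test == 0:
        raise ValueError("test_fraction too small: empty test set")
    rng = np.random.default_rng(seed)
    idx = rng.permutation(n)
    test_idx = set(idx[:n_test].tolist())
    train = [p for i, p in enumerate(occ.points) if i not in test_idx]
    test = [p for i, p in enumerate(occ.points) if i in test_idx]
    return OccurrenceSet(occ.species, train), OccurrenceSet(occ.species, test)


def percent_contribution(model: MaxEntModel) -> pd.Series:
    """Share of total fitting gain credited to each source layer, summing to 100."""
    credit = pd.Series(model.layer_gain_credit, dtype=float)
    total = credit.sum()
    if total <= 0:
        logger.warning("zero total gain; all contributions set to 0")
        return credit * 0.0
    return 100.0 * credit / total


def permutation_importance(model: MaxEntModel, presences: pd.DataFrame,
                           background: pd.DataFrame, n_perm: int = 5,
                           seed: int = 0) -> pd.Series:
    """Mean AUC drop when one layer is shuffled across presences+background,
    floored at 0 and normalized to sum 100."""
    rng = np.random.default_rng(seed)
    layers = model.features.layers
    cols = list(model.features.layer_kinds)
    union = pd.concat([presences[cols], background[cols]], ignore_index=True)
    n_p = len(presences)
    base_scores = model.raw_scores(union)
    base = auc(base_scores[:n_p], base_scores[n_p:])
    drops = {}
    for layer in layers:
        acc = 0.0
        for _ in range(n_perm):
            perm = union.copy()
            perm[layer] = rng.permutation(perm[layer].to_numpy())
            s = model.raw_scores(perm)
            acc += base - auc(s[:n_p], s[n_p:])
        drops[layer] = max(acc / n_perm, 0.0)
    out = pd.Series(drops, dtype=float)
    total = out.sum()
    if total <= 0:
        logger.warning("no permutation produced an AUC drop; importances all 0")
        return out * 0.0
    return 100.0 * out / total


def jackknife_gains(presences: pd.DataFrame, background: pd.DataFrame,
                    layer_kinds: dict[str, str], reg_multiplier: float = 1.0,
                    max_iter: int = 200, seed: int = 0,
                    tol: float = 1e-7) -> pd.DataFrame:
    """Training gain with only, and without, each layer, plus the full gain.

    Gain is the mean presence log-likelihood minus log(1/N) of the uniform
    distribution over the fitting sample.
    """
    layers = list(layer_kinds)
    if len(layers) < 2:
        raise ValueError("jackknife needs at least 2 layers")

    def _gain(subset: list[str]) -> float:
        kinds = {k: layer_kinds[k] for k in subset}
        m = fit_maxent(presences[subset], background[subset], kinds,
                       reg_multiplier=reg_multiplier, max_iter=max_iter,
                       tol=tol, seed=seed)
        return max(m.gain, 0.0)

    gain_full = _gain(layers)
    rows = []
    for layer in layers:
        rows.append({
            "layer": layer,
            "gain_with_only": _gain([layer]),
            "gain_without": _gain([l for l in layers if l != layer]),
        })
    df = pd.DataFrame(rows).set_index("layer")
    df.attrs["gain_full"] = gain_full
    return df


@dataclass
class ResponseCurve:
    layer: str
    grid: np.ndarray
    suitability: np.ndarray
    suitable_range_030: list[tuple[float, float]]
    optimal_range_050: list[tuple[float, float]]


def _threshold_ranges(grid: np.ndarray, vals: np.ndarray,
                      thr: float) -> list[tuple[float, float]]:
    above = vals > thr
    ranges = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = grid[i]
        elif not flag and start is not None:
            ranges.append((float(start), float(grid[i - 1])))
            start = None
    if start is not None:
        ranges.append((float(start), float(grid[-1])))
    return ranges


def response_curve(model: MaxEntModel, layer: str, background: pd.DataFrame,
                   n_grid: int = 100) -> ResponseCurve:
    """Univariate response: vary one layer over its training range, others at
    their background means (categorical at the mode); cloglog output."""
    if model.features.layer_kinds.get(layer) != "continuous":
        raise ValueError(f"response curves require a continuous layer, got {layer!r}")
    lin = next(d for d in model.features.definitions
               if d.layer == layer and d.kind == "linear")
    grid = np.linspace(lin.vmin, lin.vmax, n_grid)
    base = {}
    for name, kind in model.features.layer_kinds.items():
        col = background[name]
        base[name] = float(col.mode().iloc[0]) if kind == "categorical" else float(col.mean())
    df = pd.DataFrame({name: np.full(n_grid, v) for name, v in base.items()})
    df[layer] = grid
    vals = model.predict(df, output="cloglog")
    return ResponseCurve(layer, grid, vals,
                         _threshold_ranges(grid, vals, 0.30),
                         _threshold_ranges(grid, vals, 0.50))


def sample_background(stack: EnvStack, n: int = 10_000, seed: int = 0) -> pd.DataFrame:
    """Uniform sample of valid cells (all cells when fewer than ``n``)."""
    tab = stack.valid_table()
    if len(tab) <= n:
        return tab
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(tab), size=n, replace=False)
    return tab.iloc[np.sort(idx)].reset_index(drop=True)


def fit_replicates(occ: OccurrenceSet, stack: EnvStack, n_replicates: int = 10,
                   test_fraction: float = 0.25, reg_multiplier: float = 1.0,
                   max_iter: int = 500, n_background: int = 10_000,
                   seed: int = 0, output: str = "cloglog"):
    """Replicate fits with fresh splits/backgrounds; cell-wise mean suitability.

    Returns ``(mean_map, metrics)`` where metrics is a DataFrame with one row
    per replicate (train/test AUC) and the per-replicate models in attrs.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be at least 1")
    layer_kinds = {l.name: l.kind for l in stack.layers}
    rng = np.random.default_rng(seed)
    maps = []
    rows = []
    models = []
    for rep in range(n_replicates):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        train, test = train_test_split(occ, test_fraction, seed=rep_seed)
        bg = sample_background(stack, n_background, seed=rep_seed)
        tr_tab = extract_values(stack, train)
        tr_tab = tr_tab[tr_tab["valid"]]
        te_tab = extract_values(stack, test)
        te_tab = te_tab[te_tab["valid"]]
        model = fit_maxent(tr_tab, bg, layer_kinds, reg_multiplier=reg_multiplier,
                           max_iter=max_iter, seed=rep_seed)
        model.replicate_id = rep
        cols = list(layer_kinds)
        bg_scores = model.raw_scores(bg[cols])
        auc_train = auc(model.raw_scores(tr_tab[cols]), bg_scores)
        auc_test = auc(model.raw_scores(te_tab[cols]), bg_scores)
        maps.append(predict_suitability(model, stack, output=output))
        rows.append({"replicate": rep, "auc_train": auc_train, "auc_test": auc_test})
        models.append(model)
    stacked = np.ma.stack([m.values for m in maps])
    mean_map = RasterLayer(f"suitability_{output}_mean", stack.spec,
                           stacked.mean(axis=0))
    metrics = pd.DataFrame(rows)
    metrics.attrs["models"] = models
    metrics.attrs["replicate_maps"] = maps
    return mean_map, metrics
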