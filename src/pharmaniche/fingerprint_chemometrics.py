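"""Chromatographic fingerprint processing and chemometrics.

Workflow: detect peaks in each trace, correct retention-time drift against a
set of anchor times, match peaks across samples into *common peaks* (present
in every sample), build a reference (median) fingerprint, score each sample
against it with the included-angle cosine, and select marker peaks by PCA on
the correlation matrix of the common-peak areas (components with eigenvalue
≥ 1, peaks with |loading| > 0.8 on any retained component — the standard
TCM-fingerprint similarity-evaluation conventions).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, peak_prominences

logger = logging.getLogger(__name__)

__all__ = [
    "Chromatogram",
    "PeakTable",
    "detect_peaks",
    "rt_correct",
    "match_common_peaks",
    "reference_vector",
    "cosine_similarity",
    "similarity_matrix",
    "pca_select_peaks",
    "PCASelection",
    "chromatograms_from_long",
]


@dataclass
class Chromatogram:
    sample_id: str
    time: np.ndarray    # minutes, strictly increasing uniform grid
    signal: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.size != self.signal.size:
            raise ValueError("time and signal lengths differ")
        if self.time.size >= 2 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal must be finite")


@dataclass
class PeakTable:
    sample_id: str
    peaks: pd.DataFrame  # columns rt, area, height, left, right (sorted by rt)

    def __post_init__(self) -> None:
        need = {"rt", "area", "height", "left", "right"}
        if not need.issubset(self.peaks.columns):
            raise ValueError(f"peak table must have columns {sorted(need)}")
        self.peaks = self.peaks.sort_values("rt").reset_index(drop=True)


def chromatograms_from_long(df: pd.DataFrame) -> list[Chromatogram]:
    """Build Chromatogram objects from a long sample,time,signal table."""
    out = []
    for sid, g in df.groupby("sample", sort=True):
        g = g.sort_values("time")
        out.append(Chromatogram(str(sid), g["time"].to_numpy(), g["signal"].to_numpy()))
    return out


def detect_peaks(c: Chromatogram, min_height: float = 0.0,
                 min_prominence: float = 1.0) -> PeakTable:
    """Local maxima above thresholds; area = trapezoidal integral of the
    baseline-subtracted signal between the enclosing prominence minima."""
    if c.time.size < 3:
        raise ValueError("need at least 3 time points")
    idx, props = find_peaks(c.signal, height=min_height or None,
                            prominence=min_prominence)
    if idx.size == 0:
        return PeakTable(c.sample_id, pd.DataFrame(
            columns=["rt", "area", "height", "left", "right"]))
    prom, left_bases, right_bases = peak_prominences(c.signal, idx)
    rows = []
    for p, lb, rb in zip(idx, left_bases, right_bases):
        t = c.time[lb:rb + 1]
        y = c.signal[lb:rb + 1]
        baseline = np.interp(t, [c.time[lb], c.time[rb]],
                             [c.signal[lb], c.signal[rb]])
        area = float(np.trapezoid(y - baseline, t))
        if area <= 0:
            continue
        rows.append({"rt": float(c.time[p]), "area": area,
                     "height": float(c.signal[p]),
                     "left": float(c.time[lb]), "right": float(c.time[rb])})
    return PeakTable(c.sample_id, pd.DataFrame(rows))


def rt_correct(tables: list[PeakTable], anchors, window: float = 0.5
               ) -> list[PeakTable]:
    """Piecewise-linear retention-time warp through matched anchor peaks.

    Each sample's nearest peak within ``window`` minutes of each anchor is
    taken as the match; the warp maps matched times onto the anchor times
    and extends linearly outside the anchor span.  Samples matching fewer
    than 2 anchors are left uncorrected with a warning.
    """
    anchors = np.sort(np.asarray(anchors, dtype=float))
    if anchors.size < 2:
        raise ValueError("need at least 2 anchors spanning the run")
    out = []
    for t in tables:
        rts = t.peaks["rt"].to_numpy()
        matched_obs, matched_ref = [], []
        for a in anchors:
            if rts.size == 0:
                break
            j = int(np.argmin(np.abs(rts - a)))
            if abs(rts[j] - a) <= window:
                matched_obs.append(rts[j])
                matched_ref.append(a)
        if len(matched_obs) < 2:
            logger.warning("sample %s matched %d anchors; left uncorrected",
                           t.sample_id, len(matched_obs))
            out.append(t)
            continue
        obs = np.asarray(matched_obs)
        ref = np.asarray(matched_ref)
        # piecewise-linear interior; linear extension beyond the end anchors
        def warp(x, obs=obs, ref=ref):
            y = np.interp(x, obs, ref)
            lo, hi = obs[0], obs[-1]
            s_lo = (ref[1] - ref[0]) / (obs[1] - obs[0])
            s_hi = (ref[-1] - ref[-2]) / (obs[-1] - obs[-2])
            y = np.where(x < lo, ref[0] + s_lo * (x - lo), y)
            y = np.where(x > hi, ref[-1] + s_hi * (x - hi), y)
            return y
        p = t.peaks.copy()
        for col in ("rt", "left", "right"):
            p[col] = warp(p[col].to_numpy())
        out.append(PeakTable(t.sample_id, p))
    return out


def match_common_peaks(tables: list[PeakTable], rt_window: float = 0.3
                       ) -> pd.DataFrame:
    """Greedy retention-time clustering; a *common peak* is a cluster holding
    exactly one peak from every sample.

    Returns a samples × common-peaks DataFrame of areas, columns labelled by
    the cluster's consensus (mean) retention time.
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 samples")
    records = []
    for t in tables:
        for _, row in t.peaks.iterrows():
            records.append((row["rt"], t.sample_id, row["area"]))
    records.sort(key=lambda r: r[0])
    clusters: list[list[tuple[float, str, float]]] = []
    for rec in records:
        if clusters and rec[0] - clusters[-1][0][0] <= rt_window:
            clusters[-1].append(rec)
        else:
            clusters.append([rec])
    sample_ids = [t.sample_id for t in tables]
    cols = {}
    for cl in clusters:
        ids = [r[1] for r in cl]
        if sorted(ids) == sorted(sample_ids):
            rt = float(np.mean([r[0] for r in cl]))
            areas = {r[1]: r[2] for r in cl}
            cols[round(rt, 4)] = [areas[s] for s in sample_ids]
    if not cols:
        raise ValueError("no common peaks found; consider a larger rt_window")
    m = pd.DataFrame(cols, index=sample_ids)
    return m[sorted(m.columns)]


def reference_vector(m: pd.DataFrame, method: str = "median") -> pd.Series:
    """Reference fingerprint: column-wise median (or mean) of the areas."""
    if method == "median":
        return m.median(axis=0)
    if method == "mean":
        return m.mean(axis=0)
    raise ValueError(f"unknown reference method {method!r}")


def cosine_similarity(a, b) -> float:
    """Included-angle cosine a·b/(‖a‖‖b‖); in [0,1] for nonnegative vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have the same length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cannot compute similarity with a zero vector")
    return float(a @ b / (na * nb))


def _correlation_similarity(a, b) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.corrcoef(a, b)[0, 1])


def similarity_matrix(m: pd.DataFrame, method: str = "cosine",
                      reference: str = "median") -> pd.DataFrame:
    """All pairwise sample similarities plus each sample vs the reference R."""
    fn = cosine_similarity if method == "cosine" else _correlation_similarity
    ref = reference_vector(m, reference)
    labels = list(m.index) + ["R"]
    vecs = [m.loc[s].to_numpy() for s in m.index] + [ref.to_numpy()]
    n = len(vecs)
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = fn(vecs[i], vecs[j])
    return pd.DataFrame(out, index=labels, columns=labels)


@dataclass
class PCASelection:
    eigenvalues: np.ndarray
    cumulative_variance_pct: np.ndarray
    n_retained: int
    loadings: pd.DataFrame       # peaks × retained components
    selected_peaks: list
    dropped_constant: list


def pca_select_peaks(m: pd.DataFrame, eig_min: float = 1.0,
                     loading_min: float = 0.8) -> PCASelection:
    """Correlation-matrix PCA on standardized areas; retain components with
    eigenvalue ≥ ``eig_min``; select peaks with |loading| > ``loading_min``
    on at least one retained component (loading = eigenvector·√eigenvalue)."""
    if len(m) < 3 or m.shape[1] < 2:
        raise ValueError("need at least 3 samples and 2 peaks")
    sd = m.std(axis=0, ddof=1)
    constant = list(m.columns[sd == 0])
    for c in constant:
        logger.warning("constant peak column %r dropped from PCA", c)
    mm = m.drop(columns=constant)
    corr = np.corrcoef(mm.to_numpy(), rowvar=False)
    vals, vecs = np.linalg.eigh(corr)
    order = np.argsort(vals)[::-1]
    vals = np.clip(vals[order], 0.0, None)
    vecs = vecs[:, order]
    cumvar = 100.0 * np.cumsum(vals) / vals.sum()
    n_ret = int(np.sum(vals >= eig_min))
    load = vecs[:, :n_ret] * np.sqrt(vals[:n_ret])
    loadings = pd.DataFrame(load, index=mm.columns,
                            columns=[f"PC{i + 1}" for i in range(n_ret)])
    sel = [p for p in mm.columns
           if n_ret and np.any(np.abs(loadings.loc[p]) > loading_min)]
    return PCASelection(vals, cumvar, n_ret, loadings, sel, constant)
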