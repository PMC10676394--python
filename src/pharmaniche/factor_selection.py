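"""Iterative ecological-variable selection.

The procedure mirrors common SDM practice: (1) refit the maxent model
repeatedly, discarding layers whose percent contribution is effectively zero,
until every remaining layer contributes; (2) prune collinear pairs
(|Pearson r| above a threshold, computed at the presence points) by dropping
the member with the smaller contribution; (3) take the consensus of the
contribution, permutation-importance and jackknife rankings as the "main"
factors and report their cumulative contribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .io_geo import EnvStack, OccurrenceSet, extract_values
from .sdm_maxent import (fit_maxent, jackknife_gains, percent_contribution,
                         permutation_importance, sample_background)

logger = logging.getLogger(__name__)

__all__ = [
    "SelectionResult",
    "iterate_drop_zero",
    "pearson_prune",
    "consensus_main_factors",
    "cumulative_contribution",
    "select_factors",
    "load_table2",
]

#: contribution below this (%) counts as zero in the iterative drop
ZERO_EPS = 0.05


@dataclass
class SelectionResult:
    surviving_factors: list[str]
    dropped_zero: list[tuple[str, int]] = field(default_factory=list)
    dropped_collinear: list[tuple[str, str, float]] = field(default_factory=list)
    main_factors: list[str] = field(default_factory=list)
    cumulative_contribution: float = 0.0
    contributions: pd.Series | None = None


def iterate_drop_zero(occ: OccurrenceSet, stack: EnvStack,
                      reg_multiplier: float = 1.0, max_iter: int = 300,
                      n_background: int = 10_000, seed: int = 0,
                      eps: float = ZERO_EPS) -> SelectionResult:
    """Refit and discard zero-contribution layers until all contribute."""
    if len(stack) < 2:
        return SelectionResult(surviving_factors=stack.names)
    surviving = list(stack.names)
    dropped: list[tuple[str, int]] = []
    iteration = 0
    contrib = None
    while len(surviving) > 1:
        iteration += 1
        sub = stack.subset(surviving)
        bg = sample_background(sub, n_background, seed=seed)
        tab = extract_values(sub, occ)
        tab = tab[tab["valid"]]
        kinds = {l.name: l.kind for l in sub.layers}
        model = fit_maxent(tab, bg, kinds, reg_multiplier=reg_multiplier,
                           max_iter=max_iter, seed=seed)
        contrib = percent_contribution(model)
        zero = [n for n in surviving if contrib.get(n, 0.0) < eps]
        if not zero:
            break
        for n in zero:
            dropped.append((n, iteration))
        surviving = [n for n in surviving if n not in zero]
    return SelectionResult(surviving_factors=surviving, dropped_zero=dropped,
                           contributions=contrib)


def pearson_prune(values: pd.DataFrame, contributions: pd.Series,
                  r_threshold: float = 0.8,
                  categorical: set[str] | None = None) -> SelectionResult:
    """Drop the weaker member of each highly correlated continuous pair.

    Pairs with |r| > threshold are processed in decreasing |r| order; in each
    surviving pair the member with the smaller percent contribution is
    dropped.  Categorical factors are exempt.  The outcome is independent of
    input column order (ties broken by contribution, then name).
    """
    if not (0 < r_threshold < 1):
        raise ValueError("r_threshold must lie in (0, 1)")
    categorical = categorical or set()
    names = [c for c in contributions.index if c in values.columns]
    cont = [n for n in names if n not in categorical]
    sub = values[cont].astype(float)
    const = [c for c in cont if sub[c].std() == 0]
    for c in const:
        logger.warning("constant column %r: correlation treated as 0", c)
    corr = sub.corr().fillna(0.0)

    pairs = []
    for i, a in enumerate(cont):
        for b in cont[i + 1:]:
            r = float(corr.loc[a, b])
            if abs(r) > r_threshold:
                pairs.append((abs(r), a, b, r))
    # decreasing |r|; deterministic tie-break on names
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))

    dropped: list[tuple[str, str, float]] = []
    gone: set[str] = set()
    for _, a, b, r in pairs:
        if a in gone or b in gone:
            continue
        ca, cb = contributions.get(a, 0.0), contributions.get(b, 0.0)
        if ca < cb or (ca == cb and a > b):
            weaker, keeper = a, b
        else:
            weaker, keeper = b, a
        gone.add(weaker)
        dropped.append((weaker, keeper, r))
    surviving = [n for n in names if n not in gone]
    return SelectionResult(surviving_factors=surviving, dropped_collinear=dropped,
                           contributions=contributions[surviving])


def consensus_main_factors(contribution: pd.Series, permutation: pd.Series,
                           jackknife: pd.Series, top_k: int = 10
                           ) -> tuple[list[str], float]:
    """Intersection of the top-k factors of the three rankings, ordered by
    contribution, plus their cumulative percent contribution."""
    tops = [set(s.sort_values(ascending=False).index[:top_k])
            for s in (contribution, permutation, jackknife)]
    common = tops[0] & tops[1] & tops[2]
    if not common:
        raise ValueError(
            f"no factor is in the top {top_k} of all three rankings; "
            "increase top_k")
    main = [n for n in contribution.sort_values(ascending=False).index
            if n in common]
    return main, cumulative_contribution(main, contribution)


def cumulative_contribution(factors: list[str], table: pd.Series | pd.DataFrame) -> float:
    """Sum of the percent contributions of the named factors."""
    if isinstance(table, pd.DataFrame):
        table = table["percent_contribution"]
    missing = [f for f in factors if f not in table.index]
    if missing:
        raise KeyError(f"factors absent from the contribution table: {missing}")
    return float(table.loc[list(factors)].sum())


def select_factors(occ: OccurrenceSet, stack: EnvStack, r_threshold: float = 0.8,
                   top_k: int = 10, reg_multiplier: float = 1.0,
                   max_iter: int = 300, n_background: int = 10_000,
                   seed: int = 0, n_perm: int = 3) -> SelectionResult:
    """The full pipeline: drop-zero iteration → collinearity pruning →
    refit → consensus main factors."""
    step1 = iterate_drop_zero(occ, stack, reg_multiplier, max_iter,
                              n_background, seed)
    sub = stack.subset(step1.surviving_factors)
    tab = extract_values(sub, occ)
    tab = tab[tab["valid"]]
    categorical = {l.name for l in sub.layers if l.kind == "categorical"}
    step2 = pearson_prune(tab, step1.contributions, r_threshold, categorical)

    final = stack.subset(step2.surviving_factors)
    kinds = {l.name: l.kind for l in final.layers}
    bg = sample_background(final, n_background, seed=seed)
    ftab = extract_values(final, occ)
    ftab = ftab[ftab["valid"]]
    model = fit_maxent(ftab, bg, kinds, reg_multiplier=reg_multiplier,
                       max_iter=max_iter, seed=seed)
    contrib = percent_contribution(model)
    perm = permutation_importance(model, ftab, bg, n_perm=n_perm, seed=seed)
    jk = jackknife_gains(ftab, bg, kinds, reg_multiplier=reg_multiplier,
                         max_iter=max(50, max_iter // 4), seed=seed)
    k = min(top_k, len(contrib))
    main, cum = consensus_main_factors(contrib, perm, jk["gain_with_only"], top_k=k)
    return SelectionResult(
        surviving_factors=step2.surviving_factors,
        dropped_zero=step1.dropped_zero,
        dropped_collinear=step2.dropped_collinear,
        main_factors=main,
        cumulative_contribution=cum,
        contributions=contrib,
    )


def load_table2() -> pd.DataFrame:
    """The published 15-factor contribution/importance table shipped with the
    package, indexed by factor code, with a ``main_factor`` flag."""
    with resources.files("pharmaniche.data").joinpath(
            "table2_contributions.csv").open() as fh:
        df = pd.read_csv(fh)
    return df.set_index("factor")
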