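"""Sensitive-feature screening: ANOVA F-filter, SPA, and ranked SFS.

Three complementary reductions of the index bank:

* **ANOVA** keeps features whose one-way F statistic across the four
  damage levels exceeds a critical value (default: the upper-tail F
  quantile at a very small p; an explicit F override is supported since
  published thresholds do not always state their dof convention).
* **SPA** (successive projections algorithm) greedily grows a chain of
  features, at each step adding the candidate with the largest
  projection onto the orthogonal complement of the span of the chain —
  minimising collinearity.  Chains from every start feature are scored
  by cross-validated RMSE of a linear regression of the ordinal damage
  level (1–4) on the subset; the chosen size is the smallest within a
  relative tolerance of the global minimum RMSE.
* **SFS** ranks features by random-forest permutation importance (mean
  decrease in accuracy on out-of-fold data) and walks prefixes of the
  ranking, choosing the prefix with maximal cross-validated accuracy and
  fewest features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import KFold, StratifiedKFold

from pestspec.features import FeatureTable


@dataclass
class SelectionResult:
    """A selected feature subset plus method diagnostics."""

    method: str  # ANOVA | SPA | SFS
    selected: list[str]
    diagnostics: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.selected:
            raise ValueError("selection produced an empty subset")

    def to_dict(self) -> dict:
        def _clean(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, (np.floating, np.integer)):
                return v.item()
            if isinstance(v, dict):
                return {k: _clean(x) for k, x in v.items()}
            if isinstance(v, (list, tuple)):
                return [_clean(x) for x in v]
            return v

        return {
            "method": self.method,
            "selected": list(self.selected),
            "diagnostics": _clean(self.diagnostics),
            "seed": self.seed,
        }


# ----------------------------------------------------------------- ANOVA

def anova_f(values, labels) -> float:
    """One-way ANOVA F statistic: between-class over within-class mean square.

    Returns ``inf`` when the within-class variance is zero but class
    means differ, and ``nan`` when all values are identical.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    n = len(values)
    grand = values.mean()
    ssb = 0.0
    ssw = 0.0
    for c in classes:
        v = values[labels == c]
        if len(v) < 2:
            raise ValueError("each class needs at least 2 samples")
        m = v.mean()
        ssb += len(v) * (m - grand) ** 2
        ssw += ((v - m) ** 2).sum()
    k = len(classes)
    msb = ssb / (k - 1)
    msw = ssw / (n - k)
    if msw == 0.0:
        return np.nan if msb == 0.0 else np.inf
    return msb / msw


def critical_f(df1: int, df2: int, p: float) -> float:
    """Upper-tail quantile of the F(df1, df2) distribution."""
    if df1 < 1 or df2 < 1:
        raise ValueError("degrees of freedom must be >= 1")
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie in (0, 1)")
    return float(stats.f.isf(p, df1, df2))


def filter_by_f(f_values: dict[str, float] | pd.Series, threshold: float):
    """Keep features with F strictly greater than the threshold.

    Returns ``(selected, excluded)`` preserving input order.  This is
    the exclusion rule used by :func:`anova_filter`; it is exposed so a
    precomputed F map (e.g. one printed in a report) can be filtered
    directly.
    """
    if isinstance(f_values, pd.Series):
        items = list(f_values.items())
    else:
        items = list(f_values.items())
    selected = [k for k, v in items if v > threshold]
    excluded = [k for k, v in items if not (v > threshold)]
    return selected, excluded


def anova_filter(
    table: FeatureTable,
    p_threshold: float = 1e-10,
    f_override: float | None = None,
) -> SelectionResult:
    """ANOVA F-filter over a feature table.

    The threshold defaults to ``critical_f(k-1, n-k, p_threshold)``;
    ``f_override`` replaces it when given.  Diagnostics carry every
    per-feature F plus both thresholds.
    """
    y = table.labels.to_numpy()
    k = len(np.unique(y))
    n = table.n_samples
    fmap = {
        name: anova_f(table.values[name].to_numpy(), y)
        for name in table.feature_names
    }
    computed = critical_f(k - 1, n - k, p_threshold)
    threshold = f_override if f_override is not None else computed
    selected, excluded = filter_by_f(fmap, threshold)
    if not selected:
        raise ValueError("no feature exceeded the ANOVA threshold")
    return SelectionResult(
        method="ANOVA",
        selected=selected,
        diagnostics={
            "f_values": fmap,
            "critical_f_computed": computed,
            "threshold_used": float(threshold),
            "p_threshold": p_threshold,
            "excluded": excluded,
        },
    )


# ------------------------------------------------------------------- SPA

class ChainResult(NamedTuple):
    indices: list[int]
    truncated: bool


def spa_chain(X: np.ndarray, start: int, m: int) -> ChainResult:
    """Greedy successive-projections chain of column indices.

    At each step every unselected column is projected onto the
    orthogonal complement of the span of the selected columns and the
    column with the largest residual norm joins the chain (ties break
    toward the lowest index).  Implemented by iterative deflation; the
    chain truncates (flagged) when all remaining residuals are
    numerically zero.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if not 1 <= m <= p:
        raise ValueError("chain length m must be in [1, n_features]")
    if not 0 <= start < p:
        raise ValueError("start index out of range")
    R = X.copy()
    tol = 1e-10 * max(np.linalg.norm(X, axis=0).max(), 1.0)
    chain = [start]
    for _ in range(m - 1):
        s = R[:, chain[-1]].copy()
        ns = np.linalg.norm(s)
        if ns <= tol:
            return ChainResult(chain, True)
        s /= ns
        R -= np.outer(s, s @ R)  # deflate every column by the new direction
        norms = np.linalg.norm(R, axis=0)
        norms[chain] = -1.0
        best = int(np.argmax(norms))  # argmax breaks ties toward lowest index
        if norms[best] <= tol:
            return ChainResult(chain, True)
        chain.append(best)
    return ChainResult(chain, False)


def _cv_rmse(X, y, cv) -> float:
    errs = []
    for tr, te in cv:
        model = LinearRegression().fit(X[tr], y[tr])
        resid = y[te] - model.predict(X[te])
        errs.append(resid)
    resid = np.concatenate(errs)
    return float(np.sqrt(np.mean(resid**2)))


def spa_select(
    table: FeatureTable,
    size_range: tuple[int, int] | None = None,
    cv_folds: int = 5,
    rel_tol: float = 0.01,
    abs_tol: float = 0.01,
    max_starts: int | None = None,
    seed: int = 0,
) -> SelectionResult:
    """SPA feature selection scored by CV RMSE of an ordinal regression.

    Chains are grown from every start feature (optionally capped); each
    subset size is scored by ``cv_folds``-fold cross-validated RMSE of a
    linear regression of the damage level (1–4) on the standardized
    subset.  The chosen size is the smallest whose best RMSE is within
    ``max(rel_tol * min_rmse, abs_tol)`` of the global minimum RMSE: the
    relative tolerance expresses "near-minimum with fewest features",
    while the absolute floor (default 0.01 on the 1–4 level scale) keeps
    the rule stable when the minimum RMSE approaches zero and relative
    comparisons degenerate into noise-chasing.
    """
    y = table.labels.to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("response is degenerate (single class)")
    names = table.feature_names
    p = len(names)
    lo, hi = size_range if size_range is not None else (1, min(p, 25))
    if not (1 <= lo <= hi <= p):
        raise ValueError("size_range out of bounds")
    X = table.values.to_numpy(dtype=float)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    Xs = (X - mu) / sd
    rng_seed = seed % (2**31)
    cv = list(KFold(cv_folds, shuffle=True, random_state=rng_seed).split(Xs))
    starts = range(p) if max_starts is None else range(min(p, max_starts))
    sizes = list(range(lo, hi + 1))
    best_rmse = {m: np.inf for m in sizes}
    best_subset = {m: None for m in sizes}
    for start in starts:
        chain, _ = spa_chain(Xs, start, hi)
        for m in sizes:
            if len(chain) < m:
                break
            idx = chain[:m]
            rmse = _cv_rmse(Xs[:, idx], y, cv)
            if rmse < best_rmse[m]:
                best_rmse[m] = rmse
                best_subset[m] = idx
    curve = np.array([best_rmse[m] for m in sizes])
    gmin = curve.min()
    ok = np.flatnonzero(curve <= gmin + max(rel_tol * gmin, abs_tol))
    chosen_m = sizes[int(ok[0])]
    idx = best_subset[chosen_m]
    return SelectionResult(
        method="SPA",
        selected=[names[i] for i in idx],
        diagnostics={
            "sizes": sizes,
            "rmse_curve": curve,
            "chosen_size": chosen_m,
            "min_rmse": float(gmin),
            "rmse_at_chosen": float(curve[ok[0]]),
            "rel_tol": rel_tol,
            "abs_tol": abs_tol,
        },
        seed=seed,
    )


# ------------------------------------------------------------------- SFS

def sfs_select(
    table: FeatureTable,
    cv_folds: int = 5,
    n_repeats: int = 10,
    n_estimators: int = 100,
    seed: int = 0,
) -> SelectionResult:
    """Importance-ranked sequential forward selection.

    Features are ranked by random-forest permutation importance (mean
    decrease in accuracy on held-out folds, averaged over ``n_repeats``
    shuffles and ``cv_folds`` folds), then added in rank order while the
    cross-validated accuracy of a random forest on each prefix is
    recorded.  The returned subset is the prefix with maximal accuracy,
    ties broken toward fewer features (and by ranking order, i.e. table
    column order under equal importance, for determinism).
    """
    y = table.labels.to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes")
    if cv_folds < 2:
        raise ValueError("cv_folds must be >= 2")
    names = table.feature_names
    X = table.values.to_numpy(dtype=float)
    rng_seed = seed % (2**31)
    skf = StratifiedKFold(cv_folds, shuffle=True, random_state=rng_seed)
    folds = list(skf.split(X, y))
    imp = np.zeros(len(names))
    for f, (tr, te) in enumerate(folds):
        rf = RandomForestClassifier(
            n_estimators=n_estimators, random_state=rng_seed + f, n_jobs=1
        ).fit(X[tr], y[tr])
        r = permutation_importance(
            rf, X[te], y[te], n_repeats=n_repeats,
            random_state=rng_seed + f, scoring="accuracy", n_jobs=1,
        )
        imp += r.importances_mean
    imp /= len(folds)
    order = np.lexsort((np.arange(len(names)), -imp))  # desc, stable in input order
    curve = np.empty(len(names))
    for m in range(1, len(names) + 1):
        cols = order[:m]
        accs = []
        for f, (tr, te) in enumerate(folds):
            rf = RandomForestClassifier(
                n_estimators=n_estimators, random_state=rng_seed + f, n_jobs=1
            ).fit(X[tr][:, cols], y[tr])
            accs.append(rf.score(X[te][:, cols], y[te]))
        curve[m - 1] = np.mean(accs)
    best_m = int(np.argmax(curve)) + 1  # argmax -> first max -> fewest features
    return SelectionResult(
        method="SFS",
        selected=[names[i] for i in order[:best_m]],
        diagnostics={
            "importances": {names[i]: float(imp[i]) for i in order},
            "ranking": [names[i] for i in order],
            "accuracy_curve": curve,
            "chosen_size": best_m,
            "accuracy": float(curve[best_m - 1]),
        },
        seed=seed,
    )
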