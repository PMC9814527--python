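"""Model selection: feature subsets, k-fold CV, grid search, outliers.

The selection protocol evaluates every nonempty subset of the five
fragment bonds (31 subsets for 5 features) for each regression method,
scoring each candidate by 7-fold cross-validated RMSEE on the training
set, with a per-subset hyperparameter grid search where the method has
tunables.  Cross-validated errors are aggregated by pooling the held-out
residuals across folds (the fold-averaged RMSE is retained alongside).

Ties break deterministically: fewer features, then smaller canonical
subset id, then smaller hyperparameter magnitudes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from . import models
from .dataset import Dataset
from .errors import DegenerateFitError
from .geometry import BOND_ROMAN, FEATURE_NAMES
from .models import fit_ols_single

__all__ = [
    "FeatureSubset", "CVResult", "OutlierReport", "SelectionReport",
    "DEFAULT_GRIDS", "enumerate_subsets", "kfold_cv", "grid_search",
    "select_best_per_method", "flag_outliers", "discover_subseries",
]

#: Hyperparameter grids bracketing the reported optima for each method.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "OLS": {},
    "PLS": {},  # n_latent grid is subset-size dependent; built on the fly
    "SVR_linear": {"C": [1, 10, 100, 1000], "epsilon": [0.01, 0.1, 1]},
    "SVR_rbf": {"C": [1, 10, 100, 1000], "epsilon": [0.01, 0.1, 1],
                "gamma": [0.5, 1, 5, 10]},
    "RFR": {"n_estimators": [10, 25, 50, 100], "max_depth": [2, 4, 6, 8]},
    "GPR_rbf": {},
}


@dataclass(frozen=True)
class FeatureSubset:
    """A nonempty subset of the five bonds, in canonical enumeration order
    (by size, then lexicographically by member indices; ids are 1-based)."""

    model_id: int
    members: tuple[int, ...]          # 0-based feature indices

    @property
    def labels(self) -> tuple[str, ...]:
        """Roman-numeral bond labels (i-v) when five features are in play."""
        return tuple(BOND_ROMAN[m] for m in self.members)

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(FEATURE_NAMES[m] for m in self.members)


def enumerate_subsets(n_features: int) -> list[FeatureSubset]:
    """All 2^n - 1 nonempty feature subsets in canonical order."""
    if not (1 <= n_features <= 16):
        raise ValueError("n_features must lie in [1, 16]")
    out, mid = [], 1
    for size in range(1, n_features + 1):
        for combo in itertools.combinations(range(n_features), size):
            out.append(FeatureSubset(model_id=mid, members=combo))
            mid += 1
    return out


@dataclass
class CVResult:
    subset: FeatureSubset
    method: str
    hyperparams: dict
    per_fold_rmse: list[float]
    rmsee_cv: float              # pooled held-out residuals
    mae_cv: float
    rmsee_fold_mean: float       # mean of per-fold RMSEs, for comparison
    fold_seed: int


def _fit_method(method: str, X, y, hyperparams: dict, seed: int):
    if method == "OLS":
        return models.fit_ols_multi(X, y)
    if method == "PLS":
        return models.fit_pls(X, y, n_latent=hyperparams.get("n_latent", 1))
    if method == "SVR_linear":
        return models.fit_svr(X, y, kernel="linear", **hyperparams)
    if method == "SVR_rbf":
        return models.fit_svr(X, y, kernel="rbf", **hyperparams)
    if method == "RFR":
        return models.fit_rfr(X, y, seed=seed, **hyperparams)
    if method == "GPR_rbf":
        return models.fit_gpr(X, y, restarts=hyperparams.get("restarts", 5),
                              seed=seed)
    raise ValueError(f"unknown method {method!r}")


def _folds(n: int, k: int, seed: int) -> list[np.ndarray]:
    # seeded shuffle then contiguous chunking; sizes differ by at most one
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    return [np.sort(chunk) for chunk in np.array_split(order, k)]


def kfold_cv(ds: Dataset, subset: FeatureSubset, method: str,
             hyperparams: dict | None = None, k: int = 7,
             seed: int = 0) -> CVResult:
    """k-fold cross-validation of one (subset, method, hyperparams) choice.

    Records are keyed by id (sorted before shuffling), so fold membership
    is invariant to the order of records in the dataset.
    """
    hyperparams = dict(hyperparams or {})
    recs = sorted(ds.usable(), key=lambda r: r.id)
    n = len(recs)
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"training size {n} smaller than k={k}")
    X, y, _ = ds.feature_matrix(recs)
    X = X[:, list(subset.members)]
    per_fold_rmse, sq, ab = [], [], []
    for test_idx in _folds(n, k, seed):
        mask = np.zeros(n, dtype=bool)
        mask[test_idx] = True
        model = _fit_method(method, X[~mask], y[~mask], hyperparams, seed)
        resid = model.predict(X[mask]) - y[mask]
        per_fold_rmse.append(float(np.sqrt(np.mean(resid ** 2))))
        sq.extend((resid ** 2).tolist())
        ab.extend(np.abs(resid).tolist())
    return CVResult(
        subset=subset, method=method, hyperparams=hyperparams,
        per_fold_rmse=per_fold_rmse,
        rmsee_cv=float(np.sqrt(np.mean(sq))),
        mae_cv=float(np.mean(ab)),
        rmsee_fold_mean=float(np.mean(per_fold_rmse)),
        fold_seed=seed,
    )


def _complexity_key(hp: dict) -> tuple:
    return tuple(abs(float(hp[name])) for name in sorted(hp))


def grid_search(ds: Dataset, subset: FeatureSubset, method: str,
                grid: dict[str, list] | None = None, k: int = 7,
                seed: int = 0) -> tuple[dict, CVResult]:
    """Exhaustive grid evaluation; returns the RMSEE-minimising point.

    ``grid=None`` uses the method's default grid (for PLS, latent-variable
    counts 1..subset size).  Ties go to the smaller hyperparameter
    magnitudes.
    """
    if grid is None:
        grid = dict(DEFAULT_GRIDS.get(method, {}))
        if method == "PLS":
            grid = {"n_latent": list(range(1, len(subset.members) + 1))}
    if method not in ("OLS", "GPR_rbf") and not grid:
        raise ValueError("empty hyperparameter grid")
    points = [dict(zip(grid, vals)) for vals in itertools.product(*grid.values())] \
        if grid else [{}]
    best: tuple | None = None
    for hp in points:
        res = kfold_cv(ds, subset, method, hp, k=k, seed=seed)
        key = (res.rmsee_cv, _complexity_key(hp))
        if best is None or key < best[0]:
            best = (key, hp, res)
    return best[1], best[2]


@dataclass
class SelectionReport:
    """Best configuration per method plus the full per-subset table."""

    best: dict[str, tuple[FeatureSubset, dict, CVResult]]
    table: dict[str, list[CVResult]] = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd
        rows = []
        for method, results in self.table.items():
            for r in results:
                rows.append({
                    "method": method, "model_id": r.subset.model_id,
                    "features": "+".join(r.subset.labels),
                    "hyperparams": repr(r.hyperparams),
                    "rmsee_cv": r.rmsee_cv, "mae_cv": r.mae_cv,
                })
        return pd.DataFrame(rows)


def select_best_per_method(ds: Dataset, methods=("OLS",), k: int = 7,
                           seed: int = 0,
                           grids: dict[str, dict] | None = None
                           ) -> SelectionReport:
    """Exhaustive subset x grid selection, one winner per method.

    Every nonempty subset of the five bonds is scored by grid-searched
    k-fold RMSEE; the full 31-row table per method is retained for
    reporting.  Subset ties break toward fewer features, then the smaller
    canonical subset id.
    """
    n_features = 5
    subsets = enumerate_subsets(n_features)
    best, table = {}, {}
    for method in methods:
        rows = []
        winner: tuple | None = None
        for sub in subsets:
            grid = (grids or {}).get(method)
            hp, res = grid_search(ds, sub, method, grid=grid, k=k, seed=seed)
            rows.append(res)
            key = (res.rmsee_cv, len(sub.members), sub.model_id)
            if winner is None or key < winner[0]:
                winner = (key, sub, hp, res)
        best[method] = (winner[1], winner[2], winner[3])
        table[method] = rows
    return SelectionReport(best=best, table=table)


@dataclass
class OutlierReport:
    compound_id: str
    residuals: list[float]           # one per bond i-v, predicted - observed
    n_bonds_exceeding: int
    threshold: float
    flagged: bool


def flag_outliers(ds: Dataset, threshold: float = 1.5,
                  n_bonds_required: int = 4) -> list[OutlierReport]:
    """Flag compounds inconsistent with every single-bond trend.

    Each of the five bonds gets its own OLS line fitted on all usable
    records; a compound is flagged when its absolute residual exceeds
    ``threshold`` pKa units for at least ``n_bonds_required`` of the five
    bonds.  This is the rule that isolates records whose measured pKa does
    not report on the keto-enol dissociation.
    """
    recs = ds.usable()
    X, y, ids = ds.feature_matrix(recs)
    if len(recs) < 3:
        raise DegenerateFitError("need at least 3 usable records")
    bond_models = [fit_ols_single(X[:, j], y, BOND_ROMAN[j]) for j in range(5)]
    reports = []
    for i, cid in enumerate(ids):
        resid = [float(m.predict(X[i, j])[0] - y[i])
                 for j, m in enumerate(bond_models)]
        n_exc = sum(abs(r) > threshold for r in resid)
        reports.append(OutlierReport(
            compound_id=cid, residuals=resid, n_bonds_exceeding=n_exc,
            threshold=threshold, flagged=n_exc >= n_bonds_required))
    return reports


def discover_subseries(ds: Dataset, motif_label: str,
                       member_ids: list[str]) -> tuple[float, float, float]:
    """Fit the (r_CO, pKa) line through a motif-sharing subset.

    Compounds sharing a structural motif (e.g. a 5-C=O group) can sit on
    their own high-correlation line below the global trend; this returns
    (slope, intercept, r2) of that line.
    """
    if len(member_ids) < 3:
        raise ValueError("need at least 3 member ids")
    recs = []
    for cid in member_ids:
        r = ds[cid]
        if r.features is None:
            raise ValueError(f"{cid}: member has no features")
        recs.append(r)
    x = np.array([r.features.r_CO for r in recs])
    y = np.array([r.pka_exp for r in recs])
    m = fit_ols_single(x, y, "ii")
    return m.slope, m.intercept, m.r2_train
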