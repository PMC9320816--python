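"""Repeated split-sample validation with shared splits across methods.

The protocol: one fixed sequence of random 70/30 train/test splits is drawn
from the seed and reused for *every* selection method and every model size,
so MAE differences between methods are never attributable to different test
sets.  Per iteration the feature ranking is recomputed on the training rows
only, features are centered with the training means, the VIF-gated model is
fitted on the training rows and evaluated on the test rows.  Pooled
(actual, predicted) pairs across iterations feed the paired t-test and
Cohen's d summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateStatisticError, RollgaitError
from .models import VifGatedRegressor, cohens_d, mae, paired_t
from .registry import FEATURE_NAMES
from .selection import make_selector

__all__ = ["ValidationReport", "ValidationSummary", "make_splits", "validate"]

DEFAULT_METHODS = ("lasso", "f_test", "relieff")


def make_splits(
    n_rows: int,
    n_iterations: int,
    train_fraction: float,
    rng: np.random.Generator,
    groups: Sequence | None = None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """A fixed sequence of train/test index partitions.

    Row-level splits take ``ceil(train_fraction * n_rows)`` training rows.
    When ``groups`` is given (e.g. subject labels), whole groups are assigned
    to one side so no subject straddles the split.
    """
    if not (0 < train_fraction < 1):
        raise ValueError("train_fraction must lie in (0, 1)")
    splits = []
    if groups is not None:
        groups = np.asarray(groups)
        unique = np.unique(groups)
        n_train_groups = math.ceil(train_fraction * len(unique))
        for _ in range(n_iterations):
            perm = rng.permutation(unique)
            train_groups = set(perm[:n_train_groups])
            mask = np.array([g in train_groups for g in groups])
            splits.append((np.flatnonzero(mask), np.flatnonzero(~mask)))
    else:
        n_train = math.ceil(train_fraction * n_rows)
        for _ in range(n_iterations):
            perm = rng.permutation(n_rows)
            splits.append((np.sort(perm[:n_train]), np.sort(perm[n_train:])))
    return splits


@dataclass
class ValidationReport:
    """Out-of-sample performance of one (method, model size) combination."""

    method: str
    n_features: int
    outcome: str
    mae_per_iteration: np.ndarray
    pooled_actual: np.ndarray
    pooled_predicted: np.ndarray
    n_iterations_used: int
    split_indices: list[tuple[np.ndarray, np.ndarray]] = field(repr=False, default_factory=list)

    @property
    def mean_mae(self) -> float:
        return float(np.mean(self.mae_per_iteration)) if self.mae_per_iteration.size else float("nan")

    def t_test(self) -> tuple[float, float]:
        return paired_t(self.pooled_actual, self.pooled_predicted)

    def effect_size(self) -> float:
        return cohens_d(self.pooled_actual, self.pooled_predicted)

    def summary(self) -> dict:
        out = {
            "method": self.method,
            "n_features": self.n_features,
            "outcome": self.outcome,
            "mean_mae": self.mean_mae,
            "n_iterations_used": self.n_iterations_used,
            "actual_mean": float(np.mean(self.pooled_actual)) if self.pooled_actual.size else None,
            "actual_sd": float(np.std(self.pooled_actual, ddof=1)) if self.pooled_actual.size > 1 else None,
            "predicted_mean": float(np.mean(self.pooled_predicted)) if self.pooled_predicted.size else None,
            "predicted_sd": float(np.std(self.pooled_predicted, ddof=1)) if self.pooled_predicted.size > 1 else None,
        }
        try:
            t, p = self.t_test()
            out["t_statistic"], out["p_value"] = t, p
        except (DegenerateStatisticError, ValueError):
            out["t_statistic"] = out["p_value"] = None
        try:
            out["cohens_d"] = self.effect_size()
        except DegenerateStatisticError:
            out["cohens_d"] = None
        return out


@dataclass
class ValidationSummary:
    """All reports of one outcome, indexed by (method, n_features)."""

    outcome: str
    reports: dict[tuple[str, int], ValidationReport]
    split_indices: list[tuple[np.ndarray, np.ndarray]] = field(repr=False, default_factory=list)

    def mae_grid(self) -> pd.DataFrame:
        """Mean-MAE grid, rows = number of features, columns = methods."""
        methods = sorted({m for m, _ in self.reports})
        sizes = sorted({k for _, k in self.reports})
        grid = pd.DataFrame(index=pd.Index(sizes, name="n_features"), columns=methods, dtype=float)
        for (m, k), rep in self.reports.items():
            grid.loc[k, m] = rep.mean_mae
        return grid

    def best(self) -> ValidationReport:
        """Minimum mean-MAE report; ties broken toward fewer features."""
        candidates = [r for r in self.reports.values() if np.isfinite(r.mean_mae)]
        if not candidates:
            raise RollgaitError(f"no successful validation runs for {self.outcome}")
        return min(candidates, key=lambda r: (r.mean_mae, r.n_features))

    def table(self) -> pd.DataFrame:
        rows = [rep.summary() for rep in self.reports.values()]
        return pd.DataFrame(rows).sort_values(["method", "n_features"]).reset_index(drop=True)


def validate(
    table: pd.DataFrame,
    outcome: str,
    methods: Sequence[str] = DEFAULT_METHODS,
    m_values: Sequence[int] = tuple(range(1, 11)),
    n_iterations: int = 100,
    train_fraction: float = 0.7,
    seed: int | None = 0,
    split_by_subject: bool = False,
    selector_kwargs: Mapping[str, Mapping] | None = None,
    ridge_grid=None,
    cv_folds: int | None = None,
    leak_selection: bool = False,
) -> ValidationSummary:
    """Run the repeated split-sample validation protocol for one outcome.

    Feature selection is recomputed on each iteration's training rows (with
    ``leak_selection=True`` — for diagnostics only — on all rows), and a
    (method, m) cell's MAE averages only iterations in which the method
    ranked at least ``m`` features.  All methods and model sizes share the
    identical split sequence.
    """
    if len(table) < 10:
        raise ValueError("validation needs at least 10 rows")
    selector_kwargs = dict(selector_kwargs or {})
    rng = np.random.default_rng(seed)
    groups = table["subject"].to_numpy() if split_by_subject else None
    splits = make_splits(len(table), n_iterations, train_fraction, rng, groups=groups)

    X_all = table[list(FEATURE_NAMES)].to_numpy(dtype=float)
    y_all = table[outcome].to_numpy(dtype=float)

    per_cell_maes: dict[tuple[str, int], list[float]] = {
        (m, k): [] for m in methods for k in m_values
    }
    pooled: dict[tuple[str, int], tuple[list, list]] = {
        (m, k): ([], []) for m in methods for k in m_values
    }

    for it, (train_idx, test_idx) in enumerate(splits):
        X_tr, y_tr = X_all[train_idx], y_all[train_idx]
        X_te, y_te = X_all[test_idx], y_all[test_idx]
        sel_X = X_all if leak_selection else X_tr
        sel_y = y_all if leak_selection else y_tr
        for method in methods:
            kwargs = dict(selector_kwargs.get(method, {}))
            if method in ("lasso", "elastic_net") and "random_state" not in kwargs:
                kwargs["random_state"] = 0 if seed is None else int(seed)
            try:
                selector = make_selector(method, **kwargs).fit(sel_X, sel_y)
            except Exception as exc:  # pragma: no cover - surfaced with context
                raise RollgaitError(f"iteration {it}: {method} selection failed: {exc}") from exc
            ranking = selector.ranking_
            for k in m_values:
                if len(ranking) < k:
                    continue  # method did not rank enough features this round
                cols = ranking[:k]
                model = VifGatedRegressor(
                    ridge_grid=ridge_grid,
                    cv=cv_folds,
                    random_state=0 if seed is None else int(seed),
                )
                try:
                    model.fit(X_tr[:, cols], y_tr)
                    pred = model.predict(X_te[:, cols])
                except Exception as exc:  # pragma: no cover
                    raise RollgaitError(
                        f"iteration {it}: {method} m={k} model fit failed: {exc}"
                    ) from exc
                per_cell_maes[(method, k)].append(mae(pred, y_te))
                pooled[(method, k)][0].extend(y_te.tolist())
                pooled[(method, k)][1].extend(pred.tolist())

    reports = {}
    for key, maes in per_cell_maes.items():
        method, k = key
        act, pred = pooled[key]
        reports[key] = ValidationReport(
            method=method,
            n_features=k,
            outcome=outcome,
            mae_per_iteration=np.asarray(maes, dtype=float),
            pooled_actual=np.asarray(act, dtype=float),
            pooled_predicted=np.asarray(pred, dtype=float),
            n_iterations_used=len(maes),
            split_indices=splits,
        )
    return ValidationSummary(outcome=outcome, reports=reports, split_indices=splits)
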