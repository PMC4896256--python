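"""From an expression compendium to per-condition flux profiles.

Each condition's expression row is collapsed to gene-set values, turned into
condition-specific flux bounds through the logarithmic map, and the
lexicographic LP is solved, yielding one flux vector per condition.  The
resulting conditions x reactions matrix (and the expression matrix itself)
are then prepared for network construction: features that are mostly
missing are dropped, and each surviving feature is rank-discretized into
quantile bins, which tames the heavy-tailed (high-kurtosis) flux and
expression distributions without discarding outliers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .expression import (
    ExpressionCompendium,
    MapParameters,
    condition_bounds,
    gene_set_profile,
)
from .fba import FluxDistribution, InfeasibleError, ObjectiveSpec, lexicographic_fba
from .model import MetabolicModel

__all__ = [
    "ConditionFluxMatrix",
    "map_condition",
    "map_compendium",
    "filter_features",
    "quantile_discretize",
    "FiniteFilter",
    "QuantileRankDiscretizer",
]

logger = logging.getLogger(__name__)


@dataclass
class ConditionFluxMatrix:
    """Conditions x reactions flux matrix with per-condition solve status.

    Failed conditions keep their row (all-NaN) and are listed in
    ``failures`` as (condition_id, reason).
    """

    values: pd.DataFrame
    objective_values: pd.DataFrame
    failures: list[tuple[str, str]] = field(default_factory=list)

    @property
    def condition_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def reaction_ids(self) -> list[str]:
        return list(self.values.columns)


def map_condition(
    model: MetabolicModel,
    compendium: ExpressionCompendium,
    condition_id: str,
    params: MapParameters | None = None,
    objectives: ObjectiveSpec | None = None,
) -> FluxDistribution:
    """Solve the condition-specific lexicographic LP for one condition.

    Theta and sigma^2 are computed per reaction (variances across the whole
    compendium), bounds are scaled by phi, and the LP is solved.  An
    infeasible LP is reported via the status flag, never as silent NaNs
    pretending to be optimal.
    """
    params = params or MapParameters()
    if objectives is None:
        raise ValueError("objectives are required")
    profile = gene_set_profile(model, compendium, condition_id)
    bounded = condition_bounds(model, profile, params)
    try:
        return lexicographic_fba(bounded, objectives)
    except InfeasibleError as exc:
        logger.warning("condition %s: %s", condition_id, exc)
        return FluxDistribution(
            v=np.full(model.n, np.nan),
            objective_values=[np.nan] * len(objectives.selectors),
            status=f"failed: {exc}",
            reaction_ids=list(model.reaction_ids),
        )


def map_compendium(
    model: MetabolicModel,
    compendium: ExpressionCompendium,
    params: MapParameters | None = None,
    objectives: ObjectiveSpec | None = None,
) -> ConditionFluxMatrix:
    """Map every condition of the compendium to a flux profile.

    Rows are solved independently (deterministic given inputs; the
    per-condition solves share no state and may be parallelized by a
    caller).  LP failures are collected, not raised.
    """
    params = params or MapParameters()
    if objectives is None:
        raise ValueError("objectives are required")
    n_obj = len(objectives.selectors)
    rows, obj_rows, failures = [], [], []
    for cid in compendium.condition_ids:
        dist = map_condition(model, compendium, cid, params, objectives)
        rows.append(dist.v)
        obj_rows.append(dist.objective_values)
        if not dist.ok:
            failures.append((cid, dist.status))
    values = pd.DataFrame(
        np.array(rows).reshape(len(rows), model.n) if rows else np.empty((0, model.n)),
        index=compendium.condition_ids,
        columns=model.reaction_ids,
    )
    objective_values = pd.DataFrame(
        np.array(obj_rows).reshape(len(obj_rows), n_obj) if obj_rows else np.empty((0, n_obj)),
        index=compendium.condition_ids,
        columns=[f"objective_{k + 1}" for k in range(n_obj)],
    )
    if failures:
        logger.warning("%d/%d conditions failed to solve", len(failures), len(rows))
    return ConditionFluxMatrix(values, objective_values, failures)


class FiniteFilter(BaseEstimator, TransformerMixin):
    """Drop feature columns with too few known, finite values.

    A column is kept iff its finite fraction is >= ``min_finite_fraction``
    (strictly-less-than columns are dropped).  Fitted attributes:
    ``keep_mask_``, ``dropped_ids_``.
    """

    def __init__(self, min_finite_fraction: float = 0.10):
        self.min_finite_fraction = min_finite_fraction

    def fit(self, X, y=None):
        X = _as_frame(X)
        finite_frac = np.isfinite(X.to_numpy(dtype=float)).mean(axis=0)
        self.keep_mask_ = finite_frac >= self.min_finite_fraction
        self.dropped_ids_ = [c for c, k in zip(X.columns, self.keep_mask_) if not k]
        self.n_features_in_ = X.shape[1]
        if not self.keep_mask_.any():
            raise ValueError("all feature columns were dropped by the finite filter")
        return self

    def transform(self, X):
        check_is_fitted(self, "keep_mask_")
        X = _as_frame(X)
        return X.loc[:, X.columns[self.keep_mask_]]


class QuantileRankDiscretizer(BaseEstimator, TransformerMixin):
    """Replace each value by its within-column quantile bin (1..n_quantiles).

    Ranks are averaged over ties and mapped to ``ceil(rank / n * q)``,
    clamped to ``[1, q]``; the output depends only on within-column ranks,
    so it is invariant to monotone transforms and robust to extreme
    outliers.  Missing values are imputed with the column median before
    ranking.  Stateless across fit/transform: bins are recomputed on the
    data being transformed (the discretization is a per-matrix preparation
    step, not a learned mapping).
    """

    def __init__(self, n_quantiles: int = 20):
        self.n_quantiles = n_quantiles

    def fit(self, X, y=None):
        X = _as_frame(X)
        self.n_features_in_ = X.shape[1]
        self.fitted_ = True
        return self

    def transform(self, X):
        check_is_fitted(self, "fitted_")
        X = _as_frame(X)
        arr = X.to_numpy(dtype=float).copy()
        n = arr.shape[0]
        q = self.n_quantiles
        out = np.empty_like(arr, dtype=int)
        for j in range(arr.shape[1]):
            col = arr[:, j]
            mask = ~np.isfinite(col)
            if mask.any():
                med = np.nanmedian(np.where(np.isfinite(col), col, np.nan))
                col = np.where(mask, med, col)
            ranks = rankdata(col, method="average")
            bins = np.ceil(ranks / n * q).astype(int)
            out[:, j] = np.clip(bins, 1, q)
        return pd.DataFrame(out, index=X.index, columns=X.columns)


def filter_features(
    matrix: pd.DataFrame, min_finite_fraction: float = 0.10
) -> tuple[pd.DataFrame, list[str]]:
    """Drop columns whose finite fraction is below the threshold.

    Returns the reduced matrix and the list of dropped column ids.
    """
    f = FiniteFilter(min_finite_fraction).fit(matrix)
    return f.transform(matrix), f.dropped_ids_


def quantile_discretize(matrix: pd.DataFrame, n_quantiles: int = 20) -> pd.DataFrame:
    """Rank-discretize each column into ``n_quantiles`` bins (see estimator)."""
    return QuantileRankDiscretizer(n_quantiles).fit_transform(matrix)


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    return pd.DataFrame(arr)
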