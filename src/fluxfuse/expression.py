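"""Mapping gene expression onto reaction flux bounds.

Expression is held on a ratio-to-reference scale where 1 is the wild-type
level.  Each reaction's gene set is collapsed to a single "gene-set
expression" Theta by recursing over its GPR tree with AND -> min (enzyme
complexes are limited by their scarcest subunit) and OR -> max (isozymes are
interchangeable).  Theta is then turned into a multiplicative factor on the
reaction's default bounds through the variance-weighted logarithmic map

    phi(Theta) = [1 + (gamma / sigma^2) * |log(Theta)|] ** sgn(Theta - 1)

with phi(1) = 1 and phi(0) = 0 as the continuity limit.  sigma^2 is the
gene-set variance across conditions (same min/max recursion applied to
per-gene variances); genes with low variance across conditions are treated
as more important, so their deviations from 1 move the bounds further.
gamma weights that variance term.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .model import Gpr, MetabolicModel

__all__ = [
    "ExpressionCompendium",
    "GeneSetProfile",
    "MapParameters",
    "gene_set_expression",
    "gene_set_variance",
    "phi",
    "gene_set_profile",
    "condition_bounds",
    "read_expression_table",
    "from_log2_ratios",
]


@dataclass
class MapParameters:
    """Tunables of the logarithmic bound map.

    gamma
        Weight of the inverse-variance term (> 0, dimensionless, default 1).
    log_base
        Base of the logarithm (> 1, default e).
    sigma2_floor
        Lower floor for gene-set variances, avoiding division by zero for
        genes constant across conditions (default 1e-6).
    """

    gamma: float = 1.0
    log_base: float = math.e
    sigma2_floor: float = 1e-6

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.log_base <= 1:
            raise ValueError("log_base must be > 1")
        if self.sigma2_floor <= 0:
            raise ValueError("sigma2_floor must be > 0")


@dataclass
class ExpressionCompendium:
    """A conditions x genes expression table on the ratio scale (1 = wild type).

    ``values`` is a DataFrame indexed by condition id with gene-id columns;
    entries are >= 0 and may be NaN (missing).  ``metadata`` carries optional
    per-condition flags (e.g. an ``aerobic`` column or ground-truth cluster
    labels for synthetic data).
    """

    values: pd.DataFrame
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValueError("condition and gene ids must be unique")
        finite = self.values.to_numpy(dtype=float)
        if np.nanmin(finite, initial=0.0) < 0:
            raise ValueError("expression ratios must be >= 0")

    @property
    def condition_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.columns)

    def condition(self, condition_id: str) -> dict[str, float]:
        """Gene -> ratio map for one condition, NaNs dropped."""
        row = self.values.loc[condition_id]
        return {g: float(v) for g, v in row.items() if np.isfinite(v)}

    def gene_variances(self) -> dict[str, float]:
        """Per-gene variance of the ratio values across conditions (NaN-aware)."""
        var = self.values.var(axis=0, ddof=0, skipna=True)
        return {g: float(v) if np.isfinite(v) else 0.0 for g, v in var.items()}


@dataclass
class GeneSetProfile:
    """Per-reaction gene-set expression and variance for one condition.

    Reactions without a GPR carry the neutral value 1 and a NaN sentinel
    variance; the bound map leaves them untouched.
    """

    theta_set: np.ndarray
    sigma2: np.ndarray
    reaction_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.theta_set = np.asarray(self.theta_set, dtype=float)
        self.sigma2 = np.asarray(self.sigma2, dtype=float)
        if self.theta_set.shape != self.sigma2.shape:
            raise ValueError("theta_set and sigma2 must have equal length")
        if np.any(self.theta_set < 0):
            raise ValueError("gene-set expression must be >= 0")


def gene_set_expression(gpr: Gpr, theta: Mapping[str, float], missing: float = 1.0) -> float:
    """Collapse per-gene ratios to one value: AND -> min, OR -> max.

    Genes absent from ``theta`` take the neutral value ``missing`` (1 by
    default, i.e. wild type).
    """
    return gpr.evaluate(theta, missing=missing)


def gene_set_variance(gpr: Gpr, var: Mapping[str, float], missing: float = 0.0) -> float:
    """Collapse per-gene variances with the same min/max recursion as Theta."""
    return gpr.evaluate(var, missing=missing)


def phi(theta_set: float, sigma2: float, params: MapParameters | None = None) -> float:
    """The logarithmic bound-map factor for one reaction.

    Returns 1 at Theta = 1 and 0 at Theta = 0 (continuity limit); otherwise
    ``[1 + gamma/sigma2 * |log(Theta)|] ** sgn(Theta - 1)``.  A NaN sigma2
    (sentinel for "no GPR") also yields 1.  Strictly increasing in Theta.
    """
    params = params or MapParameters()
    if theta_set < 0 or not math.isfinite(theta_set):
        raise ValueError(f"gene-set expression must be finite and >= 0, got {theta_set}")
    if not math.isfinite(sigma2):
        return 1.0
    if theta_set == 1.0:
        return 1.0
    if theta_set == 0.0:
        return 0.0
    s2 = max(float(sigma2), params.sigma2_floor)
    log_theta = math.log(theta_set) / math.log(params.log_base)
    core = 1.0 + (params.gamma / s2) * abs(log_theta)
    sign = 1.0 if theta_set > 1.0 else -1.0
    return core ** sign


def gene_set_profile(
    model: MetabolicModel,
    compendium: ExpressionCompendium,
    condition_id: str,
    missing: float = 1.0,
) -> GeneSetProfile:
    """Per-reaction Theta and sigma^2 for one condition of a compendium.

    sigma^2 is computed from per-gene variances across *all* conditions of
    the raw compendium, then collapsed per reaction with the same min/max
    recursion as Theta.
    """
    theta = compendium.condition(condition_id)
    gene_var = compendium.gene_variances()
    n = model.n
    theta_set = np.ones(n)
    sigma2 = np.full(n, np.nan)
    for j, g in enumerate(model.gpr):
        if g is None:
            continue
        theta_set[j] = gene_set_expression(g, theta, missing=missing)
        sigma2[j] = gene_set_variance(g, gene_var, missing=0.0)
    return GeneSetProfile(theta_set, sigma2, reaction_ids=list(model.reaction_ids))


def condition_bounds(
    model: MetabolicModel,
    profile: GeneSetProfile,
    params: MapParameters | None = None,
) -> MetabolicModel:
    """Scale the model's default bounds by phi per reaction.

    Effective bounds are ``(v_min[i] * phi_i, v_max[i] * phi_i)``; phi is
    positive so the bound ordering is preserved.  Reactions without a GPR
    (sentinel NaN variance) keep their defaults.
    """
    params = params or MapParameters()
    if len(profile.theta_set) != model.n:
        raise ValueError(
            f"profile length {len(profile.theta_set)} != model reaction count {model.n}"
        )
    factors = np.array(
        [phi(t, s2, params) for t, s2 in zip(profile.theta_set, profile.sigma2)]
    )
    return model.with_bounds(model.v_min * factors, model.v_max * factors)


def read_expression_table(
    path: str | Path,
    sep: str = "\t",
    metadata: pd.DataFrame | None = None,
) -> ExpressionCompendium:
    """Read a delimited table with genes as rows and conditions as columns.

    Empty cells or ``NA`` mark missing values.  The table is transposed into
    the internal conditions x genes orientation.
    """
    df = pd.read_csv(path, sep=sep, index_col=0, na_values=["NA", ""])
    return ExpressionCompendium(values=df.T.astype(float), metadata=metadata)


def from_log2_ratios(values: pd.DataFrame) -> pd.DataFrame:
    """Convert log2-ratio expression (0 = wild type) to the ratio scale 2**x."""
    return values.apply(lambda col: np.power(2.0, col))
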