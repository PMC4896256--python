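"""Steady-state flux-balance analysis and lexicographic multi-level FBA.

The feasible set is the polytope {v : A v = 0, v_min <= v <= v_max}.  A
single-level solve maximizes one linear objective over it; the lexicographic
variant solves up to three objectives in priority order, fixing each solved
level via ``objective >= optimum * (1 - fix_tol)`` before the next, so outer
levels optimize over the (near-)optimal set of inner ones.  LPs are solved
with HiGHS through scipy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import linprog

from .model import MetabolicModel

__all__ = [
    "ObjectiveSpec",
    "FluxDistribution",
    "InfeasibleError",
    "fba",
    "lexicographic_fba",
    "pareto_front",
    "selector",
]

FEASIBILITY_TOL = 1e-6


class InfeasibleError(RuntimeError):
    """An LP level was infeasible or unbounded."""


@dataclass(frozen=True)
class ObjectiveSpec:
    """Ordered maximization objectives, highest priority first.

    Each selector is a 0/1 vector over reactions; at most three levels.
    """

    selectors: tuple[np.ndarray, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.selectors) <= 3:
            raise ValueError("between 1 and 3 objective levels are supported")
        for s in self.selectors:
            if not np.any(s):
                raise ValueError("objective selectors must be nonzero")

    @classmethod
    def from_reaction_ids(
        cls, model: MetabolicModel, reaction_ids: Sequence[str]
    ) -> "ObjectiveSpec":
        sels = []
        for rid in reaction_ids:
            s = np.zeros(model.n)
            s[model.reaction_index(rid)] = 1.0
            sels.append(s)
        return cls(tuple(sels))


@dataclass
class FluxDistribution:
    """A steady-state flux vector with its per-level objective values."""

    v: np.ndarray
    objective_values: list[float]
    status: str  # "optimal" | "infeasible" | "unbounded" | "failed"
    reaction_ids: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return self.status == "optimal"

    def to_series(self):
        import pandas as pd

        return pd.Series(self.v, index=self.reaction_ids, name="flux")


def selector(model: MetabolicModel, reaction_id: str) -> np.ndarray:
    """A one-hot objective vector for ``reaction_id``."""
    s = np.zeros(model.n)
    s[model.reaction_index(reaction_id)] = 1.0
    return s


def _solve(
    model: MetabolicModel,
    c_max: np.ndarray,
    extra_A_ub: list[np.ndarray],
    extra_b_ub: list[float],
):
    bounds = list(zip(model.v_min, model.v_max))
    A_ub = np.array(extra_A_ub) if extra_A_ub else None
    b_ub = np.array(extra_b_ub) if extra_b_ub else None
    res = linprog(
        c=-np.asarray(c_max, dtype=float),
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=model.A,
        b_eq=np.zeros(model.m),
        bounds=bounds,
        method="highs",
    )
    return res


def fba(model: MetabolicModel, objective: np.ndarray) -> FluxDistribution:
    """Maximize ``objective . v`` subject to Av = 0 and the model bounds."""
    res = _solve(model, objective, [], [])
    if res.status == 0:
        return FluxDistribution(
            v=res.x,
            objective_values=[float(objective @ res.x)],
            status="optimal",
            reaction_ids=list(model.reaction_ids),
        )
    status = {2: "infeasible", 3: "unbounded"}.get(res.status, "failed")
    return FluxDistribution(
        v=np.full(model.n, np.nan),
        objective_values=[np.nan],
        status=status,
        reaction_ids=list(model.reaction_ids),
    )


def lexicographic_fba(
    model: MetabolicModel,
    objectives: ObjectiveSpec | Sequence[np.ndarray],
    fix_tol: float = 1e-9,
) -> FluxDistribution:
    """Solve objectives in priority order, fixing each optimum before the next.

    After level ``l`` attains optimum ``z_l``, the constraint
    ``c_l . v >= z_l - fix_tol * |z_l|`` is added; the relative slack keeps
    the optimal face numerically non-empty.  Returns the final vertex and
    the optimum of every level.  Raises :class:`InfeasibleError` naming the
    level if any solve fails.
    """
    if isinstance(objectives, ObjectiveSpec):
        sels = objectives.selectors
    else:
        sels = tuple(np.asarray(s, dtype=float) for s in objectives)
        ObjectiveSpec(sels)  # validate
    A_ub: list[np.ndarray] = []
    b_ub: list[float] = []
    optima: list[float] = []
    x = None
    for level, c in enumerate(sels, start=1):
        res = _solve(model, c, A_ub, b_ub)
        if res.status != 0:
            kind = {2: "infeasible", 3: "unbounded"}.get(res.status, "failed")
            raise InfeasibleError(f"level {level} {kind}")
        z = float(c @ res.x)
        optima.append(z)
        x = res.x
        # c.v >= z - fix_tol*|z|   <=>   -c.v <= -(z - fix_tol*|z|)
        A_ub.append(-c)
        b_ub.append(-(z - fix_tol * abs(z)))
    assert x is not None
    return FluxDistribution(
        v=x,
        objective_values=optima,
        status="optimal",
        reaction_ids=list(model.reaction_ids),
    )


def pareto_front(
    points: Sequence[Sequence[float]] | np.ndarray,
) -> np.ndarray:
    """The non-dominated subset of ``points`` under maximization of every axis.

    A point is dominated if another point is >= in every coordinate and > in
    at least one.  Duplicates of a kept point are kept once; the result is
    sorted by the first coordinate (ties by the remaining coordinates).
    """
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        return pts.reshape(0, pts.shape[1] if pts.ndim == 2 else 0)
    if pts.ndim != 2:
        raise ValueError("points must be a 2-D array")
    if not np.all(np.isfinite(pts)):
        raise ValueError("points must be finite")
    uniq = np.unique(pts, axis=0)
    keep = []
    for i, p in enumerate(uniq):
        dominated = False
        for j, q in enumerate(uniq):
            if j != i and np.all(q >= p) and np.any(q > p):
                dominated = True
                break
        if not dominated:
            keep.append(p)
    front = np.array(keep)
    order = np.lexsort(tuple(front[:, k] for k in range(front.shape[1] - 1, -1, -1)))
    return front[order]
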