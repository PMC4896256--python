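"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

import fluxfuse as ff


# ---------------------------------------------------------------------------
# Independent LP oracle: exhaustive vertex enumeration of {Av=0, lb<=v<=ub}
# ---------------------------------------------------------------------------

def enumerate_vertices(model: ff.MetabolicModel, tol: float = 1e-9) -> np.ndarray:
    """All vertices of the flux polytope, by brute-force basis enumeration.

    A vertex has n - rank(A) variables at a bound; enumerate every choice of
    non-basic variables and bound assignment, solve for the rest, keep
    feasible unique solutions.  Only viable for tiny models (n <= 8).
    """
    A = model.A
    m, n = A.shape
    r = np.linalg.matrix_rank(A) if A.size else 0
    verts: list[np.ndarray] = []
    for basic in itertools.combinations(range(n), r):
        B = A[:, list(basic)]
        if np.linalg.matrix_rank(B) < r:
            continue
        nonbasic = [j for j in range(n) if j not in basic]
        for choice in itertools.product((0, 1), repeat=len(nonbasic)):
            v = np.zeros(n)
            for j, c in zip(nonbasic, choice):
                v[j] = model.v_min[j] if c == 0 else model.v_max[j]
            rhs = -A[:, nonbasic] @ v[nonbasic] if nonbasic else np.zeros(m)
            sol, *_ = np.linalg.lstsq(B, rhs, rcond=None)
            v[list(basic)] = sol
            if np.max(np.abs(A @ v), initial=0.0) > tol:
                continue
            if np.any(v < model.v_min - tol) or np.any(v > model.v_max + tol):
                continue
            if not any(np.allclose(v, w, atol=1e-7) for w in verts):
                verts.append(v)
    return np.array(verts)


def lexicographic_vertex_oracle(
    model: ff.MetabolicModel, selectors, tol: float = 1e-7
) -> list[float]:
    """Lexicographic optima by filtering the enumerated vertex set."""
    verts = enumerate_vertices(model)
    assert len(verts), "empty polytope"
    optima = []
    for c in selectors:
        vals = verts @ np.asarray(c, dtype=float)
        best = vals.max()
        optima.append(float(best))
        verts = verts[vals >= best - tol]
    return optima


# ---------------------------------------------------------------------------
# Independent GPR oracle: evaluation over a plain nested-tuple tree
# ---------------------------------------------------------------------------

def random_gpr_tuple(rng: np.random.Generator, depth: int, genes: list[str]):
    """A random GPR as nested tuples ('and'|'or', [children]) or a gene str."""
    if depth == 0 or rng.random() < 0.3:
        return genes[rng.integers(len(genes))]
    op = "and" if rng.random() < 0.5 else "or"
    n_children = int(rng.integers(2, 4))
    return (op, [random_gpr_tuple(rng, depth - 1, genes) for _ in range(n_children)])


def tuple_to_text(node) -> str:
    if isinstance(node, str):
        return node
    op, children = node
    joiner = f" {op.upper()} "
    return "(" + joiner.join(tuple_to_text(c) for c in children) + ")"


def eval_tuple(node, values: dict) -> float:
    if isinstance(node, str):
        return values[node]
    op, children = node
    vals = [eval_tuple(c, values) for c in children]
    return min(vals) if op == "and" else max(vals)


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def chain_model() -> ff.MetabolicModel:
    return ff.toy_model("chain")


@pytest.fixture(scope="session")
def branch_model() -> ff.MetabolicModel:
    return ff.toy_model("branch")


@pytest.fixture(scope="session")
def planted() -> tuple[ff.FixtureSpec, ff.ExpressionCompendium, ff.MetabolicModel]:
    model = ff.toy_model("chain")
    spec = ff.FixtureSpec(seed=11)
    return spec, ff.planted_compendium(spec, model), model
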