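"""Genome-scale metabolic models with gene-protein-reaction (GPR) rules.

A model is held as a stoichiometric matrix ``A`` (metabolites x reactions),
flux bounds ``v_min``/``v_max`` and one optional boolean GPR expression per
reaction.  GPR rules link genes to reactions: ``AND`` denotes an enzyme
complex (all subunits required), ``OR`` denotes isozymes (any one suffices).

Models can be read from SBML (via cobrapy) or from a light JSON dialect that
needs no SBML tooling; the JSON schema is documented in :func:`write_model`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "Gpr",
    "GprParseError",
    "MetabolicModel",
    "ModelValidationError",
    "ReactionAddition",
    "GprUpdate",
    "parse_gpr",
    "format_gpr",
    "read_model",
    "write_model",
    "augment_model",
    "read_gpr_updates",
    "read_reaction_additions",
    "DEFAULT_BOUND",
]

#: Default flux-bound magnitude (mmol h^-1 gDW^-1) used when a file omits
#: bounds: (-M, +M) for reversible reactions, (0, +M) for irreversible ones.
DEFAULT_BOUND = 1000.0


class GprParseError(ValueError):
    """Malformed GPR text; carries the character position of the error."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class ModelValidationError(ValueError):
    """A model or augmentation table violates a structural invariant."""


@dataclass(frozen=True)
class Gpr:
    """A boolean gene-association tree.

    ``op`` is ``"gene"`` for a leaf (then ``gene`` is set), or ``"and"`` /
    ``"or"`` for an internal node with >= 2 ``children``.
    """

    op: str
    gene: str | None = None
    children: tuple["Gpr", ...] = ()

    def __post_init__(self) -> None:
        if self.op == "gene":
            if not self.gene:
                raise ValueError("leaf node needs a gene id")
        elif self.op in ("and", "or"):
            if len(self.children) < 2:
                raise ValueError(f"'{self.op}' node needs >= 2 children")
        else:
            raise ValueError(f"unknown GPR operator {self.op!r}")

    def genes(self) -> set[str]:
        if self.op == "gene":
            return {self.gene}  # type: ignore[arg-type]
        out: set[str] = set()
        for c in self.children:
            out |= c.genes()
        return out

    def evaluate(self, values: Mapping[str, float], missing: float | None = 1.0) -> float:
        """Evaluate with AND -> min, OR -> max over gene ``values``.

        ``missing`` is substituted for genes absent from ``values`` (the
        neutral wild-type ratio 1 by default); pass ``None`` to raise instead.
        """
        if self.op == "gene":
            if self.gene in values:
                return float(values[self.gene])
            if missing is None:
                raise KeyError(self.gene)
            return float(missing)
        child_vals = [c.evaluate(values, missing) for c in self.children]
        return min(child_vals) if self.op == "and" else max(child_vals)

    def __str__(self) -> str:
        return format_gpr(self)


def _tokenize(text: str) -> Iterator[tuple[str, str, int]]:
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            i += 1
            continue
        if ch == "(":
            yield ("lparen", ch, i)
            i += 1
        elif ch == ")":
            yield ("rparen", ch, i)
            i += 1
        else:
            j = i
            while j < n and not text[j].isspace() and text[j] not in "()":
                j += 1
            word = text[i:j]
            low = word.lower()
            if low == "and":
                yield ("and", word, i)
            elif low == "or":
                yield ("or", word, i)
            else:
                yield ("gene", word, i)
            i = j


def parse_gpr(text: str) -> Gpr:
    """Parse GPR text such as ``"(g1 AND g2) OR g3"`` into a :class:`Gpr`.

    AND binds tighter than OR; both are left-associative and flattened to
    n-ary nodes, so ``a OR b OR c`` yields a single OR with three leaves.
    Operator keywords are case-insensitive.
    """
    tokens = list(_tokenize(text))
    if not tokens:
        raise GprParseError("empty GPR expression", 0)
    pos = 0

    def peek() -> tuple[str, str, int] | None:
        return tokens[pos] if pos < len(tokens) else None

    def advance() -> tuple[str, str, int]:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or() -> Gpr:
        parts = [parse_and()]
        while (tok := peek()) is not None and tok[0] == "or":
            advance()
            parts.append(parse_and())
        if len(parts) == 1:
            return parts[0]
        flat: list[Gpr] = []
        for p in parts:
            flat.extend(p.children if p.op == "or" else (p,))
        return Gpr("or", children=tuple(flat))

    def parse_and() -> Gpr:
        parts = [parse_atom()]
        while (tok := peek()) is not None and tok[0] == "and":
            advance()
            parts.append(parse_atom())
        if len(parts) == 1:
            return parts[0]
        flat: list[Gpr] = []
        for p in parts:
            flat.extend(p.children if p.op == "and" else (p,))
        return Gpr("and", children=tuple(flat))

    def parse_atom() -> Gpr:
        tok = peek()
        if tok is None:
            raise GprParseError("unexpected end of expression", len(text))
        kind, word, at = advance()
        if kind == "gene":
            return Gpr("gene", gene=word)
        if kind == "lparen":
            inner = parse_or()
            closing = peek()
            if closing is None or closing[0] != "rparen":
                raise GprParseError("unbalanced parenthesis", at)
            advance()
            return inner
        raise GprParseError(f"unexpected token {word!r}", at)

    tree = parse_or()
    if pos != len(tokens):
        kind, word, at = tokens[pos]
        raise GprParseError(f"trailing token {word!r}", at)
    return tree


def format_gpr(gpr: Gpr) -> str:
    """Render a GPR tree back to text; ``parse_gpr(format_gpr(t)) == t``."""
    if gpr.op == "gene":
        return gpr.gene  # type: ignore[return-value]

    def render(child: Gpr) -> str:
        text = format_gpr(child)
        # an OR child under AND needs parentheses; AND under OR does not,
        # but we parenthesize both for unambiguous reading
        if child.op in ("and", "or"):
            return f"({text})"
        return text

    joiner = " AND " if gpr.op == "and" else " OR "
    return joiner.join(render(c) for c in gpr.children)


@dataclass
class MetabolicModel:
    """Stoichiometric model: ``A v = 0`` with ``v_min <= v <= v_max``.

    Attributes
    ----------
    metabolite_ids, reaction_ids, gene_ids
        Unique identifiers; ``A`` has one row per metabolite and one column
        per reaction.
    v_min, v_max
        Flux bounds in mmol h^-1 gDW^-1 (the biomass component in h^-1).
    gpr
        One optional :class:`Gpr` per reaction.
    """

    metabolite_ids: list[str]
    reaction_ids: list[str]
    A: np.ndarray
    v_min: np.ndarray
    v_max: np.ndarray
    gpr: list[Gpr | None]
    gene_ids: list[str] = field(default_factory=list)
    id: str = "model"

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.v_min = np.asarray(self.v_min, dtype=float)
        self.v_max = np.asarray(self.v_max, dtype=float)
        self.validate()

    @property
    def m(self) -> int:
        return len(self.metabolite_ids)

    @property
    def n(self) -> int:
        return len(self.reaction_ids)

    def validate(self) -> None:
        m, n = self.m, self.n
        if self.A.shape != (m, n):
            raise ModelValidationError(
                f"A has shape {self.A.shape}, expected ({m}, {n})"
            )
        for name, ids in (
            ("metabolite", self.metabolite_ids),
            ("reaction", self.reaction_ids),
            ("gene", self.gene_ids),
        ):
            if len(set(ids)) != len(ids):
                dupes = sorted({x for x in ids if ids.count(x) > 1})
                raise ModelValidationError(f"duplicate {name} ids: {dupes}")
        if self.v_min.shape != (n,) or self.v_max.shape != (n,):
            raise ModelValidationError("bound vectors must have length n")
        if np.any(self.v_min > self.v_max):
            bad = [self.reaction_ids[i] for i in np.where(self.v_min > self.v_max)[0]]
            raise ModelValidationError(f"v_min > v_max for reactions {bad}")
        if len(self.gpr) != n:
            raise ModelValidationError("gpr list must have length n")
        known = set(self.gene_ids)
        for rid, g in zip(self.reaction_ids, self.gpr):
            if g is not None:
                extra = g.genes() - known
                if extra:
                    raise ModelValidationError(
                        f"reaction {rid} references unknown genes {sorted(extra)}"
                    )

    def reaction_index(self, reaction_id: str) -> int:
        try:
            return self.reaction_ids.index(reaction_id)
        except ValueError:
            raise KeyError(f"unknown reaction {reaction_id!r}") from None

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolite_ids=list(self.metabolite_ids),
            reaction_ids=list(self.reaction_ids),
            A=self.A.copy(),
            v_min=self.v_min.copy(),
            v_max=self.v_max.copy(),
            gpr=list(self.gpr),
            gene_ids=list(self.gene_ids),
            id=self.id,
        )

    def with_bounds(self, v_min: np.ndarray, v_max: np.ndarray) -> "MetabolicModel":
        out = self.copy()
        out.v_min = np.asarray(v_min, dtype=float)
        out.v_max = np.asarray(v_max, dtype=float)
        out.validate()
        return out


@dataclass(frozen=True)
class ReactionAddition:
    reaction_id: str
    stoichiometry: Mapping[str, float]
    v_min: float
    v_max: float
    gpr_text: str | None = None


@dataclass(frozen=True)
class GprUpdate:
    reaction_id: str
    old_gpr: str
    new_gpr: str


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------

def _model_to_dict(model: MetabolicModel) -> dict:
    reactions = []
    for j, rid in enumerate(model.reaction_ids):
        col = model.A[:, j]
        stoich = {
            model.metabolite_ids[i]: float(col[i])
            for i in np.flatnonzero(col)
        }
        rxn: dict = {
            "id": rid,
            "stoichiometry": stoich,
            "lower_bound": float(model.v_min[j]),
            "upper_bound": float(model.v_max[j]),
        }
        if model.gpr[j] is not None:
            rxn["gpr"] = format_gpr(model.gpr[j])
        reactions.append(rxn)
    return {
        "id": model.id,
        "metabolites": list(model.metabolite_ids),
        "genes": list(model.gene_ids),
        "reactions": reactions,
    }


def _model_from_dict(data: dict, source: str = "<json>") -> MetabolicModel:
    try:
        metabolite_ids = list(data["metabolites"])
        reactions = data["reactions"]
    except KeyError as exc:
        raise ModelValidationError(f"{source}: missing key {exc}") from None
    met_index = {mid: i for i, mid in enumerate(metabolite_ids)}
    if len(met_index) != len(metabolite_ids):
        raise ModelValidationError(f"{source}: duplicate metabolite ids")
    n = len(reactions)
    A = np.zeros((len(metabolite_ids), n))
    v_min = np.empty(n)
    v_max = np.empty(n)
    reaction_ids: list[str] = []
    gprs: list[Gpr | None] = []
    for j, rxn in enumerate(reactions):
        rid = rxn.get("id")
        if rid is None:
            raise ModelValidationError(f"{source}: reaction {j} has no id")
        reaction_ids.append(rid)
        for mid, coeff in rxn.get("stoichiometry", {}).items():
            if mid not in met_index:
                raise ModelValidationError(
                    f"{source}: reaction {rid} references unknown metabolite {mid!r}"
                )
            A[met_index[mid], j] = float(coeff)
        reversible = bool(rxn.get("reversible", False))
        default_lo = -DEFAULT_BOUND if reversible else 0.0
        v_min[j] = float(rxn.get("lower_bound", default_lo))
        v_max[j] = float(rxn.get("upper_bound", DEFAULT_BOUND))
        text = rxn.get("gpr")
        gprs.append(parse_gpr(text) if text else None)
    gene_ids = data.get("genes")
    if gene_ids is None:
        gene_ids = sorted({g for t in gprs if t is not None for g in t.genes()})
    return MetabolicModel(
        metabolite_ids=metabolite_ids,
        reaction_ids=reaction_ids,
        A=A,
        v_min=v_min,
        v_max=v_max,
        gpr=gprs,
        gene_ids=list(gene_ids),
        id=data.get("id", "model"),
    )


# ---------------------------------------------------------------------------
# SBML bridge (cobrapy)
# ---------------------------------------------------------------------------

def _from_cobra(cmodel) -> MetabolicModel:
    from cobra.util.array import create_stoichiometric_matrix

    A = create_stoichiometric_matrix(cmodel, array_type="dense")
    reaction_ids = [r.id for r in cmodel.reactions]
    metabolite_ids = [m.id for m in cmodel.metabolites]
    v_min = np.array([r.lower_bound for r in cmodel.reactions], dtype=float)
    v_max = np.array([r.upper_bound for r in cmodel.reactions], dtype=float)
    gprs: list[Gpr | None] = []
    for r in cmodel.reactions:
        rule = r.gene_reaction_rule
        gprs.append(parse_gpr(rule) if rule and rule.strip() else None)
    gene_ids = [g.id for g in cmodel.genes]
    referenced = {g for t in gprs if t is not None for g in t.genes()}
    gene_ids = list(dict.fromkeys(list(gene_ids) + sorted(referenced - set(gene_ids))))
    return MetabolicModel(
        metabolite_ids=metabolite_ids,
        reaction_ids=reaction_ids,
        A=A,
        v_min=v_min,
        v_max=v_max,
        gpr=gprs,
        gene_ids=gene_ids,
        id=cmodel.id or "model",
    )


def _to_cobra(model: MetabolicModel):
    import cobra

    cmodel = cobra.Model(model.id)
    mets = {mid: cobra.Metabolite(mid, compartment="c") for mid in model.metabolite_ids}
    reactions = []
    for j, rid in enumerate(model.reaction_ids):
        rxn = cobra.Reaction(rid)
        rxn.lower_bound = float(model.v_min[j])
        rxn.upper_bound = float(model.v_max[j])
        col = model.A[:, j]
        rxn.add_metabolites(
            {mets[model.metabolite_ids[i]]: float(col[i]) for i in np.flatnonzero(col)}
        )
        reactions.append(rxn)
    cmodel.add_reactions(reactions)
    for j, g in enumerate(model.gpr):
        if g is not None:
            cmodel.reactions[j].gene_reaction_rule = format_gpr(g).replace(
                "AND", "and"
            ).replace("OR", "or")
    return cmodel


def read_model(path: str | Path, format: str | None = None) -> MetabolicModel:
    """Read a model from ``path`` in ``"json"`` or ``"sbml"`` format.

    When ``format`` is omitted it is inferred from the suffix (``.json`` vs
    ``.xml``/``.sbml``).  Bounds absent from a JSON file default to
    ``(-M, +M)`` for reactions flagged reversible and ``(0, +M)`` otherwise,
    with ``M = DEFAULT_BOUND``.
    """
    path = Path(path)
    if format is None:
        format = "json" if path.suffix == ".json" else "sbml"
    if format == "json":
        try:
            data = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ModelValidationError(f"{path}: invalid JSON: {exc}") from exc
        return _model_from_dict(data, source=str(path))
    if format == "sbml":
        import cobra.io

        cmodel = cobra.io.read_sbml_model(str(path))
        return _from_cobra(cmodel)
    raise ValueError(f"unknown model format {format!r}")


def write_model(model: MetabolicModel, path: str | Path, format: str | None = None) -> None:
    """Write ``model`` to ``path`` as JSON or SBML.

    JSON schema::

        {"id": ..., "metabolites": [...], "genes": [...],
         "reactions": [{"id": ..., "stoichiometry": {met: coeff, ...},
                        "lower_bound": ..., "upper_bound": ..., "gpr": ...}]}
    """
    path = Path(path)
    if format is None:
        format = "json" if path.suffix == ".json" else "sbml"
    if format == "json":
        path.write_text(json.dumps(_model_to_dict(model), indent=1))
    elif format == "sbml":
        import cobra.io

        cobra.io.write_sbml_model(_to_cobra(model), str(path))
    else:
        raise ValueError(f"unknown model format {format!r}")


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

def augment_model(
    model: MetabolicModel,
    additions: Sequence[ReactionAddition] = (),
    gpr_updates: Sequence[GprUpdate] = (),
) -> MetabolicModel:
    """Append new reactions and replace listed GPR rules.

    New reactions become new columns of ``A``; metabolites they introduce
    become new rows.  Re-applying the same tables is idempotent: an addition
    whose reaction id is already present with identical content is skipped,
    while a conflicting duplicate raises.
    """
    out = model.copy()
    existing = set(out.reaction_ids)
    for add in additions:
        if not add.stoichiometry or any(
            not math.isfinite(c) or c == 0 for c in add.stoichiometry.values()
        ):
            raise ModelValidationError(
                f"addition {add.reaction_id}: coefficients must be finite and nonzero"
            )
        if add.reaction_id in existing:
            j = out.reaction_index(add.reaction_id)
            col = {
                out.metabolite_ids[i]: out.A[i, j]
                for i in np.flatnonzero(out.A[:, j])
            }
            same = (
                col == {k: float(v) for k, v in add.stoichiometry.items()}
                and out.v_min[j] == add.v_min
                and out.v_max[j] == add.v_max
            )
            if same:
                continue  # idempotent re-application
            raise ModelValidationError(
                f"reaction {add.reaction_id} already present with different content"
            )
        new_mets = [m for m in add.stoichiometry if m not in out.metabolite_ids]
        if new_mets:
            out.metabolite_ids.extend(new_mets)
            out.A = np.vstack([out.A, np.zeros((len(new_mets), out.A.shape[1]))])
        col_vec = np.zeros((out.A.shape[0], 1))
        for mid, coeff in add.stoichiometry.items():
            col_vec[out.metabolite_ids.index(mid), 0] = float(coeff)
        out.A = np.hstack([out.A, col_vec])
        out.reaction_ids.append(add.reaction_id)
        out.v_min = np.append(out.v_min, float(add.v_min))
        out.v_max = np.append(out.v_max, float(add.v_max))
        tree = parse_gpr(add.gpr_text) if add.gpr_text else None
        out.gpr.append(tree)
        if tree is not None:
            for g in sorted(tree.genes()):
                if g not in out.gene_ids:
                    out.gene_ids.append(g)
        existing.add(add.reaction_id)
    for upd in gpr_updates:
        j = out.reaction_index(upd.reaction_id)
        tree = parse_gpr(upd.new_gpr)
        out.gpr[j] = tree
        for g in sorted(tree.genes()):
            if g not in out.gene_ids:
                out.gene_ids.append(g)
    out.validate()
    return out


def read_gpr_updates(path: str | Path) -> list[GprUpdate]:
    """Read a tab-separated GPR-update table: reaction_id, old gpr, new gpr."""
    rows = _read_tsv(path, 3)
    return [GprUpdate(r[0], r[1], r[2]) for r in rows]


def read_reaction_additions(path: str | Path) -> list[ReactionAddition]:
    """Read a tab-separated reaction-addition table.

    Columns: reaction_id, stoichiometry (``met:coeff;met:coeff``), v_min,
    v_max, gpr (optional, may be empty).
    """
    rows = _read_tsv(path, 4)
    out = []
    for r in rows:
        stoich = {}
        for part in r[1].split(";"):
            part = part.strip()
            if not part:
                continue
            mid, _, coeff = part.rpartition(":")
            stoich[mid.strip()] = float(coeff)
        gpr_text = r[4].strip() if len(r) > 4 and r[4].strip() else None
        out.append(ReactionAddition(r[0], stoich, float(r[2]), float(r[3]), gpr_text))
    return out


def _read_tsv(path: str | Path, min_cols: int) -> list[list[str]]:
    lines = Path(path).read_text().splitlines()
    rows = []
    for lineno, line in enumerate(lines):
        if lineno == 0 or not line.strip():  # header / blank
            continue
        parts = line.split("\t")
        if len(parts) < min_cols:
            raise ModelValidationError(
                f"{path}:{lineno + 1}: expected >= {min_cols} columns, got {len(parts)}"
            )
        rows.append(parts)
    return rows
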