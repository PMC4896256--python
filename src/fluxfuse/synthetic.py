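"""Synthetic desk-scale inputs with known ground truth.

Three generators cover the pipeline's input types:

* toy stoichiometric models (``chain`` and ``branch``) whose LP optima are
  small enough to verify by exhaustive vertex enumeration;
* expression compendia with planted condition clusters, drawn as
  log-normal multiplicative noise around cluster-specific mean profiles on
  the ratio scale (centred at 1 = wild type), so that deviations act
  symmetrically through the logarithmic bound map;
* multiplex similarity networks with planted block partitions and tunable
  noise, for exercising the fusion step in isolation.

All generators are deterministic given their seed and need no I/O.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import ExpressionCompendium
from .fusion import MultiplexNetwork, SimilarityLayer
from .model import Gpr, MetabolicModel, parse_gpr

__all__ = [
    "FixtureSpec",
    "toy_model",
    "toy_objectives",
    "planted_compendium",
    "planted_multiplex",
]


@dataclass
class FixtureSpec:
    """Sizes and signal strength of a planted-cluster fixture.

    ``effect_size`` is the shift (natural-log units) applied to the
    discriminative genes' cluster means; ``noise_sd`` is the log-scale
    standard deviation of the per-condition noise.  Defaults: 90
    conditions, 50 genes, 3 equal clusters, 15 responsive genes shifted by
    1.5 log units between extreme clusters (about 4.5-fold, typical of a
    strong environmental shift), noise sd 0.3 (about 1.35-fold
    condition-to-condition variability).
    """

    seed: int = 0
    n_conditions: int = 90
    n_genes: int = 50
    n_clusters: int = 3
    effect_size: float = 1.5
    noise_sd: float = 0.3
    block_sizes: list[int] | None = None
    n_discriminative: int = 15

    def __post_init__(self) -> None:
        if min(self.n_conditions, self.n_genes, self.n_clusters) <= 0:
            raise ValueError("sizes must be positive")
        if self.effect_size < 0 or self.noise_sd < 0:
            raise ValueError("effect_size and noise_sd must be >= 0")
        if self.block_sizes is None:
            base = self.n_conditions // self.n_clusters
            sizes = [base] * self.n_clusters
            for i in range(self.n_conditions - base * self.n_clusters):
                sizes[i] += 1
            self.block_sizes = sizes
        if sum(self.block_sizes) != self.n_conditions:
            raise ValueError("block sizes must sum to n_conditions")


def toy_model(variant: str = "chain") -> MetabolicModel:
    """Tiny single-metabolite models with documented LP optima.

    ``chain``: uptake (bound 10) feeds metabolite M, consumed by biomass
    and product drains.  Max biomass = 10; lexicographic
    [biomass, product] = (10, 0).

    ``branch``: same topology, but the biomass drain has capacity 6, so
    the lexicographic solve leaves slack for the product:
    [biomass, product] = (6, 4).
    """
    if variant not in ("chain", "branch"):
        raise ValueError(f"unknown toy variant {variant!r}")
    bio_ub = 1000.0 if variant == "chain" else 6.0
    gprs: list[Gpr | None] = [
        parse_gpr("gU"),
        parse_gpr("gB1 AND gB2") if variant == "branch" else parse_gpr("gB1"),
        parse_gpr("gP1 OR gP2"),
    ]
    genes = sorted({g for t in gprs if t is not None for g in t.genes()})
    return MetabolicModel(
        metabolite_ids=["M"],
        reaction_ids=["R_uptake", "R_biomass", "R_product"],
        A=np.array([[1.0, -1.0, -1.0]]),
        v_min=np.zeros(3),
        v_max=np.array([10.0, bio_ub, 1000.0]),
        gpr=gprs,
        gene_ids=genes,
        id=f"toy_{variant}",
    )


def toy_objectives(model: MetabolicModel):
    """The standard lexicographic objective pair [biomass, product]."""
    from .fba import ObjectiveSpec

    return ObjectiveSpec.from_reaction_ids(model, ["R_biomass", "R_product"])


def planted_compendium(
    spec: FixtureSpec, model: MetabolicModel | None = None
) -> ExpressionCompendium:
    """An expression compendium with planted condition clusters.

    Gene ids start with the model's genes (when a model is given) and are
    padded with filler genes up to ``n_genes``.  A discriminative set — the
    model's uptake-controlling gene ``gU`` (if present) plus the first
    filler genes up to ``n_discriminative`` — gets cluster-specific mean
    log-ratios spread evenly in ``[-effect_size, +effect_size]``; all other
    genes have mean log-ratio 0.  Values are ``exp(mean + noise)`` with
    ``noise ~ N(0, noise_sd^2)``.  Ground-truth labels live in
    ``metadata["cluster"]``.
    """
    rng = np.random.default_rng(spec.seed)
    model_genes = list(model.gene_ids) if model is not None else []
    genes = list(model_genes)
    filler = 0
    while len(genes) < spec.n_genes:
        genes.append(f"gene_{filler:03d}")
        filler += 1
    disc = []
    if "gU" in genes:
        disc.append("gU")
    for g in genes:
        if len(disc) >= spec.n_discriminative:
            break
        if g not in model_genes and g not in disc:
            disc.append(g)
    if spec.n_clusters > 1:
        offsets = np.linspace(-spec.effect_size, spec.effect_size, spec.n_clusters)
    else:
        offsets = np.zeros(1)
    labels = np.concatenate(
        [np.full(sz, c + 1) for c, sz in enumerate(spec.block_sizes)]
    ).astype(int)
    mean_log = np.zeros((spec.n_conditions, len(genes)))
    disc_idx = [genes.index(g) for g in disc]
    for i, lab in enumerate(labels):
        mean_log[i, disc_idx] = offsets[lab - 1]
    noise = rng.normal(0.0, spec.noise_sd, size=mean_log.shape)
    values = np.exp(mean_log + noise)
    condition_ids = [f"cond_{i:03d}" for i in range(spec.n_conditions)]
    frame = pd.DataFrame(values, index=condition_ids, columns=genes)
    meta = pd.DataFrame(
        {"cluster": labels, "discriminative_genes": [",".join(disc)] * len(labels)},
        index=condition_ids,
    )
    return ExpressionCompendium(values=frame, metadata=meta)


def planted_multiplex(
    spec: FixtureSpec,
    n_layers: int = 2,
    within_sim: float = 0.8,
    between_sim: float = 0.2,
) -> MultiplexNetwork:
    """A multiplex of noisy block-structured similarity layers.

    Each layer is ``within_sim`` on the diagonal blocks and ``between_sim``
    off them, plus symmetric Gaussian noise of sd ``spec.noise_sd``
    (different realization per layer), clipped to [0, 1]; diagonals are 1.
    """
    if not 0 <= between_sim < within_sim <= 1:
        raise ValueError("need 0 <= between_sim < within_sim <= 1")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_conditions
    labels = np.concatenate(
        [np.full(sz, c + 1) for c, sz in enumerate(spec.block_sizes)]
    )
    base = np.where(labels[:, None] == labels[None, :], within_sim, between_sim)
    layers = []
    node_ids = [f"cond_{i:03d}" for i in range(n)]
    for _ in range(n_layers):
        noise = rng.normal(0.0, spec.noise_sd, size=(n, n))
        noise = (noise + noise.T) / 2.0
        W = np.clip(base + noise, 0.0, 1.0)
        np.fill_diagonal(W, 1.0)
        layers.append(SimilarityLayer(W, node_ids))
    K = max(2, n // 3)
    return MultiplexNetwork(
        layers=layers, bias=np.ones(n_layers), K=K
    )
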