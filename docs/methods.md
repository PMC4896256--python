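# Methods

## Model and assumptions

`fluxfuse` links three layers of description of a bacterial growth
condition: the expression profile (ratio to a wild-type reference, so 1 is
"unchanged"), the condition-specific flux distribution predicted from it,
and networks of pairwise condition similarity built on each.

The flux prediction rests on the standard constraint-based assumptions:
steady state (Av = 0), flux bounds as the only kinetic information, and
optimality of one or a few cellular objectives. Two further assumptions
are specific to the expression mapping:

1. **Time-scale separation** — metabolism equilibrates faster than the
   transcriptional state changes, so each expression profile can be mapped
   to its own steady-state model.
2. **Variance encodes importance** — genes with low expression variance
   across conditions are assumed tightly regulated and metabolically
   important, so their deviations from the reference move flux bounds more
   strongly. This enters as the 1/σ² weight inside the bound map.

The bound map itself is logarithmic, φ(Θ) = [1 + (γ/σ²)|log Θ|]^sgn(Θ−1):
saturating for extreme expression values (a doubling of an already high
transcript level should not double the attainable flux), approximately
linear near Θ = 1, exactly neutral at the reference, and continuous down
to φ(0) = 0 where it reproduces on/off gating. The identity
φ(Θ)·φ(1/Θ) = 1 makes up- and down-regulation symmetric on the ratio
scale; it holds for any log base, γ and σ².

Multi-objective behaviour is modelled lexicographically: up to three 0/1
objective selectors are maximized in priority order, each level being
constrained to (near) its optimum before the next is solved. The first
selector is the innermost, binding objective (biomass in all shipped
examples); the outer levels explore the optimal set it leaves. This is
not an adversarial bilevel program — every level maximizes.

## Similarity layers and weighted fusion

Both omic matrices (conditions × genes, conditions × reactions) are
prepared identically: feature columns with fewer than 10 % known finite
values are dropped (strict "less than"; a column at exactly 10 % is kept);
remaining missing entries are imputed with the column median; each column
is rank-discretized into 20 quantile bins (ties receive averaged ranks,
mapped by ceil(rank/n·20) and clamped to [1, 20]). Discretization depends
only on within-column ranks, which neutralizes the very heavy tails that
both predicted fluxes and expression ratios display without deleting the
outliers themselves — all-or-nothing responses are biologically meaningful
and are kept.

Each layer's similarity is Pᵢⱼ = exp(−dᵢⱼ²) on Euclidean distances between
the discretized rows. Raw distances in high dimension make this kernel
underflow to exactly zero off-diagonal rows, which the downstream
normalization rightly rejects as a disconnected node; `layer_from_features`
therefore divides distances by their median by default (any fixed positive
scale preserves the ranking of similarities). A locally scaled alternative
kernel, exp(−dᵢⱼ²/(μ·εᵢⱼ)) with εᵢⱼ the mean of the two nodes' K-nearest
squared distances and dᵢⱼ² itself, is also provided; defining ε on the
squared-distance scale makes the exponent dimensionless, so this kernel is
invariant to any global rescaling of the data.

Fusion initializes each layer's status matrix with the robust
normalization P₀(i,j) = W(i,j)/(2Σ_{k≠i}W(i,k)) off the diagonal and 1/2
on it (rows sum to 1; the diagonal is decoupled from the raw
self-similarity), builds the K-nearest-neighbour kernel S per layer
(neighbourhoods of size K in which the node itself competes like any
other; entries outside the neighbourhood are exactly zero; rows
normalized), and iterates

    P⁽ᵛ⁾ ← S⁽ᵛ⁾ · [Σ_{k≠v} b_k P⁽ᵏ⁾ / Σ_{k≠v} b_k] · S⁽ᵛ⁾ᵀ

for all layers simultaneously from the pre-update state (so the per-layer
updates are order-independent and parallelizable). Three numerical
choices stabilize the iteration:

- **Identity regularization.** After each cross-diffusion step the
  identity is re-added. Without this self-similarity anchor the update's
  stationary state is the uniform matrix — iterating the bare update
  provably erases all block structure (we observe within/between contrast
  decaying to 1.0). With it, the iteration sharpens contrast instead.
- **Symmetric row-stochastic projection.** Each iterate is alternately
  row-normalized and symmetrized until row sums are within 10⁻¹⁰ of 1 (a
  symmetric Sinkhorn scaling); the iterate is then simultaneously
  symmetric and row-stochastic, so neither property drifts.
- **Derivative-based convergence.** The change scalar cₙ (mean relative
  Frobenius change across layers) must satisfy cₙ < 10⁻⁶ and
  |cₙ − cₙ₋₁| < 10⁻⁶; the cap is 20 iterations (typical runs converge in
  10–17). A cₙ rising for five consecutive iterations flags divergence
  and returns the partial result.

**Where the bias acts.** With two layers the weighted mean inside the
update has a single term, so the per-layer bias cancels algebraically
there — a 2:1 fluxome:transcriptome weighting would be a no-op if it
entered only the update. The bias is therefore also applied in the final
aggregation, fused = Σ_v b_v P⁽ᵛ⁾ / Σ_v b_v, where it provably moves the
result monotonically toward the trusted layer. `bias_mode`
("update" / "aggregate" / "both", default "both") selects where it
enters; with three or more layers the update-level bias is active too.
The weighted mean is normalized by Σ_{k≠v} b_k so that equal biases reduce
exactly to the unweighted mean over the other layers.

## Downstream analysis

Spectral clustering uses the normalized graph Laplacian of the fused
matrix with k-means on the leading eigenvectors; the k-means seed is
explicit, labels are renumbered by first appearance, and a similarity
graph with more connected components than k triggers a warning rather
than an error. The cluster count k is a user choice (no automatic
selection).

Attribution fits a CART tree (Gini impurity) on the flux matrix against
the cluster labels, capped at `max_rules` internal splits
(`max_leaf_nodes = max_rules + 1`); it reports the features used, their
split thresholds, Gini importances and training accuracy. Bootstrap
stability refits the tree on `n_resamples` draws of 80 % of the
conditions without replacement and reports, per feature, the fraction of
resamples in which it was among the top-2 split features. Resamples that
lose all but one cluster are skipped and do not count toward the
denominator.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| γ (`MapParameters.gamma`) | 1 | — | weight of 1/σ² in φ; larger γ lets expression tune fluxes more aggressively |
| log base | e | — | base of the log in φ; any base > 1, reciprocal symmetry holds for all |
| σ² floor | 10⁻⁶ | — | lower floor on gene-set variance; keeps φ finite for genes constant across conditions |
| default bound M | 1000 | mmol h⁻¹ gDW⁻¹ | bounds when a model file omits them: (−M, M) reversible, (0, M) irreversible |
| `fix_tol` | 10⁻⁹ | relative | slack when fixing a solved objective level; 10⁻⁹ keeps the leaked slack (≈ bound-scale × fix_tol) well below reporting precision while leaving the optimal face numerically non-empty for HiGHS |
| finite-fraction threshold | 0.10 | — | features with a smaller finite fraction are dropped |
| quantile bins | 20 | — | rank discretization granularity |
| K | n/3 (estimator default) | nodes | neighbourhood size of the local kernel |
| bias b | 1 per layer | — | per-layer confidence; 2:1 fluxome:transcriptome is a reasonable setting for a curated model |
| `max_iter`, tolerances | 20, 10⁻⁶, 10⁻⁶ | — | fusion cap and the two derivative tolerances |
| `max_rules` | 2 | splits | tree size for attribution |

Missing genes in a condition's profile evaluate to the neutral ratio 1;
missing variances to 0 (then floored). Expression tables must already be
on the ratio scale; `from_log2_ratios` converts log₂-ratio tables.

## Synthetic study conditions

The generators define the desk-scale conditions under which the toolkit
is validated:

- **Toy models** (`chain`, `branch`): one metabolite, three reactions,
  uptake capped at 10 mmol h⁻¹ gDW⁻¹. The chain's lexicographic
  [biomass, product] optimum is (10, 0); the branch caps the biomass
  drain at 6, giving (6, 4). Both are verified against exhaustive vertex
  enumeration of the flux polytope.
- **Planted compendium**: 90 conditions in 3 equal classes over 50 genes,
  of which 15 (including the toy uptake gene) shift their mean log-ratio
  by ±1.5 natural-log units (≈ 4.5-fold) between the extreme classes;
  log-normal noise with σ = 0.3 (≈ 1.35-fold scatter). These magnitudes
  sit in the range of strong environmental responses in bacterial
  compendia; the noise-free and zero-effect corners degenerate as
  expected (identical rows; no recoverable structure).
- **Planted multiplex**: block similarity matrices (within 0.8, between
  0.2) plus symmetric Gaussian noise, clipped to [0, 1], unit diagonal;
  layers share the partition and differ by noise realization.

What passing on these fixtures does *not* show: the generators have
independent, homoscedastic log-normal noise, no gene–gene correlation
structure, no regulon or operon structure, no batch effects, and
condition classes of equal size. Real compendia violate all of these;
recovery rates measured here are upper bounds on what equally strong real
structure would yield. The toy models likewise exercise the LP machinery,
not the numerical behaviour of genome-scale (thousands-of-reactions)
models.

## Known limitations

- The LP layer targets small-to-medium models; very large SBML models are
  parsed through cobrapy but each condition's lexicographic solve builds
  a dense LP, so genome-scale compendium runs are compute-bound.
- The fused network's absolute entry scale is algorithm-defined (row
  sums 1 plus the identity anchor); only relative similarities are
  meaningful.
- Reaction-specific variants of φ (e.g. informed by protein abundance)
  are out of scope; φ is global with per-reaction Θ and σ².
- Cluster-count selection is manual by design.
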