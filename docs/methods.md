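# Methods

## Model spaces and conventions

Three constant-curvature model spaces are supported. The curvature scale
`C > 0` parameterizes the squared radius:

* **Spherical** `S^d_C`: the sphere `Σ pᵢ² = C` in `R^{d+1}`;
  `d(x,y) = √C·arccos(⟨x,y⟩/C)`, geodesic diameter `π√C`.
* **Hyperbolic** `H^d_C`: the upper sheet (`p₀ > 0`) of the hyperboloid
  `−p₀² + Σ_{i≥1} pᵢ² = −C` in Minkowski space with
  `⟨u,v⟩_L = −u₀v₀ + Σ_{i≥1} uᵢvᵢ`; `d(x,y) = √C·arcosh(−⟨x,y⟩_L/C)`.
* **Euclidean** `E^d`: flat `R^d`.

Curved components use one extra ambient coordinate (`d+1` for manifold
dimension `d`). A product manifold is an ordered list of components (its
signature, written compactly as e.g. `H50_1.0 x E50`); squared product
distances are sums of squared component distances. Tangent vectors at a
point satisfy `⟨v,x⟩ = 0` (Euclidean inner product, sphere) or
`⟨v,x⟩_L = 0` (hyperboloid); exp and log maps use the standard
closed forms with `cos/sin` and `cosh/sinh` scaled by `√C`. The spherical
log map is the one consistent with this exp map (verified by exp∘log
round-trip tests rather than taken from any printed formula, which
typesetting tends to mangle).

Numerical conventions:

* `arccos` arguments are clamped to `[−1, 1]`, `arcosh` arguments to
  `[1, ∞)`; drift beyond 1e-12 is logged at debug level.
* Tangent vectors with norm below 1e-12 are treated as exactly zero and
  `exp(x, 0)` returns `x` bit-for-bit (the closed forms divide by ‖v‖).
* A point counts as on-manifold when its constraint residual is ≤ 1e-6.
* After every optimizer retraction, points are re-projected onto the
  constraint surface: spheres rescale radially, hyperboloids recompute
  `p₀` from the spatial part. This keeps the residual at rounding level
  over arbitrarily long optimizations.
* Spherical gradient factors are zeroed within 1e-9 of the cut locus
  (antipodal pairs), where the distance is not differentiable.

## Distortion-minimizing embeddings

The loss is the relative squared-distance deviation summed over unordered
node pairs, `L(f) = Σ_{u<v} ((d_P/d_G)² − 1)²`; an absolute-value variant
`Σ |(d_P/d_G)² − 1|` is available behind `loss_form="abs"`. Training is
full-batch Riemannian gradient descent for graphs up to 200 nodes (exact
and cheap at pathway scale) and sampled pair minibatches above, rescaled
to estimate the full pair sum.

Gradients of the pair sum are large early in training (random
initializations start far from the targets), so per-point geodesic step
lengths are clipped at 1.0; this also prevents spherical steps from
overshooting the injectivity radius. The learning rate decays
exponentially to 10% of its initial value over the run
(`final_lr_fraction=0.1`), which measurably improves the curved-space
optima without affecting the flat case. Defaults: 1,000 epochs, learning
rates {0.01, 0.1} in sweeps.

Initialization: spherical points uniform on the sphere; hyperbolic points
the exp-image of per-coordinate unit Gaussian tangent noise at the origin;
Euclidean points unit Gaussian. All randomness flows through a single
seed.

**Distortion** is reported as the mean of `|d_P − d_G|/d_G` over ordered
pairs `u ≠ v`. A `normalization="v_squared"` switch divides the same sum
by `|V|²` instead (the two differ by the factor `(|V|−1)/|V|`); the
ordered-pair mean is the default because the diagonal contributes nothing
to the sum. Disconnected graphs are restricted to their largest connected
component (with a warning) before embedding — graph-distance losses are
undefined for unreachable pairs — and isolated nodes are dropped by the
same rule.

## Signature sweeps

`signature_grid` enumerates all component-count combinations with 0–3
components per space type (at least one overall), dimensions split as
evenly as possible under a fixed total budget of 100 (e.g. 34+33+33 for
three components), learning rates {0.01, 0.1} and curvature scale 1.0 by
default. `sweep_and_select` trains every configuration and returns the
minimum-distortion signature, or a tie flag when distinct signatures agree
within a relative tolerance of 1e-4 — tied graphs have no canonical best
space and downstream comparisons skip them. The same learning rate
reaching the minimum with the same signature never counts as a tie.

**Curvature and scale.** A sphere with `C = 1` has geodesic diameter π, so
pathway-scale cycles (diameter well above π) can never be represented at
low distortion by spherical components at the default curvature. Geometry
recovery sweeps (`geometry_recovery_grid`) therefore offer each curved
component at two scales: `C = 1` and the scale-matched
`C = (diam(G)/π)²`, the squared radius at which the sphere's
farthest-point distance equals the graph diameter. With this grid, a
20-cycle reaches distortion ≈ 2e-4 on a scale-matched sphere versus
≈ 0.10 in flat space, and a depth-4 binary tree reaches ≈ 0.03 with a
hyperbolic component versus ≈ 0.097 Euclidean.

Low-dimensional circle fits (`S¹`) additionally need a multistart: a
random initial circular ordering of the nodes is usually wrong and
gradient flow must pass points through each other to fix it; about half
of the seeds succeed on a 6-cycle, so sweeps over ≥ 5 seeds are used
where a 1-dimensional sphere matters.

## Baselines

* **Graph Laplacian**: rows of the eigenvector matrix of the combinatorial
  Laplacian `L = D − A` (eigenvalues ascending, dimension `|V|`, constant
  null vector kept). Eigenvector signs are fixed so each vector's
  largest-magnitude entry is positive, making the embedding deterministic.
  The normalized-Laplacian variant was considered and not used; the
  combinatorial form is the plainest reading of "graph Laplacian".
* **node2vec**: biased second-order random walks (return bias p, in–out
  bias q, defaults 1.0; walk length 80, 10 walks per node, window 10)
  feeding a from-scratch skip-gram with negative sampling: 5 negatives per
  pair from the unigram^{3/4} distribution, minibatched SGD with linear
  learning-rate decay, single-threaded and deterministic under its seed.
  Batch sizes are capped at 4× the node count because scatter-accumulated
  duplicate-row updates diverge when the batch greatly exceeds the
  vocabulary.
* **Scaling optimization**: embeddings that do not optimize distortion
  carry an arbitrary global scale, so before comparing distortions the
  constant `c` minimizing `Σ_{i<j} (c·d(x_i,x_j)/d_G(n_i,n_j) − 1)²` is
  applied; the closed-form minimizer is `c* = Σ r / Σ r²` with
  `r = d/d_G`. `c` is computed per graph (the stricter contract); a
  dataset-level aggregate is a pooling of the same ratios.

## Product GCN

One GCN stack per signature component, default depth 2. Each layer maps
points to the tangent space at the component origin via the log map,
applies `Ã = D̃^{-1/2}(A+I)D̃^{-1/2}` aggregation and a linear transform
there, then maps back with the exp map. The origin basepoint (rather than
per-node basepoints) keeps layers well-defined and is the established
convention for hyperbolic GCNs. Activation is ReLU on Euclidean tangents
and identity on curved ones (hidden layers only); attention layers are
omitted, with a hook left in the layer interface.

Pretrained product embeddings enter per component, already on-manifold.
Flat pretrained embeddings (node2vec, Laplacian, Euclidean) are sliced
into `floor(total/k)` dimensions per component — trailing remainder
dimensions are dropped with a warning (a 100-d embedding over a
7-component signature gives 7 slices of 14) — and lifted onto each
manifold by exp at the origin. When the GCN's curvature hyperparameter
differs from the embedding's, points are re-projected onto the new
constraint surface (radial rescale / recomputed time coordinate).

Edges are scored per component by a Fermi–Dirac decoder on the component
distance, `s_c = 1/(exp((d_c² − r_c)/t_c) + 1)` with trainable radius
`r_c` (init 2.0) and temperature `t_c` (init 1.0); the final score is the
arithmetic mean over components, strictly decreasing in every component
distance.

Training minimizes binary cross-entropy on observed edges against one
uniformly resampled non-edge per positive per epoch. Validation AUROC/AP
against a fixed seeded negative sample are evaluated every 5 epochs, and
the parameter snapshot with the best validation mean(AUROC, AP) is kept
(early stopping) — the validation set's stated role is to guide model
training and selection. All default trainable parameters (weights,
biases, decoder r/t) are flat vectors, so Riemannian Adam reduces to
standard Adam for them; optional embedding fine-tuning treats node points
as manifold parameters with ambient-coordinate moments and exp-map
retraction (moments are not parallel-transported — a common simplification
that changes the optimizer trajectory but not its fixed points).

Gradients are computed by hand-written reverse-mode accumulation through
the decoder, the layer algebra and the exp/log maps; every
vector-Jacobian product is finite-difference checked in the tests. With
an all-Euclidean signature the entire model reduces exactly (empirically
to ~1e-16) to a plain GCN with the same decoder, which is implemented
independently in `pathcurv.euclidean_gcn` as the reference for that
reduction. A diverging hyperparameter configuration (overflow in a curved
distance) raises a floating-point error that the benchmark sweep catches
and skips.

## Edge-prediction protocol

95% of edges train, 5% validate (at least one validation edge); splits
are uniform under a seed, and a disconnected training graph is logged but
allowed. Negative sampling is uniform over unordered non-adjacent pairs,
balanced 1:1 with positives both for training (resampled each epoch) and
for evaluation (fixed per seed). External candidate tables
(STRING-style, integer scores 0–1000) are filtered at score ≥ 500; rows
whose endpoints are not pathway nodes or that duplicate existing edges
are discarded, and test negatives are drawn from non-edges absent from
the candidate table. Test metrics never influence selection.

The benchmark compares four models — Euclidean GCNs initialized with
node2vec, Laplacian and distortion-trained Euclidean embeddings, and the
Product GCN on the minimum-distortion signature — each swept over
learning rates (and for the Product GCN additionally over three curvature
values, tripling its grid), selecting by the highest validation
mean(AUROC, AP).

## Synthetic data

The fixture generator emulates the pairing of a curated pathway with an
external candidate-edge table: a fraction of edges (holdout ≤ 0.5) is
withheld from the graph and planted in the table with scores ≥ 800, and
distractor non-edges carry uniform scores over 0–1000 so the ≥ 500 filter
removes roughly half. Generators cover balanced trees, cycles, 2-D grids,
trees-of-cycles, Erdős–Rényi and two-block planted-partition graphs at
10–300 nodes, the size range typical of curated pathways; the labeled
geometry suite (tree→hyperbolic, cycle→spherical, grid→euclidean-
competitive, tree-of-cycles→mixed) operationalizes the premise that
topology determines the best signature.

What the synthetic graphs do **not** capture: the degree heterogeneity,
annotation noise and biological context of real pathway databases, or the
distribution shift between curated pathway edges and external interaction
evidence. Passing tests demonstrate that the geometry machinery and the
training pipeline behave as designed, not that any particular biological
database will favor a particular signature. On the planted-partition
benchmark specifically, withheld within-block edges are statistically
indistinguishable from within-block non-edges, so measured AUROC mixes
true signal (block recovery) with favorable ranking noise; block-level
structure is the only recoverable signal by construction.

## Problem sizes

Default experiment scales were chosen to keep a full sweep interactive on
one CPU: embeddings are full-batch for ≤ 200 nodes; geometry-recovery
sweeps use a 31-node tree and a 20-cycle at total dimension 100 over 5
seeds; the edge-prediction benchmark uses 60-node planted-partition
graphs with 100 GCN epochs. All of these are ordinary pathway scales
(median curated pathways have a few dozen nodes).

## Known limitations

* No parallel transport: Adam moments for manifold parameters live in
  ambient coordinates; fine-tuning embeddings is therefore a retraction-
  based approximation.
* Curvature is a per-configuration constant, not learned.
* Spherical components depend on the scale-matched curvature heuristic
  for large-diameter graphs; a curvature line search would be more
  thorough and proportionally slower.
* `S¹` fits are multistart-dependent (see above).
* The node2vec trainer is exact but not performance-tuned; graphs far
  beyond 300 nodes will want a compiled implementation.
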