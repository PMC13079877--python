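# Methods

## The model

`gibbsnet` treats the molar excess Gibbs energy of an N-component liquid
mixture, expressed as the dimensionless gE/(RT), as the single generating
function of mixture thermodynamics.  Every derived property is an exact
derivative of it:

- activity coefficients:
  ln γ_i = g + ∂g/∂x_i − Σ_{j<N} x_j ∂g/∂x_j (i < N) and
  ln γ_N = g − Σ_{j<N} x_j ∂g/∂x_j, with g = gE/(RT) a function of the
  N−1 independent mole fractions (x_N is reconstructed from the summation
  condition),
- excess enthalpy: hE = −R T² ∂g/∂T at fixed composition,
- liquid-liquid stability: the curvature ∂²Δg_mix/∂x² of the Gibbs energy
  of mixing Δg_mix/(RT) = g + Σ x_i ln x_i.

Because ln γ is a gradient of one scalar, the Gibbs-Duhem relation
Σ x_i d ln γ_i = 0 (constant T, p), the pure-component limits γ_i → 1, and
permutation invariance hold *structurally* — for any parameter values,
trained or not.  The test suite asserts these properties on hundreds of
randomly initialized models.

gE/(RT) is assembled from binary subsystems.  Each component enters as an
embedding vector e_i (computed from its SMILES), standard-scaled and
refined by a one-layer EmbeddingNetwork into θ_i.  A radial-basis
similarity R_ij = exp(−β‖θ_i−θ_j‖²) with β = 100 detects effectively
identical components; lumped fractions x̃_i = Σ_j x_j R_ij and the
symmetric projection X_i^(ij) = (1 + x̃_i − x̃_j)/2 map the mixture onto
each binary pair (the projection is singularity-free at infinite dilution
and reduces to x̃ in the binary case — implemented as 0.5 + (x̃_i − x̃_j)/2
so the binary limit is bit-exact).  Per pair, feature vectors
[θ, X, T*] pass through a shared MixtureNetwork, the two outputs are
summed (a deep-set aggregation, making the pair interaction exactly
symmetric), and a PropertyNetwork head yields a scalar φ_ij.  The binary
interaction q_ij = φ_ij (1 − R_ij) vanishes for identical components, and

    gE/(RT) = Σ_{i<j} x_i x_j q_ij(X_i^(ij), X_j^(ij), T*).

q is predicted directly rather than as a gE divided by X_i X_j, which
avoids divisions by zero at the composition edges.  The reference network
width is 96 (mixture-network input 98 = 96 + X + T*); the scaled-down
studies use width 32.  Hidden activations are SiLU; the property head's
output layer is linear.

## Differentiation engine

No GPU autodiff framework is assumed.  The package ships a small
reverse-mode engine over NumPy (`gibbsnet.autodiff`) whose backward rules
are themselves built from engine primitives, so it is closed under
differentiation: ln γ needs ∂g/∂x (first order), training ln γ needs
parameter gradients of that (second order), and training the Gibbs
stability loss needs parameter gradients of ∂²g/∂x² (third order).  All
array work is vectorized over batches; derivatives are exact to machine
precision (verified against closed forms and finite differences).

## Lipschitz-constrained layers

Every layer of the three networks is a modified linear layer: raw weights
are divided by their largest singular value (estimated by two warm-started
power iterations per training step; frozen and near-converged in
evaluation mode) and rescaled by softplus(c*), a learnable per-layer
Lipschitz constant.  The product of softplus(c*) over all five layers is a
loose bound on the model's Lipschitz constant (activation factors ≤ 1.1
per hidden SiLU are not included in the bound) and enters the loss as a
regularizer.  c* is initialized so that softplus(c*) equals the raw
initialization's spectral norm, making the scaled and raw weights
initially identical.  When the regularizer weight is zero an ordinary L2
penalty on the parameters is used instead.  Weight decay in the optimizer
applies to weight matrices only; biases and c* are exempt (decaying c*
would silently shrink the model's expressiveness).

## Training objective

Mixed batches are drawn from five record types; the total loss is the
weighted sum of per-type sums divided by the batch size N_b.  All data
terms use the smooth-L1 (Huber-style) function with per-type transition
points β:

- TPXY (β = 1): the two ln γ derived from the record's (p, x, y) via
  extended Raoult's law γ_i = p y_i / (p_i^s x_i); the two component
  errors are averaged per record.
- TPX (β = 1): ln of the bubble pressure p = Σ p_i^s x_i γ_i in bar.
- ACI (β = 2): ln γ at infinite dilution, with a factor 1/2 mirroring the
  per-record averaging of the TPXY term.
- LLE (β = 0.35): the frozen surrogate solver maps the model's discretized
  Δg_mix/(RT) curve (101 nodes) to phase compositions (x₁′, x₁″); records
  where the model's curve shows no negative curvature are masked out
  (m_k = 0), and one-phase-only records contribute only the reported
  phase.
- HE (β = 2): excess enthalpy via the temperature derivative, compared in
  kJ/mol (the 1/s_T chain-rule factor comes from the temperature scaler).

Two structural terms complete the objective: the Gibbs stability loss
Σ_k max(0, min_d S_k) — penalizing the *absence* of negative curvature at
states with observed demixing, exactly complementary to the masked LLE
term — and the Lipschitz product.  Default weights
(w_TPX, w_LLE, w_HE, w_Gibbs, w_Lips) = (1, 5, 0.1, 0.1, 1e−6) are
config-exposed.

Optimization uses AdamW with a one-cycle learning-rate schedule
(max_lr = 0.01); the best epoch is selected by the weighted validation
data loss, considering only epochs past a burn-in of half the run.  The
burn-in deliberately covers the schedule's warm-up and peak: with a small
validation set the loss is flat within noise once the model has converged,
and admitting peak-learning-rate epochs would let selection land on
deliberately noisy weights.  Note also that the masked LLE term makes the
selection metric non-monotone in early training — records only start
contributing once the model predicts their miscibility gap — so the
reference point for "how much the validation loss fell" is the untrained
model, recorded before the first optimizer step.  Ensembles average ln γ
arithmetically across members (averaging gE before differentiation is
available behind a flag).

## Surrogate LLE solver

Fitting LLE data directly would put an iterative phase-split solver inside
the training loop.  Instead a three-layer network (101 → 64 → 64 → 2,
ReLU, sigmoid output) learns the map from a discretized Δg_mix/(RT) curve
to (x₁′, x₁″), trained on labels produced by the convex-envelope method on
classical ground-truth curves.  Permutation equivariance is enforced
structurally: the network runs on the curve and its reverse and the
outputs are cross-paired, x′ = (a + (1 − b_r))/2, x″ = (b + (1 − a_r))/2 —
the one pairing that satisfies the reversal identity exactly for arbitrary
weights.  The surrogate trains only on positive samples (curves with a
gap); during gE-model training its weights are frozen and gradients flow
only through its input curve.  Training: Adam, MSE, one-cycle
(max_lr = 0.01), 200 epochs, epoch-best by validation loss.

## Phase equilibria

The convex-envelope method is realized as a monotone-chain lower convex
hull over the discretized curve (101 nodes by default; a config knob).  A
hull edge skipping at least two interior nodes is reported as a
miscibility gap — requiring two skipped nodes makes the detection robust
to float-level wobble on convex curves, at the cost of being blind to gaps
narrower than three grid steps (irrelevant at the parameter ranges
studied).  An independent iterative solver (dense curvature scan for the
spinodal, then a root search on the isoactivity conditions in logit
coordinates) provides reference endpoints; the hull endpoints agree with
it within one grid step across seeded parameter draws.  LLE is treated as
pressure-independent.  Bubble pressures use extended Raoult's law with
Antoine vapor pressures in the log10(p/bar) = A − B/(T/K + C) dialect.
Temperature scans bracket critical solution temperatures at the midpoint
of the step where a gap appears or disappears.

## Synthetic data

Real phase-equilibrium collections are proprietary, so the package
generates its own data from classical models: two-suffix Margules
(A(T) = a + b/T) and binary NRTL (τ_ij = a_ij + b_ij/T, α = 0.3), with
closed-form ln γ and hE that are mutually consistent analytically and are
cross-checked against the autodiff route in the tests.  Components are
fictitious chain molecules; their embeddings come from a deterministic
SHA-256-seeded backend (D = 16).  Crucially, *all* ground-truth
parameters — including the choice of model family — are deterministic
smooth functions of the component embeddings through a fixed random linear
map with tanh squashing: without that link, no model could generalize
across systems from structure alone.  The requested fraction of demixing
systems is met by selecting component pairs, never by perturbing the map.

Records mirror the five experimental types.  Temperatures are drawn
uniformly on [273, 428] K with 5% tails; default per-system counts are
24 TPXY, 12 TPX, 6 ACI, 10 LLE (demixing systems only), 12 HE.  Default
noise: σ(ln p) = 0.01 (multiplicative on pressure), σ(y) = 0.005,
σ(ln γ∞) = 0.02, σ(x_LLE) = 0.005, σ(hE) = 10 J/mol — placeholders chosen
at the scale of good measurements, config-exposed.  A quarter of LLE
records report both phases; the rest report one (flagged), matching the
prevalence of partial records in real collections.  Curation removes
vapor-liquid records above 10 bar and LLE records above 50 bar, and
validates ternary infinite-dilution systems at their pure-solvent
endpoints against binary references within ±5 K, dropping systems with
deviations above 0.1 or no reference.

What the generator does *not* emulate: correlated or heteroscedastic
measurement errors, laboratory-specific biases, chemically meaningful
embedding geometry (embeddings are random vectors, so the structure →
parameter map is smooth but arbitrary), ternary/quaternary records, and
solid-liquid equilibria.  Passing the recovery study therefore shows the
*pipeline* (losses, constraints, surrogate coupling, splitting) is sound,
not that the model matches real mixtures.

## Scaled-down study sizes

The end-to-end recovery study uses 60 binary systems (40% demixing),
embedding dimension 16, model width 32, 100 epochs at batch 128 with one
ensemble member, and a 95/5 system-wise train/validation split; the
surrogate benchmark uses 2000 labeled curves for 200 epochs.  These sizes
keep a full reproduction on a single CPU core in the minutes range while
leaving every mechanism of the full-scale method in place.

## Numerical choices

- R = 8.31446 J/(mol K); temperatures in K, pressures in bar, hE stored in
  J/mol and compared in kJ/mol.
- Standard scaling uses sample standard deviations (ddof = 1) floored at
  1e−8; the embedding statistics pool the distinct components of the
  training split.
- The similarity RBF acts on the embedding network's activated output.
- x ln x terms use the x → 0 limit of 0 exactly; curve endpoints are
  pinned to 0.
- The spinodal mask and the argmin of the stability loss treat the
  discrete grid argmin as locally constant (standard subgradient
  convention).
- Degenerate inputs: zero weight matrices floor the spectral-norm estimate
  at 1e−12; mole fractions are validated to the simplex within 1e−9
  (CLI: 1e−6 with renormalization).

## Known limitations

Pressure dependence of the liquid phase is neglected (hence the pressure
cutoffs); ions and polymers are out of scope; multicomponent LLE
(ternary+) is not constructed — only binary curves enter the surrogate and
envelope machinery; the convex envelope cannot resolve gaps narrower than
three grid steps; and the hash-based embedding backend carries no
chemistry, so trained models transfer only within a synthetic world that
shares the same embedding map.
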