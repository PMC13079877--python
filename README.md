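# gibbsnet

Thermodynamically consistent neural excess-Gibbs-energy (gE) models for
liquid mixtures.

## The problem

Chemical-process design needs activity coefficients γ_i of liquid
mixtures — they set vapor-liquid equilibria, liquid-liquid demixing,
extraction selectivities, and azeotropes.  Classical gE models (Margules,
NRTL, UNIQUAC) are thermodynamically consistent but need fitted
parameters per system; generic machine-learning regressors can predict γ
from molecular structure but routinely violate the constraints that make
predictions physically usable.

`gibbsnet` takes the constrained route: a neural network predicts the
single scalar gE/(RT) of an N-component mixture from per-component
molecular embeddings, temperature T, and composition x, and every derived
property is an *exact derivative* of that scalar,

    ln γ_i = g + ∂g/∂x_i − Σ_{j<N} x_j ∂g/∂x_j,     g = gE/(RT),
    hE     = −R T² ∂g/∂T,
    S(x)   = ∂²Δg_mix/∂x²  (liquid-liquid stability),

so Gibbs-Duhem consistency (Σ x_i d ln γ_i = 0), the pure-component limit
γ_i → 1, and permutation invariance hold by construction, for trained and
untrained weights alike.  Multicomponent mixtures are assembled from
binary subsystems through a lumped, singularity-free symmetric projection
X_i^(ij) = (1 + x̃_i − x̃_j)/2, so a model trained purely on binary data
extrapolates to any N without extra parameters.  Layers are
Lipschitz-constrained (spectrally normalized with learnable constants),
and training covers five data types at once — vapor-liquid records with
and without vapor composition (TPXY/TPX), activity coefficients at
infinite dilution (ACI), liquid-liquid phase compositions (LLE, coupled
through a differentiable surrogate phase-split solver), and excess
enthalpies (HE) — plus a Gibbs stability term that rewards predicting the
miscibility gaps that were observed.

Real training collections of this kind are proprietary, so the package
includes a first-class synthetic-data generator: classical
Margules/NRTL ground truths whose parameters are deterministic smooth
functions of the component embeddings, Antoine vapor pressures, realistic
noise, and the standard curation filters.  Everything — data, surrogate,
training, evaluation, phase diagrams — runs on a single CPU core with no
ML framework dependency (a small NumPy reverse-mode autodiff engine is
part of the package).

## Worked example

Generate a synthetic world, pre-train the surrogate, train a small model,
and look at a mixture:

```bash
gibbsnet simulate --n-systems 60 --seed 1 --out runs/data
gibbsnet train-surrogate --data runs/data --out runs/surrogate.json --seed 1
cat > runs/config.yaml <<EOF
model: {width: 32, d: 16}
train: {epochs: 100, batch: 128, seed: 1}
EOF
gibbsnet train --data runs/data --surrogate runs/surrogate.json \
    --config runs/config.yaml --out runs/model
gibbsnet evaluate --checkpoint runs/model/model.json --data runs/data \
    --out runs/eval
```

Library use, on the package's deterministic synthetic embeddings:

```python
>>> from gibbsnet import Margules, gmix_curve, cem_binary, stability_min
>>> provider = Margules(a=2.5)          # two-suffix Margules, A = 2.5
>>> stability_min(provider, 300.0)
(-1.0, 0.5)
>>> cem_binary(gmix_curve(provider, 300.0))[0]
PhaseSplit(x1_prime=0.14, x1_doubleprime=0.86, gap_index=0)
```

The curvature minimum 4 − 2A = −1 < 0 says the mixture is unstable around
x₁ = 0.5; the convex envelope of the Δg_mix/(RT) curve places the two
coexisting phases at x₁′ = 0.14 and x₁″ = 0.86 on the 0.01 grid (the
iterative isoactivity solver gives 0.1448/0.8552).

Predicting with a model from the command line prints the activity
coefficients and the generating function, e.g. at a pure-component limit:

```
$ gibbsnet predict --smiles CCO --smiles CCCCO --x 1.0 --x 0.0 -T 300
ln gamma_1 =  0.000000  (gamma = 1.000000)  [CCO]
ln gamma_2 =  0.078602  (gamma = 1.081774)  [CCCCO]
gE/(RT) =  0.000000
```

γ₁ = 1 exactly at x₁ = 1 — the consistency constraints do this, not the
training.

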