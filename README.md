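# dvmrank

Reconstructing an evolutionary fitness function from ranked strategies, and
deriving the evolutionarily stable diel vertical migration (DVM) of
zooplankton from it.

## The problem

Herbivorous zooplankton (e.g. *Calanus* copepods) migrate up and down the
water column every day, trading food in the surface layers against the risk
of visual predation and the metabolic cost of swimming. A daily depth
trajectory `x(t)` (t in day fractions, x ≤ 0 in metres) is a heritable
behavioural strategy, and long-term selection should drive the population
toward the trajectory that maximizes evolutionary fitness. The catch is that
fitness is never observed directly — what can be observed (or assumed) is a
*ranking*: which of two strategies wins under selection.

`dvmrank` implements a learning-to-rank route from such pairwise rankings to
an explicit fitness function, and from there to the optimal trajectory:

1. **Macro-parameters.** Each trajectory is summarized by integral
   functionals: daily food intake `M1 = ∫ E(x(t)) dt`, visual-predation
   mortality `M2 = −∫ St(t) Sx(x(t)) dt`, migration cost
   `M3 = −∫ x′(t)² dt`, and unfavourable-depth mortality
   `M4 = −∫ G(x(t)) dt` (doubled to `M1..M8` for a juvenile/adult pair).
2. **Monomial lifting.** A degree-k Taylor form of fitness,
   `F = Σ λ_{i1..in} M1^{i1}···Mn^{in}`, is linear in the lifted monomial
   features `Q = M1^{i1}···Mn^{in}`.
3. **Pairwise linear separation.** A ranked pair (v ≻ w) becomes the feature
   difference `P(v) − P(w)` with label +1. A single-layer perceptron with
   sigmoid output — logistic regression without intercept, trained by
   full-batch gradient descent — separates the two orderings; the hyperplane
   normal *is* the coefficient vector λ (up to positive scale).
4. **ε-perturbation sampling.** Because field data rarely contain enough
   competing strategies, ranked pairs are generated synthetically around an
   assumed-optimal trajectory `x*(t)`: deviations `x* + ε·y(t)` along a
   common periodic direction `y` are ranked by `|ε|` (smaller is fitter).
5. **Optimal control.** The recovered fitness is maximized over periodic
   trajectories — in closed form for the linear/quadratic environment
   (`x*(t) = A + B cos 2πt` with
   `A = (σ1α − σ2γ)/2δ − C0`, `B = −σ2γ/(2δ + 2(2π)²β)`),
   or numerically by a direct Fourier-parameterized quasi-Newton method.
6. **Verification & diagnostics.** A two-stage demographic model with
   analytic (leading-eigenvalue) fitness cross-checks the reconstructed
   quadratic fitness coefficient-by-coefficient; a replicator simulator
   grounds the ranking definition and the entropy-collapse diagnostic.

## Worked example

```python
import numpy as np
from dvmrank import (closed_form_optimum, cosine_trajectory, default_dataset,
                     default_env, evaluate, extract_coefficients,
                     train_separator)
from dvmrank.fitness_optima import study_coefficients

env = default_env("lin-quad")            # E, Sx linear; G quadratic; C0=60 m
coeffs = study_coefficients("lin-quad")  # alpha=1.96, gamma=330, beta=2.5e-5, delta=1e-2

opt = closed_form_optimum(coeffs, env, cadence=8)
print(f"assumed-optimal base: A = {opt.A:.2f} m, B = {opt.B:.2f} m")

base = cosine_trajectory(opt.A, opt.B, L=8, C=env.C)
ds = default_dataset(env, base, seed=0)
print(f"dataset: {len(ds.strategies)} strategies, {len(ds.pairs)} ranked pairs")

model = train_separator(ds, {"seed": 0})
report = evaluate(model, ds.test_pairs, cv_pairs=ds.pairs, seed=0)
print(f"hold-out accuracy = {report.accuracy:.4f}, "
      f"log-loss = {report.logloss:.5f}, 5-fold CV = {report.cv_accuracy:.4f}")

lam = extract_coefficients(model, "unit").lambdas
print("recovered unit-norm coefficients:", np.array2string(lam, precision=4))
```

prints

```
assumed-optimal base: A = -85.00 m, B = -45.83 m
dataset: 202 strategies, 2031 ranked pairs
hold-out accuracy = 1.0000, log-loss = 0.01557, 5-fold CV = 1.0000
recovered unit-norm coefficients: [ 2.3623e-02  9.9972e-01  2.8453e-06 -5.8229e-05]
```

Reading the output: the base trajectory has mean depth 85 m and
half-amplitude ~46 m (negative B: the animal is deepest when visual
predators are most active, surfacing half a day later — the classic DVM
pattern). The 202 perturbed strategies yield 2031 same-direction ranked
pairs; the no-intercept separator classifies held-out pairs essentially
perfectly, and its normal vector aligns with the generating coefficient
direction to cosine similarity ≈ 0.9998 (the λ vector is only defined up to
positive scale, and with three perturbation directions the weakly loaded
`M3`/`M4` slots are identified only loosely — the ranking itself is what is
well determined).

The same workflow is available from the shell:

```bash
dvmrank generate --out pairs.csv
dvmrank train --pairs pairs.csv --out model.json
dvmrank evaluate --model model.json --pairs pairs.csv
dvmrank optimize --closed-form --coeffs '{"alpha":1.96,"gamma":330,"beta":2.5e-5,"delta":0.01}'
dvmrank verify --point 0.1195,0.0075,0.2344,0.1086
dvmrank run --out-dir run/       # full pipeline + manifest
```

## Layout

| module | contents |
| --- | --- |
| `dvmrank.environment` | lin-quad and hyperbolic profile families `E, Sx, St, G` |
| `dvmrank.trajectories` | periodic trajectories, discrete/integral `M` functionals |
| `dvmrank.feature_space` | monomial lifting, pair differences, fitness evaluation |
| `dvmrank.sample_generator` | ε-perturbation ranked-dataset construction |
| `dvmrank.ranking_classifier` | no-intercept separator, evaluation, k-NN baseline |
| `dvmrank.fitness_optima` | closed-form cosine optimum and quadratic fitness |
| `dvmrank.optimal_control` | direct Fourier/quasi-Newton trajectory optimization |
| `dvmrank.stage_verification` | two-stage demographic model, h-coefficient algebra |
| `dvmrank.selection_dynamics` | replicator simulator, tail ranking, Shannon entropy |
| `dvmrank.interface`, `dvmrank.cli` | CSV/JSON/YAML formats, pipeline, `dvmrank` CLI |

See `docs/methods.md` for the modelling assumptions, parameter defaults and
numerical choices.
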