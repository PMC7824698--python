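# Methods

## Model overview

A zooplankton strategy is a 1-periodic daily depth path `x(t)`, `t` in day
fractions, `x ≤ 0` in metres (signed; "depth 80 m" is `x = −80`). Fitness is
assumed to be a function of a small vector of integral macro-parameters of
the path — food intake, visual-predation mortality, migration cost and
unfavourable-depth mortality — and is reconstructed from pairwise strategy
rankings rather than estimated from demographic rates. The reconstruction
reduces to training an origin-through linear separator on lifted-feature
differences of ranked pairs; the separator's normal vector is the Taylor
coefficient vector of fitness, defined up to a positive scale.

## Environments

Two profile families on the column `−C < x ≤ 0`, both with diel predator
activity `St(t) = cos(2πt) + 1`:

* **lin-quad**: `E = σ1(x+C)`, `Sx = σ2(x+C)`, `G = (x+C0)²`.
  Defaults `C = 140 m`, `C0 = 60 m`, `σ1 = 0.25`, `σ2 = 0.003`.
* **hyperbolic**: `E = σ1(tanh(ξ1(x+C1)) + 1)`,
  `Sx = σ2(tanh(ξ2(x+C1)) + 1)`, `G = cosh(ξ3(x+C0))`.
  Defaults `C = 140 m`, `C0 = 80 m`, `C1 = 40 m`, same σ's,
  `ξ1 = ξ2 = 0.025 /m`, `ξ3 = 0.2 /m`.

Units: σ1 is food per metre of height above `−C`; σ2 per metre; ξ's are
rates per metre; `St` is dimensionless with unit daily mean, so `M2`
carries the same scale as `Sx`.

Phase convention: `t = 0` is taken as the peak of visual-predator activity
(`St(0) = 2`). With the closed-form amplitude `B < 0`, the optimal animal
is deepest at `t = 0` and shallowest half a day later. Only the relative
phase of `St` and the trajectory matters anywhere in the package.

## Macro-parameters

Continuous form: `M1 = ∫₀¹ E(x(t)) dt`, `M2 = −∫ St·Sx dt`,
`M3 = −∫ x′(t)² dt`, `M4 = −∫ G dt`; for a two-stage (juvenile, adult)
strategy the same four functionals of the adult path are `M5..M8`.
Sign convention: `M1, M5 ≥ 0`, all others ≤ 0, so all fitness weights are
positive.

Discrete form (the field cadence is `L = 8` samples per day, every 3 h):
plain sums over the sample grid, velocity by the central difference
`x′(t_l) ≈ (x_{l+1} − x_{l−1})/(2Δt)` with periodic index wraparound. The
common `Δt` factor is deliberately dropped — it rescales every fitness
coefficient by the same positive constant and cannot affect a ranking.
The central difference attenuates Fourier mode `m` of the velocity by
`sin(2πm/L)/(2πm/L)`; at `L = 8` the migration-cost term of a daily cosine
is therefore underestimated by the factor `sinc(2π/8)² ≈ 0.81`.
Closed-form checks consequently use the integral form (adaptive quadrature,
default tolerance 1e−10) or large `L`.

## Closed-form optimum and the discrete-cadence base

For the lin-quad environment the linear fitness
`F = αM1 + γM2 + βM3 + δM4` is maximized by the daily cosine
`x*(t) = A + B cos(2πt)` with

    A = (σ1α − σ2γ)/(2δ) − C0,
    B = −σ2γ / (2δ + 2(2π)²β).

At the package's reported coefficient set (α = 1.96, γ = 3.3·10²,
β = 2.5·10⁻⁵, δ = 10⁻²) this gives `A = −85 m` and `|B| = 45.05 m`.

`closed_form_optimum(..., cadence=L)` instead returns the maximizer of the
*L-point discrete* fitness: the circulant structure keeps it a cosine with
the same mean depth, but the `sinc(2π/L)²` attenuation of β enlarges the
amplitude (`|B| = 45.83 m` at `L = 8`). The synthetic-data generator uses
this discrete optimum as its base strategy: the construction ranks
perturbations by `|ε|` on the premise that the base maximizes the sampled
fitness, and with a base that is optimal only for the continuous problem a
small fraction (~1.5%) of labels near the discrete optimum would contradict
every linear separator, which is a property of the sampling cadence rather
than of the method under study.

## Synthetic ranked-pair generation

The generator emulates the construction of a learning sample around an
assumed-optimal strategy:

* **Directions.** Seeded random Fourier directions `y(t)` with modes 0..3,
  sup-normalized to 1 so ε carries the physical scale (metres). Default 3
  directions. Where a full ε-step would leave the water column, the
  direction is shrunk just enough to fit (with a 1 m buffer); shrinking
  rescales the metre-per-ε step along that direction and preserves every
  same-direction ranking, and it keeps the strategy count deterministic.
* **ε grid.** 34 positive magnitudes `linspace(0.5, 20, 34)` m and their 33
  smallest negatives: 67 signed values per direction, chosen so that
  3 directions × 67 + the base = 202 strategies. The 20 m cap keeps
  perturbations small relative to the 45 m base amplitude yet resolvable at
  L = 8; 0.5 m is the smallest deviation meaningfully distinguishable from
  measurement jitter in depth records.
* **Pairs.** Only strategies sharing a direction (or one being the base)
  are comparable; the smaller `|ε|` is labelled fitter; `|ε|` ties are
  skipped. The candidate list is subsampled to 2031 pairs with the run
  seed, and each pair's orientation is randomized so labels are balanced.
  An alternative "oracle" policy labels arbitrary pairs by a supplied true
  fitness, used for parameter-recovery validation.
* **Split.** Seeded 70/30 pair-level train/test split (rounded to the
  nearest integer: 1422/609 at 2031 pairs).
* **Two-stage strategies** perturb juvenile and adult paths with
  independent directions but a shared ε, so the scalar `|ε|` ranking still
  applies.

What the generator does *not* emulate: observation noise in depth records,
non-periodic behaviour, stage-dependent cadences, and any environmental
stochasticity. Passing tests therefore demonstrate that the pipeline
recovers a fitness consistent with its own ranking premise at realistic
sample sizes — not that field rankings of real trajectories are noiseless
or perfectly transitive.

## Separator training

The ranked-pair classifier is logistic regression without an intercept —
equivalently a single-layer perceptron with sigmoid output — so that the
decision is exactly antisymmetric under swapping a pair and the hyperplane
passes through the origin, as the coefficient-extraction argument requires.
Training minimizes the mean logistic loss with an L2 penalty
(default 1e−6, applied in the whitened gauge) over the antisymmetrically
augmented set {(d, y)} ∪ {(−d, −y)} by a deterministic full-batch
first-order method:

* features are whitened with the Cholesky factor of their covariance
  (the lifted columns are correlated at |r| > 0.97 and per-column scaling
  alone leaves condition numbers in the thousands);
* gradient steps carry Nesterov momentum; any step that would increase the
  loss triggers a momentum restart and step-size backtracking, so the loss
  curve is non-increasing by construction; the step grows 2% per epoch
  otherwise (defaults: initial step 0.1, 2000 epochs);
* the learned normal is mapped back to raw feature coordinates.

Non-uniqueness of the separating hyperplane is real: with only three
perturbation directions the pair differences populate a thin cone in
feature space, and weakly loaded coefficient slots (β, δ in the default
setup) are poorly identified even when the ranking is classified
perfectly. Fixing the seed, the regularization and the normalization
("unit": ‖λ‖₂ = 1, M1-coefficient ≥ 0; "match": pin one slot to a
reference value) makes runs reproducible. Evaluation reports hold-out
accuracy, natural-log loss with probabilities clipped to
[1e−12, 1 − 1e−12], seeded 5-fold cross-validated accuracy (refitting per
fold), and a Euclidean k-NN baseline on the same splits for comparison.

## Direct optimal control

Fitness maximization over periodic trajectories is done directly rather
than through the Pontryagin boundary-value problem: the trajectory is a
truncated Fourier series (default 5 modes), the daily integrals are
evaluated on a fixed 256-point periodic trapezoid grid (spectrally exact
for these band-limited integrands), the depth box (default `(−C+1, 0)` m)
enters as a smooth quadratic penalty (weight 1e4) with a post-hoc hard
check, and seeded multistart L-BFGS-B (default 5 starts) maximizes the
objective. For the lin-quad environment the closed-form cosine is an exact
oracle; the optimizer recovers it to well under 1 m sup-norm. Two-stage
problems double the decision vector and maximize the quadratic 8-parameter
fitness jointly.

## Two-stage analytic verification

The data-driven quadratic fitness over `M1..M8` is cross-checked against a
classical two-stage demography: juveniles mature at rate p and die at rate
q, adults reproduce at rate r and die at rate s (all per day), and both
stages share a competition mortality `c·N`. Because the shared competition
term shifts every strategy's growth equally, it cancels from rankings, and
the analytic fitness is the leading eigenvalue of the linear part:

    λ₊ = (−(p+q+s) + sqrt((p+q−s)² + 4pr)) / 2.

The demographic rates are positive-weighted linear combinations of the
macro-parameters (p, q from the juvenile block M1, M3, M4 and M2; r, s
from the adult block M5, M7, M8 and M6). Substituting this change of
variables into a quadratic Taylor form `F ≈ Σ hᵢ·(p,q,r,s)ᵢ + Σ hᵢⱼ·…`
expresses the machine-learned λ's in terms of (h, w); with the four linear
h's fixed the weights follow uniquely from the linear terms, and every
quadratic hᵢⱼ is over-determined by monomial ratios whose spread is
reported as a residual (an exact forward-expansion round-trips to 1e−10).
Taylor coefficients of the eigenvalue fitness at a demographic point are
computed by central finite differences (relative step 1e−5) and compared
in the reproduction-normalized gauge (coefficient of r ≡ 1). Because the
map sends non-positive M's through positive weights, intermediate rates
can come out negative during exploration; they are clamped at zero with a
warning rather than rejected.

## Selection dynamics and entropy

The ranking definition — v outranks w when ρ_w/ρ_v → 0 under selection —
is operationalized by a replicator update `ρᵢ ← ρᵢ·exp(Fᵢ·dt)` with
renormalization, under which log-density ratios drift linearly at the
fitness differences. A finite series cannot evaluate a limit, so the
empirical ranking uses a tail test: a pair is ordered when the log-ratio
slope over the final 20% of the series exceeds 1e−3 per unit time;
extinction while the rival survives also orders a pair; everything else
stays incomparable. Shannon entropy `H = −Σ ρᵢ ln ρᵢ` (0·ln 0 = 0) of the
strategy distribution decays to zero as selection concentrates mass on the
fittest strategy; monotone decrease is asserted only after a burn-in,
since with a uniform counting measure transient entropy increases are
possible from skewed initial conditions.

## Numerical choices and degenerate inputs

* Canonical monomial order: ascending total degree, descending
  lexicographic within a degree block, so the linear slots read M1..Mn;
  the basis is serialized in dataset headers so trained coefficients stay
  portable. Symmetric quadratic coefficients are stored once (i ≤ j), the
  off-diagonal monomial carrying the combined weight.
* `sign(0)` of a pair decision maps to +1 by convention; probabilities are
  clipped before logs; quadrature failures, non-finite losses, all-zero
  feature differences, zero weight vectors and empty evaluation sets raise
  typed errors rather than propagating NaNs.
* `δ = 0` makes the mean-depth problem unbounded and is rejected; a
  closed-form optimum outside the water column warns but is returned
  (the formulas are the unconstrained maximizer).
* All randomness (directions, ε subsampling, splits, CV folds, multistarts)
  flows from explicit integer seeds; identical configurations reproduce
  byte-identical artifacts.

## Problem sizes

The default study conditions (202 strategies, 2031 pairs, L = 8, k = 1)
run in seconds; the test suite and the acceptance script regenerate all
datasets from scratch at exactly these sizes, with classifier quality
averaged over five seeds. The two-stage optimizations in the tests use the
default 5-mode Fourier parameterization (22 decision variables).

## Known limitations

* The hyperbolic environment has no closed-form optimum; its results are
  validated qualitatively (a genuine large-amplitude migration, deep at
  peak predator activity), not against an analytic oracle.
* Reported two-stage trajectory amplitudes depend on fitted quadratic
  coefficients that are not identifiable from the default synthetic
  construction; only the qualitative juveniles-migrate-less-than-adults
  pattern is asserted.
* The analytic two-stage fitness here is the eigenvalue of one specific
  (and standard) demographic model; comparison tables against other stage
  models will agree only approximately at first order.
* Coefficient recovery degrades gracefully but noticeably when pair
  differences span a thin cone (few perturbation directions); use the
  oracle-labelled full-rank construction to benchmark recovery itself.
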