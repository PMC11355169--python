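# Methods

## The logistic-map model

Plaque burden `P_t` — the proportion of a lumen cross-section occupied by
plaque at surveillance visit `t` — evolves by the logistic map
`P_{t+1} = r P_t (1 − P_t)`. The map is defined for `P ∈ [0, 1]` and
`r ∈ [0, 4]` (the largest rate for which the unit interval maps into
itself); inputs outside those ranges raise domain errors naming the
offending parameter, and a simulated trajectory that would leave `[0, 1]`
aborts with the visit index.

**Regimes.** Long-run behaviour is classified by `r`: extinction
(`0 < r ≤ 1`, `P → 0`), monotone convergence to the fixed point `(r−1)/r`
(`1 < r ≤ 2`), damped fluctuation around the same fixed point
(`2 < r ≤ 3`), period-doubled oscillation (`3 < r <` onset of chaos) and
chaos (`r ≥` onset, default 3.56995). The boundary values r = 1, 2, 3 are
assigned to the lower regime; this tie-break is arbitrary but fixed, and
the instability rule below is strict (`r > 2`) independently of it.

**Dynamic growth rate.** `r` aggregates the biology driving progression
and clearance: `r(P) = α (1 + Σᵢ βᵢ fᵢ(P))` with baseline rate `α > 0`,
weights `βᵢ`, and four factor functions (conventionally hemodynamic,
inflammatory, mechanical, metabolic). No functional forms are canonical,
so the factors are user-supplied callables; a small library ships
(constant, linear in `P`, saturating `P/(P+k)`). Each visit the aggregate
is re-evaluated at the current burden, then an optional per-visit
increment is applied (additive by default: `+ increment · visit`;
a multiplicative mode `· increment^visit` exists behind a config switch),
then the result is clamped at 0 and at the lower bound. The lower bound
defaults to 1 — established lesions rarely regress, so net growth below
replacement is treated as the exception that must be opted into
(`r_lower_bound=None`).

**Remodeling.** Positive remodeling expands the lumen from `A₀` toward
`A_max`. Only the limit is specified by the biology, so the approach is
realized as a geometric relaxation `A_{t+1} = A_t + rate·(A_max − A_t)`
with a configurable per-visit rate — monotone, convergent, and
parameterized by a single interpretable number. `P` is always relative to
the *current* lumen; the derived series `P·A(t)/A₀` re-expresses plaque
mass against the baseline lumen and is reported but never fed back into
the map (the two recurrences are deliberately decoupled; nothing in the
model fixes a coupling).

**Oscillation onset.** The clinically meaningful event is erosion/rupture
of a *grown* plaque, so `oscillation_onset` is the first visit at which
`P` decreases after having previously increased. A monotonically shrinking
trajectory (e.g. extinction at `r = 0.8`) has no onset: simple regression
is not oscillation. Note a slowly ramped `r` (e.g. +0.05…0.08 per visit
from `r₀ = 1`) never produces an onset at all — the burden chases the
rising fixed point `(r−1)/r` quasi-statically from below and never
overshoots before `r` leaves `[0, 4]`. Oscillation requires `r` already
above 2 while `P` approaches its fixed point, as with a constant
`r ∈ (2, 3]` start.

**Instability proportion.** A rate `r` shrinks the plaque iff
`r P (1−P) < P ⇔ r < 1/(1−P)`, so the fraction of rates in `[0, r_max]`
that destabilize is `min(1, 1/(r_max (1−P)))` — increasing in `P` and
saturating at 1 from `P = 1 − 1/r_max` (≈ 0.714 at the default bound
3.5, i.e. around 70 % stenosis ruptures/erosions become inevitable under
the model). The closed form is cross-checked against a brute-force grid
over uniformly spaced rates in the tests and the acceptance script.

**Chaos diagnostics.** The Lyapunov exponent is the orbit average of
`ln |r (1 − 2P_t)|` (burn-in 10³, average 10⁵ iterations, start 0.1);
terms with exactly zero derivative are skipped. `chaos_onset` scans `r`
upward from 3 in steps of 0.02 until the exponent turns positive and then
bisects, reporting the first positive crossing approached from below —
the period-doubling accumulation point (≈ 3.56995). Periodic windows
above the accumulation point do not disturb the result because the scan
stops at the *first* crossing. `first_bifurcation` bisects on the
attractor period (distinct values among 256 post-transient iterates,
clustering tolerance 10⁻⁸) between period 1 and period 2. Transients
decay at a rate proportional to the distance from the bifurcation, so the
burn-in scales as `16/resolution` (1.6·10⁵ sweeps at the default
resolution 10⁻⁴); a fixed short burn-in would systematically misclassify
rates just below 3 as period-2 and bias the boundary low.

**Estimation and risk.** Over each visit pair the map inverts in closed
form: `r̂ = P_{t+1} / (P_t (1 − P_t))`. Intervals starting at the
degenerate boundary (P = 0 or 1) are flagged undefined and kept in place,
never dropped. Risk is `UNSTABLE` when the summary of the estimates — the
latest defined one by default, optionally a trailing mean — strictly
exceeds the threshold (default 2). This threshold is the model's
hypothesis, not a validated biomarker.

## The Markov ladder

**Chain.** States are 0 = stable, 1 = unstable everywhere.
`P(S→U) = base + w₁·I + w₂·L + w₃·S + w₄·B (+ w₅·D)` over non-negative
covariate scores (inflammation, lipid, shear stress, burden; dimensionless
— no physical units are canonical). The literal linear form can exit
`[0, 1]`; it is clamped, clamping events are counted, and a warning fires
once more than 1 % of at least 100 evaluations clamp — silent clamping
would hide misconfigured weights. A logistic link
(`expit(logit(base) + η)`) is available behind a switch for users who
prefer a guaranteed probability; linear-clamped is the default because
the model is literally linear. The reverse transition has no canonical
covariate form and defaults to a constant `p_US`.

**Stationary distribution.** Computed as the left eigenvector of the 2×2
row-stochastic matrix for eigenvalue 1, requiring irreducibility and
aperiodicity (`p_SU`, `p_US` not both 0 and not both 1). The closed form
`π_S = p_US/(p_SU + p_US)` serves as the independent oracle in tests; the
eigen-route is the implementation.

**Probability vs. hazard.** The instability parameter appears both as a
one-step probability (`p_su`) and as a continuous-time hazard
(`hazard_su`) in the exponential event curves
`(e^{−α t}, 1 − e^{−α t})`. Both readings are retained in separate
operations with distinct config names; `probability_to_hazard`
(`−ln(1 − p)` per interval) converts explicitly when consistency is
wanted. The event-curve components sum to 1 exactly in IEEE double
arithmetic (`p + (1 − p)` rounds to 1 for `p ∈ [0, 1]`).

**Spatial extension.** The lattice is a non-periodic height×width patch
(a plaque surface has edges), 4-neighbor by default, 8-neighbor and
periodic available. The dependence matrix is built from a distance
kernel: `uniform` (indicator within range; range 1 reproduces the
4-neighborhood) or `exponential` (`e^{−d/range}` within a cutoff,
default 3·range). Diagonal entries are 1 by convention and excluded from
neighbor averaging. The per-site spatial term `Dᵢ` is the
dependence-weighted fraction of unstable neighbors — in `[0, 1]`, zero
for an isolated site, permutation-symmetric and monotone in the number of
unstable neighbors.

The coupling of the site×site dependence matrix with the 2×2 transition
matrix is dimensionally ambiguous as stated, so both defensible readings
ship: (a) the default scalar pathway, `Dᵢ` entering the linear form via
`w₅` (used by heatmaps); (b) a literal element-wise product pathway where
a site's 2×2 modifier block `[[1, 1 + gain·Dᵢ], [1, 1]]` multiplies the
transition matrix element-wise and the rows are renormalized. The
modifier scales the S→U *element* rather than a whole row because row
scaling is invisible to renormalization. Renormalization itself is a
necessity, not part of the stated model: without it the product is not a
probability matrix; a row whose product is all zero is a degenerate model
and raises.

Lattice evolution over time uses synchronous updates by default (all
sites see the previous step's neighbor states); an asynchronous raster
mode exists, both seeded. A static risk map (the heatmap) and temporal
evolution are both supported since neither is canonically "the" model.

**Markov random field.** The Gibbs distribution
`P(config) ∝ e^{−β E(config)}` with
`E = Σᵢ V_i(sᵢ) + Σ_{(i,j)∈edges} U(sᵢ, sⱼ)`; the pair sum runs over
undirected lattice edges once (the double-counting convention is fixed
and tested via energy additivity over disjoint components). No potential
forms are canonical, so the shipped family is the simplest consistent
one: `V(U) = v_U` (optionally minus a covariate-linear term so the field
nests the chain's covariate model) and attractive Ising coupling
`U(s, s') = −J·1[s = s']`, `J ≥ 0`; arbitrary tables are accepted. The
"transition matrix" phrasing sometimes attached to this object is
mathematically a distribution over configurations; the package implements
the distribution, and exposes per-site conditional flip probabilities
(the sampler's conditionals) as the transition-flavored interpretation.

Inference: exact enumeration up to 20 free sites (vectorized over all
2ⁿ configurations, log-sum-exp stabilized), otherwise a systematic-scan
single-site Gibbs sampler (fixed raster order, burn-in default 10³
sweeps, thinning 1, fully seeded). Sites may be clamped; both routes
condition on clamps. Sampler correctness is established against
enumeration on small lattices. Because Gibbs sweeps are autocorrelated,
Monte-Carlo standard errors in the tests use batch means (50 batches),
floored at 1/n_samples (the estimator's resolution); across hundreds of
simultaneous comparisons ~0.3 % of standardized deviations are expected
beyond 3 SE for a correct sampler, so the acceptance check requires ≥99 %
within 3 SE and caps the worst at 5 SE rather than quantifying over every
comparison.

## Synthetic data

The measurement generator simulates a trajectory under a constant or
linearly drifting rate schedule and observes it with additive Gaussian
noise truncated to `(0, 1)` by resampling. The noise model is a stand-in
— no observation model is canonical — with default σ = 0.01, small
relative to the burden scale in the spirit of ~2 mm planimetric
ultrasound resolution. Ground-truth per-interval rates are emitted to a
sidecar table for recovery tests. The covariate generator produces mean
plus moving-average-filtered white noise (filter half-width =
`correlation_range`, rescaled to the requested standard deviation,
clipped at 0), with an optional rectangular hotspot of elevated
inflammation. A moving-average filter was chosen over a full
Gaussian-process machinery deliberately: it is simple, dependency-light
and induces the qualitative feature that matters (positive short-range
correlation).

What passing tests show — and don't. The generators emulate the *shape*
of surveillance data (discrete visits, bounded proportions, small noise,
smooth spatial covariates). They contain no imaging physics, no
segmentation error structure, no inter-patient heterogeneity; parameter
recovery under this noise model demonstrates the estimator inverts its own
forward model, not clinical validity.

## Numerical and design notes

* Problem sizes: chaos diagnostics use 10⁵ iterations per Lyapunov
  evaluation; the bifurcation search uses 1.6·10⁵-step burn-ins; the
  brute-force instability oracle uses 10⁶ grid points; chain simulations
  use 10⁵ steps; MRF acceptance uses 5·10³ sweeps on lattices of 2–12
  sites. These sizes make every statistical band in the tests comfortably
  resolvable while keeping the full suite in seconds.
* Occupancy-frequency checks of simulated chains use the two-state chain's
  asymptotic variance `π_S π_U (2 − p)/p`, `p = p_SU + p_US` (i.i.d.
  binomial standard errors would be anti-conservative under
  autocorrelation).
* All randomness flows through `numpy.random.default_rng` seeded
  explicitly; CLI commands take `--seed` and their CSV outputs are
  byte-reproducible.
* Config parsing is strict: unknown keys anywhere are collected and
  rejected by full key path. Probabilities serialize with 12 significant
  digits; matrix CSVs are row-major with a header and no index column.
* Known limitations: no fitting of Markov/MRF parameters to event data
  (no estimator is defined for them); no 3-D geometry → lattice mapping;
  no anisotropic kernels; the r > 2 rule and the 70 %-stenosis saturation
  are model statements, not clinical claims.
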