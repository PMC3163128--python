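# Methods

`nmfdl` implements neural-modeling-fields estimation with dynamic logic
(NMF-DL): a deterministic-annealing, vague-to-crisp mixture-model fitting
engine in which parametric top-down "concept models" compete for bottom-up
signals, plus three demonstration applications. This note records the model,
the numerical choices, and the places where the published sketch of the
method left the design open and this package had to decide.

## The estimation engine

### Objective and iteration

Given signals X(n), n = 1..N, and concept models m = 1..M with parameters
S_m, prior rates r(m) and per-family conditional similarities l(n|m), the
engine maximizes the total log-similarity (the "knowledge instinct")

    log L = Σ_n log Σ_m r(m) l(n|m),

multiplied by a skeptic penalty p(N, M) that punishes model proliferation
(below). Each iteration alternates:

1. **Association** — f(m|n) = r(m) l(n|m) / Σ_m' r(m') l(n|m'), the
   normalized responsibility of model m for datum n.
2. **Parameter update** — each active model's (S_m, spread) is replaced by
   its family's f-weighted maximum-similarity estimate. The underlying
   dynamics are a gradient flow on log L; this package implements the
   flow's fixed point (the weighted-MLE step) instead of integrating in
   time, because the stationary points coincide and no step size needs
   tuning. Families with closed forms (Gaussian mean, Bernoulli) use them;
   the cone family runs damped Gauss–Newton with an acceptance guard.
3. **Rate update** — r(m) = Σ_n f(m|n)/N for active models, renormalized;
   dormant models hold a pinned floor mass ε_r = 1e-6 each. Closed-form
   re-estimation was chosen over running rates through the flow.
4. **Structural moves** (see below) — merging, penalty-guarded pruning, and
   admission of dormant models.

Iteration stops when |Δ log L| < tol (default 1e-6·N) with an unchanged
model roster, or after max_iter (default 500; the cone pipeline uses 200).

### Monotonicity contract

Between structural changes every update is an exact or constrained
M-step, so log L is non-decreasing at every iteration — asserted at
1e-8 relative tolerance, and recorded over the full participating mixture
(active models plus the ε_r-rate dormant floor, which keeps the mixture
support constant between structural events). Structural changes are
different: removing a mixture component can only lower raw likelihood
(Jensen), so no algorithm that prunes can keep the raw trace monotone
through a pruning event. The engine therefore guarantees, at the
iterations flagged in `FitState.structural_iterations`, that the
*penalized* similarity does not decrease instead: a removal is accepted
only when its exact likelihood cost, Σ_n log((1 − f(m|n))/(1 − r_m)), is
covered by the penalty mass κ·k_m it releases, and an insertion only when
its likelihood gain exceeds the penalty of the added parameters.

### Skeptic penalty

The penalty form is log p(N, M) = −κ · (total free parameters over active
models). κ defaults to 1 (AIC-like); the "steeper for smaller N" behavior —
a penalty whose *relative* weight grows as data shrink — is available as
the BIC option κ = log(N)/2. The same κ·k quantity is the exchange rate of
every structural move, which makes pruning and admission exact mirror
images.

### Annealing: how vague-to-crisp is realized

Vagueness lives in each family's spread (the similarity variance for
Gaussian-residual families; the distance of p from one-half for Bernoulli
families). Two numerical choices make the cooling work:

- **Annealed spread updates.** The variance may shrink by at most a factor
  0.9 per iteration on its way down to its weighted MLE. Because the
  weighted likelihood is unimodal in the variance, any value between the
  old one and the MLE does not decrease it, so EM monotonicity is kept
  while the models cool gradually instead of jumping to a fixed point.
- **Initial spread just below the critical temperature.** For balanced,
  well-separated clusters the symmetric configuration (every model at the
  data centroid, variance = global variance) is a *stable* EM fixed point
  whenever the spread exceeds roughly the global data variance. Starting
  the spread exactly there freezes a substantial fraction of runs. The
  Gaussian family therefore spawns vague models at half the global
  variance (configurable `init_var_frac`), with seeded mean jitter at the
  data scale; cooling then differentiates the models. Bernoulli families
  spawn at p = 0.5 ± 0.01 seeded jitter.

### Dormant models: pruning, merging, admission

The engine keeps a store of dormant, maximally vague models at floor rate
ε_r. Three structural moves run once the fit is near stationary (|Δ log L|
below max(100·tol, 1e-6·|log L|)):

- **Merge.** Active same-family components whose parameters nearly coincide
  (family-defined normalized distance < 1) are merged, rates summed; exact
  duplicates leave the mixture density unchanged, so the move is free.
- **Prune.** Any active non-background model is trial-removed; models whose
  measured rate fell below the activation threshold (default 1/(10·M_max))
  are reviewed every iteration. Acceptance requires the penalized
  similarity not to decrease (exact cost formula above).
- **Admit.** A dormant model's pinned floor rate can never itself cross the
  activation threshold — its responsibilities scale with ε_r — so the
  plain threshold rule never fires in practice. Admission instead works
  like greedy component insertion: a candidate is seeded from a datum,
  privately adapted for 8 EM steps against the active mixture under an
  admission prior π = threshold, and activated iff inserting it at its
  best rate (searched on a geometric grid) gains more log-similarity than
  κ·k. Anchors alternate between the worst-explained decile of the data
  (structure the mixture misses outright) and uniform draws (structure
  hiding inside a too-broad component, which is *better* explained than
  genuine clutter and so never reaches the worst-explained pool). For
  binary families the candidate is the average of the anchor's
  high-overlap neighborhood rather than a copy of the anchor, which would
  just memorize one row. Probes cost about one parameter sweep and are
  rate-limited to one round per 5 iterations, with a forced probe before
  convergence is declared — a converged fit implies no admissible
  candidate remained.

The standalone `activate_deactivate` operation retains the plain
threshold rule (dormant r > threshold → active, active r < threshold →
dormant, at least one active model retained, ties broken lowest index
first) for use outside the fit loop.

### Degenerate inputs and tie-breaks

A datum with zero similarity under every model is assigned to the
background component if present, else uniformly. A model whose total
association weight falls below 1e-8 is left unchanged and flagged for
review. Bernoulli rates are clamped to [1e-6, 1 − 1e-6]; variances are
floored at 1e-8. With tol = ∞ the fit returns immediately, unconverged,
with the initial models.

## Phase-cone detection

The scene is an X×Y×T sensor array (64×64×40 by default, 5 ms per step,
unit sensor spacing) containing circular traveling-ring events in additive
Gaussian sensor noise. A cone with center (x0, y0), radial speed v,
amplitude a and ring width w contributes

    g(x, y, t) = a · exp(−(ρ − R(t))² / (2w²)),   ρ = distance to center,

with ring radius R(t) = v·(t − t0) wherever R ≥ 0: for expanding cones
(v > 0) t0 is the onset; for contracting cones (v < 0) t0 is the collapse
time. The generator's contracting cones are specified by onset and initial
radius r0 (default |v|·(T − t0), i.e. collapse exactly at the end of the
scene). The default simulation plants two expanding and one contracting
event at amplitude a = 1 in noise of the same standard deviation
(per-sample SNR 1, configurable via `--snr`).

The fit treats every (x, y, t, amplitude) grid point as one datum. Cone
models use a Gaussian residual similarity around the predicted amplitude;
one background component models the sensor noise. Choices that matter:

- **Background family.** The default background is spatially uniform with
  a Gaussian amplitude density (2 free parameters), matching the additive
  Gaussian noise of the generator; a flat amplitude-range clutter density
  1/(hi − lo) is available (`background="uniform"`). Against Gaussian
  noise a flat density always loses the competition for noise samples, so
  surplus ring models would degenerate into background imitators.
- **Background rate floor.** The background holds at least half the
  mixture (a constrained M-step). Without it the background drifts onto
  unclaimed event signal (its mean rises toward the event amplitude), and
  missed events become well-explained and invisible to admission probes.
- **Parameter updates.** Five damped Gauss–Newton steps per sweep on the
  responsibility-weighted squared residual with analytic Jacobians; a step
  is accepted only if the weighted SSE does not increase. Two cheap global
  candidates are evaluated alongside: a closed-form geometry refresh
  (amplitude-weighted centroid; ring speed and zero-radius time by
  weighted regression of ρ on t, iterated three times with a trim window
  around the fitted line to de-bias noise dilution) and a time-reversal
  candidate (v → −v, t0 reflected about the model's mean time), both
  accepted only on SSE improvement. These let a model escape the two local
  basins Gauss–Newton cannot leave: the static-blob mode and the wrong
  speed sign.
- **Constraints.** Ring width is clipped to [0.6, 0.15·array size] — rings
  wider than a modest fraction of the array are not credible events, and
  the cap removes a degenerate fat-slow-ring mode; centers may wander 25%
  outside the array; |v| ≥ 0.02.
- **Initialization.** Ten vague cone models: centers stratified over a
  3×3 grid with seeded jitter, speed signs alternating, zero-radius times
  early for expanding and late for contracting rings; w starts at 1/8 of
  the array, the residual variance at the global data variance.

Recovery is scored by greedy matching of fitted to planted cones on
center-plus-zero-radius-time distance; contracting cones are compared at
their collapse time (the identifiable time reference for a ring observed
without its birth). Event counts come from the signs of v among active
cone models.

## Situation learning

The generator plants K = 10 "important situations" in D = 1000 objects:
each type owns k_rel = 10 relevant objects (disjoint across types by
default) present in every one of its n_per_type = 800 instances, plus
k_rand = 40 objects drawn uniformly from the rest; 8,000 clutter rows
contain 50 random objects each (so clutter is indistinguishable from
structure by row sum), for 16,000 rows total, shuffled. The published
description gives two compositions (16,000 rows with half clutter in the
text; 10 + 5,000 in the figure caption); the text-consistent one is the
default and `caption_gen_config` provides the other. Optional relation
markers are extra binary columns that a type always carries; they enter
the algorithm exactly like objects.

Fitting uses a Bernoulli family (l = Π p_i^x_i (1−p_i)^(1−x_i), computed
in log space) with 20 initial models, initialized by a seeded random soft
association of rows to models followed by one closed-form update, plus a
3-model dormant store. Surplus models absorb the clutter; near
stationarity they merge and the skeptic penalty prunes them, and admission
probes re-insert any planted type that an over-broad component swallowed.

The recovery error matches truth types one-to-one to active models by the
assignment minimizing the summed mean absolute difference between p and
the type's expected presence profile (relevant objects at 1, others at
their generative marginal k_rand/(D − k_rel)); leftover models — e.g. the
clutter absorber — are ignored, and a type with no model available counts
a full error of 1. Rate-based model selection was rejected deliberately:
the clutter absorber's rate (≈ 0.5) exceeds every type model's (= 0.05),
and surplus-model rates tie with type rates, so "the K highest-rate
models" is ill-posed on exactly the data this experiment generates. The
error plateaus at a small positive value (≈ 0.005): the sampling noise of
the per-type marginals plus the p-clamp keep it off zero.

## The dual model

Each concept carries a language vector ML and a cognition vector MC with a
single shared rate and association row; the two channels are conditionally
independent given the concept, so l = l_L · l_C, and a missing language
channel contributes a factor 1 and no update weight. With every language
channel missing, the dual fit reduces bit-for-bit to the cognition-only
Bernoulli fit under the same seed (the random-association draw is taken
before any family-specific use of the random stream to make this exact).

The generator gives each of K concepts disjoint k_rel-object prototypes
per channel and flips each bit independently with channel noise rates
η_L, η_C; "ready-made" language is modeled as η_L ≪ η_C, and a
missing-language fraction models pre-linguistic samples. Crispness of a
channel is mean 2|p − 0.5| ∈ [0, 1]. The headline demonstration
(`dual_advantage_experiment`) grids η_C at fixed low η_L and shows (a)
the language channel at least as crisp as the cognitive one at every
iteration, and (b) a noise range (η_C ≈ 0.4) where the dual fit recovers
the concepts and a cognition-only fit does not — the operational reading
of "cognition cannot be learned without language"; the anthropological
claim itself is out of scope.

## What the generators do and do not emulate

All data are synthetic and seeded. The cone generator produces ideal
Gaussian rings in white Gaussian noise — no sensor artifacts, spatial
correlation, drift, or event-shape mismatch; passing tests show the engine
recovers its own model family in heavy noise, not that real EEG events
follow this family. The situation generator produces exact always-present
relevant sets; real co-occurrence data would have noisy set membership
(the dual generator's bit-flip noise covers that regime). The dual
generator's channels are conditionally independent given the concept by
construction, matching the fitting assumption.

## Problem sizes used in tests and the acceptance run

The default test suite runs the study-scale situation fit (16,000×1,000)
once, the full 64×64×40 cone scenario once, the 20-seed recovery and
asymmetry properties at reduced size (situations 1,200×200; cones 32×32×24
with two planted rings, 8 seeds; dual toys at D = 30 per channel), and the
engine property suites on ≤ 50-sample instances. `scripts/acceptance.py`
runs 4 seeded replicates of the full cone scenario and reports the largest
outer-iteration index at which all three planted events are first matched
within 1 sensor unit with correct speed signs.

## Known limitations

- Convergence is to a local optimum of the penalized similarity; the
  structural moves (merge/prune/admit) repair the common failure modes but
  carry no global guarantee. Seeds exist where a cone fit needs most of
  its 200-iteration budget.
- The cone family assumes radially symmetric rings of constant speed and
  amplitude; chirped or anisotropic events would need a richer family.
- At SNR 1 the fitted cone amplitude is biased upward (roughly 2x):
  soft assignment routes ring samples with positive noise to the cone and
  those with negative noise to the background. Event geometry (center,
  speed, timing) is unaffected.
- The engine is single-layer; hierarchical runs apply it per layer.
- At κ = 0 (penalty off) structural admission and pruning are disabled —
  there is no exchange rate to justify them — so the model count is fixed
  at initialization.
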