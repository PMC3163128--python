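# nmfdl

Vague-to-crisp mixture estimation with **neural modeling fields / dynamic
logic (NMF-DL)** — a deterministic-annealing, EM-style fitting engine in
which parametric top-down "concept models" compete for bottom-up signals
through shared association variables, with data-driven activation and
pruning of models — together with three demonstration pipelines:

- **Phase-cone detection**: find circular events that expand or contract
  over time on a noisy 64×64 sensor array (a model of cognitively related
  events in EEG-like recordings).
- **Situation learning**: discover which object subsets form recurring
  "situations" in 16,000 binary object-co-occurrence vectors that are half
  random clutter.
- **The dual model**: paired language + cognition concept representations
  sharing one association variable, demonstrating that a clean
  ("ready-made") language channel becomes crisp faster and rescues concept
  learning when the cognitive channel is too noisy on its own.

## The model

Signals X(n), n = 1..N, are explained by concept models m with parameters
S_m, prior rates r(m), and family-specific conditional similarities
l(n|m) (e.g. a Gaussian density of the observed amplitude around a
predicted ring amplitude, or a Bernoulli product over object-presence
bits). The engine maximizes the total similarity

    L = Π_n Σ_m r(m) · l(n|m),

times a "skeptic" complexity penalty p(N, M) = exp(−κ·#free parameters),
by iterating association variables

    f(m|n) = r(m) l(n|m) / Σ_m' r(m') l(n|m'),

responsibility-weighted parameter updates (the fixed point of the model
dynamics), and rate re-estimation r(m) = Σ_n f(m|n)/N. Models start
maximally vague (large spread) and sharpen as their estimates improve —
spread may shrink at most 10% per iteration, which keeps log L provably
non-decreasing while the system cools. A store of dormant vague models
supplies new components when the data demand them, and the skeptic penalty
prices every insertion and removal. See `docs/methods.md` for the full
account.

## Worked example

Simulate the two-expanding + one-contracting scene at per-sample SNR 1 and
recover the events:

```bash
$ nmfdl simulate-cones --seed 7 --snr 1 --dims 64 64 40 --out-dir run
wrote run/cones_data.h5 and run/cones_truth.json
$ nmfdl fit-cones --data run/cones_data.h5 --seed 7 --out run/fit.json
converged=True iterations=80 expanding=2 contracting=1
$ nmfdl evaluate-cones --fit run/fit.json --truth run/cones_truth.json --out run/eval.json
{
 "n_expanding": 2,
 "n_contracting": 1,
 "unmatched_truth": 0,
 "unmatched_fitted": 0,
 "matched_errors": [
  {"x0": 0.117, "y0": 0.400, "t0": 0.407, "v": 0.0149, "a": 1.03, "w": 0.55, "v_sign_ok": true},
  {"x0": 0.252, "y0": 0.235, "t0": 0.222, "v": 0.0134, "a": 1.14, "w": 0.68, "v_sign_ok": true},
  {"x0": 0.049, "y0": 0.382, "t0": 0.783, "v": 0.0205, "a": 0.95, "w": 0.31, "v_sign_ok": true}
 ]
}
```

(`matched_errors` values abbreviated here to three figures.) The fit
starts from ten vague ring models plus a noise background; duplicates
merge, the penalty prunes the rest, and the three survivors' geometry
lands within half a sensor unit / time step of the planted events
(`matched_errors` are absolute errors per parameter: center x0, y0;
zero-radius time t0; radial speed v; amplitude a; ring width w). The
fitted amplitudes run about twice the planted value — a known soft-
assignment selection bias at SNR 1, where ring samples with positive
noise go to the cone and those with negative noise to the background; the
event geometry is unaffected.

Situation learning from the library:

```python
from nmfdl import (SituationGenConfig, generate_situations, fit_situations,
                   all_sets_recovered, recovery_error)

data, truth = generate_situations(SituationGenConfig(seed=11))  # 16000 x 1000
state = fit_situations(data, seed=11)       # 20 initial models
print(state.converged, state.iteration)     # True 98
print(all_sets_recovered(state, truth))     # True: all 10 relevant sets read off
print(round(recovery_error(state, truth, dim=1000), 4))  # 0.0067
```

The error settles at a small positive plateau (≈ 0.006, the sampling noise
of the random-object marginals) — within one point of that plateau by the
third iteration, which is when the ten planted relevant-object sets become
readable from the models.

The dual-model experiment:

```bash
$ nmfdl dual-advantage --eta-l 0.05 --eta-c-grid 0.2,0.4 --seeds 10 --seed 1
       err_dual  err_cognition_only
eta_c
0.2    0.051201            0.064617
0.4    0.069151            0.144277
```

At η_C = 0.2 the cognitive channel is learnable on its own and the two
fits nearly tie; at η_C = 0.4 cognition-only fitting loses concepts
(mean error doubles) while the clean language channel's assignments keep
the dual fit near the noise floor for that η.

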