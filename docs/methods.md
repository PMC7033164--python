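# Methods

## Synthetic greenhouse campaigns

`photonet.synthetic` emulates a chamber experiment on young cucumber canopy
leaves: a full factorial sweep of leaf temperature (default 18, 20, 24, 28,
32, 36 °C), CO₂ concentration (300, 600, 900, 1200 μmol·mol⁻¹) and light
intensity (13 levels from 20 to 1500 μmol·m⁻²·s⁻¹) at fixed 50 % relative
humidity, with three replicate plants per combination — 312 combinations,
936 records.

### Net photosynthesis surface

The noise-free ground truth is a separable empirical surface

```
Pn(T, C, I) = α·I·(1 − β·I)/(1 + γ·I) · exp(−((T − T_opt)/σ_T)²) · C/(C + K_C) − R_d
```

a rectangular hyperbola in light with a linear photoinhibition factor, a
Gaussian temperature optimum and a Michaelis–Menten CO₂ response. This is
the minimal form that reproduces the three observed light regimes of young
cucumber leaves — a near-linear rise below ~300 μmol·m⁻²·s⁻¹, saturation
with slight decline above ~1000, and photoinhibition toward 1500 — while
keeping the light optimum independent of T and C (separability), so a single
calibration fixes it.

Defaults (all frozen before any downstream modelling):

| parameter | default | units | rationale |
|---|---|---|---|
| α | 0.12 | μmol CO₂ / μmol photons | apparent initial slope giving peak Pn ≈ 18 μmol·m⁻²·s⁻¹ at optimum |
| β | 2.0·10⁻⁴ | per μmol·m⁻²·s⁻¹ | visible but mild photoinhibition at 1500 |
| γ | 3.081·10⁻³ | per μmol·m⁻²·s⁻¹ | calibrated so the light optimum sits at ≈990 μmol·m⁻²·s⁻¹ (the analytic optimum of the light factor solves βγI² + 2βI − 1 = 0) |
| T_opt | 28 | °C | cucumber photosynthetic optimum |
| σ_T | 10 | °C | moderate breadth: Pn at 18 °C ≈ 37 % of optimum |
| K_C | 300 | μmol·mol⁻¹ | CO₂ half-saturation; response nearly saturated at 1200 |
| R_d | 0.8 | μmol·m⁻²·s⁻¹ | dark respiration; Pn(I=0) = −R_d |

### Fluorescence surfaces

With φ₀ = 0.75 the dark-adapted PSII yield, the actual quantum yield decays
with light under a mild (±8 %) linear temperature/CO₂ modulation m(T, C):

- ΦPSII = φ₀ · exp(−I / I_φ) · m(T, C), I_φ = 900 μmol·m⁻²·s⁻¹;
- ETR = ΦPSII · I · a · f, with absorptance a = 0.84 and PSII fraction
  f = 0.5 (so ETR / (ΦPSII·I) = 0.42 exactly);
- Fv′/Fm′ = 0.82 · (ΦPSII/φ₀)^0.6 — a concave power law, which guarantees
  Fv′/Fm′ ≥ ΦPSII across the factorial ranges;
- qP = ΦPSII / (Fv′/Fm′), clipped to (0, 1];
- NPQ = NPQ_max · I^h / (I^h + K^h) · max(0, 1 − s·max(0, I − I_d)): a Hill
  saturation (NPQ_max = 2.5, K = 400, h = 1.5) damped beyond the
  photodamage threshold I_d = 1000 at slope s = 5·10⁻⁴, so NPQ declines
  from ~1000 to 1500 μmol·m⁻²·s⁻¹;
- qN (noise-free form) = 1 − exp(−NPQ).

At zero light the fluorescence parameters are physically undefined (no
actinic excitation); such records carry `valid_fluor = False` and NaN
fluorescence values, and are excluded from fluorescence correlations.

### Noise model

Each observed quantity is its surface value × (1 + ε), ε ~ N(0, cv) i.i.d.
per record and quantity, cv = 3 % by default — a typical replicate
coefficient of variation for well-controlled gas-exchange measurements, and
small enough that multiplicative noise keeps positive quantities positive
(record invariants are additionally enforced by clipping). `noise_cv = 0`
produces fully deterministic, replicate-identical data.

qN is treated differently: in measured campaigns the sustained-quenching
coefficient shows almost no relationship with Pn, being dominated by
leaf-to-leaf variability rather than by the instantaneous light environment.
The generator therefore models observed qN as
`1 − exp(−(0.99·NPQ_ref + 0.01·NPQ)) + N(0, 0.05)` with NPQ_ref the
mid-range quenching level — a near-constant plant property with weak
instantaneous coupling. A naive `1 − exp(−NPQ)` observation would inherit
NPQ's strong positive correlation with Pn, which is not what fluorometer
campaigns report for qN.

### What the generator does and does not emulate

It reproduces the factorial design and counts, the light/temperature/CO₂
response shapes, the light-saturation point near 990 μmol·m⁻²·s⁻¹, the sign
and rank structure of factor–Pn correlations (PAR strongest environmental
driver, ETR strongest fluorescence correlate, qN ≈ uncorrelated), and
replicate-level measurement noise. It does not contain mechanistic
biochemistry (no FvCB model), stomatal or humidity responses, diurnal
effects, leaf-age or leaf-position gradients, instrument drift, or
correlated (plant-level) error structure. Tests passing on this generator
therefore demonstrate that the pipeline recovers the encoded response
structure under realistic noise — not that the trained network generalises
to any particular real cultivar or greenhouse.

## Preprocessing

Normalization to [−1, 1] is fitted per feature (min/max) on the training
split only, applied everywhere, and inverted exactly; out-of-range values
map outside [−1, 1] without clipping so leakage is detectable. Constant
features are rejected (relative humidity, fixed by design, is reported NaN
by the screen and can never be selected). Pearson correlations use the
population (divide-by-n) moments — algebraically identical to the sample
form — with a two-sided t test on n − 2 degrees of freedom at α = 0.01.
The 80/20 train/validation split is a seeded uniform permutation with
`round(0.8·N)` training rows (936 → 749/187).

## Network and training

The single-hidden-layer network defaults to tanh (`tansig`) hidden units —
the natural companion of [−1, 1] normalization — with the logistic
(`logsig`) form selectable. Gradients are exact analytic back-propagation,
verified against central finite differences. Two trainers share one
interface:

- `gd`: full-batch steepest descent. The step uses the per-sample-mean
  gradient (summed gradient divided by samples × outputs) so that the step
  factor η (default 0.05) is independent of sample size.
- `lm`: Levenberg–Marquardt on the residual Jacobian, λ₀ = 10⁻³, λ × 10 on a
  rejected step and λ / 10 on an accepted one. Steps are accepted only if
  the loss decreases, so the LM error trace is non-increasing; if a full λ
  sweep (25 doublings) finds no decrease the trainer stops, since later
  epochs would repeat verbatim.

Training stops at a target mean squared error (`goal`) or at the epoch
budget. The reference pipeline fine-tunes with LM at goal 10⁻⁶ — effectively
"train to convergence" — while the standalone trainer default (gd, goal
10⁻³, 500 epochs) keeps the literal fixed-step rule available.

## Swarm initialization

PSO runs over the flattened 26-parameter weight vector: 110 particles,
ω = 0.729, c₁ = c₂ = 1.49445 (standard constriction-equivalent values),
positions initialised on [−0.5, 0.5], velocities clamped to ±0.5 per
dimension, one fresh uniform draw per particle per dimension, 100 iterations
with early stop after 20 stalled iterations. Fitness is the training-split
MSE per sample per output neuron; validation data never enters the fitness.
The swarm's global best typically improves the starting training MSE by
roughly an order of magnitude over a random draw before fine-tuning begins.

## Method comparison

`compare_methods` races plain BP (seeded random initial weights) against
PSO-BP (swarm initial weights) with both arms sharing one trainer
configuration and matched per-seed epoch budgets — the convention under
which training-iteration counts are conventionally reported — and logs the
swarm's own fitness-evaluation count per seed so the extra search cost is
visible. The default comparison trainer is the fixed-step gradient rule
(500 epochs, goal 10⁻³): that is the regime whose slow convergence and
local-minimum sensitivity swarm initialization is meant to cure. Under LM
both arms reach the replicate-noise floor from almost any start and the
comparison degenerates to ties. `charge_pso_evals=True` instead enlarges
the BP arm's budget by the swarm's evaluation count (one full-batch
evaluation ≈ one epoch), equalizing total function evaluations for readers
who prefer that accounting. Epochs-to-goal is right-censored at the trace
length when the goal is never reached.

## Numerical and degenerate-input choices

- Node-count rule `(m + n)/2 + c` floors the half for odd m + n; c must be
  an integer in [1, 10].
- Factor selection sorts by |r| descending with a stable tie-break in input
  order; non-finite correlations (constant factors) are never selected.
- Mean-relative-error excludes entries with |truth| < 10⁻⁹ and reports the
  excluded count; R² is refused for constant truth vectors.
- Weight vectors flatten in the fixed order W1 row-major, b1, W2 row-major,
  b2; round-trips are exact.
- CSV datasets carry a `#`-prefixed JSON metadata header (seed, generator
  config, schema version) and 17-significant-digit floats, so read∘write
  reproduces values to ≥ 12 significant digits; schema violations name the
  offending column and row.
- All randomness flows through explicitly seeded NumPy generators; one run
  seed deterministically derives the split/init/swarm seed bundle.

## Known limitations

- Five hidden units cannot represent the three-factor product surface
  exactly: on noise-free data the validation R² plateaus near 0.99 (an
  expressiveness ceiling — multi-start quasi-Newton and damped-least-squares
  probes land at the same level), while data generated by a five-node
  teacher network are recovered to MSE < 10⁻⁶. At the default 3 % replicate
  noise the network's approximation error is small compared with the noise
  floor and validation R² ≈ 0.985–0.99.
- The comparison verdicts are median-based over a handful of seeds; with a
  strong second-order trainer the final-error difference between arms is
  within seed-to-seed noise, which is why the headline comparison uses the
  fixed-step trainer.
- The generator's correlation strengths depend on its frozen surface
  parameters; they reproduce sign and rank structure, not any particular
  numeric correlation values.
- Problem sizes throughout (936-record campaigns, 100-iteration swarms,
  ≤ 5-seed replications) are chosen so the full analysis reruns in seconds
  to minutes on a laptop.
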