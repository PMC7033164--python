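# photonet

Hybrid PSO-BP modelling of leaf photosynthesis for greenhouse crops.

Growers and crop physiologists who want to steer supplemental lighting, CO₂
enrichment or heating need a fast predictor of the net photosynthetic rate
(Pn, μmol CO₂·m⁻²·s⁻¹) of young canopy leaves from the conditions they can
actually control — air temperature (Tem), CO₂ concentration, and light
intensity (PAR). `photonet` implements that predictor as a single-hidden-layer
feedforward network whose initial weights are found by particle swarm
optimization (PSO) and then fine-tuned by damped least squares, together with
everything around it: a synthetic factorial-experiment generator with
realistic light/temperature/CO₂ response surfaces and chlorophyll-fluorescence
parameters (qP, ETR, ΦPSII, Fv′/Fm′, NPQ, qN), Pearson-correlation factor
screening, and the evaluation battery comparing plain back-propagation (BP)
against PSO-BP and the auxiliary ETR/NPQ prediction models.

## The model

Features are scaled to [−1, 1] by `y = 2(x − xₘᵢₙ)/(xₘₐₓ − xₘᵢₙ) − 1`. The
network is `m → L → 1` with `L = (m + n)/2 + c` hidden nodes (for m = 3
inputs, n = 1 output, c = 3: five nodes), a `tansig` (tanh) hidden activation
and linear output. Training minimises the half-sum-of-squares error
`E = ½ Σⱼ (Pn′ⱼ − Pnⱼ)²` via exact back-propagated gradients, either by the
fixed-step rule `w ← w − η ∂E/∂w` or by Levenberg–Marquardt.

The swarm searches the flattened 26-parameter weight vector with the
canonical update

```
Vᵢⱼ ← ω Vᵢⱼ + c₁ r₁ (Pᵢⱼ − Xᵢⱼ) + c₂ r₂ (P_gⱼ − Xᵢⱼ),   Xᵢⱼ ← Xᵢⱼ + Vᵢⱼ
```

(ω = 0.729, c₁ = c₂ = 1.49445, 110 particles), with the training-set mean
squared error as fitness; the global best seeds the fine-tuner.

## Worked example

```
$ photonet generate --seed 7 --out leaves.csv
wrote 936 records to leaves.csv
$ photonet correlate --data leaves.csv --out corr.csv
factor         r   n       p_value  significant_0.01
   tem  0.211683 936  6.074888e-11              True
   co2  0.282136 936  1.373902e-18              True
   par  0.598549 936  4.732847e-92              True
    rh       NaN 936           NaN             False
    qp -0.589956 936  7.649549e-89              True
   etr  0.743394 936 2.539241e-165              True
phips2 -0.630204 936 9.373589e-105              True
fvpfmp -0.606853 936  3.026363e-95              True
   npq  0.696731 936 6.545241e-137              True
    qn -0.055013 936  9.254849e-02             False
$ photonet train --data leaves.csv --seed 7 --out model.json
validation R2 = 0.9851, RMSE = 0.5526 (0.0583 normalized)
```

The generated campaign is the full factorial design — 6 temperatures ×
4 CO₂ levels × 13 light intensities × 3 replicate plants = 936 records.
The screen shows the expected physiology: Pn rises with light, CO₂ and
(mildly) temperature; the electron transport rate ETR tracks Pn most closely
of the fluorescence parameters; the quantum-yield parameters (qP, ΦPSII,
Fv′/Fm′) fall as light saturates the leaf, so they correlate negatively; the
sustained-quenching coefficient qN carries essentially no signal; relative
humidity is held at 50 % by design and is screened out as constant. The
trained PSO-BP model explains ≈98.5 % of held-out Pn variance with an RMSE
of ≈0.55 μmol·m⁻²·s⁻¹ (0.058 in normalized units).

`photonet compare` races plain BP (random initial weights) against PSO-BP
over several seeds at matched epoch budgets, and `photonet fluor` fits the
auxiliary models that predict ETR and NPQ from the same three drivers. The
same functionality is available from Python via `photonet.run_psobp`,
`photonet.compare_methods` and `photonet.fit_fluorescence_models`.

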