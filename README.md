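# gaitpower

Lifespan analysis of lower-limb joint power during walking, built around a
penalized function-on-scalar regression (FoSR) of gait-cycle waveforms.

Joint power — the dot product of net joint moment and joint angular
velocity, time-normalised to 101 points of the gait cycle and scaled to
body mass (W/kg) — changes non-linearly from childhood to old age, and its
canonical peaks (Winter's discrete indices: ankle push-off A2, hip
early-stance H1, hip pull-off H3, …) are candidate biomarkers of gait
maturation and ageing.  Pooling participants across studies and ages
requires a model that lets every effect vary smoothly over the cycle while
adjusting for walking speed, body size and between-study differences.
`gaitpower` implements that model, per joint:

```
y_ij(t) = β₀(t) + sex_ij·β_sex + f_age(age_ij, t) + f_speed(speed_ij, t)
          + f_strlen(l_ij, t) + f_ht(h_ij, t)
          + f_age,speed(age_ij, speed_ij, t) + b_j(t) + ε_ij(t)
```

with tensor-product penalized B-spline smooths, sum-to-zero
identifiability constraints, study-level random intercept curves b_j(t),
REML smoothing selection with analytic gradients, and posterior-simulation
confidence intervals for derived peak values.  See `docs/methods.md` for
the full model account and known limitations.

The package is aimed at biomechanists and biostatisticians who want a
tested, reproducible FoSR pipeline for gait waveforms — including a
synthetic-cohort generator with known ground truth, so every stage can be
validated by parameter-recovery and calibration simulations.

## Worked example

```python
from gaitpower import (GeneratorConfig, ModelSpec, simulate_dataset,
                       prepare_waveforms, build_design, fit, peak_trajectories)

cfg = GeneratorConfig(n_participants=300, seed=1)      # lifespan cohort, 6 studies
covs, waves, truth = simulate_dataset(cfg, joints=("ankle",))
ready = prepare_waveforms(waves)                       # ankle -> cycle points 25..75
model = fit(build_design(ready, covs, ModelSpec.for_joint("ankle", "compact")))

test = model.sex_effect_test()
print(f"sigma^2 = {model.sigma2:.4f}")
print(f"sex effect = {test.estimate:+.4f} W/kg (t = {test.tstat:.2f})")

traj = peak_trajectories(model, n_draws=2000, seed=1)
a2 = traj[(traj.label == "A2") & (traj.speed == 1.2)]
print(a2[["decade", "mean_wkg", "lower_wkg", "upper_wkg"]].round(3).to_string(index=False))
```

prints

```
sigma^2 = 0.0226
sex effect = -0.0265 W/kg (t = -10.47)
 decade  mean_wkg  lower_wkg  upper_wkg
      1     2.142      2.092      2.189
      2     2.336      2.291      2.381
      3     2.384      2.338      2.428
      4     2.330      2.284      2.374
      5     2.266      2.219      2.308
      6     2.214      2.166      2.256
      7     2.181      2.134      2.223
      8     2.157      2.109      2.201
      9     2.164      2.115      2.210
```

Read: the residual variance matches the generator's noise (0.15² = 0.0225);
the constant sex offset recovers the true −0.026 W/kg (males lower); and
the predicted ankle push-off peak (A2, W/kg, at 1.2 m/s with decade-typical
height and stride length) rises through childhood, culminates in the 3rd
decade of life — where the generator's true age profile peaks — and
declines gently thereafter, each value with a 95% posterior-simulation CI.

The same pipeline runs from the shell:

```sh
gaitpower all --config config.yaml --out results/   # simulate -> fit -> report
```

writing the dataset, per-joint model bundles, trajectory tables, plots and
a manifest sufficient to reproduce the run bit-for-bit.

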