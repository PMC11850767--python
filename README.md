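# compete-dynamics

Analysis pipeline for competitive social behavior and the neural population
dynamics underneath it. The package targets the food-competition setting:
two mice contest a pellet while one animal's ventral-hippocampal units are
recorded. It provides, as tested library code with a thin CLI:

- **synthetic sessions with known ground truth** — rSLDS-generated latents
  with a point-attractor state and rotational states, Gaussian or Poisson
  rate emissions, behavior labels coupled to rotational phase, scripted
  two-mouse keypoint videos, and drifting unit waveforms with
  log-normal-mixture inter-spike intervals;
- **pose featurization** — a 26-feature space (9 self features per mouse +
  8 interaction features) from six-node keypoint tracks, 500 ms clips,
  hierarchical behavioral-motif clustering, the four-class labelling
  (snatch / chase / retreat / other), run-length event metrics and the 3 s
  defender rule for pellet possession;
- **peri-event unit analysis** — Wilcoxon signed-rank responsiveness with
  the z > 1.5 / z ≤ −1 rule, functional clustering of event-aligned
  z-series, rank-sum group comparisons, KS tests on rate-variance
  distributions;
- **cross-day unit tracking** — time-shifted waveform correlation
  (threshold 0.81) combined with an eight-parameter ISIH mixture distance
  (ln I < 1);
- **the rSLDS itself** — a recurrent switching linear dynamical system

  `p(z_t=i | z_{t−1}=j, x_{t−1}) ∝ exp(log P_ji + R_iᵀx_{t−1})`,
  `x_t = A_{z_t} x_{t−1} + b_{z_t} + w_t`,
  `y_t = C x_t + d + v_t`,

  fitted by deterministic MAP-EM (Kalman smoother × Viterbi alternation
  with closed-form M-steps), with cross-validated model selection and BIC;
- **dynamics metrics** — emission-aware PCA, per-state flow fields, dynamic
  velocity `V_z = mean‖A_z x_t‖` normalized to state 1, rotation angles
  about the geometric median referenced to the state-1 point attractor,
  transition/dwell statistics, attractor time-constant scores
  (`τ = |1/ln|λ||`, line-attractor score `log₂(τ_max/τ_second)`), and a
  sequentiality index with shuffle nulls;
- **state-specific GLM decoding** — one multinomial GLM per discrete state
  (softmax filters, zero 'other' filter, smoothness penalty) against a
  frequency chance model;
- **longitudinal cross-correlation** — lagged correlation of daily
  neural/behavioral series with a permutation test.

See `docs/methods.md` for the models, assumptions, parameter defaults and
numerical choices.

## Worked example

Simulate a rotational session, fit the switching model, and read off the
dynamics metrics:

```python
import numpy as np
from compete_dynamics import synthetic_data, rslds, dynamics_metrics as dm

cfg = synthetic_data.SimConfig(n_latent=2, n_units=30, n_timesteps=2000, seed=1)
params = synthetic_data.make_rotational_params(cfg)
latents, rates, truth = synthetic_data.simulate_session(params, cfg)

fit = rslds.fit(rates, K=3, D=2, seed=1, max_iter=150)
z = rslds.permute_to_match(latents.z, fit.z, 3)
print(f"state accuracy      {np.mean(z == latents.z):.3f}")
print(f"variance explained  {fit.variance_explained:.4f}")

vel = dm.dynamic_velocity(fit.params, fit.x, fit.z)
print(f"dynamic velocity    {np.round(vel, 3)}")
print(dm.attractor_scores(np.diag([0.99, 0.9]))["line_attractor_score"])
```

prints

```
state accuracy      0.980
variance explained  0.9958
dynamic velocity    [1.    1.097 1.256]
3.3900186935275545
```

The fitted discrete path matches the generating one on 98% of bins after
label permutation; the posterior-mean reconstruction carries ~99.6% of the
rate variance; per-state velocities are reported relative to state 1; and
the eigenvalue pair {0.99, 0.9} yields a line-attractor score of ≈ 3.39
(log₂ of the time-constant ratio 99.5/9.49).

An end-to-end run on synthetic data (simulate → features → fit → dynamics
→ GLM → cross-correlation, with a manifest of output hashes):

```bash
compete-dynamics run --out demo_run/ --seed 0
```

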