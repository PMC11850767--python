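# Methods

This package reimplements, end to end on synthetic data, a computational
analysis of competitive behavior and hippocampal population dynamics: pose
featurization and behavioral motif clustering, peri-event single-unit
analysis, cross-day unit tracking, a recurrent switching linear dynamical
system (rSLDS) for population activity, rotational-dynamics and attractor
metrics, state-specific multinomial GLM behavior decoding, and lagged
cross-correlation of daily series.

## The switching model

The generative model couples discrete behavioral-strategy states `z_t ∈
{1..K}` with continuous population latents `x_t ∈ R^D` and binned firing
rates `y_t ∈ R^N` (500 ms bins):

- transitions: `p(z_t = i | z_{t−1} = j, x_{t−1}) ∝ exp(log P_{ji} + W_iᵀu_t
  + R_iᵀ x_{t−1})` — a softmax over a base row-stochastic matrix `P` plus a
  recurrent readout `R` of the previous latent;
- dynamics: `x_t = A_k x_{t−1} + V_k u_t + b_k + w_t`, `w_t ~ N(0, Q_k)`;
- emissions: Gaussian `y_t = C x_t + d + v_t`, `v_t ~ N(0, S)` by default,
  or Poisson with an exponential link for spike counts.

The exogenous input `u_t` is identically zero; `W, V, F` are carried in the
parameter type for completeness but fixed at zero. Emissions are tied
across discrete states (a single `C, d, S`), the usual convention for this
model class.

### Fitting

Fitting is a deterministic MAP-EM rather than black-box variational
inference: conditioned on a discrete path, the model is linear-Gaussian, so
the E-step alternates an RTS Kalman smoother for `x | z` with a Viterbi
pass for `z | x`; the M-step is closed-form weighted least squares for
`{A_k, b_k, Q_k, C, d, S}` and an L-BFGS multinomial logistic regression
(warm-started, ridge 1e−6) for `{P, R}`. The reported objective is the
joint log density at the MAP point; coordinate ascent makes it monotone
non-decreasing (tolerance 1e−6 relative), which the tests assert.

Initialization: latents from PCA of the rates; the discrete path from
k-means regime segmentation. Because the EM surface has basins
corresponding to shifted state boundaries, the fit is run from several
segmentation feature stacks — position + one-step displacement (default),
position + global-AR(1) residual, and position alone — and the run with the
highest final objective is kept. All randomness is derived from the `seed`
argument; refits are bit-identical.

Noise covariances carry a small variance floor (1e−4) so degenerate
noise-free inputs do not produce unbounded densities.

### Model selection

`select_model` scores a (K, D) grid by 5-fold cross-validation on
contiguous time blocks. The held-out score decodes the discrete path by
coordinate ascent, then computes `log p(y | ẑ)` exactly by the
Kalman-filter innovations decomposition plus the transition log-probability
of `ẑ`. Integrating the latents out matters: a max-over-x score has no
volume correction and systematically favours high-noise or high-dimensional
models. The same innovations likelihood enters BIC
(`k·ln n − 2·log L̂`). The selector returns the CV argmax with the full
table.

## Synthetic sessions

The generator produces sessions with one point-attractor state and
rotational states, in the smallest geometry that sustains itself:

- states partition the 2D rotation plane by phase: state k's recurrent row
  `R_k` points at its sector centre (gain 2.5);
- each state's affine offset places its fixed point one sector *ahead*
  (rotation about off-centre points). With fixed points inside their own
  sectors the chain collapses permanently into the point-attractor state;
  the ahead-placement is the standard construction for a self-sustaining
  switching loop. The resulting trajectory orbits at radius ≈ 9 with the
  nominal 10°/step advance;
- state 1 contracts (spectral radius 0.9 — all eigenvalue magnitudes below
  one), states 2–3 carry a ρ = 0.98 rotation block, padded with 0.8
  contractions in any extra dimensions.

Process and emission noise default to SD 0.5. This is a deliberate
modelling choice, not a nuisance: with near-noise-free latents the
trajectory lies on a one-dimensional phase manifold, and per-state affine
maps restricted to disjoint arcs are unidentifiable (boundary-shifted
blends fit the arcs exactly). Realistic state-space exploration is what
makes the per-state dynamics — and hence recovery tests — well-posed.

Behavior labels are a pure function of the rotation angle (computed with
the same three-point construction as the analysis code) through a
user-supplied partition of [0°, 360°) into snatch / chase / retreat /
other.

Pose sessions are scripted kinematic chains for two mice (nose, ears, head,
body centroid, tail base) at 30 Hz whose class signatures match the
feature-space descriptions (snatch: noses together, bent head; retreat:
stretched bodies separating fast). Unit fixtures pair Gaussian-derivative
waveform templates (day-to-day jitter SD `drift_sd`) with fixed
three-component log-normal ISI mixtures per unit.

What the generator does *not* emulate: recording nonstationarities, true
spike-sorting errors, correlated noise across units, identity swaps in
tracking, or any animal-to-animal variability structure. Passing tests
demonstrate the pipeline's correctness and recoverability under the model's
own assumptions, not performance on real recordings.

## Pose features and behavior classes

26 features per frame: 9 per mouse (head length, body length, head–body
angle, two ear-to-nose lengths, two ear–body angles, displacement distance
and direction) and 8 interaction features (body–body and head–head angles,
nose–nose distance and angle, two tail-to-opposite-nose distances and
angles). Lengths are in pixels; all angles are undirected in [0°, 180°]
except the displacement direction in [0°, 360°). Frame features are
averaged in 500 ms clips and z-scored across clips; hierarchical clustering
(Euclidean, Ward by default — configurable) yields motifs, mapped to the
four behavior classes by a user- or preset-supplied table with declared
noise motifs dropped. Events are maximal runs of one class; possession
scoring applies the 3 s defender rule (a challenger's take counts only
after a 3 s hold, otherwise it is a failed bout).

## Unit analysis and tracking

Peri-event analysis smooths 50 ms-binned rates with a 100 ms Gaussian
kernel, z-scores against a 3 s baseline ending 1 s before onset, tests
baseline-vs-response rate pairs with the Wilcoxon signed-rank test, and
calls a unit responsive when p < 0.05 and the mean response-window z is
strictly above 1.5 or at/below −1. Units under 0.1 Hz are excluded.
Functional clusters cut an average-linkage dendrogram at 0.4 × the maximum
linkage height (absolute-height mode available); non-responsive units form
a residual cluster.

Cross-day matching accepts a pair as the same neuron when the maximum
time-shifted Pearson waveform correlation w exceeds 0.81 *and* the log ISIH
score I′ = ln √(Σ (A_i−B_i)²/σ_i²) over the eight log-normal-mixture
parameters is below 1. The σ_i normalizers default to across-population SDs
of each fitted parameter (a per-fit alternative is configurable).

## Dynamics metrics

The PCA change of basis whitens the latents, takes the SVD `C W⁻¹ = U S
Vᵀ`, and maps `x″ = (S Vᵀ) W x`, giving `y = U x″` with orthonormal `U` and
`cov(x″) = S²` — components ordered by the observed variance they carry.

Dynamic velocity is the literal per-state mean `‖A_z x_t‖` over visited
bins, normalized to state 1; an alternative displacement mode
`‖(A_z − I) x_t + b_z‖` is available behind a flag for sensitivity
analysis. The rotation angle at each bin is formed from the state-1 point
attractor (visited bin minimizing `‖A₁x‖`), the trajectory's geometric
median (Weiszfeld, tolerance 1e−8), and the current point, with the 2D
cross product resolving direction against the trajectory's global rotation
sense (sign of the mean signed angular increment). Attractor scores follow
the eigenvalue time constants `τ = |1/ln|λ||`: stability is the largest τ
and the line-attractor score is `log₂(τ_max/τ_second)` (exactly 0 for an
equal-magnitude conjugate pair, +∞ flagged at |λ| = 1).

The sequentiality index has no canonical definition here; this package uses
the mean of (a) normalized entropy of the per-unit peak-time distribution
and (b) a squashed log ridge-to-background contrast around each unit's
peak, with a per-unit independent circular-shift null (1000 shuffles).
Treat it as this package's operationalization, not a community standard.

## State-specific GLM

One multinomial GLM per discrete state maps z-scored cues (latent
dimensions plus distance and facing angle) to the four classes through
`P(i|s) = exp(F_i·s)/Σ_j exp(F_j·s)`, with the 'other' filter pinned at
zero. The penalized likelihood (smoothness penalty λ Σ (F[j+1]−F[j])² on
adjacent coefficients in the fixed cue ordering, λ = 0.1 default) is
concave; L-BFGS with analytic gradients finds the unique optimum. Decoding
is per-bin argmax with ties to the lowest class index; evaluation uses a
contiguous 80/20 block split (random splits leak autocorrelation) against
the constant-probability chance model `p(i) = N_i/N`.

## Longitudinal cross-correlation

Daily series are compared by the sample cross-covariance with 1/T
normalization, divided by the product of the series SDs; lags run to
⌊T/2⌋. The optimal lag maximizes r (ties: smallest |k|, then negative).
Significance uses a permutation test on the max-|r| statistic (default
n = 1000, add-one correction). A source formula for the cross-covariance
appeared typographically garbled (a missing second centred factor); the
standard two-factor form is implemented.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale, chosen as the smallest
sizes at which the statistical claims are stable: recovery fits use K = 3,
D = 2–3, N = 30 units, T = 2000 bins; model selection uses T = 1000,
N = 20 with a K ∈ {1..4} grid; tracking uses 40 units × 2 days with 5000
ISIs per day; calibration checks use 300–1000 replicate pairs. Weiszfeld
iterations stop at 1e−8; EM at 1e−6 relative objective change with a
150-sweep cap; absent behavior classes within a state cap their filter
weights at ±20 with a warning.

## Known limitations

- Hard-assignment MAP-EM can converge to boundary-shifted local optima;
  multiple structured initializations mitigate but do not eliminate this.
- The held-out model-selection score conditions on the decoded discrete
  path rather than marginalizing it.
- The Poisson emission path supports simulation and moment checks; fitting
  quality is validated primarily for the Gaussian case.
- The pose generator produces stereotyped kinematics; motif clustering on
  real videos will need its own preset and noise-cluster curation.
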