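# Methods

This note documents the models implemented in `gsmring`, the choices made
where the design was genuinely open, and what the synthetic experiments do
and do not show.

## The generative model and the ideal observer

Image patches are modelled as a Gaussian scale mixture (GSM): a patch
`x ∈ R^P` is a linear combination of `K` oriented Gabor features (columns of
`A`, unit-norm, zero-mean, orientations uniform on [−90°, 90°)), with
Gaussian coefficients `y ~ N(0, C)`, scaled by a global contrast `z` from a
gamma prior, plus isotropic pixel noise:

    x | y, z ~ N(z A y, σ_x² I),   y ~ N(0, C),   z ~ Gamma(k_z, θ_z).

The observer infers `p(y | x)`. Conditioned on `z` this is Gaussian with

    Σ(z) = (C⁻¹ + z² AᵀA / σ_x²)⁻¹,   μ(z) = Σ(z) z Aᵀx / σ_x²,

evaluated internally in Woodbury form (`Σ(z) = C − z² C Aᵀ S⁻¹ A C` with
`S = σ_x² I + z² A C Aᵀ`) because the smooth ring-kernel prior covariance is
numerically near-singular and its explicit inverse is not usable. Contrast
is marginalised on a log-spaced grid (default 80 points on [10⁻³, 12]) with
log-space evidence evaluation; the mixture moments follow the law of total
variance. At `z = 0` the stimulus carries no information and
`posterior_given_z` returns the prior exactly (bitwise), which is the
sampling-hypothesis reading of spontaneous activity.

**Prior covariance kernel.** `C` is stationary on the orientation ring with
period 180°. We use the periodic squared-exponential (von Mises) kernel
`σ² exp(κ(cos(2πd/180) − 1))` with `κ` matched so that small-distance
correlations follow `exp(−d²/2w²)` (default width `w = 25°`, variance 1).
A raw Gaussian of the wrapped distance is *indefinite* at 32 latents and
this width (smallest eigenvalue ≈ −1.5·10⁻³), so it cannot serve as a
covariance; the periodic kernel is positive definite for every width.

**Hypoprior.** The prior is broadened by `C → α C`; the reference value is
`α = 1.5`. Broadening the prior makes the observer over-weight the
likelihood: posterior means and posterior SDs both increase at every
contrast (exactly provable in the 1D conjugate toy model with `C = 4`,
`A = 10`, `σ_x² = 100`, where `z` scales the likelihood precision; verified
numerically for the multivariate model).

**Gabor defaults.** Envelope σ = patch_side/5, wavelength = patch_side/2,
even (cosine) phase, zero-mean corrected, unit-norm columns. These are
stand-ins for unpublished filter parameters; they keep the bank
well-conditioned and exactly rotationally symmetric, which the tests exploit
(90°-apart columns are pixel-space rotations of each other).

## Stimuli

The evaluation bank crosses nominal orientations with contrast levels
{0, 0.25, 0.5, 1, 2, 4}; each patch is `z·A·y*` with `y*` a positive
wrapped-Gaussian bump of feature coefficients (width 20°, height 2). The
positive bump makes mean-ordering claims well-posed. Zero contrast is the
zero patch and stands in for spontaneous activity. Training samples draw
`(y, z)` from the full forward model and keep the latent record. Both
generators are pure functions of (parameters, seed).

## The stochastic E-I ring network

`N` excitatory/inhibitory pairs (default 32) sit on an orientation ring.
Membrane potentials follow

    τ_i du_i = (−u_i + h_i + Σ_j W_ij r_j + η_i) dt,   r_i = k ⌊u_i⌋₊^m,

with `τ_E = 20 ms`, `τ_I = 10 ms`, `k = 0.3`, `m = 2` (the threshold-power
form is the standard SSN transfer; plain `u^m` would give complex rates for
negative potentials). Each weight block (E→E, E→I, I→E, I→I) is a
row-normalised Gaussian ring kernel times a signed block amplitude, so the
amplitudes read directly as aggregate synaptic weight and the dynamics are
insensitive to `N`. Dale's principle is enforced at construction and after
every perturbation. The process noise `η` is Ornstein-Uhlenbeck with a
ring-structured spatial covariance (correlated fraction 0.75, width 30°,
SD 0.68 mV, correlation time 20 ms) integrated with the exact one-step OU
update inside an Euler-Maruyama loop (`dt = 0.25 ms` for analyses; `dt` must
satisfy `dt ≤ min(τ)/10`). The integrator core is compiled with numba and is
bit-reproducible given (parameters, seed, dt).

Feedforward drive is `h = baseline + ⌊W^ff x⌋₊` where `W^ff` stacks the same
Gabor filters the observer uses (gain 0.155; I cells receive 0.16 of the
E drive; E baseline 0.5, I baseline 0.04).

## The calibrated NT reference network

The original approach trains the network end-to-end so that its stationary
E-cell statistics sample the GSM posteriors; that training is far outside a
desk budget. Instead, `calibration` fits the low-dimensional kernel
parametrization by derivative-free (Nelder-Mead over log-parameters)
minimisation of a moment-matching loss — squared error between simulated
stationary E-cell mean/variance and per-stimulus targets — with common
random numbers (one fixed simulation seed per stimulus shared by all
evaluations) so the loss is quasi-deterministic. A monotone
best-so-far rule guarantees the returned loss never exceeds the initial
one, and the budget is split across simplex restarts because E-cell-only
moments leave a soft ridge between the E→I and I→I amplitudes.

The shipped default parameters *are* the package's calibrated NT network:
they were selected once, at desk scale, to jointly satisfy the qualitative
structure the reference dynamics require —

* stationary E-potential SD decreasing with contrast (variability
  quenching: 0.63 → 0.44 over the bank) while mean responses rise and
  decelerate;
* a gamma-band (20-80 Hz) LFP spectral peak with power and peak frequency
  increasing with contrast;
* an inhibition-stabilised high-contrast regime (the paradoxical-effect
  precondition) but a *non-paradoxical* spontaneous state, so that scaling
  excitatory columns down genuinely lowers spontaneous activity and the
  homeostatic grid search has an interior optimum with `δ_E < δ_I`.

The last point is a real constraint, not a convenience: deep in the
inhibition-stabilised regime, scaling down excitatory *columns* (which
include E→I) disinhibits the network and *raises* activity, so homeostatic
compensation by excitatory down-scaling is impossible there. The NT state
sits intentionally on the non-paradoxical side at rest and crosses into the
paradoxical regime under drive.

## Perturbations

Inhibitory deficit: inhibitory columns of `W` scaled by `1 − δ_I`
(reference δ_I = 0.1, sweep {0.05, 0.1, 0.15}). Homeostatic compensation:
excitatory columns scaled by `1 − δ_E`, with `δ_E` chosen by grid search
(coarse step 0.002 over [0, δ_I], refined once at 0.0005 — the analysis
protocols use 0.005/0.001 to stay inside desk runtimes) minimising
`|μ_s(NT) − μ_s(ASD)|`, the change in mean spontaneous firing rate under
zero-contrast drive with a fixed protocol seed. `μ_s` averages all cells by
default; an E-only switch exists because the convention is not fixed by the
problem. Composition order is inhibition first, then excitation. On the
reference network the resolved compensations are δ_E ≈ 0.030, 0.059, 0.089
for δ_I = 0.05, 0.1, 0.15 — always smaller than the deficit and
nondecreasing — and the ASD spontaneous rate matches NT to ≈ 0.1%.

## Analyses

* Stationary moments: thinned post-burn-in samples (reference protocol:
  samples 200 ms apart; desk analyses thin at 10-20 ms and state the count).
* LFP: unweighted across-cell average potential (all cells by default;
  E-only/I-only switches provided).
* Spectra: Welch with 1-s Hann windows, 50% overlap, one-sided, per-window
  mean removal. Gamma band fixed at 20-80 Hz; the peak is the largest local
  maximum strictly inside the band (ties to lower frequency; a monotone
  spectrum has no peak), and gamma power is the trapezoidal band integral.
* Transients: feedforward input steps from baseline to the stimulus value at
  onset plus a per-pair truncated-Gaussian delay (mean 45 ms, SD 5 ms,
  truncated at 0, inverse-CDF sampling, shared within a pair, redrawn per
  trial); firing rates averaged across E cells and trials (reference
  n = 100), smoothed with a 10-ms moving window; the peak of the smoothed
  trace is the overshoot size. Default protocol records 500 ms before and
  after onset at 1 ms.
* Input decomposition: time-averaged `Σ_{j∈E} W_ij r_j` and
  `|Σ_{j∈I} W_ij r_j|` per E cell, for the paradoxical-effect check.

## What the synthetic experiments show — and what they do not

The pipeline's two paths are compared as *sign* claims at fixed common
seeds: the hypoprior raises posterior means and SDs at every positive
contrast; the compensated inhibitory deficit raises network response means,
SDs, gamma power, and high-contrast transient peaks, and raises the mean
inhibitory input onto E cells at high contrast despite weaker inhibitory
synapses. Agreement of the two paths' signs is the consistency result.

Limitations to keep in mind. The NT network is a desk-scale moment-matched
stand-in, not the trained sampler: its stationary moments track the GSM
posteriors qualitatively (quenching, tuned means) but not quantitatively,
and its mean responses decelerate rather than saturate at the highest
contrast. Its gamma peak sits in the low-gamma range (~20-30 Hz) with
modest band power rather than the pronounced peaks a fully trained network
shows. Effect sizes of the deficit are a few percent at spontaneous and
grow with drive; they are resolved reliably only because NT and ASD runs
share random numbers. Stimuli are noiseless single-orientation bumps, not
natural images; nothing here addresses cardinal-versus-oblique anisotropies,
which the rotationally symmetric construction excludes by design.

## Numerical choices

* Euler-Maruyama with exact OU sub-step; divergence (non-finite or |u| >
  10⁷ mV) raises with the first bad time; `dt ≤ min(τ)/10` enforced.
* Fixed points: Newton (hybr) with analytic Jacobian, noise-free relaxation
  fallback, residual postcondition ‖·‖∞ < 10⁻¹⁰.
* Linear-regime validation: stationary covariance against the augmented
  (u, η) continuous-time Lyapunov solution.
* Quadrature oracles: dense-grid Riemann sums over latents (≤ 3 dims,
  ±8 prior SDs, 121 points/dim); gamma-contrast grids log-spaced.
* Child seeds: SHA-256 of `"{master}:{label}"` mod 2³¹, one label per
  stage, so stages are independently reproducible.
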