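# Methods

## Scope and model family

`pfgdiff` models the attenuation of a pulsed-field-gradient (PFG) diffusion-NMR
signal. A bipolar gradient pair (strength `g`, pulse duration `δ`, leading-edge
interspacing `Δ`, first pulse starting at `t₁` after excitation) imprints on
each spin the phase

    φ = γ ∫ x(t) G(t) dt = γ g [ ∫_{t₁}^{t₁+δ} x dt − ∫_{t₁+Δ}^{t₁+Δ+δ} x dt ],

and the normalized echo amplitude is the ensemble average S/S₀ = E{e^{iφ}}.
Under the second-order (Gaussian) cumulant approximation with a zero-mean,
stationary velocity autocorrelation C(s) = ⟨v(t)v(t+s)⟩, the log-signal reduces
to a five-panel single integral over C — implemented verbatim in
`lnS_general_velocity`, with an equivalent three-panel form over a stationary
position autocorrelation in `lnS_general_position`. Specific kernels give the
closed forms:

* **Free (Stejskal–Tanner) diffusion** — `ln S/S₀ = −bD` with
  `b = γ²g²δ²(Δ − δ/3)`.
* **Langevin Brownian motion** (Ornstein–Uhlenbeck velocity, drag rate ζ,
  unit mass, k_BT = Dζ) — the Stejskal–Tanner term plus a finite-correlation-
  time correction `2γ²g²D{δ/ζ² − [1 − e^{−δζ} + e^{−Δζ}(cosh δζ − 1)]/ζ³}`.
  The cosh·exp product is expanded into pure negative exponentials so large
  δζ cannot overflow.
* **Anomalous Gaussian stationary-increment diffusion** (MSD = 2D_α t^α,
  equivalently fractional Brownian motion with H = α/2, K = 2D_α) — the full
  four-power-law form and its `Δ ≳ 2δ` reduction
  `−γ²g²δ²D_α[Δ^α − 2δ^α/((α+1)(α+2))]`; at α = 1 both collapse to −bD
  algebraically.
* **Superstatistical (Brownian yet non-Gaussian) diffusion** — the
  Stejskal–Tanner kernel averaged over a per-molecule diffusivity law P(D):
  `−k ln(1 + bθ)` for Gamma(k, θ), and an erfc-corrected Gaussian form for a
  zero-truncated normal P(D). Both depend on the acquisition only through b.

### Numerical choices in the attenuation layer

* The anomalous velocity kernel `C(s) = α(α−1)D_α s^{α−2}` is not absolutely
  integrable at s = 0 for α < 1. Panel integrals touching s = 0 are evaluated
  by analytic continuation in α (finite part) through the `PowerLawVACF`
  kernel's closed-form moments — exactly the rule under which
  `2∫₀ᵗ C(s)(t−s) ds = 2D_α t^α` holds for every α ∈ (0, 2). Generic callables
  are integrated adaptively with a cube-root substitution on the zero-endpoint
  panel to tame mild algebraic singularities.
* Quadrature results carry explicit convergence checks (accumulated panel
  error vs. dominant panel magnitude, guard 1e−5); failure raises
  `QuadratureError` with the achieved tolerance.
* `ln erfc` is computed as `ln 2 + log_ndtr(−√2 x)`, stable to arbitrarily
  deep tails; the truncated-Gaussian form is accurate to ~1e−13 against
  direct quadrature of the diffusivity average over the whole tested b range.
* The position-autocorrelation form assumes stationarity of ⟨x(0)x(s)⟩, which
  a freely diffusing process does not satisfy. It is implemented literally;
  with the stationary surrogate `X(s) = const − D_α s^α` (additive constants
  cancel identically between its three panels) it reproduces the anomalous
  closed form, which is the sense in which the two routes agree.

## Trajectory simulators

All simulators are seeded (`numpy.random.default_rng` / `SeedSequence`),
bit-reproducible, and stream trajectories in blocks so paper-scale ensembles
never materialize a full position matrix.

* **bm** — exact joint one-step update of the OU velocity and its time
  integral (the position increment), with the velocity initialized from its
  stationary distribution. The exact discretization removes the O(dt) bias an
  Euler scheme would put precisely into the ζ-sensitive correction term.
* **fbm** — Davies–Harte circulant embedding of the exact fractional Gaussian
  noise covariance `γ(k) = (K/2)dt^{2H}(|k+1|^{2H} − 2|k|^{2H} + |k−1|^{2H})`;
  the embedding is padded and retried if an eigenvalue dips negative, and
  fails loudly otherwise.
* **ss** — one diffusivity per trajectory (Gamma draws, or zero-truncated
  normal via rejection with an inverse-CDF fallback below 50% acceptance),
  then overdamped Gaussian increments of variance 2D·dt.
* **ctrw** — event-driven subdiffusive walk: Mittag-Leffler waiting times by
  the Kozubowski–Rachev transform
  `τ = −γ_t ln u [sin(βπ)/tan(βπv) − cos(βπ)]^{1/β}`, Gaussian jumps, and the
  piecewise-constant path resampled onto the uniform sampling grid.

**CTRW jump-scale convention.** The generalized diffusion coefficient is tied
to the jump and waiting scales by `D_α = γ_x²/(γ_t^β Γ(1+β))`, where γ_x is
the *stable* length scale of the jump density. For the Gaussian (2-stable)
case the density with Chambers scale γ_x has variance 2γ_x², so jumps are
drawn with standard deviation √2·γ_x. With the renewal mean count
`⟨N(t)⟩ = (t/γ_t)^β/Γ(1+β)` this yields ensemble MSD = 2D_α t^β — the same
normalization as the Gaussian-stationary family — and is verified empirically
by the MSD-prefactor test.

Default sampling steps are dt = 1e−3 s for the continuous models and
dt = 1e−5 s for the CTRW (waiting-time scale γ_t = 1e−4 s); default ensemble
sizes are 1e5 (5e4 for CTRW) in the full-scale benchmark profile and 1e4–3e4
in the test suite.

## Signal synthesis

Spin phases are accumulated by trapezoid integration of the sampled path over
the two gradient windows; a per-trajectory cumulative integral produces all Δ
values of a grid in one pass (identical to the direct window trapezoid to
machine precision, asserted in tests). Pulse timings must align to the
sampling grid — they are snapped, with a warning above a quarter-step shift
for scalar timings; dense Δ grids snap silently and deduplicate. The FID uses
the real-part convention (the imaginary component is retained as a
diagnostic; its residual is statistically zero for the symmetric dynamics
simulated here). Points where the ensemble mean signal is ≤ 0 are flagged and
excluded from the log, never silently clipped. Rician noise
`S → √((S+ε₁)² + ε₂²)` with ε ~ N(0, (S₀/SNR)²) models magnitude detection.

The default acquisition grid is 48 linearly spaced Δ values on
[max(2δ, 0.01), 1] s with t₁ = 0.005 s. For strongly attenuating conditions,
`attenuation_matched_grid` caps the upper Δ where the *predicted* log-signal
(from the planned model parameters) reaches −5, mirroring how an
experimentalist matches diffusion weighting to the measurable dynamic range;
without this, conditions such as δ = 0.02 s at g = 0.02 T/m leave only a
handful of points above the Monte-Carlo noise floor and no meaningful fit.

### Acquisition design in the benchmark

A single trajectory ensemble shared across the whole Δ grid (the cheap
default) makes every point of the curve ride one noise realization: the
errors are strongly correlated across Δ, and for conditions whose measurable
window is short the fit effectively sees only a couple of independent
numbers, inflating parameter dispersion by an order of magnitude. The
benchmark therefore synthesizes rows whose matched window ends below 0.35 s
with one *independent* full-size ensemble per Δ point — exactly what a real
experiment does, where each interspacing is a separate acquisition. Those
rows are cheap precisely because their trajectories are short. Benchmark
fits additionally use *pre-registered* weights computed from the predicted
per-point standard error rather than the estimated one: an estimated
standard error is anti-correlated with the very fluctuation it weights
(a point that fluctuates high gets a smaller error estimate, hence more
weight), which measurably biases the fitted exponent low on
information-starved rows. Robust losses were evaluated and rejected: they
clip the informative deep-attenuation points asymmetrically and bias the
exponent high. Even so, the δ = 0.02 s, g = 0.02 T/m setting retains a
seed-level exponent dispersion of several percent at 10⁵ trajectories — an
information limit of that acquisition, not an estimator defect.

## Fitting

All fits act on ln(S/S₀) by bounded trust-region least squares with three
perturbed starts (the (D, ζ) surface is a correlated valley when δζ is either
very small or very large); standard errors come from the Gauss–Newton
curvature at the optimum. Initialization uses the Stejskal–Tanner tangent
(slope of −lnS vs b) and, for the superstatistical forms, the quadratic
curvature in b.

**Weighting.** Every Δ point of one synthesized curve is computed from the
*same* trajectory ensemble, so Monte-Carlo errors are strongly correlated
across the grid; a coherent excursion in the noisy deep-attenuation tail can
tilt a uniform-weight fit by tens of percent while the same fit on the exact
closed-form curve is perfect. Curves carrying per-point standard errors are
therefore fitted with 1/se(lnS)² weights; analytic curves and files without
error columns keep uniform weights. Benchmark fits additionally restrict to
points with relative signal error ≤ 0.15 (the noise-floor filter
`AttenuationCurve.reliable`).

Fits that end on a parameter bound report `converged = False`; non-convergence
never raises.

## Validation rules and classifier

Three quantitative rescaling checks mirror the visual criteria:

* **g² collapse** (equal δ, different g): normalized RMS of pairwise
  differences of g⁻²·lnS on the common Δ support, threshold 0.05.
* **f(δ₁, δ₂) constancy** (equal g, different δ): relative drift of
  `(γg)⁻²[δ₁⁻²lnS₁ − δ₂⁻²lnS₂]` over the window, threshold 0.1. On the
  anomalous closed form f equals `2D_α(δ₁^α − δ₂^α)/((α+1)(α+2))` for every Δ.
* **b collapse** (any two conditions): the same RMS statistic after
  re-indexing by b.

For Monte-Carlo or Rician-noisy curves, points with relative signal error
above 0.10 are excluded, and the expected noise contribution to the squared
pairwise difference is subtracted before normalizing, so the statistic
estimates the true curve separation and stays comparable to the
analytic-curve thresholds at any ensemble size. Thresholds are configuration
fields and are echoed in every report.

The flowchart classifier runs the Gaussian-stationary checks on all available
condition pairs; on a pass it pools the log-log trend of −d lnS/dΔ across
conditions (common slope, per-curve intercept) over the asymptotic tail
(Δ ≥ Δ_max/4) and recommends the Brownian formula (constant derivative) or
the anomalous formula (decaying/growing); on a fail it tries the b collapse
and recommends the superstatistical family; if that also fails, no formula in
this toolkit applies.

Two deliberate guards in the trend rule: the regression window excludes short
Δ (a Brownian system with a finite velocity correlation time has a genuine
e^{−ζΔ} transient there), and slopes below 0.12 in magnitude read as
"normal" — measured residual Brownian slopes reach +0.09 in noise-truncated
windows while the benchmark anomalous cases sit beyond ±0.17. The classifier
therefore resolves the diffusive *regime*; exponents within ~0.15 of 1 are
reported as normal at these conditions.

## What the generators do and do not emulate

The synthetic ensembles reproduce the idealized study conditions: 1-D
dynamics, no relaxation weighting, no restricted geometry, rectangular
gradient lobes, noise entering only as optional Rician magnitude noise. The
trajectory-correlation structure of the Monte-Carlo curves (all Δ points from
one ensemble) differs from a real experiment, where each Δ is an independent
acquisition — the variance-weighted fits address exactly this. Passing tests
demonstrate correctness of the formulas, simulators and decision logic under
these conditions; they do not certify behavior on restricted-geometry or
relaxation-weighted data, which the attenuation models deliberately exclude.

## Known limitations

* The reduced anomalous formula is used outside Δ ≥ 2δ only with a warning;
  its error grows toward Δ = δ.
* The superstatistical Gaussian form becomes indistinguishable from free
  diffusion as σ_D/D* → 0; the spread is then unidentifiable (flat
  likelihood) and its estimate is meaningful only through its negligible
  effect on the curve.
* Strongly attenuating conditions retain few informative Δ points even with
  a matched grid once snapped to the sampling step; their fitted-parameter
  dispersion is correspondingly larger (the δ = 0.02 s, g = 0.02 T/m
  fractional-Brownian setting is the worst case in the benchmark).
* The classifier needs at least two acquisition conditions; with one curve it
  refuses rather than guesses.
* No plotting layer is included; reports and curves are plain text designed
  to drop into any external plotting tool.
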