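# pfgdiff

Pulsed-field-gradient (PFG) diffusion-NMR signal modelling: analytic
attenuation formulas, Monte-Carlo trajectory/signal simulators, model
fitting, and the rescaling *validation rules* that decide which fitting
formula legitimately applies to a set of measured or synthetic curves.

## The problem

A PFG experiment encodes molecular displacement into spin phase with a pair
of gradient pulses (strength *g*, duration *δ*, interspacing *Δ*); the echo
amplitude S(Δ)/S(0) decays with the diffusion of the spin-bearing molecules.
Many parametric models fit such decays beautifully — and return wrong
parameters when their microscopic assumptions (Gaussian displacements,
stationary increments) do not hold for the system at hand. `pfgdiff` is a
toolkit for NMR scientists and method developers who need to (a) know which
attenuation formula they may trust for a given dataset and (b) generate
controlled synthetic signals from well-defined stochastic dynamics to test
analysis pipelines.

## What is inside

**Attenuation models** (`pfgdiff.attenuation`), all on the ln S/S₀ scale with
b = γ²g²δ²(Δ − δ/3):

| model | formula |
|---|---|
| free diffusion (Stejskal–Tanner) | −bD |
| Langevin Brownian motion, drag ζ | −bD + 2γ²g²D{δ/ζ² − [1 − e^{−δζ} + e^{−Δζ}(cosh δζ − 1)]/ζ³} |
| anomalous, MSD = 2D_αt^α (Δ ≳ 2δ) | −γ²g²δ²D_α[Δ^α − 2δ^α/((α+1)(α+2))] |
| superstatistical, Gamma(k, θ) diffusivity | −k ln(1 + bθ) |
| superstatistical, truncated-Gaussian diffusivity | −D⁎b + ½a²D⁎²b² + Δln erfc terms, a = σ_D/D⁎ |

plus quadrature engines for arbitrary velocity/position autocorrelation
kernels and arbitrary P(D) — the oracles the closed forms are tested against.

**Trajectory simulators** (`pfgdiff.trajectories`): exact-discretization
Ornstein–Uhlenbeck Brownian motion, Davies–Harte fractional Brownian motion,
superstatistical ensembles (random per-trajectory diffusivity), and
subdiffusive continuous-time random walks (Mittag-Leffler waiting times).

**Signal engine** (`pfgdiff.engine`): gradient waveform, spin-phase
accumulation, ensemble FID averaging with per-point standard errors, Rician
noise, and a plain-text curve interchange format.

**Fitting** (`pfgdiff.fitting`): variance-weighted nonlinear least squares
for every model above, plus the −d lnS/dΔ diagnostic whose log-log trend
separates sub-, normal and superdiffusion.

**Validation rules** (`pfgdiff.validation`): the g² collapse, the two-pulse
f(δ₁, δ₂) constancy, and the b-value collapse, combined into a flowchart
classifier that recommends the legitimate formula (or none).

## Worked example

Simulate a Brownian ensemble (D = 2×10⁻⁹ m²/s, ζ = 20 s⁻¹, 2×10⁴
trajectories), synthesize its PFG attenuation at δ = 5 ms, g = 0.01 T/m over
48 interspacings in [0.01, 1] s, fit the Brownian formula, and let the
classifier confirm the formula choice from two gradient strengths:

```python
from pfgdiff import PFGParams, NormalParams
from pfgdiff.pipeline import simulate_curve
from pfgdiff.fitting import fit_bm
from pfgdiff.validation import classify

npar = NormalParams(D=2e-9, zeta=20.0)
cond = PFGParams(g=0.01, delta=0.005, Delta=0.01)
curve = simulate_curve("bm", npar, cond, n_traj=20_000, seed=1)
fit = fit_bm(curve.reliable(0.15))
print(f"fitted D    = {fit.params['D']:.4e} m^2/s  (+/- {fit.stderr['D']:.1e})")
print(f"fitted zeta = {fit.params['zeta']:.3f} 1/s    (+/- {fit.stderr['zeta']:.3f})")

curves = [simulate_curve("bm", npar, cond.replace(g=g), 20_000, seed=s)
          for g, s in ((0.01, 1), (0.02, 2))]
report = classify(curves)
print(f"classification      = {report.classification}")
print(f"recommended formula = {report.recommended_formula}")
```

Output:

```
fitted D    = 1.9696e-09 m^2/s  (+/- 2.5e-12)
fitted zeta = 20.132 1/s    (+/- 0.088)
classification      = gaussian_stationary_normal
recommended formula = Eq22
```

The fit recovers the simulation inputs to ~1.5% (D) and ~0.7% (ζ) at this
reduced ensemble size; the classifier sees the g²-rescaled curves collapse
and the log-derivative stay flat, so it endorses the finite-correlation-time
Brownian formula ("Eq22"; "Eq24" denotes the anomalous extension and
"Eq28/29" the superstatistical pair).

The same pipeline is scriptable from the shell:

```bash
pfgdiff signal config.yaml --out curves/      # synthesize curve files
pfgdiff fit curves/bm_g0.01_d0.005.tsv --model bm
pfgdiff classify curves/*.tsv
pfgdiff demo 2 --n-traj 10000                 # regenerate a benchmark table
```

`pfgdiff demo {1,2,3,5}` regenerates the synthetic benchmark tables (Brownian,
fractional-Brownian, superstatistical, and CTRW settings) with columns
δ, g, exact, fitted ± stderr, and percent error.

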