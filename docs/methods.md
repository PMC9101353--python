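# Methods

## Model

A peripheral stress fiber is treated as a single mechanical device: a main
spring K (the bundle's extensional stiffness, K₀ = EA/L₀ at rest) in series
with a parallel combination of a secondary spring k (cross-linker
elasticity), a dashpot γ (motor/filament attachment–detachment
dissipation) and an active element M representing the averaged myosin
ensemble.  M's force–velocity law is a Gaussian, F_M(v) = λ₀ e^(−v²/V²):
maximal (stall) force λ₀ at zero sliding rate, falling off over a velocity
scale V.  With δ₁, δ₂ the elongations of the two branches and δl the
imposed total elongation,

    K δ₁ + λ₀ = λ,   k δ₂ + γ δ̇₂ + F_M(δ̇₂) = λ,   δ₁ + δ₂ = δl.

The observable is the arc radius R = λ/σ (Bischofs balance) of the bundle
curved by the cortical tension σ.

Two experimental asymmetries are built in as strain gates:

- ε < 0 (compression, applied after a prestretch): k = 0 and K = K₀.  The
  device is then a Maxwell material — it relaxes all stress, R(t) → R₀ —
  which models motors gliding filaments back without loading the
  cross-linkers.
- ε > 0 (extension): k engages, and fresh-actin recruitment raises the
  bundle fluorescence as ΔI/I₀ = αε(1−e^(−t/t*)) while softening the main
  spring, K(ε,t) = K₀(1 − αε(1−e^(−t/t*))), steady state K∞ = (1−αε)K₀.

Closed-form limits used as oracles and for inference: the instantaneous
elastic response R₀⁺ = (K₀L₀/σ)ε + R₀, and the steady extension response
ΔR∞ = [kK₀/(k+K₀)](L₀/σ)(1 − α k/(k+K₀) ε)ε (first order in αε; the exact
form with K∞ in the series factor is also provided, the two agree within
0.5% on the R scale for ε ≤ 0.3).

## Local dynamics

On a short segment the same device governs the local strain ε_l ≈ δr/R₀,
and the local Bischofs balance σ_l = λ_l/r_l maps fluorescence to tension.
Writing ξ = (σ_l−σ₀)/σ₀ and χ = τξ (χ carries units of time; χ̇ is
dimensionless, as required inside e^(−χ̇²)), the dynamics close into

    χ̇ = f/Γ − νχ − (1/2Γ)(1 − e^(−χ̇²)),

with ν = 2K₀/γ (passive relaxation rate), τ = σ₀R₀/(K₀V) (motor time
scale), f = K₀ε_l/(2σ₀) (elasticity-to-cortex ratio) and Γ = γV/(2σ₀R₀)
(contracting- vs sliding-motor competition).  Computed from one physical
parameter set the groups satisfy Γντ = 1; when fitted they are free and
the product is reported as a diagnostic.  The reduced equation assumes
k/K₀ ≈ 1 (supported by the measured K₀/k ≈ 0.8); a supplied ratio
deviating by more than 25% is flagged.  Differentiating once gives the
second-order form

    χ̈ (Γ + χ̇ e^(−χ̇²)) = −νf + ν²Γχ + (ν/2)(1 − e^(−χ̇²)),

which accepts independent initial conditions and is the form fitted to
measured traces.  The fixed point χ_ss = f/(νΓ) serves as initializer and
test oracle.

## Numerics

- **Implicit rate solve.**  The Gaussian motor term makes δ̇₂ implicit:
  γx + λ₀e^(−x²/V²) = RHS.  The left side is monotone iff
  γ ≥ √2 e^(−1/2) λ₀/V; all study-level parameter sets are comfortably in
  that regime.  Roots are bracketed and solved by Brent's method with a
  Newton polish (residual < 1e−10·λ₀); in the non-monotone regime all
  roots are scanned and the one nearest the previous rate is taken
  (continuation), with a warning.
- **Integration.**  δ₂ is stepped by classic RK4 between output nodes with
  automatic substep doubling until the trajectory changes by < 1e−6
  relative.  Strain steps are linear ramps of duration |Δδl|/rate
  (~0.07–0.15 s at 100 μm/s), not discontinuities; the ramp end is always
  an integration node.  Prestretch phases are integrated internally before
  t = 0 to set the initial state.
- **Second-order χ form.**  Differentiating the first-order equation
  introduces a spurious solution growing like e^(+νt); the physical
  trajectory is its stable manifold.  The integrator therefore caps the
  state (|χ|, |χ̇|) and the number of derivative evaluations so that
  off-manifold parameter guesses during fitting fail fast instead of
  stalling the solver; a vanishing denominator Γ + χ̇e^(−χ̇²) triggers a
  singularity flag and a fallback to the first-order form.
- **Circle fitting.**  Algebraic (Kåsa) linear least squares initializes a
  geometric (orthogonal-distance) Gauss–Newton refinement.  Exact on
  noiseless circles, rotation/translation invariant, and unbiased within
  0.5% under 0.3 μm point noise at the study geometry (shallow arcs,
  sagitta ≈ 2.6 μm).  Collinear input raises a degenerate-geometry error;
  failed frames in a time series propagate as NaN, never silently dropped.

## The local ODE fit and its identifiability

`fit_local_ode` estimates (ν, τ, f, Γ) by least squares between the
second-order trajectory (mapped through ξ = χ/τ and a configurable
intensity-to-ξ proportionality, default 1) and a normalized relative
intensity trace.  Initial conditions (ξ₀, ξ̇₀) are started from
Savitzky–Golay smoothed values and derivatives (window 11 samples ≈ 22 s,
quadratic) and then co-estimated as nuisance parameters — with fixed
data-derived values, any IC error is amplified by the spurious growing
mode and biases the parameters.  Multi-start: a 3×3×3×3 log-spaced grid
over the default box ν⁻¹ ∈ [50, 2000] s, τ ∈ [50, 1000] s, f ∈ [0.1, 20],
Γ ∈ [0.05, 5], plus the physics-informed initializer; the two best grid
starts and the initializer are refined and the winner polished to full
convergence.

Identifiability is the central caveat.  Along a trajectory the data
constrain ν, the plateau combination f/(Γτ) and, through the quadratic
expansion of the Gaussian term, τ/Γ — but separating f from Γτ requires
the O(χ̇⁴) tail of the nonlinearity.  When the motor rate is order one
(f ≳ 2, strong transients) all four groups are identified and the free
fit recovers noiseless truth to optimizer tolerance.  When |χ̇| ≪ 1 the
objective has a flat ridge: the fit then refits with f constrained to the
initializer's value — the static-analysis estimate f = K₀ε_l/(2σ₀), i.e.
the procedure is anchored at the radius-versus-strain chain — and adopts
that constrained solution unless the data reject it (residual more than 2%
above the free fit).  The constraint adoption is recorded in the result
diagnostics (`f_constrained`, `ridge_flat`), and the mapped estimates
σ₀ = K₀ε_l/(2f) and λ₀ = σ₀R₀ inherit the anchor in that regime.
Uncertainties are covariance-based from the Jacobian at the solution.

## Synthetic data: what it emulates, and what it does not

Generator defaults are the study conditions: chord L₀ = 36.47 μm (SD
4.21), rest radius R₀ = 65.60 μm (SD 5.44), cross-section A = 0.6 μm² (SD
0.2), steps at 100 μm/s up to 40% strain, 60-min prestretch before
compression, images every 2 s for 900 s, recruitment α = 0.64 with
t* = 427 s, passive relaxation γ/2K₀ = 300 s, photobleaching τ_b = 1500 s,
5% multiplicative intensity noise, 0.3 μm edge-point noise (≈1.5 μm on R
after propagation through the shallow-arc geometry).  Population
variability draws per-replicate geometry from truncated Gaussians (±3 SD)
and re-derives each replicate's mechanical constants, so every replicate
is an internally consistent bundle.

Kymographs use a bimodal spatial template (two FA end peaks, mid-fiber
valley); FA regions overshoot as a difference of exponentials (slow scale
178.5 s, fast scale 40 s — the overshoot *shape* is a generator choice,
only its slow scale is a measured quantity), the mid-fiber grows with
scale 387.9 s, and the rest of the bundle carries the residual that pins
the bundle-total trace to the recruitment law.  An optional pre-stimulus
quiet window provides the stimulus-free segment the bleach correction is
designed to be fitted on.

Not emulated: frame-to-frame correlated noise (frames are independent),
drift or registration errors (inputs are assumed registered), cell-scale
background structure, buckling under fast compression, and any biochemical
readout beyond F-actin intensity.  Passing recovery tests on this
generator therefore demonstrates the estimators are consistent and
correctly propagate the modelled noise — not that real microscopy meets
these assumptions.

## Design choices on genuinely open points

- Bleach fitting uses the spatially averaged total intensity on a
  configurable stimulus-free window; the whole kymograph is divided by the
  fitted decay.  Brightening (negative decay constant) is an error, never
  a silent pass-through; a numerically flat fit is the identity.
- Relative normalization is per-position by default; per-region is
  available (the averaging choice is not dictated by the processing chain).
- Segment tiling anchors at the FA-proximal end; a trailing remainder
  shorter than half a segment merges into the last full segment (a
  36.47 μm bundle at 5 μm gives 7 segments), otherwise it stands alone.
- Landmark windows: FA maxima in the outer 25% of arc length per side,
  mid-fiber minimum in the central 50%, ties toward the midpoint.
- Compression strain is referenced to the unstretched length L₀ (so
  prestretch +e then step −e returns exactly to rest); the radius response
  is measured from the prestretched radius R₀p.  Referencing the
  elongation to the prestretched length would inflate the compression
  elastic slope by 1+ε_p, contradicting the observed near-symmetry of the
  extension and compression slopes.
- The reproduce pipeline runs cohorts of N = 12 replicates at strains
  ±0.1…±0.4 and, by default, 6 local segment-trace fits (configurable);
  exponential relaxation fits bound the time constant to 10× the data span
  to exclude the degenerate near-linear solution.

## Known limitations

- The local fit's σ₀ is anchor-dominated in the weak-nonlinearity regime
  (see above); it is a consistency check against the static analysis
  there, not an independent measurement.
- Fitted (τ, Γ) split is weakly identified at 5% noise even when their
  product and ratio are constrained; per-trace scatter is large and the
  covariance-based SDs underestimate ridge uncertainty.
- The quadratic steady-state law and the exact K∞ series factor diverge
  beyond ε ≈ 0.3 (0.8% at ε = 0.4 on the R scale).
- The density analysis reports both the empirical slope fit and the
  model-implied values without reconciling them; with ρ = I/L the
  extension model implies a density slope ≈ −(1−α)ε, shallower than the
  measured −0.64ε, and the pipeline makes no attempt to force agreement.
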