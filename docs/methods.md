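# Methods

## Model and assumptions

The package models a *Volvox* colony as a neutrally buoyant sphere at zero
Reynolds number whose surface — the envelope through the flagellar tips —
performs small-amplitude travelling-wave deformations with an azimuthal
(swirl) component.  The assumptions inherited from the envelope picture:

- **Axisymmetry.**  All fields depend on (r, θ, t) only; the azimuthal
  velocity is axisymmetric swirl.  Non-axisymmetric beating and phase
  defects of the metachronal wave are outside the model.
- **Quasi-static Stokes flow.**  Inertia is neglected entirely (for a
  300 µm colony beating at 203 rad/s the oscillatory boundary layer is
  comparable to the radius, so the quasi-static approximation is itself a
  modelling choice of the underlying theory, not a numerical one).
- **Neutral buoyancy.**  No gravity, sedimentation or bottom-heaviness
  torque; the computed speed corresponds to the sum of upswimming and
  sedimentation speeds when compared with measurements on dense colonies.
- **Small amplitude.**  Means are the leading, O(ε²), terms of an
  expansion in the beat amplitude ε; the package enforces ε ≤ 0.1.
- **Single-harmonic waves.**  The tip orbits are ellipses traversed at the
  beat frequency; a sine wave is the assumed waveform.  Its tangential
  component does not vanish at the poles — a known, accepted inconsistency
  of the sine-wave choice (see *Truncation*, below).

## Orientation and sign conventions (fixed package-wide)

θ = 0 is the anterior (swimming) pole.  The wave and the power stroke run
anterior → posterior (crest toward increasing θ).  Positive mean speed
means swimming toward θ = 0.  The tangential phase default χ = +π/2 is the
quadrature phase for which the radially extended tip (power stroke) sweeps
*with* the wave; with this orientation the model reproduces forward
swimming at the measured wavenumbers and reversed swimming at low k.  The
sign of the rotation rate follows the sign of β about the swimming axis.
All angular integrals use the measure sinθ dθ on [0, π].

## Parameters, units, defaults

| parameter | meaning | default | unit |
|---|---|---|---|
| a₀ | extracellular-matrix radius | per colony | µm |
| L | flagellum length | 20 (package choice) | µm |
| a | envelope radius | a₀ + ⅔L | µm |
| k | metachronal wavenumber | 4.7 (population mean) | — |
| σ | beat angular frequency | 203 (population mean) | rad/s |
| ε | beat amplitude | L/(3a); 0.035 for the mean colony | — |
| δ | tangential/radial orbit ratio | 1.68 (population mean; range 1.45–1.86) | — |
| χ | tangential phase | +π/2 (package choice, see above) | rad |
| β | tan(azimuthal beat-plane offset) | tan 15° ≈ 0.268 (mid-range of 10–20°) | — |
| ψ | tip-orbit tilt to local surface | 0 | rad |
| μ | dynamic viscosity | 10⁻³ | Pa·s |

Velocities are reported in µm/s, rotation rates in rad/s, power in watts
(internally the natural velocity scale is εaσ).  Defaults marked "package
choice" are flagged as such in every run report.

## Numerical formulation

**First order.**  The travelling waves are projected onto Legendre modes in
closed form via the finite cosine representation of Pₙ(cosθ) and elementary
trigonometric integrals; the expansion is singular at integer k, and
wavenumbers within 10⁻⁶ of an integer are rejected (guard band) rather than
evaluated by limit.  The exterior flow is the axisymmetric Stokes
eigenfunction series; force- and torque-free conditions remove the
Stokeslet and rotlet exactly, fixing U(t) and Ω(t).

**Second order.**  The beat-averaged means come from (i) quadratic products
of first-order material motions and (ii) Taylor transfer of the boundary
condition from the displaced envelope to the mean sphere.  Time averages of
harmonic products are evaluated analytically (⟨Re X e^{−iσt} · Re Y
e^{−iσt}⟩ = ½Re X Ȳ).  The θ₀-projections onto the n = 1 modes are
computed by **two independent routes** — explicit bilinear sums with a
closed-form Legendre product-integral table, and direct Gauss–Legendre
quadrature of the assembled integrands — which agree to ~10⁻¹³ and are the
package's realisation of the "general" and "applied" formulations of the
theory.  The azimuthal displacement is defined through the azimuthal angle
perturbation Φ − φ₀ − ∫Ω dt = ε Σ cₙ(t) Vₙ(θ₀)/sinθ₀, the natural analog of
the radial/tangential Lagrangian coordinates; the volume-change mode A₀ is
retained by default (Lighthill's choice) and can be toggled — it changes
the mean speed by well under 5 % and provably cancels out of the rotation
rate.

**Independent oracle.**  A finite-amplitude boundary-collocation solver
fits the force-free series (and the torque-free swirl series with unknown
rigid rotation) to the material velocity of the *displaced* envelope by
least squares at Gauss collocation points, then averages U(t), Ω(t) over a
beat by uniform (spectrally accurate) time quadrature.  Its relative
deviation from the closed forms decreases as ε² (better than the required
linear rate) and is ~0.1 % at ε = 0.005.  This solver shares only the basis
functions with the closed-form routes.

**Power.**  The rate of working of the envelope on the fluid is the
quadratic form P/(πμa) = 16A₀² + (16/3)(A₁+B₁)² + Σₙ≥₂ [4(2n²+3n+4) Aₙ² +
48 AₙBₙ]/((n+1)(2n+1)) + 16Bₙ²/(n(n+1)) + 16(n+2)Cₙ²/(n(n+1)(2n+1)),
derived symbolically from the surface tractions of the mode series and
verified in the tests against a volume-dissipation quadrature oracle.  The
swirl contribution is non-negative mode by mode.  Efficiency is Lighthill's
drag-power ratio; the package reports it as a dimensionless number (it is
of order 10⁻⁴ for the mean colony — the biological point being that this
swimming mode is energetically far from optimal).

**Truncation.**  Default N = 25 modes.  Because the tangential sine wave
does not vanish at the poles, its Vₙ-series converges only algebraically,
so the second-order means converge algebraically in N as well (relative
change ~10⁻³–10⁻⁴ per +5 modes at the mean parameters, not the 10⁻⁸ a
spectrally smooth problem would give).  Every summary records the relative
change of both means between N and N+5 as a convergence diagnostic; a
caller-supplied tolerance turns the diagnostic into a hard error with the
convergence trace attached.  A fixed truncation can be forced and is then
flagged in the run report.

**Tilted orbits.**  ψ ≠ 0 rotates the tip ellipse in the (radial,
tangential) plane, mixing the two waveforms (exactly the identity at
ψ = 0); the azimuthal displacement is β times the tilted tangential
component.  Because δ > 1 puts the orbit's major axis along the surface,
the means are *not* insensitive to ψ under this construction (U roughly
doubles at ψ = 30°); the tests therefore assert the geometric contract
(rotated-ellipse point sets, ψ-evenness) rather than any quantitative
insensitivity claim.

## Bead-near-wall companion model

A point force of strength 6πμa_b v(t) (the quasi-static drag of a bead of
radius a_b translating at its orbital velocity) circles in a vertical plane
above a no-slip wall enforced exactly by the classical image system (image
Stokeslet + Stokes doublet + source doublet).  Tracers are advected with an
adaptive 8th-order Runge–Kutta integrator, re-synchronised to the orbit
phase each beat; per-beat net drift is the reported statistic, converged to
well under 1 % under tolerance refinement.  Defaults (bead 5 µm, orbit
radius 10 µm, centre height 20 µm, σ = 203 rad/s) are package choices tuned
only for qualitative similarity to observed single-flagellum particle
paths.  Finite bead size (Faxén corrections), flagellar slenderness and
inter-flagella coupling are deliberately omitted; the drift-reversal and
phase-invariance properties hold in the far field of the orbit, where the
second-order drift dominates the per-beat loop excursion.

## Synthetic populations

`synthesize_population` draws colonies with a₀ ~ U(100, 400) µm, k ~
N(4.7, 0.5²) clipped to [3, 6.5] (nudged off integers), σ ~ N(203, 20²)
rad/s, δ ~ N(1.68, 0.1²) clipped to the measured range — centres are the
measured population means; the spreads and the radius range are package
choices standing in for unpublished histograms.  ε is resolved per colony
as L/(3a) with fixed L, which is what produces the observed decrease of
both means with colony radius (U ~ L²/a, Ω ~ L²/a²); a constant-ε override
reverses that trend to U ~ a.  What passing population tests show is the
model's *parameter dependence*, not agreement with any measured colony:
no experimental data ship with the package (an import hook for a
user-supplied measurement CSV is the supported comparison path).

## Known limitations

- The envelope approximation itself: widely spaced flagella, single-valued
  envelope, no back-leakage — the theory's own discussion expects it to
  overestimate oscillation amplitudes and underestimate means.
- Algebraic (not spectral) truncation convergence, inherited from the
  pole-nonvanishing tangential wave.
- The quasi-static Stokes assumption at finite beat frequency.
- Tilted-orbit results depend on the geometric construction chosen here.
- The bead model is qualitative by design.
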