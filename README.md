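# volvox-squirmer

A spherical **squirmer-with-swirl** model of *Volvox* swimming.

Colonies of the green alga *Volvox carteri* are spheres (radius ~100–400 µm)
covered by thousands of biflagellate somatic cells.  The flagella beat in a
coordinated **symplectic metachronal wave** running from the anterior
(swimming) pole to the posterior, and their beat planes are offset from the
meridian by a small azimuthal angle, which makes the colony spin about its
swimming axis.  This package implements the extension of the classical
Lighthill/Blake spherical-envelope ("squirmer") model that adds that
azimuthal **swirl**, and predicts — per colony — the mean swimming speed,
body rotation rate, mechanical power and efficiency from the measurable
kinematics of the metachronal wave.

## The model

The flagellar tips are represented by a continuous deforming envelope about
a sphere of radius *a* = *a*₀ + ⅔*L* (*a*₀ the extracellular-matrix radius,
*L* the flagellum length).  Material points labelled by their mean polar
angle θ₀ execute small elliptical orbits

    radial:      ε a sin(kθ₀ − σt)
    tangential:  δ ε a sin(kθ₀ − σt + χ)
    azimuthal:   β × tangential      (in the co-rotating frame)

with wavenumber *k* (non-integer), beat frequency σ, amplitude ε ≪ 1, orbit
aspect ratio δ, quadrature phase χ and azimuthal beat-plane offset β =
tan(offset angle).  The waves are projected onto Legendre modes (*P*ₙ for
radial, *V*ₙ = (2/n(n+1)) sinθ *P*ₙ′(cosθ) for tangential/azimuthal), and
the exterior Stokes flow is the axisymmetric eigenfunction series with
surface modes *A*ₙ(t), *B*ₙ(t) and swirl modes *C*ₙ(t).  Force-free and
torque-free swimming fix the instantaneous speed and rotation

    U(t) = (2B₁ − A₁)/3,        Ω(t) = −C₁/a,

both of which average to zero at first order in ε.  The observable means
arise at **second order**, from quadratic couplings between the envelope
displacement and the first-order flow gradients; the package evaluates them
by two independent routes (closed-form Legendre product-integral sums, and
direct Gauss–Legendre projection) and validates both against a
finite-amplitude boundary-collocation solver averaged over a beat.  Power
follows from the surface tractions of the mode series, and efficiency is
Lighthill's E = 6πμa Ū² / P̄.

A companion model drives a small
bead around a circular orbit perpendicular to a no-slip wall — the crudest
caricature of a single beating flagellum near the colony surface — using
the classical Stokeslet image system, and advects passive tracers to show
the loop-plus-drift particle paths such a flagellum produces.

## Worked example

```python
from volvox_squirmer import ColonyGeometry, WaveParameters, swim_summary

g = ColonyGeometry(a0=200.0)          # matrix radius 200 um, flagella 20 um
w = WaveParameters.volvox_mean()      # k=4.7, sigma=203 rad/s, delta=1.68, eps=0.035
s = swim_summary(w, g)
print(f"envelope radius a = {g.a:.1f} um")
print(f"mean swimming speed  Ubar2 = {s.Ubar2:.1f} um/s")
print(f"mean rotation rate   Omegabar2 = {s.Omegabar2:.3f} rad/s")
print(f"mean power           Pbar = {s.Pbar*1e12:.1f} pW")
print(f"mechanical efficiency E = {s.efficiency*100:.4f} %")
```

prints

```
envelope radius a = 213.3 um
mean swimming speed  Ubar2 = 70.7 um/s
mean rotation rate   Omegabar2 = 0.101 rad/s
mean power           Pbar = 94.2 pW
mechanical efficiency E = 0.0213 %
```

i.e. a population-mean colony is predicted to swim forward at ~70 µm/s
while spinning at ~0.1 rad/s and dissipating ~10⁻¹⁰ W — the right orders of
magnitude for *Volvox*, though (as the underlying theory itself concludes)
both means underestimate measured values unless the effective beat
amplitude is taken larger than the nominal tip-orbit scale.  Both means
scale exactly as ε², the rotation is odd in the azimuthal offset β, and for
wavenumbers below the measured range (k ≲ 2) the predicted mean speed turns
negative.

## Command line

```bash
volvox-squirmer synth -n 60 --seed 1 -o colonies.csv     # synthetic population
volvox-squirmer predict colonies.csv -o predictions.csv  # per-colony means
volvox-squirmer kymograph -o kymo.csv                    # u_r, u_theta space-time maps
volvox-squirmer field -o field.csv                       # (r, theta, t) velocity grid
volvox-squirmer bead -o tracers.csv --n-beats 100        # bead-near-wall tracer paths
```

Every run writes a JSON report alongside its output recording the
parameters, which defaults were substituted, and truncation/convergence
diagnostics.

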