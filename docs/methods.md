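# Methods

`ppgmc` simulates photon migration in a laboratory reflectance-PPG scene
and reports how the source-detector geometry shapes the detected DC
level, the differential pathlength factor (DPF), the maximum penetration
depth and the photon density ("banana") maps.  This note records the
model, its assumptions, the numerical choices, and what the package's
tests do and do not demonstrate.

## Scene and materials

The phantom is a homogeneous cylinder (radius 25 mm, height 50 mm) of
epoxy resin loaded with 250 nm TiO2 spheres, optically characterised at
520, 637 and 940 nm:

| λ [nm] | μa [1/mm] | μs′ [1/mm] | n | g |
|---|---|---|---|---|
| 520 | 0.093 | 1.719 | 1.561 | 0.550 |
| 637 | 0.019 | 1.376 | 1.552 | 0.550 |
| 940 | 0.016 | 0.793 | 1.543 | 0.550 |

Glass slides (1 mm; μa = 0.004/0.005/0.029 per wavelength, n = 1.520)
cover the surface on either side of a vertical opaque barrier (0.5 mm
thick) that stands on the phantom, centred between the source and
detector spots, to suppress direct cross-talk.  A thin air gap separates
slides and phantom; its thickness is not measurable in the physical
setup, so the default is 0.02 mm (configurable).  The barrier height
above the surface is likewise unspecified; default 5 mm.  The phantom is
the only scattering medium; glass and air are traversed with Lambert-Beer
attenuation only, and the barrier zeroes the packet weight on entry.

Coordinates: origin at the surface midpoint between the spots, +z into
the phantom, +x from source toward detector, lengths in mm.  Below the
surface the phantom is an analytic homogeneous half-cylinder (a layered
representation keeps the transport cheap); above it the gap, slides and
barrier are voxelized (default edge 0.1 mm, finer than the 0.5 mm
barrier; 0.2154 mm — a 0.01 mm³ cube — is available as an override for
literal replication of the original voxel volume, and the slides touch
the barrier with no extra slot).  The compiled kernel evaluates the same
superstructure rules in closed form; a test pins voxel lookup and
closed-form rule against each other away from voxel-boundary skin.
The sub-voxel air gap is therefore exact in the transport physics even
though the voxel grid (a provenance/inspection artefact) cannot resolve
it.  Slide edges at the cylinder rim are crossed without a Fresnel event;
photons that far out (>24 mm lateral) have no realistic path back to the
sub-millimetre detector spot.

## Transport kernel

Standard weighted photon-packet Monte Carlo:

* free paths sampled from the interaction coefficient μt = μa + μs with
  μs = μs′/(1 − g);
* at each interaction a weight fraction μa/μt is deposited and the
  packet is deflected by the active phase function, with uniform azimuth;
* unpolarized Fresnel reflection/Snell refraction at every index step
  (phantom/air, air/glass), decided statistically; total internal
  reflection beyond the critical angle (≈40° inside the phantom);
* non-scattering media attenuate deterministically (Lambert-Beer along
  the chord), so a non-scattering medium has DPF = 1 by construction;
* Russian roulette below weight 1e-4 with survival factor 10;
* packets crossing the cylinder wall or bottom terminate (`side_exit`);
  in the discussion of the original experiment such photons never return
  to the detector, and the simulation confirms the phantom rim is
  irrelevant to the detected signal;
* optical path length `l` and maximum depth accumulate only inside the
  phantom: the DPF in `l = d · DPF` is a tissue-path quantity.

Leftover optical depth is carried across the only interface reachable
mid-flight in the scattering medium (internal reflection at the phantom
surface).  On re-entry from the superstructure a fresh optical depth is
sampled; by the memorylessness of the exponential distribution this is
equivalent in distribution to carrying the remainder.

Two variance/compute devices, both weight-compensated and therefore
unbiased in expectation:

* the low-weight roulette above;
* a single-shot *far-field* roulette: the first time a packet scatters
  deeper than 15 mm or laterally beyond 18 mm it survives with
  probability 0.2 (weight ×5).  Packets that far from the
  source-detector region almost never reach the 0.55 mm detector spot,
  but their random walks dominate wall-clock time at the weakly
  absorbing red/infrared wavelengths.  An energy audit
  (launched = detected + escaped + side-exit + deposited + roulette net)
  holds to bookkeeping identity and is asserted to 0.5 % over 10⁶
  packets.

Randomness comes from an inline xorshift128+ stream (splitmix64-seeded),
one stream per batch; identical seed and configuration reproduce results
bitwise, independent of library RNG internals.

## Phase functions

*Henyey-Greenstein* (default): closed-form inverse CDF with g = 0.550.

*Mie*: the single-sphere phase function for 250 nm TiO2 in the epoxy
host, from the Bohren-Huffman amplitude series (logarithmic-derivative
downward recurrence).  The TiO2 index follows the DeVore dispersion for
rutile (ordinary ray), n² = 5.913 + 0.2441/(λ² − 0.0803) with λ in µm;
anatase constants are not bundled (the rutile pigment grade is the
common choice, and unverified constants are worse than an explicit
error).  The table uses 2048 Gauss-Legendre nodes in cos θ plus the ±1
endpoints; sampling is a linear-interpolated inverse CDF, and the
quadrature mean cosine matches 10⁶ sampled draws to better than 1e-3.
With the Mie backend the transport conversion μs = μs′/(1 − ⟨cos θ⟩)
uses the Mie mean cosine (0.65/0.56/0.39 at 520/637/940 nm), keeping the
measured μs′ fixed rather than reusing the HG anisotropy.  That the Mie
mean cosine at 637 nm lands at 0.56, next to the characterised g = 0.55,
is a consistency point, not an input.

## Source and detector

The source is a collimated beam imaged to a 0.610 mm spot (200 µm facet,
magnification 3.05), launched across the surface spot with the beam axis
tilted by θs in the x-z plane; oblique incidence stretches the footprint
to an ellipse (major axis /cos θs).  Specular loss at entry uses the
standard statistical interface event.  Divergence of the laboratory
collimator is taken as zero.

The detector is modelled at the phantom surface: a 0.55 mm spot
(projected to an ellipse at θd) plus an acceptance cone about the tilted
detector axis.  Positive angles tilt source and detector toward each
other across the barrier; negative angles away.  Angle changes never
move the spot centres (±d/2), matching the mechanical design of the
measurement frame.

The acceptance half-angle α is the one optical parameter that cannot be
derived from the published geometry (the lens working distance is not
stated).  It matters: the exiting flux at the detector spot is tilted
toward +x, so a narrow cone starves the negative-angle branch — at
α = 15° essentially no packet is accepted at negative angles at any
practical budget, which would make the negative-angle phenomena the
study explores unrepresentable.  The default is α = 30°, the collection
half-angle of the 10.9 mm lens at a ~9-10 mm working distance;
`DetectorConfig.acceptance_half_angle` exposes it, and sweeping it is a
one-line config change.  DC *ratios* (the normalised levels and
distance-attenuation factors) are only weakly sensitive to α on the
positive branch.

## Metrics and sweeps

A configuration is (λ, d, θs, θd).  The total photon budget scales
linearly with distance, N(d) = N0 · d / 2 mm, split across 5 independent
seed replicates whose detected weights are averaged (the seed spread
provides the standard errors used by the statistical tests).  Default
N0 = 2×10⁶ packets per configuration.

* DC level  S̄ = mean over seeds of (Σ detected weight)/N;
* DPF = ⟨l⟩_w / d with ⟨l⟩_w the weight-averaged path length over
  detected packets (pooled across seeds); weight-averaging matches the
  weight-based DC definition;
* mean maximum penetration depth, weight-averaged the same way;
* normalised level S̄′ divides each row by its branch reference at the
  same (λ, d): (15°, 25°) for the positive branch (0° rows included),
  (−15°, −25°) for the negative branch;
* the distance-attenuation factor per wavelength is the mean of
  S̄(5 mm)/S̄(2 mm) over positive-angle configurations present at both
  distances (the "average factor" interpretation: total-range ratio, not
  per-mm);
* density maps accumulate weight × path length of detected packets on an
  (x, z) grid over x ∈ [−5, 5] mm, normalised to a designated reference
  configuration's maximum.

A configuration with zero detected packets is flagged
(`flagged_no_detection`, DPF = NaN), never silently zero.

## Problem sizes

Study-scale runs (`scripts/acceptance.py`, the CLI defaults) use
N0 = 2×10⁶ per configuration on the reduced angle diagonal
{(15, 25), (35, 35), (55, 55)} at d ∈ {2, 5} mm.  The test suite scales
down: the shared trend sweep uses N0 = 4×10⁵ over an 11-pair grid, and a
dedicated 940 nm negative-diagonal run uses N0 = 3×10⁶ at d = 5 mm
because negative-angle DC levels are 10-100× below the positive branch.
Statistical assertions carry 3-standard-error tolerances from the seed
spread.

## What the simulation does and does not show

The scene reproduces the *laboratory phantom*, not skin: one homogeneous
scattering layer, no chromophore layering, no pulsatile component.
Agreement of trends (attenuation factors, angle monotonicity, DPF
ordering, depth behaviour) therefore speaks to the transport physics and
geometry handling, not to physiological PPG.  Absolute DC levels depend
on the unpublished acceptance cone and air-gap thickness; only
normalised and ratio quantities are compared.  Known limitations: the
detector is a spot-plus-cone, not a ray-traced imaging train; LED-like
(Lambertian) sources are out of scope; polarization and time-of-flight
are not modelled; the Mie backend treats the scatterers as monodisperse
spheres.
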