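# Methods

This note documents the models, conventions and numerical choices behind
`blurfield`, in the package's own words.  Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Schematic eye and ray tracing

The eye is the unaccommodated wide-angle Navarro model (Escudero-Sanz &
Navarro, JOSA A 16:1881, 1999): four conic refracting surfaces

| surface | R (mm) | Q | thickness (mm) | medium after |
| --- | --- | --- | --- | --- |
| anterior cornea | 7.72 | −0.26 | 0.55 | cornea |
| posterior cornea | 6.50 | 0 | 3.05 | aqueous |
| anterior lens | 10.2 | −3.1316 | 4.0 | lens |
| posterior lens | −6.0 | −1.0 | 16.3203 | vitreous |

plus a spherical retina (R = −12 mm) at 23.9203 mm.  Refractive indices are
linearly interpolated at the working wavelength (550 nm by default) from
the published 458/543/589.3/632.8 nm dispersion table; constants live in
`src/blurfield/data/navarro_eye.json`.

Rays are traced exactly: conic surfaces are quadrics, so the intersection
is the closed-form quadratic root on the principal branch (the numerically
stable `q = −(B + sign(B)√disc)/2` form matters because the posterior lens
has 1 + Q = 0, which sends the quadratic coefficient to zero for paraxial
rays); refraction is the vector Snell law; total internal reflection or a
missed aperture flags the ray as vignetted rather than raising.  A paraxial
ABCD-matrix solution of the same surface list is kept as an independent
oracle; the exact tracer reproduces its back focal distance to better than
0.1 %.

**Stop geometry.**  The limiting aperture models the simulator's artificial
pupil, which is optically conjugated to the eye pupil.  It is therefore a
disk in the iris plane (the anterior lens vertex, z = 3.6 mm), *fixed in
world coordinates*.  Bundles for any field angle are ray-aimed through the
cornea onto this disk with a shared-Jacobian Newton iteration (the
cornea-to-stop map is nearly affine over a few millimetres; three
iterations reach sub-nanometre residuals).  Two observations support this
conjugation over the alternative of an aperture in front of the cornea:
the aligned model stays diffraction-limited at large eccentricities at
small pupils (an anterior aperture leaves ~1.5 D of uncompensated corneal
oblique astigmatism at 9.25°), and the model's own Airy radius at a 1.5 mm
stop comes out at 6.5 μm, matching the apparatus specification this
simulator emulates.

**Misalignment.**  Fixational eye movements are modelled by their static
displacement envelope: the whole eye is rotated about the corneal vertex
(tip about x, tilt about y, each uniform within ±0.35°) and then
decentered transversally (uniform on a disk of radius 0.75 mm — the disk,
rather than a square, honors the radial bound), while the stop and the
incoming beam stay fixed.  Ray launch points sit 5 mm upstream of the
cornea so no origin can start inside a perturbed surface.

**Wavefront convention.**  The wavefront at a field point is the optical
path from a plane wavefront in object space to each ray's crossing of the
*image plane through the chief-ray retinal point, perpendicular to the
chief ray*, referenced to the chief ray, with piston and tilt removed by
least squares over the valid pupil.  For a focused bundle this equals the
classical exit-pupil reference-sphere OPD to second order (within the spot,
the retinal sphere and the reference sphere deviate only quadratically).
Measuring instead to the curved retina *surface* would inject a term linear
in the transverse aberration wherever the chief ray meets the retina
obliquely — an error of ~0.3 μm at 9.25° that misrepresents a
geometrically diffraction-limited bundle as heavily aberrated.  The plane
convention also makes an index-matched, flat-image synthetic system exactly
aberration-free, which the test suite asserts.

There is no per-field refocus: the retina is the image surface everywhere.
On-axis defocus of the aligned model is nulled once at build time by an
ideal quadratic "Badal" path term solved at a 1 mm reference pupil
(residual +0.03 D); field curvature and oblique astigmatism are left
untouched, as in the apparatus, where the observer focuses a foveal target
once.

**Strehl ratio.**  The pupil function is sampled on a square grid with
pixel centers at half-integers (32 samples across the diameter for the
Monte-Carlo sweeps, 64 for single analyses), embedded in a 4× zero-padded
array; Strehl is the discrete peak of |FFT|² divided by the peak of the
aberration-free pattern on the identical grid.  Piston/tilt are removed
before the FFT so the peak is not penalized by sub-pixel peak shifts.  The
worst case at the decision boundary was checked to be stable from 32 to 96
pupil samples.  For RMS < λ/10 the computed Strehl agrees with the extended
Marechal expression exp(−(2πσ/λ)²) to 5 %.

## Monte-Carlo isoplanatism study

Field grids are the printed eccentricities {2.5°, 4.25°, 9.25°} truncated
at the chosen extent, × 8 meridians, plus the on-axis point.  An ensemble
is n uniform draws (5000 by default, 500 in the scaled-down acceptance
procedure) plus the zero perturbation, optionally extended by 16
bound-corner probes (tip/tilt sign corners × decenter compass points) —
under box/disk-bounded uniform perturbations the worst case is approached
at the bounds, so the corners are a cheap lower-bound oracle for the
Monte-Carlo minimum.  `isoplanatic_pupil` answers on the supplied pupil
grid only; during the search a pupil's scan stops early once its running
minimum violates the criterion (the reported per-pupil worst is then
flagged non-exhaustive).  The pass/fail criterion is Strehl ≥ 0.8; RMS is
reported alongside.

**Known limitation.**  With this (physically literal) fixed-stop geometry,
a 0.75 mm decentration dominates the worst case: sampling the eye's
spherical aberration off-center induces ~0.3 D of defocus plus comparable
astigmatism even on axis at a 1.35 mm pupil, and the worst corner at 9.25°
drives the Strehl to ~0.47.  Consequently the largest passing pupil is
1.0 mm for the parafoveal extent and no tested pupil passes the perifoveal
extent.  Commercial ray tracers whose ray aiming follows the displaced
stop largely neutralize decentration and would admit pupils one grid step
larger; we keep the literal fixed-stop geometry and report what it
computes.  The aligned-eye results (Strehl 0.96 at 1.35 mm over the full
perifoveal grid) are unaffected by this choice.

## Blur synthesis

Defocus PSFs use the Fourier-optics pupil model: A·exp(i2πW/λ) with
W = c20·Z2⁰, Z2⁰ = √3(2ρ²−1), c20 = M·r²/(4√3) μm (M in diopters, r in
mm), a 2 mm simulation pupil and λ = 550 nm.  The pupil is embedded so the
FFT samples the PSF at an odd integer multiple of the display pixel scale
(≥4× pupil padding; the multiple adapts to the pixel scale); the fine PSF
is binned to display pixels with bins centered on the peak pixel, which
preserves the exact rotational symmetry of pure defocus, then cropped to
the support holding all but 1e−8 of the energy and renormalized to unit
sum.  More than 1 % of energy on the grid border raises an error instead
of silently aliasing.  PSFs are precomputed and cached on the 0–5 D grid in
0.05 D steps; requested levels round to the nearest step.

Convolution runs in linear luminance with mirror-reflected edge padding
(display gamma 2.2 is applied only at image export); unit-sum kernels
preserve mean luminance to well under 0.1 %.

**Spatially-varying blur** splits the 7.5° radius into 20 rings of 0.375°.
Every pixel belongs to exactly one ring by its center eccentricity
(`ceil(E/width)`, clipped); display corners beyond 7.5° continue the
outermost ring so the composite has no unblurred frame.  Ring defocus is
the profile evaluated at the ring's *outer-edge* eccentricity (the
convention that pins ring 20 to the defocus peak a; ring-center sampling is
available), quantized to the 0.05 D grid; one convolution is performed per
distinct level.  **Zonal blur** applies a single level inside one 1.5°-wide
annulus on a uniform background; the five standard zones (outer edges 1.5,
3, 4.5, 6, 7.5°) partition the 7.5° disk exactly.

**Sigmoid profile.**  The printed form of the radial profile is
typographically ambiguous; the adopted reading

y(E; K) = E / (1 + K (1 − E)),  E ∈ [0, 1],  K > −1

is normalized (y(0) = 0, y(1) = 1), reduces to the linear profile at
K = 0, and reproduces the published K ↔ blur-volume-fraction table: with
A(K) = ∫₀¹ y dE = −1/K + (1+K)/K² ln(1+K), the fractions A(K)/A(0) for
K ∈ {−0.8, −0.53, 1.1, 4.0, 16.7} are {1.494, 1.247, 0.757, 0.506, 0.245}
against the published {1.5, 1.25, 0.75, 0.5, 0.25} — within 0.013
everywhere.  This agreement is asserted by the test suite (closed form
cross-checked against adaptive quadrature to 1e−8).  K ≤ −1 is rejected:
the denominator vanishes inside the domain, and profiles quoted outside
this domain elsewhere cannot be reconciled with the adopted formula.

## M-scaled binary noise

The stimulus emulates a high-resolution (2160², 15°) binary noise whose
element size grows with eccentricity as the inverse of the cortical
magnification M(E) = 1/(1 + E/E₂), E₂ = 2.5° (the standard inverse-linear
V1 approximation; only the relative scaling matters).  Seeded uniform white
noise is low-pass filtered in the Fourier domain with a Gaussian
(half-amplitude cutoff) whose cutoff is fc(E) = fc₀·M(E), one filtered
field per 0.375° band, blended with triangular weights between band
centers (no visible seams), then thresholded at the global median —
exactly two levels at 50/50.

The central cutoff fc₀ = 6 cpd (foveal element half-period ≈ 5 arcmin) was
calibrated once against the stimulus's published spectral falloff and sits
on a plateau where the measured slope is insensitive to the choice.  On
measurement conventions: the one-directional *amplitude* slope of any
sharp-edged binary image is bounded by −1 (the edge/Porod law: the 2-D
power tail ~f⁻³ integrates over the orthogonal frequency to a 1-D power
tail ~f⁻²), so a falloff quoted near −2 for this stimulus class is the
*power*-spectral slope, which saturates at exactly −2.  `amplitude_slope`
therefore measures the row-averaged one-directional spectrum in either
convention and defaults to power; the default stimulus regresses to
−1.97 ± 0.002 over 1 cpd–half-Nyquist across seeds.  Element size is
verified against M(E) with a run-length oracle (mean horizontal run per
black/white transition within an annular band — robust to the percolating
connected clusters of a 50/50 binary field), agreeing with the configured
magnification ratio within 15 %.

What the generator does not emulate: photometric calibration (luminance,
gamma of a physical projector), temporal presentation, chromatic content,
and any deviation of real displays from ideal square pixels.  Tests passing
on this stimulus therefore validate the geometry and statistics of the
pattern, not a display chain.

## Psychophysics

One staircase per condition, one-down/one-up with a fixed 0.15 D step,
clamped to the synthesizable 0–5 D range; conditions are interleaved by
drawing uniformly (seeded) among those with remaining trials.  The rule's
fixed point is the 50 % level of the response function; thresholds are read
from the fitted function instead.  For global-profile conditions the
staircase variable is the defocus peak a, which rescales the whole ring
table through y(E; K).  Start levels default to 1.0 D (zonal) and 2.0 D
(global peak) and 60 trials/condition — session-scale choices exposed in
the configuration.

Fitting follows the Gumbel (log-Weibull) convention with base-10 exponent:
F(x) = γ + (1−γ−λ)(1 − exp(−10^{β(x−α)})).  γ and λ are fixed at 0 for
the yes/no bothersome judgment (a lapse rate ≤ 0.05 can be freed); the
Bernoulli likelihood is aggregated per level and maximized by Nelder-Mead
with an L-BFGS-B polish.  The threshold is the 1 − e⁻¹ (≈63 %) point of
the unscaled core, which is α identically — an analytic identity the tests
assert.  Degenerate data (single level, all-identical responses, complete
separation) raise a diagnostic error rather than returning a divergent
slope.  Standard errors come from a seeded parametric bootstrap (1000
datasets by default) simulated at the observed levels and per-level trial
counts; simulated observers respond Bernoulli from a configured Gumbel, so
parameter recovery (bias < 0.05 D, ~95 % coverage of ±1.96·SE) is testable
end to end.

**Zonal vs global comparison.**  For each global condition the fitted peak
a* defines the per-ring defocus a*·y(Eᵢ; K).  Each 1.5° zone aggregates
the rings geometrically inside it — exactly 4 of the 0.375° rings (an
overlapping 5-ring mode that adds the shared-edge ring is provided, since
zone/ring bookkeeping conventions differ); the zonal-equivalent global
threshold is their mean, and the reported difference is global-equivalent
minus zonal, on the zone-center grid {0.75, 2.25, 3.75, 5.25, 6.75}°.

## Orchestration and reproducibility

All angles are degrees, defocus diopters, Zernike coefficients μm, lengths
mm.  A single global seed expands via `SeedSequence.spawn` into independent
per-stage streams, so changing one stage's draw count cannot shift
another's.  Identical configuration + seed reproduce byte-identical
CSV/JSON artifacts (asserted in the tests).  The configuration file
round-trips losslessly and rejects unknown keys by name.

**Problem sizes.**  The package's standard study sizes are 5000
misalignment draws and 1000 bootstrap replicates; the bundled acceptance
procedure and test suite run the same computations at 500 draws + 16
corner probes and 100–1000 bootstrap replicates, with single-condition
sessions of 150–200 trials — sizes chosen so the full verification runs in
minutes on one CPU while leaving the Monte-Carlo decisions converged (the
corner probes bound the ensemble minimum).
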