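# Methods

`tissuelight` implements a three-stage workflow for differentiating biological
tissue from steady-state optical measurements: (1) estimate the transport
parameters (μa, μs, g) of a slab from total diffuse reflectance Rd, total
diffuse transmittance Td and collimated transmittance Tc; (2) validate the
estimate by re-simulating Rd with photon-packet Monte-Carlo transport; and
(3) render the surface fluence-rate distribution Φ(x, y) implied by those
parameters by solving the steady-state diffusion equation with finite
elements. All coefficients are in cm⁻¹ and lengths in cm; measurement files
carry thickness in mm and are converted at the I/O boundary.

## Two-flux inversion (km_optics)

The slab is modelled by two counter-propagating diffuse fluxes with a
scattering flux coefficient S and an absorption flux coefficient A
(Kubelka-Munk two-flux model). In the Kottler closed form,

    Rd = sinh(Sbd) / (a sinh(Sbd) + b cosh(Sbd)),
    Td =         b / (a sinh(Sbd) + b cosh(Sbd)),

with a = 1 + A/S and b = √(a² − 1). This form satisfies Td(0) = 1, Rd(0) = 0,
Rd(∞) = a − b, and Rd + Td ≤ 1 with equality only at A = 0 — and it is the
form that the algebraic inversion

    a = (1 + Rd² − Td²) / 2Rd,  b = √(a² − 1),
    S = ln[(1 − Rd(a − b)) / Td] / (b d),  A = (a − 1) S

inverts exactly. The flux coefficients map to transport quantities through
A = 2μa and S = (3/4)μs′ − (1/4)μa with μs′ = μs(1 − g); Beer-Lambert
attenuation of the collimated beam, Tc = exp(−μt d), supplies
μt = μa + μs, after which μs = μt − μa and g = 1 − μs′/μs.

Numerical choices. The naive expression for a loses all significant digits
near the pure-scattering edge Rd + Td → 1, so a − 1 is computed as
(1 − Rd − Td)(1 − Rd + Td)/(2Rd) and the logarithm as
log1p[((1 − Rd − Td) + Rd(b − (a − 1)))/Td]; this achieves 10⁻⁹ relative
round-trip accuracy over S ∈ [0.5, 50], A ∈ [0, 60], d ∈ [0.05, 0.3] cm. The
b = 0 (conservative) case uses the analytic limits Rd = Sd/(1 + Sd) and
S = Rd/((1 − Rd)d); arguments Sbd > 350 use the semi-infinite asymptotics.
Specular reflection is assumed already excluded from Rd (matched-index
convention), so no Fresnel correction is applied.

Degenerate inputs are rejected with stage-specific errors: Rd + Td ≥ 1
(a < 1, not invertible), Td = 0 (optically semi-infinite, S unrecoverable),
μt ≤ μa (no scattering left for Beer-Lambert to attribute) and μs′ > μs
(g would be negative).

## Photon-packet Monte-Carlo (mc_transport)

Standard multilayer hop-drop-spin transport: a pencil beam enters normally
at the origin; free paths are sampled as −ln(u)/μt; each interaction deposits
the fraction μa/μt of the packet weight and deflects the packet by a
Henyey-Greenstein angle with mean cosine g (azimuthally uniform). Packets
below weight 10⁻⁴ undergo Russian roulette with survival probability 1/10
(standard variance-reduction constants). Layer interfaces apply Snell
refraction and the polarisation-averaged Fresnel reflectance; with matched
indices (the convention used throughout the validation runs) every escape
attempt succeeds and the specular component is zero. Escaping weight is
tallied as total diffuse reflectance/transmittance, with the top-surface
escapes binned into 1 mm annuli out to 10 mm (plus an overflow bin),
mirroring a detector scanned across the surface in 1 mm steps. The inner
loop is compiled with numba; one seeded generator per run makes tallies
bit-identical for a fixed (stack, n_photons, seed).

Default photon count is 10⁶, which puts the Monte-Carlo standard error of a
reflectance fraction near 5 × 10⁻⁴ and completes in a few seconds per slab
on one core. Energy conservation (Rd + Td + absorbed = 1) holds to within
the roulette-induced statistical fluctuation, < 3 N^(−1/2).

## Diffusion solver (diffusion_fluence)

The steady-state diffusion equation

    −∇·(D∇Φ) + μa Φ = S,  D = 1 / (3(μa + μs′)),

is solved on an axisymmetric (r, z) rectangle with linear (P1) triangular
elements on a structured mesh graded toward the source (grading factor 5,
geometric growth 1.3). The pencil beam is reduced to an isotropic point
source carrying the beam power at depth z₀ = 1/(μa + μs′) on the axis — the
standard first-scatter reduction; if the slab is thinner than z₀ the source
is clamped to mid-slab with a warning. The illuminated and exit faces carry
the matched-index partial-current (Robin) condition Φ + 2D ∂Φ/∂n = 0; the
lateral wall and the axis are natural zero-flux boundaries. The weak form is
assembled with the axisymmetric measure r dr dz, lumped mass (which keeps
the system an M-matrix on the non-obtuse structured mesh and hence the
discrete solution positive), and solved with a sparse direct factorisation;
residuals above 10⁻¹⁰ relative or negative nodal values beyond
10⁻¹² · max Φ are treated as solver failures. Observed L2 convergence
against the analytic one-dimensional Robin-slab solution is order ≈ 2.1, and
an interior point source reproduces the infinite-medium Green's function
P e^(−μeff ρ)/(4πDρ) within 5 % for ρ ∈ [2/μt′, radius/2].

Default geometry is a 1 cm radius disc with the sample's physical thickness
(0.2 cm liver, 0.1 cm skin) and unit beam power. The surface map revolves
Φ(r, 0) about the axis onto a Cartesian pixel grid and reports log₁₀ Φ with
its extremes. Absolute extremes depend strongly on geometry, source power,
mesh resolution at the source singularity and display windowing; the robust,
physically meaningful discriminant is the ordering of the extremes across
tissue states (e.g. coagulated liver shows a higher peak and a much deeper
periphery than normal liver at both wavelengths, because coagulation raises
both μa and μeff), and only orderings are asserted.

## Synthetic data (synthetic_data)

The generator emulates a distant-detector experiment on thin ex-vivo slabs.
Measurement triples are produced by the exact forward model at known ground
truth and perturbed by independent multiplicative Gaussian factors
N(1, σrel); draws outside the invertible simplex (Rd + Td ≥ 1 or
non-positive values) are rejected and redrawn to avoid edge bias. Defaults:
σrel = 2 % and 5 replicates, matching the repeat count of the emulated scan;
a noise model is refused when more than half its draws are rejected or when
σrel ≥ 0.5 (the 2σ band then reaches zero intensity and the multiplicative
model stops describing a measurement). Radial scan fixtures take the
Monte-Carlo annulus profile as the mean and add replicate scatter that is
largest at the first millimetre step and decays geometrically outward
(default 0.8 per mm) — the error-bar pattern produced by proximity to the
specular spot — with a Poisson floor from the finite photon count. Eight
reference tissue states (normal/coagulated chicken liver, normal/boiled
chicken skin at 635 and 808 nm) are built in as ground-truth fixtures.

What the generator does not emulate: detector pixel response, spectrometer
calibration, specular-spot geometry, spatial inhomogeneity of real tissue,
or inter-sample biological variability. Passing recovery tests therefore
demonstrates correctness and noise robustness of the inversion chain, not
field accuracy on real instruments.

## Known limitations

* The two-flux model assumes perfectly diffuse incident flux and recovers
  μs′ only through the similarity relation; strongly absorbing samples
  (μa ≳ μs′) violate both the two-flux and the diffusion approximations —
  such media are flagged with an advisory warning but still processed.
* The published validation table this package re-derives contains two rows
  (the 635 nm normal-tissue entries) whose simulated reflectance cannot be
  reproduced from the tabulated optical parameters by any consistent photon
  transport at those albedos; the package reports its own computed values
  and the discrepancy rather than matching the printed numbers.
* Problem sizes used throughout the test suite — 10⁵–10⁶ photons per
  Monte-Carlo case, meshes of order 10³–10⁴ nodes — are the package's
  default desk-scale settings; both scale linearly if tighter statistics or
  finer maps are needed.
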