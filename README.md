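# tissuelight

Optical differentiation of biological tissue from steady-state light
measurements. Given the total diffuse reflectance *R<sub>d</sub>*, total
diffuse transmittance *T<sub>d</sub>* and collimated transmittance
*T<sub>c</sub>* of a thin tissue slab, `tissuelight`

1. **estimates the optical parameters** — absorption coefficient μ<sub>a</sub>,
   scattering coefficient μ<sub>s</sub> and anisotropy *g* — by inverting the
   Kubelka-Munk two-flux model combined with the Bouguer-Beer-Lambert law,
2. **validates** the estimate by re-simulating the diffuse reflectance with
   photon-packet Monte-Carlo transport through the slab (hop-drop-spin,
   Henyey-Greenstein phase function, Russian roulette), and
3. **renders the surface fluence-rate distribution** Φ(x, y) implied by the
   parameters, by solving the steady-state diffusion equation
   −∇·(D∇Φ) + μ<sub>a</sub>Φ = S, D = 1/(3(μ<sub>a</sub> + μ′<sub>s</sub>)),
   with P1 finite elements on an axisymmetric mesh.

Fluence-rate images discriminate tissue states (e.g. normal vs. coagulated
liver) visually: coagulation raises μ<sub>a</sub> and μ<sub>eff</sub>, which
sharpens the surface peak and deepens the periphery of log₁₀ Φ. The package
is aimed at biomedical-optics work on ex-vivo slab samples measured with a
scanned distant detector.

The inversion chain is, with a = (1 + R<sub>d</sub>² − T<sub>d</sub>²)/2R<sub>d</sub>
and b = √(a² − 1):

    S  = ln[(1 − Rd(a − b))/Td] / (b d)        A  = (a − 1) S
    μa = A/2                                   μs′ = (4S + μa)/3
    μt = −ln(Tc)/d                             μs  = μt − μa,   g = 1 − μs′/μs

## Worked example

```python
import tissuelight as tl

# one measurement record of a 2 mm liver slice at 635 nm
m = tl.MeasurementSet(rd=0.354064, td=0.245521, tc=0.005305,
                      thickness=0.2, wavelength=635, sample_id="normal liver")
p = tl.invert_measurements(m)
print(f"mu_a = {p.mu_a:.4f} /cm, mu_s = {p.mu_s:.4f} /cm, g = {p.g:.4f}")

res = tl.run_mc(tl.SlabStack.single(p), n_photons=1_000_000, seed=1)
print(f"MC: Rd = {res.rd_total:.4f}, Td = {res.td_total:.4f}")

med = tl.DiffusionMedium(mu_a=p.mu_a, mu_s_prime=p.mu_s_prime)
src = tl.place_source(med, beam_power=1.0, thickness=p.thickness)
mesh = tl.build_mesh(1.0, p.thickness, 0.01, refine_near=src)
img = tl.surface_map(tl.solve_fluence(mesh, med, src))
print(f"max log10(phi) = {img.max_log10:.2f}, min log10(phi) = {img.min_log10:.2f}")
```

prints

```
mu_a = 1.4129 /cm, mu_s = 24.7826 /cm, g = 0.6794
MC: Rd = 0.2727, Td = 0.3326
max log10(phi) = 1.02, min log10(phi) = -3.90
```

The first line recovers the absorption (1.41 cm⁻¹), scattering
(24.78 cm⁻¹) and anisotropy (0.68) of normal liver from the three measured
fractions. The second line is the independent Monte-Carlo check: at these
parameters a matched-boundary slab returns 27 % of the incident power
diffusely through the entry face. The last line summarises the rendered
surface map: the fluence rate spans about five decades between the beam axis
and the 1 cm periphery; comparing these extremes across tissue states is the
diagnostic signal (a coagulated-liver sample gives a higher peak and a far
deeper periphery under identical solve settings).

A command-line interface mirrors the library
(`tissuelight invert|mc|fluence|synth|pipeline`); `tissuelight pipeline
measurements.csv --seed 0` runs the whole chain over a CSV batch and writes
parameter reports, radial profiles, nodal solutions, surface matrices, PNG
heat maps and a manifest.

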