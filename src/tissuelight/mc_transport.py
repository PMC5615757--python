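"""Photon-packet Monte-Carlo transport in a layered slab.

Standard hop-drop-spin photon-packet transport (the MCML scheme): an
infinitely narrow beam enters a stack of plane-parallel layers perpendicular
to the top surface; each packet hops a free path sampled from the Beer
distribution ``-ln(u)/mu_t``, deposits the fraction ``mu_a/mu_t`` of its
weight at each interaction, and is deflected by a Henyey-Greenstein angle
with mean cosine ``g``.  Low-weight packets are terminated by unbiased
Russian roulette.  Escaping weight through the top surface is tallied as
diffuse reflectance (into radial annuli mirroring a 1 mm detector scan) and
through the bottom as diffuse transmittance.

Boundaries may be refractive-index mismatched (Fresnel reflection /
refraction), but the validation runs use matched indices, under which the
specular component is zero and every escape attempt succeeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .km_optics import OpticalProperties

__all__ = [
    "SlabStack",
    "MCResult",
    "sample_step",
    "sample_hg",
    "run_mc",
    "mc_radial_profile",
]

# MCML variance-reduction constants: roulette below this weight, survive with
# probability CHANCE (survivors boosted by 1/CHANCE; unbiased).
WEIGHT_THRESHOLD = 1e-4
ROULETTE_CHANCE = 0.1


@dataclass(frozen=True)
class SlabStack:
    """Ordered stack of tissue layers with the surrounding media.

    Layers are listed top (illuminated) to bottom.  The matched-boundary
    condition holds when every layer index equals both ambient indices.
    """

    layers: tuple[OpticalProperties, ...]
    ambient_n_top: float = 1.0
    ambient_n_bottom: float = 1.0

    def __init__(self, layers, ambient_n_top: float = 1.0,
                 ambient_n_bottom: float = 1.0):
        layers = tuple(layers)
        if not layers:
            raise ValueError("SlabStack needs at least one layer")
        object.__setattr__(self, "layers", layers)
        object.__setattr__(self, "ambient_n_top", float(ambient_n_top))
        object.__setattr__(self, "ambient_n_bottom", float(ambient_n_bottom))

    @classmethod
    def single(cls, props: OpticalProperties, matched: bool = True) -> "SlabStack":
        """Single homogeneous slab; ``matched`` sets both ambients to the layer index."""
        n_amb = props.n if matched else 1.0
        return cls((props,), ambient_n_top=n_amb, ambient_n_bottom=n_amb)

    @property
    def matched(self) -> bool:
        ns = {layer.n for layer in self.layers}
        return ns == {self.ambient_n_top} == {self.ambient_n_bottom}

    @property
    def total_thickness(self) -> float:
        return sum(layer.thickness for layer in self.layers)


@dataclass(frozen=True)
class MCResult:
    """Tallies of one Monte-Carlo run (all weights are fractions of input power)."""

    rd_total: float
    td_total: float
    absorbed: float
    specular: float
    rd_radial: np.ndarray  # length n_bins + 1; last entry is the overflow annulus
    r_bin_width: float     # cm
    n_photons: int
    seed: int

    def __post_init__(self) -> None:
        if self.rd_total < 0 or self.td_total < 0 or self.absorbed < 0:
            raise ValueError("tallies must be non-negative")


def sample_step(mu_t: float, u: float) -> float:
    """Free path length ``-ln(u)/mu_t`` for interaction coefficient mu_t (1/cm)."""
    if mu_t <= 0.0:
        raise ValueError(f"mu_t must be > 0, got {mu_t}")
    if not (0.0 < u <= 1.0):
        raise ValueError(f"u must be in (0,1], got {u}")
    return -math.log(u) / mu_t


def sample_hg(g: float, u):
    """Henyey-Greenstein scattering cosine for anisotropy g and uniform deviate u.

    For g = 0 the phase function is isotropic and cos(theta) = 2u - 1.
    Accepts scalar or ndarray ``u``.
    """
    if not (-1.0 < g < 1.0):
        raise ValueError(f"g must be in (-1,1), got {g}")
    u = np.asarray(u, dtype=float)
    if abs(g) < 1e-12:
        ct = 2.0 * u - 1.0
    else:
        frac = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
        ct = (1.0 + g * g - frac * frac) / (2.0 * g)
    ct = np.clip(ct, -1.0, 1.0)
    return float(ct) if ct.ndim == 0 else ct


@njit(cache=True)
def _transport_kernel(mu_a, mu_s, g, n_layer, z_bounds, n_top, n_bot,
                      n_photons, seed, r_bin_width, n_bins):
    """Hop-drop-spin loop over photon packets; returns raw weight tallies."""
    np.random.seed(seed)
    n_lay = mu_a.shape[0]
    rd = 0.0
    td = 0.0
    absorbed = 0.0
    specular = 0.0
    radial = np.zeros(n_bins + 1)

    for _ in range(n_photons):
        x = 0.0
        y = 0.0
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        layer = 0
        w = 1.0

        # specular reflection at normal-incidence entry (zero when matched)
        if n_top != n_layer[0]:
            rsp = ((n_top - n_layer[0]) / (n_top + n_layer[0])) ** 2
            specular += rsp
            w -= rsp

        alive = True
        while alive:
            mt = mu_a[layer] + mu_s[layer]
            u = np.random.random()
            while u <= 0.0:
                u = np.random.random()
            s = -math.log(u) / mt

            # advance, crossing layer boundaries as needed
            while True:
                if uz > 0.0:
                    db = (z_bounds[layer + 1] - z) / uz
                elif uz < 0.0:
                    db = (z_bounds[layer] - z) / uz
                else:
                    db = 1e30
                if s < db:
                    x += s * ux
                    y += s * uy
                    z += s * uz
                    break
                # hit an interface: move there and resolve crossing
                x += db * ux
                y += db * uy
                z += db * uz
                s_left = (s - db) * mt  # dimensionless remainder

                going_up = uz < 0.0
                n1 = n_layer[layer]
                if going_up:
                    n2 = n_top if layer == 0 else n_layer[layer - 1]
                else:
                    n2 = n_bot if layer == n_lay - 1 else n_layer[layer + 1]

                ci = abs(uz)
                if n1 == n2:
                    refl = 0.0
                    ct = ci
                else:
                    si = math.sqrt(max(1.0 - ci * ci, 0.0))
                    st = n1 / n2 * si
                    if st >= 1.0:
                        refl = 1.0
                        ct = 0.0
                    else:
                        ct = math.sqrt(1.0 - st * st)
                        rs = ((n1 * ci - n2 * ct) / (n1 * ci + n2 * ct)) ** 2
                        rp = ((n1 * ct - n2 * ci) / (n1 * ct + n2 * ci)) ** 2
                        refl = 0.5 * (rs + rp)

                if np.random.random() < refl:
                    uz = -uz  # internally reflected; keep propagating in layer
                else:
                    if going_up and layer == 0:
                        r = math.sqrt(x * x + y * y)
                        ib = int(r / r_bin_width)
                        if ib > n_bins:
                            ib = n_bins
                        radial[ib] += w
                        rd += w
                        alive = False
                        break
                    if (not going_up) and layer == n_lay - 1:
                        td += w
                        alive = False
                        break
                    # refract into the neighbouring layer
                    scale = n1 / n2
                    ux *= scale
                    uy *= scale
                    uz = ct if uz > 0.0 else -ct
                    layer = layer - 1 if going_up else layer + 1
                    mt = mu_a[layer] + mu_s[layer]
                if s_left <= 0.0:
                    s = 0.0
                    break
                s = s_left / mt

            if not alive:
                break

            # drop
            dw = w * mu_a[layer] / (mu_a[layer] + mu_s[layer])
            absorbed += dw
            w -= dw
            if w <= 0.0:
                break

            # spin (Henyey-Greenstein)
            gg = g[layer]
            u = np.random.random()
            if abs(gg) < 1e-12:
                ct = 2.0 * u - 1.0
            else:
                frac = (1.0 - gg * gg) / (1.0 - gg + 2.0 * gg * u)
                ct = (1.0 + gg * gg - frac * frac) / (2.0 * gg)
            if ct > 1.0:
                ct = 1.0
            elif ct < -1.0:
                ct = -1.0
            st = math.sqrt(1.0 - ct * ct)
            phi = 2.0 * math.pi * np.random.random()
            cp = math.cos(phi)
            sp = math.sin(phi)
            if abs(uz) > 0.99999:
                ux = st * cp
                uy = st * sp
                uz = ct if uz > 0.0 else -ct
            else:
                den = math.sqrt(1.0 - uz * uz)
                nux = st * (ux * uz * cp - uy * sp) / den + ux * ct
                nuy = st * (uy * uz * cp + ux * sp) / den + uy * ct
                nuz = -den * st * cp + uz * ct
                norm = math.sqrt(nux * nux + nuy * nuy + nuz * nuz)
                ux = nux / norm
                uy = nuy / norm
                uz = nuz / norm

            # Russian roulette
            if w < WEIGHT_THRESHOLD:
                if np.random.random() < ROULETTE_CHANCE:
                    w /= ROULETTE_CHANCE
                else:
                    break

    return rd, td, absorbed, specular, radial


def run_mc(stack: SlabStack, n_photons: int = 1_000_000, seed: int = 0,
           r_bin_width: float = 0.1, r_max: float = 1.0) -> MCResult:
    """Run photon-packet transport through a slab stack.

    Parameters
    ----------
    stack : SlabStack
        Layer geometry and optical properties.
    n_photons : int
        Number of photon packets (default 1e6).
    seed : int
        RNG seed; identical inputs give bit-identical tallies.
    r_bin_width : float
        Radial annulus width in cm for the reflectance profile (default
        0.1 cm, mirroring a 1 mm detector step).
    r_max : float
        Outer radius of the last regular annulus; weight beyond it goes to an
        overflow bin.

    Returns
    -------
    MCResult
        Total diffuse reflectance / transmittance / absorbed fractions plus
        the per-annulus reflectance profile.
    """
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    for layer in stack.layers:
        if layer.mu_t <= 0.0:
            raise ValueError("every layer needs mu_a + mu_s > 0")
    mu_a = np.array([la.mu_a for la in stack.layers])
    mu_s = np.array([la.mu_s for la in stack.layers])
    g = np.array([la.g for la in stack.layers])
    n_layer = np.array([la.n for la in stack.layers])
    z_bounds = np.concatenate(
        [[0.0], np.cumsum([la.thickness for la in stack.layers])]
    )
    n_bins = int(round(r_max / r_bin_width))
    rd, td, absorbed, specular, radial = _transport_kernel(
        mu_a, mu_s, g, n_layer, z_bounds,
        float(stack.ambient_n_top), float(stack.ambient_n_bottom),
        int(n_photons), int(seed), float(r_bin_width), int(n_bins),
    )
    inv = 1.0 / n_photons
    return MCResult(
        rd_total=rd * inv,
        td_total=td * inv,
        absorbed=absorbed * inv,
        specular=specular * inv,
        rd_radial=radial * inv,
        r_bin_width=r_bin_width,
        n_photons=n_photons,
        seed=seed,
    )


def mc_radial_profile(result: MCResult):
    """Radial reflectance profile of a run as a SpatialProfile.

    Bin centers at 0.5, 1.5, ... mm (the overflow annulus is excluded); the
    values are the per-annulus escaping weight fractions, which sum with the
    overflow to ``rd_total``.
    """
    from .synthetic_data import SpatialProfile  # local import avoids a cycle

    n_bins = result.rd_radial.shape[0] - 1
    centers_mm = (np.arange(n_bins) + 0.5) * result.r_bin_width * 10.0
    values = result.rd_radial[:n_bins].copy()
    return SpatialProfile(
        distances=centers_mm,
        values=values,
        sd=np.zeros(n_bins),
        replicates=1,
    )
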