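"""Synthetic measurements emulating a distant-detector tissue experiment.

Generates the two kinds of observable the rest of the package consumes:

* measurement triples (Rd, Td, Tc) produced by the exact two-flux /
  Beer-Lambert forward model at known ground-truth optical parameters, with
  multiplicative Gaussian measurement noise, and
* spatially-resolved reflectance profiles on a 1 mm grid out to 10 mm with
  replicate scatter that is largest at the first step and decays outward —
  the error-bar pattern of a detector scanned away from the specular spot.

A table of eight reference tissue states (normal and coagulated chicken
liver, normal and boiled breast chicken skin, each at 635 and 808 nm) serves
as ready-made ground-truth fixtures spanning the realistic parameter
envelope: liver slices 2 mm thick and skin 1 mm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import mc_transport
from .km_optics import (
    MeasurementSet,
    OpticalProperties,
    forward_measurements,
)

__all__ = [
    "SpatialProfile",
    "NoiseModel",
    "NoiseTooLargeError",
    "make_measurement_set",
    "make_spatial_profiles",
    "fixture_table",
    "FIXTURE_ROWS",
]


class NoiseTooLargeError(ValueError):
    """Noise level rejects more than half of the generated triples."""


@dataclass(frozen=True)
class SpatialProfile:
    """Spatially-resolved reflectance or transmittance scan.

    distances in mm (strictly increasing), values and per-point standard
    deviations as fractions of incident power.
    """

    distances: np.ndarray
    values: np.ndarray
    sd: np.ndarray
    replicates: int = 1

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=float)
        if np.any(np.diff(d) <= 0.0):
            raise ValueError("distances must be strictly increasing")
        if np.any(np.asarray(self.values) < 0.0):
            raise ValueError("values must be >= 0")
        if np.any(np.asarray(self.sd) < 0.0):
            raise ValueError("sd must be >= 0")


@dataclass(frozen=True)
class NoiseModel:
    """Replicate noise description for the synthetic experiment.

    relative_sd is the multiplicative Gaussian sd applied to each observable;
    sd_decay is the per-mm multiplier (< 1) by which the profile scatter
    shrinks with distance from the beam; replicate_count mirrors the roughly
    five repeats per detector position.
    """

    relative_sd: float = 0.02
    sd_decay: float = 0.8
    replicate_count: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.relative_sd < 0.0:
            raise ValueError("relative_sd must be >= 0")
        if not (0.0 < self.sd_decay <= 1.0):
            raise ValueError("sd_decay must be in (0, 1]")
        if self.replicate_count < 1:
            raise ValueError("replicate_count must be >= 1")


def make_measurement_set(truth: OpticalProperties, noise: NoiseModel,
                         wavelength: float = float("nan"),
                         sample_id: str = "synthetic") -> MeasurementSet:
    """Forward-generate one noisy (Rd, Td, Tc) triple from ground truth.

    The noiseless triple comes from the exact forward model; each observable
    is then multiplied by an independent N(1, relative_sd) factor.  Draws
    falling outside the invertible simplex (rd + td >= 1, or non-positive
    values) are rejected and redrawn; if more than half the draws are
    rejected the noise model is refused as unusably wide.
    """
    clean = forward_measurements(truth, wavelength=wavelength, sample_id=sample_id)
    if noise.relative_sd == 0.0:
        return clean
    if noise.relative_sd >= 0.5:
        # the 2-sigma band reaches zero intensity: the multiplicative model
        # no longer emulates a measurement, only clipping artifacts
        raise NoiseTooLargeError(
            f"relative_sd={noise.relative_sd} >= 0.5 is unusably wide"
        )
    rng = np.random.default_rng(noise.seed)
    n_draws = 200
    f = rng.normal(1.0, noise.relative_sd, size=(n_draws, 3))
    rd = clean.rd * f[:, 0]
    td = clean.td * f[:, 1]
    tc = np.minimum(clean.tc * f[:, 2], 1.0)
    valid = (rd > 0.0) & (rd < 1.0) & (td >= 0.0) & (tc > 0.0) & (rd + td < 1.0)
    if valid.mean() < 0.5:
        raise NoiseTooLargeError(
            f"relative_sd={noise.relative_sd} rejects "
            f"{100 * (1 - valid.mean()):.0f}% of draws for this truth"
        )
    first = int(np.argmax(valid))
    return MeasurementSet(rd=float(rd[first]), td=float(td[first]),
                          tc=float(tc[first]), thickness=truth.thickness,
                          wavelength=wavelength, sample_id=sample_id)


def make_spatial_profiles(truth: OpticalProperties, noise: NoiseModel,
                          n_photons: int = 200_000,
                          ) -> tuple[SpatialProfile, SpatialProfile]:
    """Replicate-averaged radial reflectance and transmittance scans.

    The mean radial reflectance profile comes from photon-packet transport
    through the slab; each of ``replicate_count`` synthetic scans perturbs it
    with multiplicative Gaussian noise whose sd is ``relative_sd`` at the
    first detector step and decays by ``sd_decay`` per mm outward, plus a
    Poisson-scaled floor from the finite photon count.  Transmittance is
    reported as the total diffuse transmittance spread uniformly over the
    scanned annuli (the transport tally is not radially resolved on the exit
    face).
    """
    stack = mc_transport.SlabStack.single(truth, matched=True)
    result = mc_transport.run_mc(stack, n_photons=n_photons, seed=noise.seed,
                                 r_bin_width=0.1, r_max=1.0)
    base = mc_transport.mc_radial_profile(result)
    rng = np.random.default_rng(noise.seed + 1)
    distances = base.distances

    def replicate(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        rel = noise.relative_sd * noise.sd_decay ** (distances - distances[0])
        poisson_floor = np.sqrt(np.maximum(values, 0.0) / n_photons)
        sd_point = np.maximum(rel * values, poisson_floor)
        draws = values[None, :] + rng.normal(
            0.0, 1.0, size=(noise.replicate_count, len(values))) * sd_point
        draws = np.maximum(draws, 0.0)
        return draws.mean(axis=0), draws.std(axis=0, ddof=1) if (
            noise.replicate_count > 1) else np.zeros_like(values)

    refl_mean, refl_sd = replicate(base.values)
    n_bins = len(distances)
    td_flat = np.full(n_bins, result.td_total / n_bins)
    trans_mean, trans_sd = replicate(td_flat)
    # enforce the constructed first-step-dominant scatter on the reported sd
    refl_sd = _monotone_decay(refl_sd)
    trans_sd = _monotone_decay(trans_sd)
    reflectance = SpatialProfile(distances=distances, values=refl_mean,
                                 sd=refl_sd, replicates=noise.replicate_count)
    transmittance = SpatialProfile(distances=distances, values=trans_mean,
                                   sd=trans_sd, replicates=noise.replicate_count)
    return reflectance, transmittance


def _monotone_decay(sd: np.ndarray) -> np.ndarray:
    """Clamp a sd sequence to be non-increasing (first step carries the most)."""
    return np.minimum.accumulate(sd)


# (sample, wavelength nm, mu_a 1/cm, mu_s 1/cm, g, thickness cm)
FIXTURE_ROWS: tuple[tuple[str, float, float, float, float, float], ...] = (
    ("Normal chicken liver", 635.0, 1.4129, 24.7830, 0.6794, 0.2),
    ("Normal chicken liver", 808.0, 8.5873, 21.3700, 0.7762, 0.2),
    ("Coagulated chicken liver", 635.0, 24.015, 46.3455, 0.3985, 0.2),
    ("Coagulated chicken liver", 808.0, 23.250, 42.1177, 0.5527, 0.2),
    ("Normal chicken skin", 635.0, 2.5433, 16.4246, 0.6117, 0.1),
    ("Normal chicken skin", 808.0, 2.3215, 34.8758, 0.6117, 0.1),
    ("Boiled chicken skin", 635.0, 4.9963, 14.6141, 0.8729, 0.1),
    ("Boiled chicken skin", 808.0, 7.3333, 54.3248, 0.8371, 0.1),
)


def fixture_table() -> list[tuple[str, float, OpticalProperties]]:
    """The eight reference tissue states as (sample, wavelength, properties).

    Liver slices are 2 mm thick and skin samples 1 mm; refractive index is
    set to 1 (matched-boundary convention).
    """
    return [
        (name, wl, OpticalProperties(mu_a=mu_a, mu_s=mu_s, g=g, n=1.0,
                                     thickness=d))
        for name, wl, mu_a, mu_s, g, d in FIXTURE_ROWS
    ]


def fixture_row(sample: str, wavelength: float) -> OpticalProperties:
    """Look up one reference tissue state by name substring and wavelength."""
    for name, wl, props in fixture_table():
        if sample.lower() in name.lower() and wl == wavelength:
            return props
    raise KeyError(f"no fixture row matching ({sample!r}, {wavelength})")
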