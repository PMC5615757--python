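"""Kubelka-Munk two-flux optics combined with Beer-Lambert collimated attenuation.

The two-flux (Kubelka-Munk) model describes diffuse light in a turbid slab by
two counter-propagating fluxes with a scattering flux coefficient ``S`` and an
absorption flux coefficient ``A`` (both 1/cm).  In the Kottler closed form the
diffuse reflectance and transmittance of a slab of thickness ``d`` are

    Rd = sinh(S b d) / (a sinh(S b d) + b cosh(S b d))
    Td =           b / (a sinh(S b d) + b cosh(S b d))

with the dimensionless auxiliaries ``a = 1 + A/S`` and ``b = sqrt(a^2 - 1)``.
These relations are exactly inverted from measured (Rd, Td):

    a = (1 + Rd^2 - Td^2) / (2 Rd),   b = sqrt(a^2 - 1)
    S = (1 / (b d)) ln[(1 - Rd (a - b)) / Td],   A = (a - 1) S

The flux coefficients connect to the transport coefficients through

    A = 2 mu_a           and      S = (3/4) mu_s' - (1/4) mu_a

where ``mu_s' = mu_s (1 - g)`` is the reduced scattering coefficient.  The
total attenuation coefficient ``mu_t = mu_a + mu_s`` comes from the collimated
(ballistic) transmittance via Beer-Lambert, ``Tc = exp(-mu_t d)``, after which
``mu_s = mu_t - mu_a`` and ``g = 1 - mu_s'/mu_s``.

All coefficients are in 1/cm and all lengths in cm.  Specular reflection is
assumed already excluded from Rd (refractive-index-matched convention), so no
Fresnel correction is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "MeasurementSet",
    "KMCoefficients",
    "OpticalProperties",
    "InvalidMeasurementError",
    "SemiInfiniteSampleError",
    "InvalidRegimeError",
    "km_auxiliary",
    "km_forward",
    "km_invert_SA",
    "sa_to_transport",
    "transport_to_sa",
    "beer_lambert_mu_t",
    "assemble_properties",
    "invert_measurements",
    "forward_measurements",
]

class InvalidMeasurementError(ValueError):
    """Measurement triple is outside the physically invertible domain."""


class SemiInfiniteSampleError(InvalidMeasurementError):
    """Td = 0: the slab is optically semi-infinite and S is unrecoverable."""


class InvalidRegimeError(ValueError):
    """Derived transport coefficients fall outside the physical regime."""


@dataclass(frozen=True)
class MeasurementSet:
    """One experimental observation of a tissue slab.

    Parameters
    ----------
    rd : float
        Total diffuse reflectance, fraction in (0, 1).
    td : float
        Total diffuse transmittance, fraction in [0, 1).
    tc : float
        Collimated (ballistic) transmittance, fraction in (0, 1].
    thickness : float
        Slab thickness in cm.
    wavelength : float
        Illumination wavelength in nm (label only; not used numerically).
    sample_id : str
        Free-form sample label.
    """

    rd: float
    td: float
    tc: float
    thickness: float
    wavelength: float = float("nan")
    sample_id: str = ""

    def __post_init__(self) -> None:
        if not (0.0 < self.rd < 1.0):
            raise InvalidMeasurementError(f"rd must be in (0,1), got {self.rd}")
        if not (0.0 <= self.td < 1.0):
            raise InvalidMeasurementError(f"td must be in [0,1), got {self.td}")
        if not (0.0 < self.tc <= 1.0):
            raise InvalidMeasurementError(f"tc must be in (0,1], got {self.tc}")
        if self.rd + self.td >= 1.0:
            raise InvalidMeasurementError(
                f"rd + td = {self.rd + self.td} >= 1: not invertible (a < 1)"
            )
        if self.thickness <= 0.0:
            raise InvalidMeasurementError(f"thickness must be > 0, got {self.thickness}")


@dataclass(frozen=True)
class KMCoefficients:
    """Two-flux coefficients S, A with the dimensionless auxiliaries a, b.

    ``s`` and ``a_cap`` are the scattering and absorption flux coefficients
    (1/cm); ``a = 1 + a_cap/s`` and ``b = sqrt(a^2 - 1)``.
    """

    s: float
    a_cap: float
    a: float = field(default=float("nan"))
    b: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if self.s <= 0.0:
            raise ValueError(f"S must be > 0, got {self.s}")
        if self.a_cap < 0.0:
            raise ValueError(f"A must be >= 0, got {self.a_cap}")
        if math.isnan(self.a):
            object.__setattr__(self, "a", 1.0 + self.a_cap / self.s)
        if math.isnan(self.b):
            object.__setattr__(self, "b", math.sqrt(max(self.a * self.a - 1.0, 0.0)))
        if self.a < 1.0:
            raise ValueError(f"a must be >= 1, got {self.a}")


@dataclass(frozen=True)
class OpticalProperties:
    """Transport description of a tissue layer.

    Parameters
    ----------
    mu_a, mu_s : float
        Absorption and scattering coefficients, 1/cm.
    g : float
        Scattering anisotropy (mean cosine), in [0, 1).
    n : float
        Refractive index (>= 1).
    thickness : float
        Layer thickness in cm.
    """

    mu_a: float
    mu_s: float
    g: float
    n: float = 1.0
    thickness: float = 0.1

    def __post_init__(self) -> None:
        if self.mu_a < 0.0:
            raise ValueError(f"mu_a must be >= 0, got {self.mu_a}")
        if self.mu_s < 0.0:
            raise ValueError(f"mu_s must be >= 0, got {self.mu_s}")
        if not (0.0 <= self.g < 1.0):
            raise ValueError(f"g must be in [0,1), got {self.g}")
        if self.thickness <= 0.0:
            raise ValueError(f"thickness must be > 0, got {self.thickness}")
        if self.n < 1.0:
            raise ValueError(f"n must be >= 1, got {self.n}")

    @property
    def mu_s_prime(self) -> float:
        """Reduced scattering coefficient mu_s (1 - g), 1/cm."""
        return self.mu_s * (1.0 - self.g)

    @property
    def mu_t(self) -> float:
        """Total attenuation coefficient mu_a + mu_s, 1/cm."""
        return self.mu_a + self.mu_s


def _auxiliary(rd: float, td: float) -> tuple[float, float, float]:
    """(a, b, a - 1) from a (Rd, Td) pair, cancellation-free.

    Uses a - 1 = (1 - Rd - Td)(1 - Rd + Td) / (2 Rd), algebraically equal to
    (1 + Rd^2 - Td^2)/(2 Rd) - 1 but exact near the pure-scattering edge
    Rd + Td = 1 where the direct form loses all significant digits.
    """
    if rd <= 0.0:
        raise InvalidMeasurementError(f"rd must be > 0 to form auxiliaries, got {rd}")
    am1 = (1.0 - rd - td) * (1.0 - rd + td) / (2.0 * rd)
    if am1 < 0.0:
        # allow rounding-level excursions at the simplex edge
        if am1 > -1e-12:
            am1 = 0.0
        else:
            raise InvalidMeasurementError(
                f"a = {1.0 + am1} < 1 (rd + td >= 1): measurement not invertible"
            )
    a = 1.0 + am1
    b = math.sqrt(am1 * (a + 1.0))
    return a, b, am1


def km_auxiliary(rd: float, td: float) -> tuple[float, float]:
    """Dimensionless auxiliaries (a, b) from a (Rd, Td) pair.

    a = (1 + Rd^2 - Td^2) / (2 Rd); b = sqrt(a^2 - 1).  Requires Rd > 0 and
    Rd + Td < 1 (otherwise a < 1 and b is undefined).
    """
    a, b, _ = _auxiliary(rd, td)
    return a, b


def km_forward(coeff: KMCoefficients, thickness: float) -> tuple[float, float]:
    """Diffuse reflectance and transmittance of a slab from (S, A).

    Kottler closed form; the pure-scattering limit b -> 0 is evaluated
    analytically as Rd = S d / (1 + S d), Td = 1 / (1 + S d).
    """
    if thickness < 0.0:
        raise ValueError(f"thickness must be >= 0, got {thickness}")
    s, a, b = coeff.s, coeff.a, coeff.b
    if b == 0.0:
        # analytic pure-scattering limit (the closed form is 0/0 at b = 0)
        sd = s * thickness
        return sd / (1.0 + sd), 1.0 / (1.0 + sd)
    x = s * b * thickness
    if x > 350.0:
        # asymptotic slab: rd -> a - b (note (a+b)(a-b) = 1), td -> 0
        rd = 1.0 / (a + b / math.tanh(x))
        td = 2.0 * b * math.exp(-x) / (a + b) if x < 745.0 else 0.0
        return rd, td
    sh, ch = math.sinh(x), math.cosh(x)
    den = a * sh + b * ch
    return sh / den, b / den


def km_invert_SA(rd: float, td: float, thickness: float) -> KMCoefficients:
    """Invert a (Rd, Td) pair of a slab of known thickness to (S, A).

    Exact algebraic inverse of :func:`km_forward`.  Td = 0 means the slab is
    effectively semi-infinite and S cannot be recovered.
    """
    if td <= 0.0:
        raise SemiInfiniteSampleError(
            "td = 0: semi-infinite sample, S unrecoverable from (rd, td)"
        )
    if thickness <= 0.0:
        raise ValueError(f"thickness must be > 0, got {thickness}")
    a, b, am1 = _auxiliary(rd, td)
    if b == 0.0:
        # exact pure-scattering limit of ln[(1 - rd(a-b))/td]/b
        s = rd / ((1.0 - rd) * thickness)
    else:
        # arg - 1 formed without cancellation: 1 - rd(a-b) - td
        delta = (1.0 - rd - td) + rd * (b - am1)
        if delta <= 0.0:
            raise InvalidMeasurementError(
                f"log argument {1.0 + delta / td} <= 1: S would be non-positive"
            )
        s = math.log1p(delta / td) / (b * thickness)
    a_cap = am1 * s
    return KMCoefficients(s=s, a_cap=a_cap, a=a, b=b)


def sa_to_transport(coeff: KMCoefficients) -> tuple[float, float]:
    """Transport coefficients (mu_a, mu_s') from the flux coefficients (S, A).

    Inverts A = 2 mu_a and S = (3/4) mu_s' - (1/4) mu_a:
    mu_a = A/2, mu_s' = (4 S + mu_a) / 3.
    """
    mu_a = coeff.a_cap / 2.0
    mu_s_prime = (4.0 * coeff.s + mu_a) / 3.0
    if mu_s_prime <= 0.0:
        raise InvalidRegimeError(f"derived mu_s' = {mu_s_prime} <= 0")
    return mu_a, mu_s_prime


def transport_to_sa(mu_a: float, mu_s_prime: float) -> KMCoefficients:
    """Flux coefficients (S, A) from transport coefficients (forward map)."""
    s = 0.75 * mu_s_prime - 0.25 * mu_a
    if s <= 0.0:
        raise InvalidRegimeError(
            f"S = 0.75*mu_s' - 0.25*mu_a = {s} <= 0: outside the two-flux regime"
        )
    return KMCoefficients(s=s, a_cap=2.0 * mu_a)


def beer_lambert_mu_t(tc: float, thickness: float) -> float:
    """Total attenuation coefficient from collimated transmittance.

    mu_t = -ln(Tc) / d.
    """
    if tc <= 0.0:
        raise InvalidMeasurementError(f"tc must be > 0, got {tc}")
    if tc > 1.0:
        raise InvalidMeasurementError(f"tc must be <= 1, got {tc}")
    if thickness <= 0.0:
        raise ValueError(f"thickness must be > 0, got {thickness}")
    return -math.log(tc) / thickness


def assemble_properties(
    mu_a: float, mu_s_prime: float, mu_t: float, thickness: float, n: float = 1.0
) -> OpticalProperties:
    """Combine (mu_a, mu_s', mu_t) into the full (mu_a, mu_s, g) description.

    mu_s = mu_t - mu_a and g = 1 - mu_s'/mu_s.  Raises if mu_t <= mu_a (no
    scattering left) or mu_s' > mu_s (g would be negative).
    """
    if mu_t <= mu_a:
        raise InvalidRegimeError(
            f"mu_t = {mu_t} <= mu_a = {mu_a}: no scattering component"
        )
    mu_s = mu_t - mu_a
    if mu_s_prime > mu_s * (1.0 + 1e-12):
        raise InvalidRegimeError(
            f"mu_s' = {mu_s_prime} > mu_s = {mu_s}: anisotropy out of range"
        )
    g = 1.0 - mu_s_prime / mu_s
    g = min(max(g, 0.0), 1.0 - 1e-15)
    return OpticalProperties(mu_a=mu_a, mu_s=mu_s, g=g, n=n, thickness=thickness)


def invert_measurements(m: MeasurementSet) -> OpticalProperties:
    """Full inversion of a measurement triple to (mu_a, mu_s, g).

    Chains the two-flux inversion of (Rd, Td) with the Beer-Lambert inversion
    of Tc; error messages identify the failing stage.
    """
    try:
        coeff = km_invert_SA(m.rd, m.td, m.thickness)
    except (InvalidMeasurementError, ValueError) as exc:
        raise type(exc)(f"two-flux inversion failed: {exc}") from exc
    mu_a, mu_s_prime = sa_to_transport(coeff)
    mu_t = beer_lambert_mu_t(m.tc, m.thickness)
    try:
        return assemble_properties(mu_a, mu_s_prime, mu_t, m.thickness)
    except InvalidRegimeError as exc:
        raise InvalidRegimeError(f"property assembly failed: {exc}") from exc


def forward_measurements(props: OpticalProperties, wavelength: float = float("nan"),
                         sample_id: str = "") -> MeasurementSet:
    """Noiseless forward model: (mu_a, mu_s, g, d) -> (Rd, Td, Tc).

    Exact inverse of :func:`invert_measurements` for parameters inside the
    two-flux regime.
    """
    coeff = transport_to_sa(props.mu_a, props.mu_s_prime)
    rd, td = km_forward(coeff, props.thickness)
    tc = math.exp(-props.mu_t * props.thickness)
    return MeasurementSet(rd=rd, td=td, tc=tc, thickness=props.thickness,
                          wavelength=wavelength, sample_id=sample_id)
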