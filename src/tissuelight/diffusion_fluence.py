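"""Steady-state diffusion-approximation solver for surface fluence-rate maps.

Solves the steady-state diffusion equation

    -div( D grad(Phi) ) + mu_a Phi = S,      D = 1 / (3 (mu_a + mu_s'))

on an axisymmetric (r, z) slab with linear (P1) triangular finite elements.
The pencil beam is reduced to an isotropic point source of the beam power at
depth ``z0 = 1/(mu_a + mu_s')`` below the illuminated surface.  On the
illuminated and exit faces the partial-current (Robin) condition

    Phi + 2 D dPhi/dn = 0

approximates zero inward diffuse flux for matched refractive indices; the
lateral wall and the symmetry axis carry natural zero-flux conditions.  The
surface fluence rate Phi(r, z=0) is revolved about the axis to a Cartesian
map displayed on a log10 scale, the format in which tissue states are
compared.

Positivity of the discrete solution is preserved by mass lumping (the
structured, non-obtuse triangulation makes the system an M-matrix), so nodal
fluence rates are strictly positive whenever the source is.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "DiffusionMedium",
    "SourceSpec",
    "AxisymMesh",
    "FluenceMap",
    "SurfaceImage",
    "build_mesh",
    "place_source",
    "solve_fluence",
    "surface_map",
    "greens_function_infinite",
]


@dataclass(frozen=True)
class DiffusionMedium:
    """Absorbing/scattering medium in the diffusion approximation.

    ``diffusion_coeff`` is D = 1/(3 (mu_a + mu_s')) in cm and ``mu_eff`` the
    effective attenuation sqrt(mu_a / D) in 1/cm.  The approximation is
    advisory-flagged (not rejected) when mu_s' <= mu_a.
    """

    mu_a: float
    mu_s_prime: float

    def __post_init__(self) -> None:
        if self.mu_a < 0.0:
            raise ValueError(f"mu_a must be >= 0, got {self.mu_a}")
        if self.mu_s_prime <= 0.0:
            raise ValueError(f"mu_s' must be > 0, got {self.mu_s_prime}")
        if self.mu_s_prime <= self.mu_a:
            warnings.warn(
                f"diffusion approximation dubious: mu_s'={self.mu_s_prime} <= "
                f"mu_a={self.mu_a}",
                stacklevel=2,
            )

    @property
    def diffusion_coeff(self) -> float:
        return 1.0 / (3.0 * (self.mu_a + self.mu_s_prime))

    @property
    def mu_eff(self) -> float:
        return math.sqrt(self.mu_a / self.diffusion_coeff)


@dataclass(frozen=True)
class SourceSpec:
    """Isotropic point source at (r, z) in cm with total power in W."""

    r: float
    z: float
    power: float = 1.0

    def __post_init__(self) -> None:
        if self.power <= 0.0:
            raise ValueError(f"power must be > 0, got {self.power}")
        if self.r < 0.0 or self.z < 0.0:
            raise ValueError("source must lie at r >= 0, z >= 0")


class AxisymMesh:
    """Conforming triangulation of the (r, z) rectangle [0, R] x [0, T].

    Attributes
    ----------
    nodes : (N, 2) array of (r, z) coordinates in cm.
    elements : (M, 3) int array of node indices (counter-clockwise).
    boundary : dict mapping tag ('top', 'bottom', 'lateral', 'axis') to an
        (K, 2) int array of boundary edge node pairs.
    """

    def __init__(self, nodes: np.ndarray, elements: np.ndarray,
                 boundary: dict[str, np.ndarray], radius: float, thickness: float):
        self.nodes = np.asarray(nodes, dtype=float)
        self.elements = np.asarray(elements, dtype=np.int64)
        self.boundary = boundary
        self.radius = float(radius)
        self.thickness = float(thickness)
        areas = self._areas()
        if np.any(areas <= 0.0):
            raise ValueError("mesh contains degenerate or inverted triangles")

    def _areas(self) -> np.ndarray:
        p = self.nodes[self.elements]
        return 0.5 * ((p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
                      - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1]))

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    def nearest_node(self, r: float, z: float) -> int:
        d2 = (self.nodes[:, 0] - r) ** 2 + (self.nodes[:, 1] - z) ** 2
        return int(np.argmin(d2))


@dataclass
class FluenceMap:
    """Nodal fluence-rate solution on an axisymmetric mesh (W/cm^2)."""

    mesh: AxisymMesh
    phi: np.ndarray

    @property
    def log10_phi(self) -> np.ndarray:
        return np.log10(self.phi)

    def surface_profile(self) -> tuple[np.ndarray, np.ndarray]:
        """(r, Phi(r, z=0)) at the illuminated surface, sorted by r."""
        at_top = np.isclose(self.mesh.nodes[:, 1], 0.0)
        idx = np.where(at_top)[0]
        order = np.argsort(self.mesh.nodes[idx, 0])
        idx = idx[order]
        return self.mesh.nodes[idx, 0], self.phi[idx]


@dataclass(frozen=True)
class SurfaceImage:
    """Revolved Cartesian surface map of log10 fluence rate."""

    x: np.ndarray            # 1-D pixel coordinates, cm
    log10_phi: np.ndarray    # (n, n) image
    max_log10: float
    min_log10: float


def _graded_axis(length: float, target_edge: float, focus: float,
                 grading: float) -> np.ndarray:
    """1-D node coordinates on [0, length], spacing target_edge/grading at
    ``focus`` growing geometrically to target_edge away from it."""
    h_min = target_edge / grading
    coords = [focus]
    # march in both directions with geometric growth
    for direction in (+1.0, -1.0):
        pos = focus
        h = h_min
        while 0.0 < pos < length or pos == focus:
            pos = pos + direction * h
            if pos >= length - 0.25 * h_min:
                coords.append(length)
                break
            if pos <= 0.25 * h_min:
                coords.append(0.0)
                break
            coords.append(pos)
            h = min(h * 1.3, target_edge)
        else:
            pass
    arr = np.unique(np.clip(np.array(coords), 0.0, length))
    if arr[0] > 0.0:
        arr = np.concatenate([[0.0], arr])
    if arr[-1] < length:
        arr = np.concatenate([arr, [length]])
    return arr


def build_mesh(radius: float, thickness: float, target_edge: float,
               refine_near: SourceSpec | None = None,
               grading: float = 5.0) -> AxisymMesh:
    """Structured graded triangulation of the axisymmetric slab.

    The grid is graded toward the source location (``refine_near``), with the
    local edge length shrinking by ``grading`` there.  Each rectangular cell
    is split into two triangles.
    """
    if radius <= 0.0 or thickness <= 0.0 or target_edge <= 0.0:
        raise ValueError("radius, thickness and target_edge must be > 0")
    if target_edge >= min(radius, thickness):
        raise ValueError(
            f"target_edge={target_edge} too coarse for domain "
            f"({radius} x {thickness})"
        )
    if refine_near is None:
        rs = np.linspace(0.0, radius, max(int(round(radius / target_edge)), 2) + 1)
        zs = np.linspace(0.0, thickness,
                         max(int(round(thickness / target_edge)), 2) + 1)
    else:
        rs = _graded_axis(radius, target_edge, refine_near.r, grading)
        zs = _graded_axis(thickness, target_edge, refine_near.z, grading)
    nr, nz = len(rs), len(zs)

    rr, zz = np.meshgrid(rs, zs, indexing="ij")
    nodes = np.column_stack([rr.ravel(), zz.ravel()])

    def nid(i: int, j: int) -> int:
        return i * nz + j

    tris = []
    for i in range(nr - 1):
        for j in range(nz - 1):
            a, b = nid(i, j), nid(i + 1, j)
            c, d = nid(i + 1, j + 1), nid(i, j + 1)
            # counter-clockwise in (r, z)
            tris.append((a, b, c))
            tris.append((a, c, d))
    elements = np.array(tris, dtype=np.int64)

    top = np.array([(nid(i, 0), nid(i + 1, 0)) for i in range(nr - 1)])
    bottom = np.array([(nid(i, nz - 1), nid(i + 1, nz - 1)) for i in range(nr - 1)])
    lateral = np.array([(nid(nr - 1, j), nid(nr - 1, j + 1)) for j in range(nz - 1)])
    axis = np.array([(nid(0, j), nid(0, j + 1)) for j in range(nz - 1)])
    boundary = {"top": top, "bottom": bottom, "lateral": lateral, "axis": axis}
    return AxisymMesh(nodes, elements, boundary, radius, thickness)


def place_source(medium: DiffusionMedium, beam_power: float = 1.0,
                 thickness: float | None = None) -> SourceSpec:
    """Pencil-beam reduction: isotropic point source on the axis at one
    transport mean free path, z0 = 1/(mu_a + mu_s'), below the surface.

    If the slab is thinner than z0 the source is clamped to mid-slab with a
    warning (thin-sample path).
    """
    z0 = 1.0 / (medium.mu_a + medium.mu_s_prime)
    if thickness is not None and z0 >= thickness:
        warnings.warn(
            f"source depth z0={z0:.4g} cm >= thickness {thickness} cm; "
            "clamping to mid-slab",
            stacklevel=2,
        )
        z0 = 0.5 * thickness
    return SourceSpec(r=0.0, z=z0, power=beam_power)


def _assemble(mesh: AxisymMesh, medium: DiffusionMedium, bc: str):
    """Lumped-mass P1 assembly of the axisymmetric weak form.

    Returns (system matrix, node weight vector w_i = int phi_i r dA) — the
    weights turn a volumetric source density into a load vector.
    """
    nodes, elements = mesh.nodes, mesh.elements
    n = mesh.n_nodes
    D = medium.diffusion_coeff
    mu_a = medium.mu_a

    p = nodes[elements]                           # (M, 3, 2)
    r1, z1 = p[:, 0, 0], p[:, 0, 1]
    r2, z2 = p[:, 1, 0], p[:, 1, 1]
    r3, z3 = p[:, 2, 0], p[:, 2, 1]
    area = 0.5 * ((r2 - r1) * (z3 - z1) - (r3 - r1) * (z2 - z1))

    # gradients of the barycentric basis functions (constant per element)
    b_r = np.stack([z2 - z3, z3 - z1, z1 - z2], axis=1) / (2 * area)[:, None]
    b_z = np.stack([r3 - r2, r1 - r3, r2 - r1], axis=1) / (2 * area)[:, None]
    r_cent = (r1 + r2 + r3) / 3.0

    rows, cols, vals = [], [], []
    for i in range(3):
        for j in range(3):
            k_ij = D * (b_r[:, i] * b_r[:, j] + b_z[:, i] * b_z[:, j]) * r_cent * area
            rows.append(elements[:, i])
            cols.append(elements[:, j])
            vals.append(k_ij)

    # lumped mass: w_i = int phi_i r dA by edge-midpoint quadrature
    rm = np.stack([(r1 + r2) / 2, (r2 + r3) / 2, (r3 + r1) / 2], axis=1)
    w_elem = np.empty((len(area), 3))
    # phi_i is 1/2 at the two midpoints of edges containing vertex i
    w_elem[:, 0] = area / 3.0 * 0.5 * (rm[:, 0] + rm[:, 2])
    w_elem[:, 1] = area / 3.0 * 0.5 * (rm[:, 0] + rm[:, 1])
    w_elem[:, 2] = area / 3.0 * 0.5 * (rm[:, 1] + rm[:, 2])
    weights = np.zeros(n)
    np.add.at(weights, elements.ravel(), w_elem.ravel())

    rows.append(np.arange(n))
    cols.append(np.arange(n))
    vals.append(mu_a * weights)

    if bc == "robin":
        # Phi + 2 D dPhi/dn = 0  =>  flux term (1/2) int phi_i phi_j r ds, lumped
        for tag in ("top", "bottom"):
            edges = mesh.boundary[tag]
            e1, e2 = edges[:, 0], edges[:, 1]
            seg = nodes[e2] - nodes[e1]
            length = np.hypot(seg[:, 0], seg[:, 1])
            ra, rb = nodes[e1, 0], nodes[e2, 0]
            # lumped edge weights: int phi_1 r ds = L(2 ra + rb)/6 etc.
            w1 = 0.5 * length * (2 * ra + rb) / 6.0
            w2 = 0.5 * length * (ra + 2 * rb) / 6.0
            rows.append(e1)
            cols.append(e1)
            vals.append(w1)
            rows.append(e2)
            cols.append(e2)
            vals.append(w2)
    elif bc != "neumann":
        raise ValueError(f"unknown boundary condition {bc!r}")

    mat = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()
    return mat, weights


def solve_fluence(mesh: AxisymMesh, medium: DiffusionMedium,
                  source: SourceSpec | None = None, bc: str = "robin",
                  volumetric_source: float = 0.0) -> FluenceMap:
    """Solve the steady-state diffusion equation on the mesh.

    Parameters
    ----------
    source : SourceSpec, optional
        Isotropic point source; its power is deposited at the nearest mesh
        node (the weak-form load P/(2 pi) for the revolved geometry).
    bc : {'robin', 'neumann'}
        'robin' applies the partial-current condition on the top and bottom
        faces (lateral wall and axis are zero-flux); 'neumann' is zero-flux
        everywhere (ill-posed when mu_a = 0).
    volumetric_source : float
        Uniform source density in W/cm^3 added over the whole domain.
    """
    if source is None and volumetric_source == 0.0:
        raise ValueError("need a point source and/or a volumetric source")
    if bc == "neumann" and medium.mu_a == 0.0:
        raise ValueError("mu_a = 0 with all-Neumann boundaries is ill-posed")
    mat, weights = _assemble(mesh, medium, bc)
    rhs = np.zeros(mesh.n_nodes)
    if volumetric_source != 0.0:
        rhs += volumetric_source * weights
    if source is not None:
        if not (0.0 <= source.r <= mesh.radius and 0.0 <= source.z <= mesh.thickness):
            raise ValueError("source lies outside the mesh domain")
        node = mesh.nearest_node(source.r, source.z)
        rhs[node] += source.power / (2.0 * math.pi)
    phi = spla.spsolve(mat.tocsc(), rhs)
    resid = np.linalg.norm(mat @ phi - rhs) / max(np.linalg.norm(rhs), 1e-300)
    if resid > 1e-10:
        raise RuntimeError(f"sparse solve residual {resid:.2e} exceeds 1e-10")
    if np.min(phi) < -1e-12 * np.max(phi):
        raise RuntimeError("solver produced significantly negative fluence")
    phi = np.maximum(phi, np.finfo(float).tiny)
    return FluenceMap(mesh=mesh, phi=phi)


def surface_map(fl: FluenceMap, half_width: float | None = None,
                n_pixels: int = 101) -> SurfaceImage:
    """Revolve the surface fluence profile Phi(r, z=0) into a Cartesian image.

    Returns log10 values on an (n_pixels x n_pixels) grid over
    [-half_width, half_width]^2 (default: the mesh radius), plus the image
    extremes — the quantities used to compare tissue states.
    """
    r, phi = fl.surface_profile()
    if half_width is None:
        half_width = fl.mesh.radius
    x = np.linspace(-half_width, half_width, n_pixels)
    xx, yy = np.meshgrid(x, x, indexing="ij")
    rho = np.hypot(xx, yy)
    vals = np.interp(rho, r, phi, right=phi[-1])
    img = np.log10(np.maximum(vals, np.finfo(float).tiny))
    return SurfaceImage(x=x, log10_phi=img,
                        max_log10=float(img.max()), min_log10=float(img.min()))


def greens_function_infinite(medium: DiffusionMedium, rho, power: float = 1.0):
    """Closed-form point-source fluence in an infinite medium:
    Phi(rho) = P exp(-mu_eff rho) / (4 pi D rho).  Oracle for the FEM solver."""
    rho = np.asarray(rho, dtype=float)
    D = medium.diffusion_coeff
    return power * np.exp(-medium.mu_eff * rho) / (4.0 * math.pi * D * rho)
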