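"""Continuous-wave diffusion forward model on the slab.

Photon transport in the highly scattering breast is modelled by the CW
diffusion equation

    -div(kappa grad Phi) + mu_a Phi = q0        in the slab,
    Phi + 2 kappa zeta (n . grad Phi) = 0       on the surface,

with diffusion coefficient kappa = 1/(3 (mu_a + mu_s')) and internal
reflection factor zeta = (1 + R_f)/(1 - R_f).  The speed of light is set to 1
throughout: CW amplitudes only ever enter the pipeline in ratios, where it
cancels.  The equation is discretized with linear tetrahedral finite elements
on the structured slab mesh; the Robin condition contributes a boundary mass
term, so the system is symmetric positive definite and one sparse
factorization serves every source.

Source/detector coupling: each LED is an isotropic point source buried one
transport mean free path (1/mu_s') beneath its surface position; each
photodiode reads the photon density at the mirrored interior point divided by
2 zeta (the boundary flux implied by the Robin condition).  Using the same
interior coupling for sources and detectors makes every transmission
amplitude exactly reciprocal under source-detector exchange.

:func:`analytic_slab_flux` provides the classical extrapolated-boundary
image-source series for an infinite homogeneous slab as an independent check
of the FEM solution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .calibrate import MeasurementSet
from .errors import GeometryError, SolverError, UnsupportedInputError
from .mesh import SlabMesh
from .probe import ProbeArray, SDPair, enumerate_pairs, retained


def groenhuis_reflection(n: float) -> float:
    """Internal reflection coefficient R_f from the refractive index via the
    Groenhuis polynomial fit, the standard choice for tissue-air interfaces."""
    return -1.440 / n**2 + 0.710 / n + 0.668 + 0.0636 * n


@dataclass(frozen=True)
class OpticalProperties:
    """Homogeneous optical properties of a turbid medium (mm^-1 units).

    ``anisotropy_g`` only matters for Monte Carlo transport; the diffusion
    model uses the reduced scattering coefficient directly.
    """

    mu_a: float
    mu_s_prime: float
    refractive_index: float = 1.33
    anisotropy_g: float = 0.9

    def __post_init__(self):
        if self.mu_a <= 0:
            raise UnsupportedInputError("mu_a must be positive")
        if self.mu_s_prime <= 0:
            raise UnsupportedInputError("mu_s_prime must be positive")
        if not 0 <= self.anisotropy_g < 1:
            raise UnsupportedInputError("anisotropy g must lie in [0, 1)")

    @property
    def R_f(self) -> float:
        return groenhuis_reflection(self.refractive_index)

    @property
    def zeta(self) -> float:
        rf = self.R_f
        if not 0 <= rf < 1:
            raise UnsupportedInputError(f"R_f = {rf:.4f} outside [0, 1)")
        return (1 + rf) / (1 - rf)

    @property
    def kappa(self) -> float:
        """Diffusion coefficient 1/(3 (mu_a + mu_s')) in mm."""
        return 1.0 / (3.0 * (self.mu_a + self.mu_s_prime))

    @property
    def mu_eff(self) -> float:
        """Effective attenuation sqrt(mu_a / kappa) in mm^-1."""
        return float(np.sqrt(self.mu_a / self.kappa))


@dataclass
class FieldSolution:
    """Nodal photon density for one point source."""

    phi: np.ndarray  # (N,) arbitrary CW amplitude units
    source_position: np.ndarray  # (3,) injection point (mm)
    source_strength: float = 1.0


class SlabSolver:
    """Assembles and factorizes the FEM diffusion operator for a slab mesh.

    Element geometry (gradients, volumes, unit stiffness/mass matrices) is
    precomputed once; reassembly after a nodal mu_a update only recomputes the
    element coefficients, which is what the iterative reconstruction needs.
    """

    def __init__(self, mesh: SlabMesh, refractive_index: float = 1.33):
        if mesh.mu_a is None or mesh.mu_s_prime is None:
            raise SolverError("mesh has no nodal optical properties")
        self.mesh = mesh
        self.refractive_index = refractive_index
        rf = groenhuis_reflection(refractive_index)
        self.zeta = (1 + rf) / (1 - rf)
        self._precompute_geometry()
        self._lu = None

    def _precompute_geometry(self):
        """Tensor-product Q1 element matrices from per-cell sizes.

        For a rectangular cell (dx, dy, dz) the stiffness and mass matrices
        are Kronecker combinations of the 1D P1 matrices, so the unit tensors
        from :mod:`platedot.mesh` just need size weights per cell.
        """
        from .mesh import UNIT_FACE_M, UNIT_KX, UNIT_KY, UNIT_KZ, UNIT_M

        mesh = self.mesh
        dx, dy, dz = mesh.cell_sizes.T
        self.volumes = mesh.cell_volumes
        if np.any(self.volumes <= 0):
            raise SolverError("degenerate cell with non-positive volume")
        self.Ke = (
            (dy * dz / dx)[:, None, None] * UNIT_KX[None]
            + (dx * dz / dy)[:, None, None] * UNIT_KY[None]
            + (dx * dy / dz)[:, None, None] * UNIT_KZ[None]
        )
        self.Me = self.volumes[:, None, None] * UNIT_M[None]
        # boundary mass (Robin term), coefficient 1/(2 zeta)
        f = mesh.boundary_faces
        areas = mesh.boundary_face_sizes.prod(axis=1)
        Be = areas[:, None, None] * UNIT_FACE_M[None]
        ii = np.repeat(f, 4, axis=1).ravel()
        jj = np.tile(f, (1, 4)).ravel()
        N = mesh.n_nodes
        self._B = sp.coo_matrix((Be.ravel(), (ii, jj)), shape=(N, N)).tocsr()
        el = mesh.elements
        self._el_ii = np.repeat(el, 8, axis=1).ravel()
        self._el_jj = np.tile(el, (1, 8)).ravel()

    def element_mu_a(self) -> np.ndarray:
        return self.mesh.mu_a[self.mesh.elements].mean(axis=1)

    def element_kappa(self) -> np.ndarray:
        mu_a = self.element_mu_a()
        mu_sp = self.mesh.mu_s_prime[self.mesh.elements].mean(axis=1)
        return 1.0 / (3.0 * (mu_a + mu_sp))

    def assemble(self) -> sp.csc_matrix:
        kappa = self.element_kappa()
        mu_a = self.element_mu_a()
        data = (kappa[:, None, None] * self.Ke + mu_a[:, None, None] * self.Me).ravel()
        N = self.mesh.n_nodes
        A = sp.coo_matrix((data, (self._el_ii, self._el_jj)), shape=(N, N)).tocsr()
        return (A + self._B / (2.0 * self.zeta)).tocsc()

    def factorize(self):
        try:
            self._lu = spla.splu(self.assemble())
        except RuntimeError as exc:  # pragma: no cover - singular systems
            raise SolverError(f"factorization failed: {exc}") from exc
        return self

    def solve_point_sources(self, points, strengths=None) -> np.ndarray:
        """Fields (n_points, N) for unit (or given-strength) point loads."""
        if self._lu is None:
            self.factorize()
        points = np.atleast_2d(np.asarray(points, float))
        rhs = np.zeros((self.mesh.n_nodes, len(points)))
        for k, p in enumerate(points):
            nodes, weights = self.mesh.trilinear_weights(p)
            s = 1.0 if strengths is None else float(strengths[k])
            rhs[nodes, k] += weights * s
        return self._lu.solve(rhs).T

    def read_amplitude(self, phi: np.ndarray, point) -> float:
        """Detector amplitude Phi(conjugate point)/(2 zeta)."""
        nodes, weights = self.mesh.trilinear_weights(point)
        return float(np.dot(phi[nodes], weights) / (2.0 * self.zeta))


def _conjugate_points(probe: ProbeArray, mu_s_prime_bg: float):
    """Interior coupling points one transport mean free path inside each plate."""
    depth = 1.0 / mu_s_prime_bg
    src = probe.source_positions.copy()
    det = probe.detector_positions.copy()
    src[:, 0] += depth
    det[:, 0] -= depth
    return src, det


def _validate_probe_on_slab(mesh: SlabMesh, probe: ProbeArray):
    Lx, Ly, Lz = mesh.extent
    if abs(probe.plate_separation - Lx) > 1e-6:
        raise GeometryError(
            f"plate separation {probe.plate_separation} mm does not match "
            f"slab thickness {Lx} mm"
        )
    for pos in np.vstack([probe.source_positions, probe.detector_positions]):
        if not (-1e-9 <= pos[1] <= Ly + 1e-9 and -1e-9 <= pos[2] <= Lz + 1e-9):
            raise GeometryError(f"optode at {pos} lies outside the slab face")


def solve_cw(
    mesh: SlabMesh,
    probe: ProbeArray,
    active_sources=None,
    pairs: list[SDPair] | None = None,
    source_strength: float = 1.0,
    wavelength_nm: float = 750.0,
    solver: SlabSolver | None = None,
):
    """Solve the CW diffusion equation for each source and evaluate every
    retained SD pair's transmission amplitude.

    Returns ``(fields, measurements)`` where ``fields`` is a list of
    :class:`FieldSolution` (one per active source, in source-index order) and
    ``measurements`` has role ``predicted``.  ``active_sources`` is a 1-based
    index list (default: all sources appearing in ``pairs``).
    """
    _validate_probe_on_slab(mesh, probe)
    if pairs is None:
        pairs = enumerate_pairs(probe)
    if solver is None:
        solver = SlabSolver(mesh).factorize()
    elif solver._lu is None:
        solver.factorize()
    mu_sp_bg = float(np.median(mesh.mu_s_prime))
    src_pts, det_pts = _conjugate_points(probe, mu_sp_bg)
    needed = sorted({p.source_index for p in retained(pairs)})
    if active_sources is not None:
        active = sorted(int(s) for s in active_sources)
        missing = set(needed) - set(active)
        if missing:
            raise GeometryError(f"pairs reference inactive sources {sorted(missing)}")
        needed = active
    phis = solver.solve_point_sources(
        src_pts[[s - 1 for s in needed]],
        strengths=[source_strength] * len(needed),
    )
    fields = [
        FieldSolution(phi=phis[k], source_position=src_pts[s - 1], source_strength=source_strength)
        for k, s in enumerate(needed)
    ]
    by_source = {s: phis[k] for k, s in enumerate(needed)}
    amplitudes = np.full(len(pairs), np.nan)
    for p, pair in enumerate(pairs):
        if pair.excluded:
            continue
        amplitudes[p] = solver.read_amplitude(
            by_source[pair.source_index], det_pts[pair.detector_index - 1]
        )
    ms = MeasurementSet.from_pairs(
        pairs, amplitudes, wavelength_nm=wavelength_nm, role="predicted",
        meta={"generator": "diffusion_fem", "mesh_nodes": mesh.n_nodes},
    )
    if np.any(ms.amplitude[~ms.excluded] <= 0):
        raise SolverError("non-positive predicted amplitude; mesh too coarse?")
    return fields, ms


def analytic_slab_flux(
    props: OpticalProperties,
    probe: ProbeArray,
    pairs: list[SDPair] | None = None,
    rtol: float = 1e-12,
    wavelength_nm: float = 750.0,
) -> MeasurementSet:
    """Transmission amplitudes for an infinite homogeneous slab via the
    extrapolated-boundary image-source series.

    The slab thickness equals the plate separation; lateral boundaries are
    ignored, so amplitudes depend only on the lateral offset (|dy|, |dz|) and
    are identical within a distance class.  The detector model matches the
    FEM one: photon density at the conjugate interior point over 2 zeta.
    """
    if not isinstance(props, OpticalProperties):
        raise UnsupportedInputError(
            "analytic slab flux requires homogeneous OpticalProperties"
        )
    if pairs is None:
        pairs = enumerate_pairs(probe)
    s = probe.plate_separation
    kappa = props.kappa
    zeta = props.zeta
    mu_eff = props.mu_eff
    z0 = 1.0 / props.mu_s_prime
    ze = 2.0 * kappa * zeta
    period = 2.0 * (s + 2.0 * ze)

    keep = ~np.array([p.excluded for p in pairs])
    src = probe.source_positions
    det = probe.detector_positions
    rho = np.array(
        [
            np.hypot(
                src[p.source_index - 1, 1] - det[p.detector_index - 1, 1],
                src[p.source_index - 1, 2] - det[p.detector_index - 1, 2],
            )
            for p in pairs
        ]
    )
    z_eval = s - z0  # conjugate detector depth

    def green(dz):
        r = np.sqrt(rho**2 + dz**2)
        r = np.maximum(r, 1e-9)
        return np.exp(-mu_eff * r) / (4.0 * np.pi * kappa * r)

    phi = np.zeros(len(pairs))
    m = 0
    while True:
        term = np.zeros(len(pairs))
        for mm in ((m,) if m == 0 else (m, -m)):
            z_plus = mm * period + z0
            z_minus = mm * period - 2.0 * ze - z0
            term += green(z_eval - z_plus) - green(z_eval - z_minus)
        phi += term
        m += 1
        scale = np.max(np.abs(phi))
        if scale > 0 and np.max(np.abs(term)) < rtol * scale:
            break
        if m > 1000:  # pragma: no cover - safety net
            break
    amplitudes = np.where(keep, phi / (2.0 * zeta), np.nan)
    return MeasurementSet.from_pairs(
        pairs, amplitudes, wavelength_nm=wavelength_nm, role="predicted",
        meta={"generator": "analytic_slab"},
    )
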