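"""Structured hexahedral meshing of the slab domain.

The imaging domain is a rectangular slab: thickness along x (between the two
plates) and lateral extents along y and z.  The mesh is a structured lattice
of nodes; each cell is a rectangular hexahedron carrying trilinear (Q1)
shape functions.  Tensor-product elements keep the discrete operator fully
symmetric under the lattice's reflections, so source-detector pairs related
by a mirror see identical numerics — important when distance classes are
compared against each other.  Nodal optical properties (mu_a, mu_s') live on
the lattice, so fields can be interpolated trilinearly and resampled to
regular grids for image output.

Element node ordering within a cell is (dx, dy, dz) bit order with dz
fastest: local index = 4*dx + 2*dy + dz.  This matches the Kronecker-product
structure of the element matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError

# 1D P1 unit matrices on [0, 1]: stiffness (scale 1/h) and mass (scale h).
_K1 = np.array([[1.0, -1.0], [-1.0, 1.0]])
_M1 = np.array([[1.0 / 3.0, 1.0 / 6.0], [1.0 / 6.0, 1.0 / 3.0]])


def _kron3(a, b, c):
    return np.kron(a, np.kron(b, c))


#: unit 8x8 tensors; element matrices are size-weighted combinations of these
UNIT_KX = _kron3(_K1, _M1, _M1)
UNIT_KY = _kron3(_M1, _K1, _M1)
UNIT_KZ = _kron3(_M1, _M1, _K1)
UNIT_M = _kron3(_M1, _M1, _M1)
#: unit 4x4 boundary (face) mass tensor
UNIT_FACE_M = np.kron(_M1, _M1)


@dataclass
class SlabMesh:
    """Structured Q1 FEM discretization of the slab with nodal properties.

    Nodes are lattice-major: ``node_id = (ix * ny + iy) * nz + iz`` with
    ``(nx, ny, nz) = lattice_shape``; the lattice coordinates along each axis
    are in ``axes`` (not necessarily uniform — plate-depth and optode planes
    may be inserted).
    """

    nodes: np.ndarray  # (N, 3) mm
    elements: np.ndarray  # (M, 8) node indices, bit order 4dx+2dy+dz
    cell_sizes: np.ndarray  # (M, 3) dx, dy, dz per cell (mm)
    boundary_faces: np.ndarray  # (F, 4) node indices, bit order 2da+db
    boundary_face_sizes: np.ndarray  # (F, 2) in-plane spans (mm)
    boundary_normals: np.ndarray  # (F, 3) outward unit normals
    axes: tuple[np.ndarray, np.ndarray, np.ndarray]
    lattice_shape: tuple[int, int, int]
    extent: tuple[float, float, float]
    mu_a: np.ndarray = field(default=None)  # (N,) mm^-1
    mu_s_prime: np.ndarray = field(default=None)  # (N,) mm^-1
    region_labels: np.ndarray = field(default=None)  # (M,) int tags

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @property
    def cell_volumes(self) -> np.ndarray:
        return self.cell_sizes.prod(axis=1)

    def copy(self) -> "SlabMesh":
        return SlabMesh(
            nodes=self.nodes,
            elements=self.elements,
            cell_sizes=self.cell_sizes,
            boundary_faces=self.boundary_faces,
            boundary_face_sizes=self.boundary_face_sizes,
            boundary_normals=self.boundary_normals,
            axes=self.axes,
            lattice_shape=self.lattice_shape,
            extent=self.extent,
            mu_a=None if self.mu_a is None else self.mu_a.copy(),
            mu_s_prime=None if self.mu_s_prime is None else self.mu_s_prime.copy(),
            region_labels=None if self.region_labels is None else self.region_labels.copy(),
        )

    def set_homogeneous(self, mu_a: float, mu_s_prime: float) -> None:
        self.mu_a = np.full(self.n_nodes, float(mu_a))
        self.mu_s_prime = np.full(self.n_nodes, float(mu_s_prime))
        self.region_labels = np.zeros(self.n_elements, dtype=np.int32)

    def nodal_lattice(self, values: np.ndarray) -> np.ndarray:
        """Reshape a nodal array onto the (nx, ny, nz) lattice."""
        return np.asarray(values).reshape(self.lattice_shape)

    def node_volumes(self) -> np.ndarray:
        """Lumped (tributary) volume of every node (mm^3)."""
        vols = np.zeros(self.n_nodes)
        np.add.at(
            vols,
            self.elements.ravel(),
            np.repeat(self.cell_volumes / 8.0, 8),
        )
        return vols

    def trilinear_weights(self, point) -> tuple[np.ndarray, np.ndarray]:
        """Node indices and trilinear weights of a point inside the slab.

        Used both to inject point loads and to read fields; using the same
        weight function for sources and detectors makes transmission
        amplitudes exactly reciprocal under source-detector exchange.
        """
        point = np.asarray(point, float)
        idx = np.empty(3, dtype=np.int64)
        frac = np.empty(3)
        for a in range(3):
            ax = self.axes[a]
            if not (ax[0] - 1e-9 <= point[a] <= ax[-1] + 1e-9):
                raise GeometryError(
                    f"point {point} outside slab extent along axis {a} "
                    f"([{ax[0]}, {ax[-1]}])"
                )
            i = int(np.searchsorted(ax, point[a], side="right")) - 1
            i = min(max(i, 0), len(ax) - 2) if len(ax) > 1 else 0
            idx[a] = i
            h = ax[i + 1] - ax[i] if len(ax) > 1 else 1.0
            frac[a] = (point[a] - ax[i]) / h
        frac = np.clip(frac, 0.0, 1.0)
        nx, ny, nz = self.lattice_shape
        nodes = []
        weights = []
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    w = (
                        (frac[0] if dx else 1 - frac[0])
                        * (frac[1] if dy else 1 - frac[1])
                        * (frac[2] if dz else 1 - frac[2])
                    )
                    n = ((idx[0] + dx) * ny + (idx[1] + dy)) * nz + (idx[2] + dz)
                    nodes.append(n)
                    weights.append(w)
        return np.array(nodes), np.array(weights)

    def interpolate(self, values: np.ndarray, points: np.ndarray) -> np.ndarray:
        """Trilinear interpolation of a nodal field at arbitrary points."""
        points = np.atleast_2d(points)
        out = np.empty(len(points))
        for k, p in enumerate(points):
            n, w = self.trilinear_weights(p)
            out[k] = float(np.dot(np.asarray(values)[n], w))
        return out


def _insert_plane(ax: np.ndarray, value: float, tol: float = 1e-6) -> np.ndarray:
    if np.min(np.abs(ax - value)) > tol:
        ax = np.sort(np.append(ax, value))
    return ax


def build_slab_mesh(
    extent,
    h: float = 3.0,
    plate_depth: float | None = None,
    snap_yz=None,
) -> SlabMesh:
    """Mesh a slab of ``extent = (Lx, Ly, Lz)`` mm at nominal cell size h.

    The cell count per axis is ``round(L / h)`` (at least 1), so the outer
    faces lie exactly on the slab surfaces.  ``plate_depth`` (mm) inserts
    lattice planes at x = plate_depth and x = Lx - plate_depth so optode
    coupling points one transport mean free path inside the plates fall
    exactly on nodes.  ``snap_yz = (y_values, z_values)`` inserts lateral
    planes at the optode coordinates so every source/detector couples to the
    lattice identically; nearby regular planes (< 0.3 h away) are dropped to
    avoid sliver cells.
    """
    extent = tuple(float(v) for v in extent)
    if any(v <= 0 for v in extent) or h <= 0:
        raise GeometryError("slab extent and element size must be positive")
    ncells = [max(1, int(round(L / h))) for L in extent]
    axes = [np.linspace(0.0, extent[a], ncells[a] + 1) for a in range(3)]
    if plate_depth is not None:
        if not 0 < plate_depth < extent[0] / 2:
            raise GeometryError("plate_depth must lie strictly inside the slab half")
        for value in (plate_depth, extent[0] - plate_depth):
            axes[0] = _insert_plane(axes[0], value)
    if snap_yz is not None:
        for a, values in ((1, snap_yz[0]), (2, snap_yz[1])):
            snapped = np.unique(np.round(np.asarray(values, float), 9))
            ax = axes[a]
            for value in snapped:
                if not 0 <= value <= extent[a]:
                    raise GeometryError(
                        f"snap coordinate {value} outside slab extent along axis {a}"
                    )
                ax = _insert_plane(ax, value)
            keep = np.ones(len(ax), bool)
            for k in range(1, len(ax) - 1):
                d = np.min(np.abs(snapped - ax[k]))
                if 1e-6 < d < 0.3 * h:
                    keep[k] = False
            axes[a] = ax[keep]
    axes = tuple(axes)

    nx, ny, nz = (len(ax) for ax in axes)
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    ix, iy, iz = np.meshgrid(
        np.arange(nx - 1), np.arange(ny - 1), np.arange(nz - 1), indexing="ij"
    )
    ix, iy, iz = ix.ravel(), iy.ravel(), iz.ravel()

    def node_id(dx, dy, dz):
        return ((ix + dx) * ny + (iy + dy)) * nz + (iz + dz)

    elements = np.column_stack(
        [node_id(dx, dy, dz) for dx in (0, 1) for dy in (0, 1) for dz in (0, 1)]
    ).astype(np.int64)
    dx = np.diff(axes[0])[ix]
    dy = np.diff(axes[1])[iy]
    dz = np.diff(axes[2])[iz]
    cell_sizes = np.column_stack([dx, dy, dz])

    faces = []
    face_sizes = []
    normals = []

    def face_grid(axis, fixed_index, sign):
        """Quads covering one outer face of the slab."""
        other = [a for a in range(3) if a != axis]
        na, nb = len(axes[other[0]]), len(axes[other[1]])
        ia, ib = np.meshgrid(np.arange(na - 1), np.arange(nb - 1), indexing="ij")
        ia, ib = ia.ravel(), ib.ravel()

        def nid(da, db):
            lattice = [0, 0, 0]
            grid = {axis: fixed_index, other[0]: ia + da, other[1]: ib + db}
            gx = np.full(len(ia), grid[0]) if np.isscalar(grid[0]) else grid[0]
            gy = np.full(len(ia), grid[1]) if np.isscalar(grid[1]) else grid[1]
            gz = np.full(len(ia), grid[2]) if np.isscalar(grid[2]) else grid[2]
            return (gx * ny + gy) * nz + gz

        quad = np.column_stack([nid(da, db) for da in (0, 1) for db in (0, 1)])
        faces.append(quad)
        face_sizes.append(
            np.column_stack(
                [np.diff(axes[other[0]])[ia], np.diff(axes[other[1]])[ib]]
            )
        )
        n = np.zeros((len(ia), 3))
        n[:, axis] = sign
        normals.append(n)

    for axis, count in ((0, nx), (1, ny), (2, nz)):
        face_grid(axis, 0, -1.0)
        face_grid(axis, count - 1, +1.0)

    return SlabMesh(
        nodes=nodes,
        elements=elements,
        cell_sizes=cell_sizes,
        boundary_faces=np.vstack(faces).astype(np.int64),
        boundary_face_sizes=np.vstack(face_sizes),
        boundary_normals=np.vstack(normals),
        axes=axes,
        lattice_shape=(nx, ny, nz),
        extent=extent,
    )
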