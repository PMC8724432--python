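"""Parallel-plate source/detector geometry.

The imager consists of two parallel plates: LEDs on the plane x = 0 and
photodiodes on the plane x = plate_separation, with each detector mounted at
the mirror position of the opposite source.  Transmission amplitudes are
collected for every source-detector (SD) combination.  Because the grids are
regular, many SD pairs share the same Euclidean distance; those pairs form a
*distance class*, the unit on which the self-calibration method operates.

Coordinate convention (mm): x runs through the plates (source plane x = 0,
detector plane x = plate_separation), y is the row axis, z is the column
axis.  Source/detector indices are 1-based in all public interfaces.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError, InvalidInputError, NoDataError, SelectionFailureError

#: SD pairs farther apart than this are dropped before self-calibration (mm).
DEFAULT_MAX_DISTANCE_MM = 110.0
#: Coefficient-of-variation threshold separating boundary from non-boundary pairs.
DEFAULT_COV_THRESHOLD = 0.3
#: Squared-distance rounding tolerance used when grouping pairs (mm^2).
DEFAULT_GROUP_TOLERANCE_MM2 = 1e-6


@dataclass(frozen=True)
class ProbeArray:
    """Mirrored source/detector grids on two parallel plates.

    Index ``k`` (1-based) maps to grid position ``row = (k-1) // n_cols``,
    ``col = (k-1) % n_cols``; detector ``k`` shares (y, z) with source ``k``.
    ``origin_yz`` shifts the whole grid laterally, e.g. to centre it on a slab.
    """

    n_rows: int
    n_cols: int
    row_spacing: float
    col_spacing: float
    plate_separation: float
    origin_yz: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if self.n_rows < 1 or self.n_cols < 1:
            raise GeometryError("grid counts must be >= 1")
        for name in ("row_spacing", "col_spacing", "plate_separation"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be positive")

    @property
    def I(self) -> int:  # noqa: E743 - conventional symbol for the source count
        return self.n_rows * self.n_cols

    @property
    def J(self) -> int:
        return self.n_rows * self.n_cols

    def _grid_yz(self) -> np.ndarray:
        rows = np.arange(self.n_rows) * self.row_spacing + self.origin_yz[0]
        cols = np.arange(self.n_cols) * self.col_spacing + self.origin_yz[1]
        yy, zz = np.meshgrid(rows, cols, indexing="ij")
        return np.column_stack([yy.ravel(), zz.ravel()])

    @property
    def source_positions(self) -> np.ndarray:
        """(I, 3) source coordinates, all on the plane x = 0."""
        yz = self._grid_yz()
        return np.column_stack([np.zeros(len(yz)), yz])

    @property
    def detector_positions(self) -> np.ndarray:
        """(J, 3) detector coordinates, mirror images on x = plate_separation."""
        yz = self._grid_yz()
        return np.column_stack([np.full(len(yz), self.plate_separation), yz])

    def grid_position(self, index: int) -> tuple[int, int]:
        """(row, col) of a 1-based source/detector index."""
        if not 1 <= index <= self.I:
            raise InvalidInputError(f"index {index} outside [1, {self.I}]")
        return (index - 1) // self.n_cols, (index - 1) % self.n_cols

    def centered_on(self, y_center: float, z_center: float) -> "ProbeArray":
        """Copy of this probe with the grid centre moved to (y_center, z_center)."""
        y0 = y_center - (self.n_rows - 1) * self.row_spacing / 2.0
        z0 = z_center - (self.n_cols - 1) * self.col_spacing / 2.0
        return dataclasses.replace(self, origin_yz=(y0, z0))


@dataclass
class SDPair:
    """One source-detector combination with its separation and exclusion state."""

    source_index: int
    detector_index: int
    distance: float
    excluded: bool = False
    reason: str | None = None

    @property
    def key(self) -> tuple[int, int]:
        return (self.source_index, self.detector_index)


@dataclass
class DistanceClass:
    """The set of retained SD pairs sharing one SD distance d_k.

    ``class_max`` (the per-distance maximum amplitude) and ``cov``
    (std/mean of member amplitudes) are populated by
    :meth:`attach_measurements`.
    """

    d_k: float
    members: list[SDPair] = field(default_factory=list)
    class_max: float | None = None
    cov: float | None = None

    def __len__(self) -> int:
        return len(self.members)

    def attach_measurements(self, measurements) -> np.ndarray:
        """Record the class maximum and coefficient of variation from a
        measurement set; returns the member amplitudes in member order."""
        amps = np.array(
            [measurements.amplitude_at(p.source_index, p.detector_index) for p in self.members]
        )
        self.class_max = float(amps.max())
        mean = float(amps.mean())
        self.cov = float(amps.std() / mean) if mean > 0 else float("inf")
        return amps


def build_probe(
    n_rows: int,
    n_cols: int,
    row_spacing: float,
    col_spacing: float,
    plate_separation: float,
    origin_yz: tuple[float, float] = (0.0, 0.0),
) -> ProbeArray:
    """Construct mirrored source/detector grids on two parallel plates."""
    return ProbeArray(
        n_rows=int(n_rows),
        n_cols=int(n_cols),
        row_spacing=float(row_spacing),
        col_spacing=float(col_spacing),
        plate_separation=float(plate_separation),
        origin_yz=(float(origin_yz[0]), float(origin_yz[1])),
    )


def enumerate_pairs(probe: ProbeArray) -> list[SDPair]:
    """All I x J SD pairs in source-major order, each with its Euclidean distance."""
    src = probe.source_positions
    det = probe.detector_positions
    diff = src[:, None, :] - det[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    pairs = []
    for i in range(probe.I):
        for j in range(probe.J):
            pairs.append(SDPair(i + 1, j + 1, float(dist[i, j])))
    return pairs


def retained(pairs: list[SDPair]) -> list[SDPair]:
    """The non-excluded subset of a pair list, original order preserved."""
    return [p for p in pairs if not p.excluded]


def group_by_distance(
    pairs: list[SDPair],
    tolerance: float = DEFAULT_GROUP_TOLERANCE_MM2,
) -> list[DistanceClass]:
    """Partition retained pairs into distance classes, sorted by d_k ascending.

    The grouping key is the squared distance rounded to ``tolerance`` (mm^2),
    which is exact for integer-millimetre grid pitches and immune to
    floating-point noise well below the tolerance.
    """
    if not pairs:
        raise NoDataError("empty pair list")
    if tolerance < 0:
        raise InvalidInputError("tolerance must be >= 0")
    tol = tolerance if tolerance > 0 else DEFAULT_GROUP_TOLERANCE_MM2
    groups: dict[int, DistanceClass] = {}
    for p in retained(pairs):
        key = int(round(p.distance * p.distance / tol))
        cls = groups.get(key)
        if cls is None:
            groups[key] = cls = DistanceClass(d_k=p.distance)
        cls.members.append(p)
    return sorted(groups.values(), key=lambda c: c.d_k)


def _normalize_coverage(coverage_mask, I: int, J: int):
    """Accept either one mask (applied to both mirrored grids) or a
    (source_mask, detector_mask) pair; return boolean arrays of length I, J."""
    if coverage_mask is None:
        return np.ones(I, bool), np.ones(J, bool)
    if isinstance(coverage_mask, tuple) and len(coverage_mask) == 2:
        smask = np.asarray(coverage_mask[0], bool)
        dmask = np.asarray(coverage_mask[1], bool)
    else:
        smask = np.asarray(coverage_mask, bool)
        dmask = smask
    if len(smask) != I or len(dmask) != J:
        raise InvalidInputError(
            f"coverage mask length ({len(smask)}, {len(dmask)}) does not match (I={I}, J={J})"
        )
    return smask, dmask


def apply_exclusions(
    pairs: list[SDPair],
    coverage_mask=None,
    max_distance: float = DEFAULT_MAX_DISTANCE_MM,
) -> list[SDPair]:
    """Flag pairs whose endpoints are uncovered by the imaging object or whose
    SD distance exceeds ``max_distance``; returns a new list in input order.

    ``coverage_mask`` marks covered sources/detectors (1-based index order);
    either a single boolean sequence applied to both mirrored grids or a
    ``(source_mask, detector_mask)`` tuple.
    """
    I = max((p.source_index for p in pairs), default=0)
    J = max((p.detector_index for p in pairs), default=0)
    smask, dmask = _normalize_coverage(coverage_mask, I, J)
    out = []
    for p in pairs:
        if not (smask[p.source_index - 1] and dmask[p.detector_index - 1]):
            out.append(dataclasses.replace(p, excluded=True, reason="uncovered"))
        elif p.distance > max_distance:
            out.append(dataclasses.replace(p, excluded=True, reason="over_max_distance"))
        else:
            out.append(dataclasses.replace(p, excluded=False, reason=None))
    return out


@dataclass
class SelectionResult:
    """Outcome of the non-boundary ring-peeling selection."""

    pairs: list[SDPair]
    classes: list[DistanceClass]
    report: list[dict]


def _peel_report(classes, measurements, iteration, active_rows, active_cols):
    covs = {}
    for cls in classes:
        cls.attach_measurements(measurements)
        if len(cls) >= 2:
            covs[round(cls.d_k, 6)] = cls.cov
    max_cov = max(covs.values()) if covs else 0.0
    return {
        "iteration": iteration,
        "active_rows": active_rows,
        "active_cols": active_cols,
        "n_pairs": sum(len(c) for c in classes),
        "class_cov": covs,
        "max_cov": max_cov,
        "data_role": getattr(measurements, "role", "unknown"),
    }


def select_non_boundary(
    probe: ProbeArray,
    classes: list[DistanceClass],
    measurements,
    cov_threshold: float = DEFAULT_COV_THRESHOLD,
    tolerance: float = DEFAULT_GROUP_TOLERANCE_MM2,
) -> SelectionResult:
    """Iteratively peel the outermost ring of sources/detectors until every
    distance class with >= 2 members has CoV = std/mean <= ``cov_threshold``.

    On a large homogeneous medium, pairs near the lateral boundary of the
    imaged object see systematically different flux than central pairs at the
    same SD distance, inflating the within-class spread.  Removing the outer
    ring of the (mirrored) grids restores class uniformity.  The CoV here is
    computed on whatever measurement set is supplied — with task data this is
    the clinically available choice; the report records the data role used.

    Raises :class:`SelectionFailureError` with the per-iteration CoV report if
    the grid cannot shrink further while a class still violates the threshold.
    """
    pairs = [p for cls in classes for p in cls.members]
    if not pairs:
        raise NoDataError("no retained pairs to select from")
    r0, r1 = 0, probe.n_rows  # active row range [r0, r1)
    c0, c1 = 0, probe.n_cols
    report: list[dict] = []
    iteration = 0
    while True:
        active = []
        for p in pairs:
            sr, sc = probe.grid_position(p.source_index)
            dr, dc = probe.grid_position(p.detector_index)
            if all(r0 <= r < r1 for r in (sr, dr)) and all(c0 <= c < c1 for c in (sc, dc)):
                active.append(p)
        if not active:
            raise SelectionFailureError("ring peeling removed every pair", report)
        current = group_by_distance(active, tolerance)
        entry = _peel_report(current, measurements, iteration, (r0, r1), (c0, c1))
        report.append(entry)
        if entry["max_cov"] <= cov_threshold:
            return SelectionResult(active, current, report)
        can_peel_rows = (r1 - r0) >= 3
        can_peel_cols = (c1 - c0) >= 3
        if not (can_peel_rows or can_peel_cols):
            raise SelectionFailureError(
                f"grid cannot shrink further; max CoV {entry['max_cov']:.4f} "
                f"> threshold {cov_threshold}",
                report,
            )
        if can_peel_rows:
            r0, r1 = r0 + 1, r1 - 1
        if can_peel_cols:
            c0, c1 = c0 + 1, c1 - 1
        iteration += 1
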