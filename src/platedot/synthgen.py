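"""Synthetic phantoms, simulated measurement sets and scenario presets.

Everything the pipeline consumes can be generated here: a breast-size slab
phantom (44 mm between the plates, 130 x 79 mm lateral) with cylindrical
absorbing inclusions, its homogeneous twin for reference scans, simulated
task/reference amplitude tables with per-channel gain and noise corruption,
and named presets reproducing the baseline two-target experiment plus its
position / size / contrast robustness sweeps.

The default study conditions: background mu_a = 0.004 mm^-1,
mu_s' = 1 mm^-1, g = 0.9, n = 1.33; two cylindrical targets of radius
7.5 mm and height 10 mm (axis along x, i.e. through-plate), centred at
(17, 45, 42) and (17, 85, 42) mm, absorption three times background; mirrored
3 x 4 source/detector grids at 13 / 14 mm pitch centred on the slab face,
plate separation 44 mm.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .calibrate import MeasurementSet
from .errors import PhantomSpecError, PresetLookupError
from .forward import OpticalProperties, solve_cw
from .mesh import SlabMesh, build_slab_mesh
from .probe import ProbeArray, build_probe, enumerate_pairs

#: slab extent (x=through-plate thickness, y, z) in mm
DEFAULT_SLAB_SHAPE = (44.0, 130.0, 79.0)
DEFAULT_BACKGROUND = OpticalProperties(
    mu_a=0.004, mu_s_prime=1.0, refractive_index=1.33, anisotropy_g=0.9
)
#: generation mesh cell size (mm); optode and plate-depth planes are snapped
DEFAULT_GENERATION_H = 3.0


@dataclass(frozen=True)
class Cylinder:
    """Cylindrical inclusion with axis along a coordinate direction."""

    center: tuple[float, float, float]  # mm
    radius: float  # mm
    height: float  # mm
    mu_a: float  # mm^-1
    axis: str = "x"
    mu_s_prime: float | None = None  # None: same as background

    def contains(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(points)
        ax = "xyz".index(self.axis)
        lat = [a for a in range(3) if a != ax]
        c = np.asarray(self.center)
        axial = np.abs(points[:, ax] - c[ax]) <= self.height / 2.0 + 1e-9
        radial = (
            (points[:, lat[0]] - c[lat[0]]) ** 2
            + (points[:, lat[1]] - c[lat[1]]) ** 2
        ) <= self.radius**2 + 1e-9
        return axial & radial

    def bounds(self):
        ax = "xyz".index(self.axis)
        c = np.asarray(self.center)
        lo, hi = c.copy(), c.copy()
        lo[ax] -= self.height / 2.0
        hi[ax] += self.height / 2.0
        for a in range(3):
            if a != ax:
                lo[a] -= self.radius
                hi[a] += self.radius
        return lo, hi


@dataclass(frozen=True)
class PhantomSpec:
    """Slab phantom: background optics plus absorbing cylindrical targets."""

    slab_shape: tuple[float, float, float] = DEFAULT_SLAB_SHAPE
    background: OpticalProperties = DEFAULT_BACKGROUND
    inclusions: tuple[Cylinder, ...] = ()
    name: str = "custom"

    def __post_init__(self):
        for inc in self.inclusions:
            lo, hi = inc.bounds()
            if np.any(lo < -1e-9) or np.any(hi > np.asarray(self.slab_shape) + 1e-9):
                raise PhantomSpecError(
                    f"inclusion at {inc.center} (R={inc.radius}) extends outside "
                    f"the slab {self.slab_shape}"
                )
            if inc.mu_a < self.background.mu_a:
                raise PhantomSpecError(
                    "inclusions must be absorbing (mu_a >= background)"
                )

    @property
    def homogeneous_twin(self) -> "PhantomSpec":
        return dataclasses.replace(self, inclusions=(), name=self.name + "_twin")


@dataclass
class ChannelGainModel:
    """Multiplicative per-channel corruption of a measurement session.

    measurement = global_scale * g_s(i) * g_d(j) * amp_true * (1 + noise),
    floored at zero.  One realization represents one hardware state and is
    applied identically to the task and reference scans of a session.
    """

    global_scale: float = 1.0
    source_gains: np.ndarray | None = None  # (I,) positive factors
    detector_gains: np.ndarray | None = None  # (J,)
    multiplicative_sigma: float = 0.0
    additive_floor: float = 0.0
    seed: int = 0

    @classmethod
    def identity(cls) -> "ChannelGainModel":
        return cls()

    @classmethod
    def random(
        cls,
        n_sources: int,
        n_detectors: int,
        gain_sigma: float = 0.05,
        noise_sigma: float = 0.0,
        global_scale: float = 1.0,
        seed: int = 0,
    ) -> "ChannelGainModel":
        """Log-normal per-channel gains (median 1, log-sd ``gain_sigma``)."""
        rng = np.random.default_rng(seed)
        return cls(
            global_scale=global_scale,
            source_gains=np.exp(rng.normal(0.0, gain_sigma, n_sources)),
            detector_gains=np.exp(rng.normal(0.0, gain_sigma, n_detectors)),
            multiplicative_sigma=noise_sigma,
            additive_floor=0.0,
            seed=seed,
        )

    def apply(self, ms: MeasurementSet, rng: np.random.Generator) -> MeasurementSet:
        amp = ms.amplitude.copy()
        gs = self.source_gains
        gd = self.detector_gains
        factors = np.full(len(amp), self.global_scale)
        if gs is not None:
            factors *= np.asarray(gs)[ms.source_index - 1]
        if gd is not None:
            factors *= np.asarray(gd)[ms.detector_index - 1]
        amp = amp * factors
        if self.multiplicative_sigma > 0:
            amp = amp * (1.0 + rng.normal(0.0, self.multiplicative_sigma, len(amp)))
        if self.additive_floor > 0:
            amp = amp + self.additive_floor
        return ms.with_amplitudes(np.maximum(amp, 0.0))


def default_probe(
    n_rows: int = 3, n_cols: int = 4, slab_shape=DEFAULT_SLAB_SHAPE
) -> ProbeArray:
    """Mirrored grids at the standard 13 / 14 mm pitch, centred on the slab face."""
    probe = build_probe(n_rows, n_cols, 13.0, 14.0, slab_shape[0])
    return probe.centered_on(slab_shape[1] / 2.0, slab_shape[2] / 2.0)


def build_phantom(
    spec: PhantomSpec,
    h: float = DEFAULT_GENERATION_H,
    probe: ProbeArray | None = None,
) -> tuple[SlabMesh, SlabMesh]:
    """Mesh the phantom and assign nodal properties; returns the task mesh
    and its homogeneous twin (identical lattice, inclusions removed).

    If a probe is given, lattice planes are snapped to the optode coordinates
    and to the coupling depth 1/mu_s' so both meshes resolve the optodes
    identically.
    """
    snap = None
    plate_depth = 1.0 / spec.background.mu_s_prime
    if probe is not None:
        src = probe.source_positions
        snap = (np.unique(src[:, 1]), np.unique(src[:, 2]))
    mesh = build_slab_mesh(spec.slab_shape, h=h, plate_depth=plate_depth, snap_yz=snap)
    mesh.set_homogeneous(spec.background.mu_a, spec.background.mu_s_prime)
    twin = mesh.copy()
    for label, inc in enumerate(spec.inclusions, start=1):
        inside = inc.contains(mesh.nodes)
        mesh.mu_a[inside] = inc.mu_a
        if inc.mu_s_prime is not None:
            mesh.mu_s_prime[inside] = inc.mu_s_prime
        centroids = mesh.nodes[mesh.elements].mean(axis=1)
        mesh.region_labels[inc.contains(centroids)] = label
    return mesh, twin


@dataclass
class SimulatedDataset:
    """Task and reference scans of one session plus provenance."""

    task: MeasurementSet
    reference: MeasurementSet
    predicted: MeasurementSet  # clean homogeneous-twin amplitudes (no gains)
    manifest: dict


def simulate_dataset(
    spec: PhantomSpec,
    probe: ProbeArray,
    gain_model: ChannelGainModel | None = None,
    generator: str = "diffusion",
    h: float = DEFAULT_GENERATION_H,
    n_photons: int = 10**6,
    seed: int = 0,
    wavelength_nm: float = 750.0,
    pairs=None,
) -> SimulatedDataset:
    """Simulate one measurement session: a task scan of the phantom and a
    reference scan of its homogeneous twin, with the same gain/noise
    realization applied to both (one hardware state).
    """
    if gain_model is None:
        gain_model = ChannelGainModel.identity()
    if pairs is None:
        pairs = enumerate_pairs(probe)
    if generator == "diffusion":
        mesh, twin = build_phantom(spec, h=h, probe=probe)
        _, task_clean = solve_cw(mesh, probe, pairs=pairs, wavelength_nm=wavelength_nm)
        _, ref_clean = solve_cw(twin, probe, pairs=pairs, wavelength_nm=wavelength_nm)
    elif generator == "mc":
        from .montecarlo import voxel_monte_carlo

        task_clean = voxel_monte_carlo(
            spec, probe, n_photons=n_photons, seed=seed, pairs=pairs,
            wavelength_nm=wavelength_nm,
        )
        ref_clean = voxel_monte_carlo(
            spec.homogeneous_twin, probe, n_photons=n_photons, seed=seed + 1,
            pairs=pairs, wavelength_nm=wavelength_nm,
        )
    else:
        raise PhantomSpecError(f"unknown generator '{generator}'")

    rng_task = np.random.default_rng(seed)
    rng_ref = np.random.default_rng(seed)  # same realization: one session
    task = gain_model.apply(task_clean, rng_task)
    reference = gain_model.apply(ref_clean, rng_ref)
    task = task.with_amplitudes(task.amplitude, role="task")
    reference = reference.with_amplitudes(reference.amplitude, role="reference")
    manifest = {
        "phantom": spec.name,
        "generator": generator,
        "mesh_h": h if generator == "diffusion" else None,
        "n_photons": n_photons if generator == "mc" else None,
        "seed": seed,
        "wavelength_nm": wavelength_nm,
        "global_scale": gain_model.global_scale,
        "gain_sigma": None
        if gain_model.source_gains is None
        else float(np.std(np.log(gain_model.source_gains))),
        "noise_sigma": gain_model.multiplicative_sigma,
    }
    return SimulatedDataset(
        task=task, reference=reference, predicted=ref_clean, manifest=manifest
    )


def voxel_monte_carlo(spec, probe, n_photons, seed, **kwargs):
    """Weighted-photon voxel Monte Carlo transmission simulation; see
    :func:`platedot.montecarlo.voxel_monte_carlo`."""
    from .montecarlo import voxel_monte_carlo as _mc

    return _mc(spec, probe, n_photons=n_photons, seed=seed, **kwargs)


def _baseline_targets(
    centers=((17.0, 45.0, 42.0), (17.0, 85.0, 42.0)),
    radius: float = 7.5,
    height: float = 10.0,
    mu_a: float = 0.012,
) -> tuple[Cylinder, ...]:
    return tuple(
        Cylinder(center=c, radius=radius, height=height, mu_a=mu_a, axis="x")
        for c in centers
    )


def scenario_presets(name: str) -> tuple[PhantomSpec, ProbeArray]:
    """Named experiment setups: the baseline two-target phantom and its
    position / size / contrast variants, plus the full 7 x 8 system layout.

    The three alternative target placements keep the target geometry
    (R = 7.5 mm, h = 10 mm, 3x contrast) and the 40 mm centre separation but
    move the pair within the slab: shifted toward one lateral wall, shifted
    along the probe rows, and rotated to lie along the column axis.
    """
    presets = {
        "sim_baseline": dict(targets=_baseline_targets()),
        "sim_3x4": dict(targets=_baseline_targets()),
        "position_1": dict(
            targets=_baseline_targets(
                centers=((17.0, 45.0, 22.0), (17.0, 85.0, 22.0))
            )
        ),
        "position_2": dict(
            targets=_baseline_targets(
                centers=((17.0, 65.0, 42.0), (17.0, 105.0, 42.0))
            )
        ),
        "position_3": dict(
            targets=_baseline_targets(
                centers=((17.0, 65.0, 19.5), (17.0, 65.0, 59.5))
            )
        ),
        "size_R5": dict(targets=_baseline_targets(radius=5.0)),
        "size_R10": dict(targets=_baseline_targets(radius=10.0)),
        "contrast_2x": dict(targets=_baseline_targets(mu_a=0.008)),
        "contrast_4x": dict(targets=_baseline_targets(mu_a=0.016)),
        "system_7x8": dict(targets=_baseline_targets(), n_rows=7, n_cols=8),
    }
    try:
        entry = presets[name]
    except KeyError:
        raise PresetLookupError(
            f"unknown scenario '{name}'; available: {sorted(presets)}"
        ) from None
    spec = PhantomSpec(inclusions=entry["targets"], name=name)
    probe = default_probe(
        n_rows=entry.get("n_rows", 3), n_cols=entry.get("n_cols", 4)
    )
    return spec, probe
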