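"""End-to-end study runs on the simulated breast-size slab.

These helpers rerun the package's headline experiments under the default
study conditions — the two-target slab phantom measured with the mirrored
3 x 4 arrays — and report the quantities the method is judged by: the
virtual-reference fidelity (mean relative deviation from the homogeneous
twin scan), the two-target peak ratio of reference- and self-calibrated
reconstructions, the per-target FWHM of the absorption profile, and the
position / size robustness sweeps.

Problem sizes: the measurement generator meshes the slab at 3 mm (~24k
nodes) and the reconstruction mesh matches the classical 22k-node
discretization of this geometry; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibrate import (
    build_virtual_reference,
    mean_relative_error,
    reference_calibrate,
    self_calibrate,
)
from .forward import solve_cw
from .mesh import build_slab_mesh
from .probe import apply_exclusions, enumerate_pairs, group_by_distance, retained
from .recon import (
    ReconSettings,
    centroid_above_half_max,
    line_profile_metrics,
    reconstruct_absorption,
    split_half_maxima,
)
from .synthgen import scenario_presets, simulate_dataset

GENERATION_H = 3.0
RECONSTRUCTION_H = 3.0


@dataclass
class VirtualReferenceStudy:
    """Task/reference session with the virtual reference and its fidelity."""

    scenario: str
    probe: object
    pairs: list
    classes: list
    task: object
    reference: object
    estimated: object
    error: float  # mean |est - ref| / ref over retained pairs
    n_pairs: int


def virtual_reference_study(
    scenario: str = "sim_baseline",
    seed: int = 1,
    h: float = GENERATION_H,
    max_distance: float = 110.0,
) -> VirtualReferenceStudy:
    """Simulate one scenario and measure how well the per-distance-class
    maxima of the task scan reproduce the homogeneous reference scan."""
    spec, probe = scenario_presets(scenario)
    ds = simulate_dataset(spec, probe, seed=seed, h=h)
    pairs = apply_exclusions(enumerate_pairs(probe), None, max_distance)
    kept = retained(pairs)
    classes = group_by_distance(kept)
    keys = [p.key for p in kept]
    task = ds.task.restrict_to(keys)
    reference = ds.reference.restrict_to(keys)
    estimated = build_virtual_reference(task, classes)
    return VirtualReferenceStudy(
        scenario=scenario,
        probe=probe,
        pairs=kept,
        classes=classes,
        task=task,
        reference=reference,
        estimated=estimated,
        error=mean_relative_error(estimated, reference),
        n_pairs=len(kept),
    )


@dataclass
class ReconstructionStudy:
    """Both calibration routes reconstructed on the baseline phantom."""

    base: VirtualReferenceStudy
    image_reference: object
    image_self: object
    ratio_reference: float
    ratio_self: float
    profile_reference: dict
    profile_self: dict
    peaks_reference: tuple[float, float]
    peaks_self: tuple[float, float]
    split_y: float
    target_centers: tuple


def reconstruction_study(
    seed: int = 1,
    generation_h: float = GENERATION_H,
    reconstruction_h: float = RECONSTRUCTION_H,
    base: VirtualReferenceStudy | None = None,
) -> ReconstructionStudy:
    """Reconstruct the baseline two-target phantom from reference-calibrated
    and self-calibrated data and report the two-target peak ratios and the
    absorption profile through the target centres."""
    if base is None:
        base = virtual_reference_study("sim_baseline", seed=seed, h=generation_h)
    spec, probe = scenario_presets(base.scenario)
    src = probe.source_positions
    mesh = build_slab_mesh(
        spec.slab_shape,
        h=reconstruction_h,
        plate_depth=1.0 / spec.background.mu_s_prime,
        snap_yz=(np.unique(src[:, 1]), np.unique(src[:, 2])),
    )
    mesh.set_homogeneous(spec.background.mu_a, spec.background.mu_s_prime)
    _, predicted = solve_cw(mesh, probe, pairs=base.pairs)
    settings = ReconSettings(background_props=spec.background)

    cal_ref = reference_calibrate(base.task, base.reference, predicted)
    cal_self = self_calibrate(base.task, base.estimated, predicted)
    image_ref = reconstruct_absorption(cal_ref, mesh, probe, settings)
    image_self = reconstruct_absorption(cal_self, mesh, probe, settings)

    c0 = np.asarray(spec.inclusions[0].center)
    c1 = np.asarray(spec.inclusions[1].center)
    split_y = float((c0[1] + c1[1]) / 2.0)
    line = (float(c0[0]), float(c0[2]))
    peaks_ref = split_half_maxima(image_ref, split_y)
    peaks_self = split_half_maxima(image_self, split_y)
    return ReconstructionStudy(
        base=base,
        image_reference=image_ref,
        image_self=image_self,
        ratio_reference=peaks_ref[0] / peaks_ref[1],
        ratio_self=peaks_self[0] / peaks_self[1],
        profile_reference=line_profile_metrics(image_ref, line),
        profile_self=line_profile_metrics(image_self, line),
        peaks_reference=peaks_ref,
        peaks_self=peaks_self,
        split_y=split_y,
        target_centers=(tuple(c0), tuple(c1)),
    )


def recovered_centroids(study: ReconstructionStudy, which: str = "self"):
    """Above-half-max centroids of the two recovered targets (mm)."""
    image = study.image_self if which == "self" else study.image_reference
    y = image.mesh.nodes[:, 1]
    return (
        centroid_above_half_max(image, y < study.split_y),
        centroid_above_half_max(image, y >= study.split_y),
    )


def position_sweep(seed: int = 1, h: float = GENERATION_H) -> dict[str, float]:
    """Virtual-reference error for the baseline target placement and the
    three alternative placements; targets unchanged."""
    return {
        name: virtual_reference_study(name, seed=seed, h=h).error
        for name in ("sim_baseline", "position_1", "position_2", "position_3")
    }


def size_sweep(seed: int = 1, h: float = GENERATION_H) -> dict[float, float]:
    """Virtual-reference error as a function of target radius (mm)."""
    return {
        5.0: virtual_reference_study("size_R5", seed=seed, h=h).error,
        7.5: virtual_reference_study("sim_baseline", seed=seed, h=h).error,
        10.0: virtual_reference_study("size_R10", seed=seed, h=h).error,
    }
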