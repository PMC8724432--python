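"""Phantom construction, simulated measurement sessions and scenario presets."""

import numpy as np
import pytest

from platedot.calibrate import (
    build_virtual_reference,
    mean_relative_error,
    reference_calibrate,
)
from platedot.errors import PhantomSpecError, PresetLookupError
from platedot.forward import OpticalProperties, solve_cw
from platedot.probe import build_probe, enumerate_pairs, group_by_distance
from platedot.synthgen import (
    ChannelGainModel,
    Cylinder,
    PhantomSpec,
    build_phantom,
    default_probe,
    scenario_presets,
    simulate_dataset,
)


@pytest.fixture(scope="module")
def tiny_spec():
    """Small slab with one off-centre absorber, cheap to mesh and solve."""
    return PhantomSpec(
        slab_shape=(30.0, 60.0, 50.0),
        background=OpticalProperties(0.004, 1.0),
        inclusions=(
            Cylinder(center=(12.0, 25.0, 25.0), radius=6.0, height=8.0, mu_a=0.012),
        ),
        name="tiny",
    )


@pytest.fixture(scope="module")
def tiny_probe():
    return build_probe(2, 2, 13.0, 14.0, 30.0).centered_on(30.0, 25.0)


def test_baseline_phantom_geometry():
    spec, probe = scenario_presets("sim_baseline")
    assert spec.slab_shape == (44.0, 130.0, 79.0)
    assert len(spec.inclusions) == 2
    for inc, center in zip(spec.inclusions, ((17, 45, 42), (17, 85, 42))):
        assert inc.center == center
        assert inc.radius == 7.5
        assert inc.height == 10.0
        assert inc.mu_a == pytest.approx(3.0 * spec.background.mu_a)
    assert probe.n_rows == 3 and probe.n_cols == 4
    # membership: target centre inside, inter-target midpoint outside
    assert spec.inclusions[0].contains(np.array([[17.0, 45.0, 42.0]]))[0]
    assert not spec.inclusions[0].contains(np.array([[17.0, 65.0, 42.0]]))[0]


@pytest.mark.parametrize(
    "name,check",
    [
        ("size_R5", lambda s: s.inclusions[0].radius == 5.0),
        ("size_R10", lambda s: s.inclusions[0].radius == 10.0),
        ("contrast_2x", lambda s: s.inclusions[0].mu_a == pytest.approx(0.008)),
        ("contrast_4x", lambda s: s.inclusions[0].mu_a == pytest.approx(0.016)),
    ],
)
def test_sweep_presets(name, check):
    spec, _ = scenario_presets(name)
    assert check(spec)
    # variants share the slab and background with the baseline
    assert spec.slab_shape == (44.0, 130.0, 79.0)
    assert spec.background.mu_a == 0.004


def test_position_presets_preserve_target_geometry():
    for name in ("position_1", "position_2", "position_3"):
        spec, _ = scenario_presets(name)
        (a, b) = spec.inclusions
        assert a.radius == b.radius == 7.5
        assert a.height == b.height == 10.0
        sep = np.linalg.norm(np.asarray(a.center) - np.asarray(b.center))
        assert sep == pytest.approx(40.0)


def test_full_system_preset():
    _, probe = scenario_presets("system_7x8")
    assert probe.I == 56


def test_unknown_preset():
    with pytest.raises(PresetLookupError):
        scenario_presets("does_not_exist")


def test_inclusion_outside_slab_rejected():
    with pytest.raises(PhantomSpecError):
        PhantomSpec(
            slab_shape=(30.0, 60.0, 50.0),
            inclusions=(
                Cylinder(center=(12.0, 58.0, 25.0), radius=6.0, height=8.0, mu_a=0.012),
            ),
        )


def test_transparent_inclusion_rejected():
    with pytest.raises(PhantomSpecError):
        PhantomSpec(
            inclusions=(
                Cylinder(center=(17.0, 45.0, 42.0), radius=5.0, height=8.0, mu_a=0.001),
            ),
        )


def test_phantom_mesh_properties(tiny_spec, tiny_probe):
    mesh, twin = build_phantom(tiny_spec, h=5.0, probe=tiny_probe)
    inc = tiny_spec.inclusions[0]
    inside = inc.contains(mesh.nodes)
    assert np.allclose(mesh.mu_a[inside], 0.012)
    assert np.allclose(mesh.mu_a[~inside], 0.004)
    assert np.allclose(twin.mu_a, 0.004)
    assert (mesh.region_labels > 0).any()
    assert not (twin.region_labels > 0).any()


def test_empty_inclusion_list_matches_twin():
    spec = PhantomSpec(slab_shape=(30.0, 60.0, 50.0), name="empty")
    mesh, twin = build_phantom(spec, h=6.0)
    assert np.array_equal(mesh.mu_a, twin.mu_a)
    assert np.array_equal(mesh.region_labels, twin.region_labels)


def test_simulation_deterministic_under_seed(tiny_spec, tiny_probe):
    gain = ChannelGainModel.random(4, 4, gain_sigma=0.1, noise_sigma=0.02, seed=5)
    a = simulate_dataset(tiny_spec, tiny_probe, gain_model=gain, h=5.0, seed=5)
    b = simulate_dataset(tiny_spec, tiny_probe, gain_model=gain, h=5.0, seed=5)
    assert np.array_equal(a.task.amplitude, b.task.amplitude)
    assert np.array_equal(a.reference.amplitude, b.reference.amplitude)


def test_identity_gains_reproduce_forward_prediction(tiny_spec, tiny_probe):
    ds = simulate_dataset(tiny_spec, tiny_probe, h=5.0, seed=0)
    mesh, twin = build_phantom(tiny_spec, h=5.0, probe=tiny_probe)
    _, direct = solve_cw(mesh, tiny_probe)
    assert np.allclose(ds.task.amplitude, direct.amplitude, rtol=1e-12)
    # the clean reference equals the twin's forward prediction
    _, twin_direct = solve_cw(twin, tiny_probe)
    assert np.allclose(ds.reference.amplitude, twin_direct.amplitude, rtol=1e-12)


def test_session_gains_cancel_in_reference_calibration(tiny_spec, tiny_probe):
    """A gain realization shared by task and reference scans leaves the
    reference-calibrated data equal to the gain-free result."""
    gain = ChannelGainModel.random(4, 4, gain_sigma=0.2, seed=11)
    corrupted = simulate_dataset(tiny_spec, tiny_probe, gain_model=gain, h=5.0, seed=3)
    clean = simulate_dataset(tiny_spec, tiny_probe, h=5.0, seed=3)
    pre = clean.predicted
    cal_corrupted = reference_calibrate(corrupted.task, corrupted.reference, pre)
    cal_clean = reference_calibrate(clean.task, clean.reference, pre)
    assert np.allclose(cal_corrupted.amplitude, cal_clean.amplitude, rtol=1e-10)


def test_virtual_reference_error_vanishes_without_inclusions(tiny_probe):
    spec = PhantomSpec(
        slab_shape=(30.0, 60.0, 50.0),
        background=OpticalProperties(0.004, 1.0),
        name="homog",
    )
    ds = simulate_dataset(spec, tiny_probe, h=5.0, seed=0)
    classes = group_by_distance(enumerate_pairs(tiny_probe))
    est = build_virtual_reference(ds.task, classes)
    assert mean_relative_error(est, ds.reference) == pytest.approx(0.0, abs=1e-12)


def test_default_probe_fits_slab_face():
    probe = default_probe()
    src = probe.source_positions
    assert (src[:, 1] > 0).all() and (src[:, 1] < 130).all()
    assert (src[:, 2] > 0).all() and (src[:, 2] < 79).all()
    # centred: grid centre at the face centre
    assert np.isclose(src[:, 1].mean(), 65.0)
    assert np.isclose(src[:, 2].mean(), 39.5)
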