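"""Calibration algebra: reference-phantom calibration, virtual-reference
construction from per-distance-class maxima, self-calibration and the
relative-error metric."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from platedot.calibrate import (
    build_virtual_reference,
    mean_relative_error,
    reference_calibrate,
    relative_error_by_class,
    self_calibrate,
)
from platedot.errors import DivisionHazardError, InvalidInputError, NoDataError
from platedot.forward import OpticalProperties, analytic_slab_flux
from platedot.probe import SDPair, group_by_distance

from conftest import make_measurements


def _three_pair_class():
    pairs = [SDPair(1, 1, 44.0), SDPair(2, 2, 44.0), SDPair(3, 3, 44.0)]
    return pairs, group_by_distance(pairs)


@pytest.fixture(scope="module")
def analytic_sets(sim_probe, sim_pairs):
    """Homogeneous noiseless amplitudes in all three roles."""
    props = OpticalProperties(mu_a=0.004, mu_s_prime=1.0)
    base = analytic_slab_flux(props, sim_probe)
    return {
        "task": base.with_amplitudes(base.amplitude, role="task"),
        "reference": base.with_amplitudes(base.amplitude, role="reference"),
        "predicted": base,
    }


def test_reference_calibration_identity(analytic_sets):
    cal = reference_calibrate(
        analytic_sets["task"], analytic_sets["reference"], analytic_sets["predicted"]
    )
    assert np.allclose(cal.amplitude, analytic_sets["predicted"].amplitude)
    assert cal.role == "calibrated"


def test_reference_calibration_scaling(analytic_sets):
    task2 = analytic_sets["task"].with_amplitudes(
        2.0 * analytic_sets["task"].amplitude
    )
    cal = reference_calibrate(
        task2, analytic_sets["reference"], analytic_sets["predicted"]
    )
    assert np.allclose(cal.amplitude, 2.0 * analytic_sets["predicted"].amplitude)


def test_per_channel_gains_cancel_exactly(sim_probe, analytic_sets):
    """Gains g_s(i) g_d(j) applied identically to task and reference drop out
    of the reference calibration to machine precision."""
    rng = np.random.default_rng(11)
    gs = np.exp(rng.normal(0, 0.3, sim_probe.I))
    gd = np.exp(rng.normal(0, 0.3, sim_probe.J))
    task, ref, pre = (analytic_sets[k] for k in ("task", "reference", "predicted"))
    factors = gs[task.source_index - 1] * gd[task.detector_index - 1]
    gained = reference_calibrate(
        task.with_amplitudes(task.amplitude * factors),
        ref.with_amplitudes(ref.amplitude * factors),
        pre,
    )
    clean = reference_calibrate(task, ref, pre)
    assert np.allclose(gained.amplitude, clean.amplitude, rtol=1e-12)


def test_zero_reference_raises_division_hazard(analytic_sets):
    bad = analytic_sets["reference"].amplitude.copy()
    bad[3] = 0.0
    with pytest.raises(DivisionHazardError) as err:
        reference_calibrate(
            analytic_sets["task"],
            analytic_sets["reference"].with_amplitudes(bad),
            analytic_sets["predicted"],
        )
    assert err.value.pair is not None


def test_mismatched_retained_sets_rejected(analytic_sets):
    restricted = analytic_sets["reference"].restrict_to([(1, 1), (1, 2)])
    with pytest.raises(InvalidInputError):
        reference_calibrate(
            analytic_sets["task"], restricted, analytic_sets["predicted"]
        )


# ------------------------------------------------------------ virtual reference
def test_class_maximum_assigned_to_every_member():
    pairs, classes = _three_pair_class()
    task = make_measurements(pairs, [1.0, 0.8, 0.9])
    est = build_virtual_reference(task, classes)
    assert np.allclose(est.amplitude, 1.0)
    assert est.role == "estimated"


def test_virtual_reference_idempotent():
    pairs, classes = _three_pair_class()
    task = make_measurements(pairs, [1.0, 0.8, 0.9])
    est = build_virtual_reference(task, classes)
    again = build_virtual_reference(
        est.with_amplitudes(est.amplitude, role="task"), classes
    )
    assert np.allclose(again.amplitude, est.amplitude)


def test_virtual_reference_is_least_dominating_class_constant(sim_pairs):
    """Gamma_est dominates the task pairwise and equals the class maximum —
    i.e. it is the smallest class-constant set above the task."""
    rng = np.random.default_rng(5)
    amps = rng.uniform(0.1, 2.0, len(sim_pairs))
    task = make_measurements(sim_pairs, amps)
    classes = group_by_distance(sim_pairs)
    est = build_virtual_reference(task, classes)
    assert (est.amplitude >= task.amplitude - 1e-15).all()
    for cls in classes:
        members = [est.amplitude_at(*p.key) for p in cls.members]
        brute_max = max(task.amplitude_at(*p.key) for p in cls.members)
        assert np.allclose(members, brute_max)


def test_homogeneous_noiseless_estimate_equals_task(sim_pairs, analytic_sets):
    classes = group_by_distance(sim_pairs)
    est = build_virtual_reference(analytic_sets["task"], classes)
    assert np.allclose(est.amplitude, analytic_sets["task"].amplitude, rtol=1e-9)


def test_empty_class_set_raises():
    pairs, _ = _three_pair_class()
    task = make_measurements(pairs, [1.0, 0.8, 0.9])
    with pytest.raises(NoDataError):
        build_virtual_reference(task, [])


# --------------------------------------------------------------- self-calibrate
def test_self_calibration_recovers_prediction_for_homogeneous_task(
    sim_pairs, analytic_sets
):
    classes = group_by_distance(sim_pairs)
    est = build_virtual_reference(analytic_sets["task"], classes)
    cal = self_calibrate(analytic_sets["task"], est, analytic_sets["predicted"])
    assert np.allclose(cal.amplitude, analytic_sets["predicted"].amplitude, rtol=1e-9)


@settings(deadline=None, max_examples=20, derandomize=True)
@given(scale=st.floats(min_value=1e-6, max_value=1e6))
def test_global_scale_invariance(scale):
    """Multiplying the task by any c > 0 leaves the self-calibrated data
    unchanged: c cancels between the task and its class maxima."""
    pairs = [SDPair(1, 1, 44.0), SDPair(2, 2, 44.0), SDPair(1, 2, 46.0),
             SDPair(2, 1, 46.0)]
    classes = group_by_distance(pairs)
    amps = np.array([1.0, 0.7, 0.5, 0.45])
    pre = make_measurements(pairs, [0.9, 0.9, 0.4, 0.4], role="predicted")
    task = make_measurements(pairs, amps)
    scaled = make_measurements(pairs, scale * amps)
    cal = self_calibrate(task, build_virtual_reference(task, classes), pre)
    cal_scaled = self_calibrate(
        scaled, build_virtual_reference(scaled, classes), pre
    )
    assert np.allclose(cal.amplitude, cal_scaled.amplitude, rtol=1e-9)


def test_self_calibrated_never_exceeds_prediction(sim_pairs):
    rng = np.random.default_rng(9)
    amps = rng.uniform(0.1, 2.0, len(sim_pairs))
    classes = group_by_distance(sim_pairs)
    task = make_measurements(sim_pairs, amps)
    pre = make_measurements(sim_pairs, rng.uniform(0.5, 1.5, len(sim_pairs)),
                            role="predicted")
    cal = self_calibrate(task, build_virtual_reference(task, classes), pre)
    assert (cal.amplitude <= pre.amplitude + 1e-12).all()


def test_self_equals_reference_for_homogeneous_noiseless(sim_pairs, analytic_sets):
    classes = group_by_distance(sim_pairs)
    est = build_virtual_reference(analytic_sets["task"], classes)
    by_self = self_calibrate(analytic_sets["task"], est, analytic_sets["predicted"])
    by_ref = reference_calibrate(
        analytic_sets["task"], analytic_sets["reference"], analytic_sets["predicted"]
    )
    assert np.allclose(by_self.amplitude, by_ref.amplitude, rtol=1e-9)


# --------------------------------------------------------------- error metric
def test_relative_error_zero_for_identical_sets(analytic_sets):
    assert mean_relative_error(
        analytic_sets["task"], analytic_sets["reference"]
    ) == pytest.approx(0.0)


def test_relative_error_constant_ratio(analytic_sets):
    est = analytic_sets["task"].with_amplitudes(
        0.9 * analytic_sets["task"].amplitude, role="estimated"
    )
    assert mean_relative_error(est, analytic_sets["reference"]) == pytest.approx(0.10)


def test_relative_error_by_class_reports_every_class(sim_pairs, analytic_sets):
    classes = group_by_distance(sim_pairs)
    est = analytic_sets["task"].with_amplitudes(
        0.95 * analytic_sets["task"].amplitude, role="estimated"
    )
    per_class = relative_error_by_class(est, analytic_sets["reference"], classes)
    assert len(per_class) == len(classes)
    assert all(v == pytest.approx(0.05) for v in per_class.values())
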