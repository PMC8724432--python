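"""Pipeline configuration, end-to-end runs on a small phantom, file-format
round trips and the command-line surface."""

import json

import numpy as np
import pytest
from click.testing import CliRunner

from platedot import io as pio
from platedot.cli import main as cli_main
from platedot.errors import ValidationError
from platedot.forward import OpticalProperties
from platedot.mesh import build_slab_mesh
from platedot.probe import build_probe, enumerate_pairs
from platedot.synthgen import Cylinder, PhantomSpec
from platedot.workbench import (
    load_and_validate,
    run_pipeline,
    save_config,
    validate_config,
)

from conftest import make_measurements


@pytest.fixture()
def tiny_setup(tmp_path):
    """Phantom + probe config files for a fast two-target pipeline run."""
    spec = PhantomSpec(
        slab_shape=(30.0, 80.0, 50.0),
        background=OpticalProperties(0.004, 1.0),
        inclusions=(
            Cylinder(center=(12.0, 25.0, 25.0), radius=6.0, height=8.0, mu_a=0.02),
            Cylinder(center=(12.0, 55.0, 25.0), radius=6.0, height=8.0, mu_a=0.02),
        ),
        name="tiny_two_target",
    )
    probe = build_probe(3, 3, 13.0, 14.0, 30.0).centered_on(40.0, 25.0)
    phantom_path = tmp_path / "phantom.yaml"
    probe_path = tmp_path / "probe.yaml"
    pio.save_phantom_spec(spec, phantom_path)
    pio.save_probe_config(probe, probe_path)
    return spec, probe, phantom_path, probe_path


def _tiny_config(tmp_path, phantom_path, probe_path, mode="self", out="run"):
    return {
        "phantom": str(phantom_path),
        "probe": str(probe_path),
        "mode": mode,
        "wavelengths": [750.0],
        "seed": 3,
        "output_dir": str(tmp_path / out),
        "recon": {"mesh_h": 5.0, "n_iterations": 3},
        "generation": {"mesh_h": 5.0},
    }


def test_defaults_injected_for_minimal_config():
    cfg = validate_config({"scenario": "sim_baseline"})
    assert cfg.mode == "self"
    assert cfg.recon["regularization_lambda"] == 10.0
    assert cfg.recon["n_iterations"] == 6
    assert cfg.selection["cov_threshold"] == 0.3
    assert cfg.selection["max_distance_mm"] == 110.0


def test_validation_collects_all_problems():
    with pytest.raises(ValidationError) as err:
        validate_config(
            {
                "mode": "banana",
                "measurements": {"reference": "x.csv"},
                "wavelengths": [],
            }
        )
    text = str(err.value)
    assert "mode" in text
    assert "task" in text
    assert "wavelength" in text


def test_reference_mode_requires_reference_input():
    with pytest.raises(ValidationError) as err:
        validate_config(
            {"mode": "reference", "measurements": {"task": "t.csv"}, "probe": "p.yaml"}
        )
    assert any("reference" in p for p in err.value.problems)


def test_self_mode_rejects_reference_input():
    with pytest.raises(ValidationError):
        validate_config(
            {
                "mode": "self",
                "measurements": {"task": "t.csv", "reference": "r.csv"},
                "probe": "p.yaml",
            }
        )


def test_config_round_trip_is_stable(tmp_path):
    raw = {"scenario": "sim_baseline", "seed": 7, "recon": {"mesh_h": 5.0}}
    cfg = validate_config(raw)
    path = tmp_path / "cfg.yaml"
    save_config(cfg, path)
    reloaded = load_and_validate(path)
    assert reloaded == cfg


def test_pipeline_self_mode_produces_metrics_and_volumes(tmp_path, tiny_setup):
    _, _, phantom_path, probe_path = tiny_setup
    cfg = validate_config(_tiny_config(tmp_path, phantom_path, probe_path))
    result = run_pipeline(cfg)
    out = result.output_dir
    for name in (
        "metrics.json",
        "manifest.json",
        "exclusion_report.csv",
        "measurements.h5",
        "mu_a_750nm.vtk",
        "mu_a_750nm.nii.gz",
        "calibration_report_750nm.json",
    ):
        assert (out / name).exists()
    per_wl = result.metrics["per_wavelength"]["750"]
    assert "contrast_ratio" in per_wl
    assert len(per_wl["fwhm_mm"]) == 2
    # symmetric twin targets: equal recovered maxima
    assert per_wl["contrast_ratio"] == pytest.approx(1.0, abs=0.05)


def test_pipeline_reference_mode_reports_virtual_reference_error(
    tmp_path, tiny_setup
):
    _, _, phantom_path, probe_path = tiny_setup
    cfg = validate_config(
        _tiny_config(tmp_path, phantom_path, probe_path, mode="reference", out="ref")
    )
    result = run_pipeline(cfg)
    per_wl = result.metrics["per_wavelength"]["750"]
    assert 0.0 <= per_wl["virtual_reference_error"] < 0.5
    assert per_wl["virtual_reference_error_by_class"]


def test_pipeline_deterministic_manifest(tmp_path, tiny_setup):
    _, _, phantom_path, probe_path = tiny_setup
    cfg = validate_config(_tiny_config(tmp_path, phantom_path, probe_path, out="det"))
    run_pipeline(cfg)
    first = (tmp_path / "det" / "manifest.json").read_text()
    run_pipeline(cfg)
    second = (tmp_path / "det" / "manifest.json").read_text()
    assert first == second


# ------------------------------------------------------------- file round trips
def test_measurement_csv_round_trip(tmp_path, sim_pairs):
    rng = np.random.default_rng(0)
    ms = make_measurements(sim_pairs, rng.uniform(0.1, 1.0, len(sim_pairs)))
    path = tmp_path / "m.csv"
    pio.save_measurements_csv(ms, path)
    back = pio.load_measurements_csv(path, role="task")
    assert np.allclose(back.amplitude, ms.amplitude)
    assert np.array_equal(back.source_index, ms.source_index)
    assert back.wavelength_nm == ms.wavelength_nm


def test_bundle_h5_round_trip(tmp_path, sim_pairs):
    rng = np.random.default_rng(1)
    sets = {
        "task": [
            make_measurements(sim_pairs, rng.uniform(0.1, 1.0, len(sim_pairs)),
                              wavelength_nm=wl)
            for wl in (660.0, 750.0)
        ]
    }
    path = tmp_path / "bundle.h5"
    pio.save_bundle_h5(sets, path)
    back = pio.load_bundle_h5(path)
    assert sorted(ms.wavelength_nm for ms in back["task"]) == [660.0, 750.0]
    assert np.allclose(back["task"][0].amplitude, sets["task"][0].amplitude)


def test_probe_config_round_trip(tmp_path):
    probe = build_probe(3, 4, 13.0, 14.0, 44.0).centered_on(65.0, 39.5)
    path = tmp_path / "probe.yaml"
    pio.save_probe_config(probe, path, coverage=[1, 2, 3])
    back, coverage = pio.load_probe_config(path)
    assert back == probe
    assert coverage == [1, 2, 3]


def test_phantom_spec_round_trip(tmp_path, tiny_setup):
    spec, _, phantom_path, _ = tiny_setup
    back = pio.load_phantom_spec(phantom_path)
    assert back == spec


def test_vtk_round_trip(tmp_path):
    mesh = build_slab_mesh((20.0, 30.0, 25.0), h=10.0)
    mesh.set_homogeneous(0.004, 1.0)
    values = np.arange(mesh.n_nodes, dtype=float)
    path = tmp_path / "mesh.vtk"
    pio.save_vtk(mesh, path, point_data={"mu_a": values})
    points, cells, data = pio.load_vtk(path)
    assert np.allclose(points, mesh.nodes)
    assert np.array_equal(cells, mesh.elements)
    assert np.allclose(data["mu_a"], values)


def test_nifti_round_trip(tmp_path):
    mesh = build_slab_mesh((20.0, 30.0, 25.0), h=5.0)
    mesh.set_homogeneous(0.004, 1.0)
    values = mesh.nodes[:, 1] * 0.001  # linear in y: exact under resampling
    path = tmp_path / "vol.nii.gz"
    pio.save_nifti(mesh, values, path)
    vol, affine = pio.load_nifti(path)
    assert vol.shape == (21, 31, 26)
    assert np.allclose(vol[5, :, 5], np.arange(31) * 0.001, atol=1e-6)
    assert np.allclose(np.diag(affine), [1.0, 1.0, 1.0, 1.0])


def test_exclusion_report_schema(tmp_path, sim_probe):
    import pandas as pd

    from platedot.probe import apply_exclusions

    pairs = apply_exclusions(enumerate_pairs(sim_probe), None, 50.0)
    path = tmp_path / "excl.csv"
    pio.save_exclusion_report(pairs, path)
    df = pd.read_csv(path)
    assert list(df.columns) == [
        "source_index", "detector_index", "distance_mm", "excluded", "reason",
    ]
    assert df.excluded.sum() == sum(p.excluded for p in pairs)


# ------------------------------------------------------------------------- CLI
def test_cli_validation_exit_code(tmp_path):
    bad = tmp_path / "bad.yaml"
    bad.write_text("mode: banana\n")
    runner = CliRunner()
    result = runner.invoke(cli_main, ["run", "--config", str(bad)])
    assert result.exit_code == 2


def test_cli_metrics_pretty_print(tmp_path):
    path = tmp_path / "metrics.json"
    path.write_text(json.dumps({"a": 1}))
    runner = CliRunner()
    result = runner.invoke(cli_main, ["metrics", str(path)])
    assert result.exit_code == 0
    assert '"a": 1' in result.output
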