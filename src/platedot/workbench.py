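"""Configuration handling and the end-to-end pipeline.

One config file describes a full run: which phantom/scenario to measure (or
which measurement tables to load), the calibration mode (physical reference
scan vs. data self-calibration), exclusion and boundary-selection settings,
reconstruction settings and the wavelength list.  ``run_pipeline`` executes
simulate/load -> exclusions -> (CoV selection) -> calibrate -> reconstruct
(-> unmix when multi-wavelength) and writes volumes, reports and a
provenance manifest; every stage logs the retained-pair count, since the
pair bookkeeping is where calibration quality is decided.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as pio
from .calibrate import (
    MeasurementSet,
    build_virtual_reference,
    mean_relative_error,
    reference_calibrate,
    relative_error_by_class,
    self_calibrate,
)
from .errors import PipelineStageError, PlateDOTError, ValidationError
from .forward import OpticalProperties, solve_cw
from .mesh import build_slab_mesh
from .probe import (
    DEFAULT_COV_THRESHOLD,
    DEFAULT_MAX_DISTANCE_MM,
    apply_exclusions,
    enumerate_pairs,
    group_by_distance,
    retained,
    select_non_boundary,
)
from .recon import (
    ReconSettings,
    line_profile_metrics,
    reconstruct_absorption,
    split_half_maxima,
)
from .synthgen import (
    ChannelGainModel,
    default_probe,
    scenario_presets,
    simulate_dataset,
)

DEFAULTS = {
    "mode": "self",
    "wavelengths": [750.0],
    "seed": 0,
    "output_dir": "platedot_out",
    "recon": {"regularization_lambda": 10.0, "n_iterations": 6, "mesh_h": 3.0},
    "selection": {
        "max_distance_mm": DEFAULT_MAX_DISTANCE_MM,
        "cov_threshold": DEFAULT_COV_THRESHOLD,
        "apply_cov_selection": False,
    },
    "generation": {
        "generator": "diffusion",
        "mesh_h": 3.0,
        "gain_sigma": 0.0,
        "noise_sigma": 0.0,
        "global_scale": 1.0,
        "n_photons": 10**6,
    },
}


@dataclass
class PipelineConfig:
    """Validated, defaults-injected pipeline configuration."""

    mode: str
    scenario: str | None
    phantom_path: str | None
    probe_path: str | None
    measurements: dict | None
    wavelengths: list[float]
    seed: int
    output_dir: str
    recon: dict
    selection: dict
    generation: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _merge_defaults(section: dict | None, defaults: dict) -> dict:
    out = dict(defaults)
    out.update(section or {})
    return out


def validate_config(raw: dict) -> PipelineConfig:
    """Check cross-field constraints and inject defaults; collects *all*
    problems into one :class:`ValidationError`."""
    problems = []
    mode = raw.get("mode", DEFAULTS["mode"])
    if mode not in ("self", "reference"):
        problems.append(f"mode must be 'self' or 'reference', got '{mode}'")
    scenario = raw.get("scenario")
    phantom_path = raw.get("phantom")
    measurements = raw.get("measurements")
    n_inputs = sum(x is not None for x in (scenario, phantom_path, measurements))
    if n_inputs == 0:
        problems.append("one of 'scenario', 'phantom' or 'measurements' is required")
    elif n_inputs > 1:
        problems.append("'scenario', 'phantom' and 'measurements' are mutually exclusive")
    if measurements is not None:
        if "task" not in measurements:
            problems.append("measurements input requires a 'task' table")
        if mode == "reference" and "reference" not in measurements:
            problems.append("mode 'reference' requires a reference measurement input")
        if mode == "self" and "reference" in measurements:
            problems.append("mode 'self' must not be given a reference measurement input")
        if raw.get("probe") is None:
            problems.append("measurements input requires a 'probe' config")
    wavelengths = raw.get("wavelengths", DEFAULTS["wavelengths"])
    if not wavelengths:
        problems.append("wavelength list must not be empty")
    recon = _merge_defaults(raw.get("recon"), DEFAULTS["recon"])
    if recon["regularization_lambda"] <= 0:
        problems.append("recon.regularization_lambda must be positive")
    if recon["n_iterations"] < 1:
        problems.append("recon.n_iterations must be >= 1")
    selection = _merge_defaults(raw.get("selection"), DEFAULTS["selection"])
    if selection["cov_threshold"] < 0:
        problems.append("selection.cov_threshold must be >= 0")
    generation = _merge_defaults(raw.get("generation"), DEFAULTS["generation"])
    if generation["generator"] not in ("diffusion", "mc"):
        problems.append("generation.generator must be 'diffusion' or 'mc'")
    if problems:
        raise ValidationError(problems)
    return PipelineConfig(
        mode=mode,
        scenario=scenario,
        phantom_path=phantom_path,
        probe_path=raw.get("probe"),
        measurements=measurements,
        wavelengths=[float(w) for w in wavelengths],
        seed=int(raw.get("seed", DEFAULTS["seed"])),
        output_dir=str(raw.get("output_dir", DEFAULTS["output_dir"])),
        recon=recon,
        selection=selection,
        generation=generation,
    )


def load_and_validate(config_path) -> PipelineConfig:
    raw = pio._load_config(config_path)
    if not isinstance(raw, dict):
        raise ValidationError(["config file did not parse to a mapping"])
    return validate_config(raw)


def save_config(config: PipelineConfig, path) -> None:
    d = config.to_dict()
    d["phantom"] = d.pop("phantom_path")
    d["probe"] = d.pop("probe_path")
    pio._dump_config({k: v for k, v in d.items() if v is not None}, path)


@dataclass
class PipelineResult:
    """Artifacts of one pipeline run."""

    config: PipelineConfig
    images: list  # AbsorptionImage per wavelength
    metrics: dict
    manifest: dict
    output_dir: Path
    chromophores: object = None


def _stage(manifest, name, **info):
    manifest["stages"].append({"stage": name, **info})


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full pipeline for one config; deterministic given the seed.

    Any stage failure raises :class:`PipelineStageError` naming the stage;
    artifacts written before the failure stay on disk.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "stages": []}
    stage = "setup"
    try:
        # ------------------------------------------------------------- inputs
        coverage = None
        spec = None
        if config.scenario is not None:
            spec, probe = scenario_presets(config.scenario)
        elif config.phantom_path is not None:
            spec = pio.load_phantom_spec(config.phantom_path)
            if config.probe_path:
                probe, coverage = pio.load_probe_config(config.probe_path)
            else:
                probe = default_probe(slab_shape=spec.slab_shape)
        else:
            probe, coverage = pio.load_probe_config(config.probe_path)
        if config.probe_path and config.scenario is None and spec is not None:
            probe, coverage = pio.load_probe_config(config.probe_path)
        _stage(manifest, "setup", I=probe.I, J=probe.J)

        # --------------------------------------------------- measure/simulate
        stage = "simulate"
        gen = config.generation
        datasets = {}
        if config.measurements is not None:
            task_sets = {}
            ref_sets = {}
            for wl in config.wavelengths:
                task_sets[wl] = pio.load_measurements_csv(
                    config.measurements["task"], role="task"
                )
                if "reference" in config.measurements:
                    ref_sets[wl] = pio.load_measurements_csv(
                        config.measurements["reference"], role="reference"
                    )
            datasets = {
                wl: (task_sets[wl], ref_sets.get(wl)) for wl in config.wavelengths
            }
        else:
            gain = (
                ChannelGainModel.random(
                    probe.I,
                    probe.J,
                    gain_sigma=gen["gain_sigma"],
                    noise_sigma=gen["noise_sigma"],
                    global_scale=gen["global_scale"],
                    seed=config.seed,
                )
                if (gen["gain_sigma"] > 0 or gen["noise_sigma"] > 0
                    or gen["global_scale"] != 1.0)
                else ChannelGainModel.identity()
            )
            for wl in config.wavelengths:
                ds = simulate_dataset(
                    spec,
                    probe,
                    gain_model=gain,
                    generator=gen["generator"],
                    h=gen["mesh_h"],
                    n_photons=gen["n_photons"],
                    seed=config.seed,
                    wavelength_nm=wl,
                )
                datasets[wl] = (ds.task, ds.reference)
        _stage(
            manifest,
            "simulate",
            generator=gen["generator"],
            n_pairs=len(datasets[config.wavelengths[0]][0]),
        )

        # ---------------------------------------------------------- exclusions
        stage = "exclusions"
        sel = config.selection
        pairs = enumerate_pairs(probe)
        mask = None
        if coverage is not None:
            mask = np.zeros(probe.I, bool)
            mask[np.asarray(coverage, int) - 1] = True
        pairs = apply_exclusions(pairs, mask, sel["max_distance_mm"])
        pio.save_exclusion_report(pairs, out / "exclusion_report.csv")
        kept = retained(pairs)
        _stage(manifest, "exclusions", retained=len(kept), excluded=len(pairs) - len(kept))

        # ------------------------------------------------------- CoV selection
        stage = "cov_selection"
        classes = group_by_distance(kept)
        first_wl = config.wavelengths[0]
        if sel["apply_cov_selection"]:
            task0 = datasets[first_wl][0].restrict_to(
                [p.key for p in kept], reason_meta="exclusions"
            )
            result = select_non_boundary(
                probe, classes, task0, cov_threshold=sel["cov_threshold"]
            )
            kept = result.pairs
            classes = result.classes
            (out / "selection_report.json").write_text(
                json.dumps(result.report, indent=2)
            )
        _stage(manifest, "cov_selection", retained=len(kept),
               applied=bool(sel["apply_cov_selection"]))
        keys = [p.key for p in kept]

        # ------------------------------------------------- model prediction
        stage = "predict"
        background = (
            spec.background
            if spec is not None
            else OpticalProperties(mu_a=0.004, mu_s_prime=1.0)
        )
        slab_shape = spec.slab_shape if spec is not None else (
            probe.plate_separation, 130.0, 79.0
        )
        src = probe.source_positions
        recon_mesh = build_slab_mesh(
            slab_shape,
            h=config.recon["mesh_h"],
            plate_depth=1.0 / background.mu_s_prime,
            snap_yz=(np.unique(src[:, 1]), np.unique(src[:, 2])),
        )
        recon_mesh.set_homogeneous(background.mu_a, background.mu_s_prime)
        _stage(manifest, "predict", mesh_nodes=recon_mesh.n_nodes)

        # --------------------------------------------- calibrate + reconstruct
        images = []
        metrics: dict = {"wavelengths_nm": config.wavelengths, "per_wavelength": {}}
        mu_maps = {}
        for wl in config.wavelengths:
            stage = "calibrate"
            task, reference = datasets[wl]
            task = task.restrict_to(keys, reason_meta="exclusions+selection")
            _, predicted = solve_cw(
                recon_mesh, probe, pairs=kept, wavelength_nm=wl
            )
            estimated = build_virtual_reference(task, classes)
            wl_metrics: dict = {}
            if config.mode == "reference":
                reference = reference.restrict_to(keys)
                calibrated = reference_calibrate(task, reference, predicted)
                wl_metrics["virtual_reference_error"] = mean_relative_error(
                    estimated, reference
                )
                wl_metrics["virtual_reference_error_by_class"] = {
                    f"{d:.3f}": e
                    for d, e in relative_error_by_class(
                        estimated, reference, classes
                    ).items()
                }
            else:
                calibrated = self_calibrate(task, estimated, predicted)
            calib_report = {
                "classes": [
                    {
                        "d_k_mm": c.d_k,
                        "members": len(c),
                        "class_max": c.class_max,
                        "cov": c.cov,
                    }
                    for c in classes
                ],
                "mode": config.mode,
                **{
                    k: v
                    for k, v in wl_metrics.items()
                    if k == "virtual_reference_error"
                },
            }
            (out / f"calibration_report_{wl:g}nm.json").write_text(
                json.dumps(calib_report, indent=2)
            )

            stage = "reconstruct"
            settings = ReconSettings(
                background_props=background,
                regularization_lambda=config.recon["regularization_lambda"],
                n_iterations=config.recon["n_iterations"],
            )
            image = reconstruct_absorption(calibrated, recon_mesh, probe, settings)
            images.append(image)
            mu_maps[wl] = image.mu_a

            stage = "metrics"
            if spec is not None and len(spec.inclusions) >= 2:
                c0 = np.asarray(spec.inclusions[0].center)
                c1 = np.asarray(spec.inclusions[1].center)
                line = (float(c0[0]), float(c0[2]))
                profile = line_profile_metrics(image, line, n_targets=2)
                split = float((c0[1] + c1[1]) / 2.0)
                peak1, peak2 = split_half_maxima(image, split)
                wl_metrics.update(
                    {
                        "fwhm_mm": profile["fwhm_mm"],
                        "peak_positions_mm": profile["positions_mm"],
                        "profile_contrast_ratio": profile["contrast_ratio"],
                        "peak_mu_a": [peak1, peak2],
                        "contrast_ratio": peak1 / peak2,
                    }
                )
            wl_metrics["residual_history"] = image.residual_history
            metrics["per_wavelength"][f"{wl:g}"] = wl_metrics

            stage = "write"
            pio.save_vtk(
                image.mesh,
                out / f"mu_a_{wl:g}nm.vtk",
                point_data={"mu_a": image.mu_a},
            )
            pio.save_nifti(image.mesh, image.mu_a, out / f"mu_a_{wl:g}nm.nii.gz")
            pio.save_measurements_csv(calibrated, out / f"calibrated_{wl:g}nm.csv")

        # --------------------------------------------------------------- unmix
        cmap = None
        if len(config.wavelengths) >= 2:
            stage = "unmix"
            from .spectra import physiology_summary, threshold_tumor_region, unmix_chromophores

            cmap = unmix_chromophores(mu_maps)
            tumor = threshold_tumor_region(cmap)
            if tumor.any() and (~tumor).any():
                metrics["tumor_background_contrast"] = physiology_summary(
                    cmap, tumor, ~tumor
                )
            for name in ("Hb", "HbO2", "HbT", "StO2"):
                pio.save_nifti(
                    images[0].mesh, cmap.quantity(name), out / f"{name}.nii.gz"
                )
            _stage(manifest, "unmix", wavelengths=len(config.wavelengths))

        stage = "finalize"
        (out / "metrics.json").write_text(json.dumps(metrics, indent=2, default=float))
        bundle = {
            "task": [datasets[wl][0] for wl in config.wavelengths],
        }
        if all(datasets[wl][1] is not None for wl in config.wavelengths):
            bundle["reference"] = [datasets[wl][1] for wl in config.wavelengths]
        pio.save_bundle_h5(bundle, out / "measurements.h5")
        pio.save_measurements_csv(
            datasets[first_wl][0], out / f"task_{first_wl:g}nm.csv"
        )
        manifest["seed"] = config.seed
        manifest["retained_pairs"] = len(kept)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
    except PlateDOTError as exc:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
        raise PipelineStageError(stage, str(exc)) from exc
    except Exception as exc:  # noqa: BLE001 - wrap with stage context
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
        raise PipelineStageError(stage, str(exc)) from exc

    return PipelineResult(
        config=config,
        images=images,
        metrics=metrics,
        manifest=manifest,
        output_dir=out,
        chromophores=cmap,
    )
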