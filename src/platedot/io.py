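"""File formats: measurement tables, probe/phantom configs, meshes, volumes.

Measurement tables are plain CSV (one row per SD pair); multi-wavelength
bundles go to HDF5.  Probe and phantom specs are YAML (or JSON).  Meshes and
nodal fields are written as legacy-ASCII VTK unstructured grids (hexahedral
cells); reconstructed maps are additionally resampled onto a regular 1 mm
grid and saved as NIfTI so standard medical-image viewers can open them.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .calibrate import MeasurementSet
from .errors import InvalidInputError
from .forward import OpticalProperties
from .mesh import SlabMesh
from .probe import ProbeArray, SDPair, build_probe
from .synthgen import Cylinder, PhantomSpec

MEASUREMENT_COLUMNS = [
    "wavelength_nm",
    "source_index",
    "detector_index",
    "amplitude",
    "excluded",
]


# ---------------------------------------------------------------- measurements
def measurements_to_frame(ms: MeasurementSet) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "wavelength_nm": ms.wavelength_nm,
            "source_index": ms.source_index,
            "detector_index": ms.detector_index,
            "amplitude": ms.amplitude,
            "excluded": ms.excluded,
        }
    )


def measurements_from_frame(df: pd.DataFrame, role: str) -> MeasurementSet:
    missing = set(MEASUREMENT_COLUMNS) - set(df.columns)
    if missing:
        raise InvalidInputError(f"measurement table missing columns {sorted(missing)}")
    wl = df["wavelength_nm"].unique()
    if len(wl) != 1:
        raise InvalidInputError(
            "one MeasurementSet per wavelength; use the HDF5 bundle for multi-wavelength"
        )
    return MeasurementSet(
        wavelength_nm=float(wl[0]),
        role=role,
        source_index=df["source_index"].to_numpy(),
        detector_index=df["detector_index"].to_numpy(),
        amplitude=df["amplitude"].to_numpy(float),
        excluded=df["excluded"].to_numpy(bool),
    )


def save_measurements_csv(ms: MeasurementSet, path) -> None:
    measurements_to_frame(ms).to_csv(path, index=False)


def load_measurements_csv(path, role: str) -> MeasurementSet:
    return measurements_from_frame(pd.read_csv(path), role)


def save_bundle_h5(sets: dict, path) -> None:
    """HDF5 bundle: group per role, dataset table per wavelength.

    ``sets`` maps role -> list of MeasurementSet (one per wavelength).
    """
    with h5py.File(path, "w") as f:
        for role, role_sets in sets.items():
            grp = f.create_group(role)
            for ms in role_sets:
                sub = grp.create_group(f"wl_{ms.wavelength_nm:g}")
                sub.attrs["wavelength_nm"] = ms.wavelength_nm
                sub.create_dataset("source_index", data=ms.source_index)
                sub.create_dataset("detector_index", data=ms.detector_index)
                sub.create_dataset("amplitude", data=ms.amplitude)
                sub.create_dataset("excluded", data=ms.excluded)


def load_bundle_h5(path) -> dict:
    out: dict[str, list[MeasurementSet]] = {}
    with h5py.File(path, "r") as f:
        for role in f:
            out[role] = []
            for key in sorted(f[role]):
                sub = f[role][key]
                out[role].append(
                    MeasurementSet(
                        wavelength_nm=float(sub.attrs["wavelength_nm"]),
                        role=role,
                        source_index=sub["source_index"][()],
                        detector_index=sub["detector_index"][()],
                        amplitude=sub["amplitude"][()],
                        excluded=sub["excluded"][()],
                    )
                )
    return out


# ---------------------------------------------------------------- probe config
def save_probe_config(probe: ProbeArray, path, coverage=None) -> None:
    cfg = {
        "n_rows": probe.n_rows,
        "n_cols": probe.n_cols,
        "row_spacing_mm": probe.row_spacing,
        "col_spacing_mm": probe.col_spacing,
        "plate_separation_mm": probe.plate_separation,
        "origin_yz_mm": list(probe.origin_yz),
    }
    if coverage is not None:
        cfg["coverage"] = [int(i) for i in coverage]
    _dump_config(cfg, path)


def load_probe_config(path) -> tuple[ProbeArray, list[int] | None]:
    cfg = _load_config(path)
    probe = build_probe(
        cfg["n_rows"],
        cfg["n_cols"],
        cfg["row_spacing_mm"],
        cfg["col_spacing_mm"],
        cfg["plate_separation_mm"],
        origin_yz=tuple(cfg.get("origin_yz_mm", (0.0, 0.0))),
    )
    return probe, cfg.get("coverage")


# --------------------------------------------------------------- phantom spec
def save_phantom_spec(spec: PhantomSpec, path) -> None:
    bg = spec.background
    cfg = {
        "name": spec.name,
        "slab_shape_mm": list(spec.slab_shape),
        "background": {
            "mu_a": bg.mu_a,
            "mu_s_prime": bg.mu_s_prime,
            "refractive_index": bg.refractive_index,
            "anisotropy_g": bg.anisotropy_g,
        },
        "inclusions": [
            {
                "center_mm": list(inc.center),
                "radius_mm": inc.radius,
                "height_mm": inc.height,
                "axis": inc.axis,
                "mu_a": inc.mu_a,
                **(
                    {"mu_s_prime": inc.mu_s_prime}
                    if inc.mu_s_prime is not None
                    else {}
                ),
            }
            for inc in spec.inclusions
        ],
    }
    _dump_config(cfg, path)


def load_phantom_spec(path) -> PhantomSpec:
    cfg = _load_config(path)
    bg = cfg.get("background", {})
    return PhantomSpec(
        slab_shape=tuple(cfg.get("slab_shape_mm", (44.0, 130.0, 79.0))),
        background=OpticalProperties(
            mu_a=bg.get("mu_a", 0.004),
            mu_s_prime=bg.get("mu_s_prime", 1.0),
            refractive_index=bg.get("refractive_index", 1.33),
            anisotropy_g=bg.get("anisotropy_g", 0.9),
        ),
        inclusions=tuple(
            Cylinder(
                center=tuple(inc["center_mm"]),
                radius=inc["radius_mm"],
                height=inc["height_mm"],
                mu_a=inc["mu_a"],
                axis=inc.get("axis", "x"),
                mu_s_prime=inc.get("mu_s_prime"),
            )
            for inc in cfg.get("inclusions", [])
        ),
        name=cfg.get("name", "custom"),
    )


def _dump_config(cfg: dict, path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(cfg, indent=2))
    else:
        path.write_text(yaml.safe_dump(cfg, sort_keys=False))


def _load_config(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


# ----------------------------------------------------------- exclusion report
def save_exclusion_report(pairs: list[SDPair], path) -> None:
    pd.DataFrame(
        {
            "source_index": [p.source_index for p in pairs],
            "detector_index": [p.detector_index for p in pairs],
            "distance_mm": [p.distance for p in pairs],
            "excluded": [p.excluded for p in pairs],
            "reason": [p.reason or "" for p in pairs],
        }
    ).to_csv(path, index=False)


# ------------------------------------------------------------------------ VTK
# VTK cell node order for a hexahedron vs. our (4dx + 2dy + dz) bit order.
_VTK_HEX_ORDER = [0, 4, 6, 2, 1, 5, 7, 3]


def save_vtk(mesh: SlabMesh, path, point_data: dict | None = None) -> None:
    """Legacy-ASCII VTK unstructured grid with hexahedral cells."""
    lines = [
        "# vtk DataFile Version 3.0",
        "platedot slab mesh",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_nodes} double",
    ]
    lines += [" ".join(f"{v:.9g}" for v in p) for p in mesh.nodes]
    M = mesh.n_elements
    lines.append(f"CELLS {M} {M * 9}")
    reordered = mesh.elements[:, _VTK_HEX_ORDER]
    lines += ["8 " + " ".join(str(n) for n in cell) for cell in reordered]
    lines.append(f"CELL_TYPES {M}")
    lines += ["12"] * M
    if point_data:
        lines.append(f"POINT_DATA {mesh.n_nodes}")
        for name, values in point_data.items():
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines += [f"{float(v):.9g}" for v in values]
    Path(path).write_text("\n".join(lines) + "\n")


def load_vtk(path) -> tuple[np.ndarray, np.ndarray, dict]:
    """Read back points, hexahedral cells (platedot bit order) and point data."""
    tokens = Path(path).read_text().split("\n")
    points = None
    cells = None
    point_data: dict[str, np.ndarray] = {}
    i = 0
    while i < len(tokens):
        line = tokens[i].strip()
        if line.startswith("POINTS"):
            n = int(line.split()[1])
            vals = []
            i += 1
            while len(vals) < 3 * n:
                vals += [float(v) for v in tokens[i].split()]
                i += 1
            points = np.array(vals).reshape(n, 3)
            continue
        if line.startswith("CELLS"):
            m = int(line.split()[1])
            rows = []
            i += 1
            for _ in range(m):
                parts = [int(v) for v in tokens[i].split()]
                rows.append(parts[1:])
                i += 1
            inverse = np.argsort(_VTK_HEX_ORDER)
            cells = np.array(rows)[:, inverse]
            continue
        if line.startswith("SCALARS"):
            name = line.split()[1]
            i += 2  # skip LOOKUP_TABLE
            vals = []
            while len(vals) < len(points) and i < len(tokens):
                stripped = tokens[i].strip()
                if not stripped:
                    i += 1
                    continue
                vals += [float(v) for v in stripped.split()]
                i += 1
            point_data[name] = np.array(vals)
            continue
        i += 1
    return points, cells, point_data


# ---------------------------------------------------------------------- NIfTI
def save_nifti(mesh: SlabMesh, values: np.ndarray, path, grid_mm: float = 1.0) -> None:
    """Resample a nodal field onto a regular ``grid_mm`` lattice and save as
    NIfTI with a millimetre affine."""
    from scipy.interpolate import RegularGridInterpolator

    interp = RegularGridInterpolator(
        mesh.axes, mesh.nodal_lattice(values), bounds_error=False, fill_value=None
    )
    grids = [np.arange(0.0, mesh.extent[a] + grid_mm / 2, grid_mm) for a in range(3)]
    X, Y, Z = np.meshgrid(*grids, indexing="ij")
    vol = interp(np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])).reshape(X.shape)
    img = nib.Nifti1Image(vol.astype(np.float32), np.diag([grid_mm] * 3 + [1.0]))
    nib.save(img, str(path))


def load_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine
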