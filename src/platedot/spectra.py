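"""Spectral unmixing of multi-wavelength absorption maps.

At near-infrared wavelengths the absorption of breast tissue is dominated by
deoxy- and oxyhemoglobin, so per node the reconstructed absorption obeys

    mu_a(lambda) = sum_c  epsilon(c, lambda) * C_c,

a small non-negative least-squares problem per node.  Derived maps: total
hemoglobin HbT = Hb + HbO2 and oxygen saturation StO2 = HbO2 / HbT (masked
where HbT vanishes).  Tumor tissue typically shows elevated HbT and reduced
StO2, which is what the tumor-to-background contrast summary quantifies.

The extinction table ships as a versioned CSV of compiled literature values
(units cm^-1 per mol/L, converted to mm^-1 per uM); it is configuration, not
a constant — water/lipid columns can be added the same way.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .errors import RegionError, UnmixingConfigurationError

#: ln(10) * 1e-6 (mol/L per uM) * 0.1 (mm per cm)
MOLAR_CM_TO_UM_MM = float(np.log(10.0) * 1e-7)


def load_extinction_table(path=None) -> pd.DataFrame:
    """Extinction table with columns chromophore, wavelength_nm, epsilon
    (mm^-1 per uM).  Default: the packaged hemoglobin table."""
    if path is None:
        with resources.files("platedot.data").joinpath("extinction_hb.csv").open() as fh:
            df = pd.read_csv(fh, comment="#")
    else:
        df = pd.read_csv(path, comment="#")
    if "epsilon" not in df.columns:
        if "epsilon_molar_cm_inv_M" not in df.columns:
            raise UnmixingConfigurationError(
                "extinction table needs an 'epsilon' (mm^-1/uM) or "
                "'epsilon_molar_cm_inv_M' column"
            )
        df = df.assign(epsilon=df["epsilon_molar_cm_inv_M"] * MOLAR_CM_TO_UM_MM)
    return df[["chromophore", "wavelength_nm", "epsilon"]]


def extinction_matrix(
    table: pd.DataFrame, wavelengths, chromophores=("Hb", "HbO2")
) -> np.ndarray:
    """(n_wavelengths x n_chromophores) epsilon matrix in mm^-1 per uM."""
    E = np.empty((len(wavelengths), len(chromophores)))
    for r, wl in enumerate(wavelengths):
        for c, chrom in enumerate(chromophores):
            sel = table[
                (table.chromophore == chrom)
                & (np.abs(table.wavelength_nm - wl) < 0.5)
            ]
            if len(sel) != 1:
                raise UnmixingConfigurationError(
                    f"no unique extinction entry for {chrom} at {wl} nm"
                )
            E[r, c] = float(sel.epsilon.iloc[0])
    return E


@dataclass
class ChromophoreMap:
    """Nodal chromophore concentrations (uM) and derived quantities."""

    Hb: np.ndarray
    HbO2: np.ndarray
    wavelengths_nm: tuple
    residual: np.ndarray = None  # per-node unmixing residual norm
    extinction: np.ndarray = None
    meta: dict = field(default_factory=dict)

    @property
    def HbT(self) -> np.ndarray:
        return self.Hb + self.HbO2

    @property
    def StO2(self) -> np.ndarray:
        """HbO2 / HbT, NaN-masked where HbT = 0."""
        hbt = self.HbT
        out = np.full_like(hbt, np.nan, dtype=float)
        nz = hbt > 0
        out[nz] = self.HbO2[nz] / hbt[nz]
        return out

    def quantity(self, name: str) -> np.ndarray:
        return {"Hb": self.Hb, "HbO2": self.HbO2, "HbT": self.HbT, "StO2": self.StO2}[
            name
        ]


def unmix_chromophores(
    absorption_maps: dict[float, np.ndarray],
    extinction_table: pd.DataFrame | None = None,
    chromophores=("Hb", "HbO2"),
) -> ChromophoreMap:
    """Per-node non-negative spectral unmixing of nodal mu_a maps.

    ``absorption_maps`` maps wavelength (nm) to a nodal mu_a array (mm^-1);
    at least as many wavelengths as chromophores are required and the
    extinction matrix must have full column rank.  Nodes whose unconstrained
    least-squares solution is already non-negative are solved in one
    vectorized call; only the remainder runs per-node NNLS.
    """
    wavelengths = tuple(sorted(absorption_maps))
    if len(wavelengths) < 2 or len(wavelengths) < len(chromophores):
        raise UnmixingConfigurationError(
            f"need >= max(2, {len(chromophores)}) wavelengths, got {len(wavelengths)}"
        )
    if extinction_table is None:
        extinction_table = load_extinction_table()
    E = extinction_matrix(extinction_table, wavelengths, chromophores)
    if np.linalg.matrix_rank(E) < E.shape[1]:
        raise UnmixingConfigurationError("extinction matrix is rank deficient")
    A = np.vstack([np.asarray(absorption_maps[wl], float) for wl in wavelengths])
    n_nodes = A.shape[1]
    C, *_ = np.linalg.lstsq(E, A, rcond=None)
    resid = np.linalg.norm(E @ C - A, axis=0)
    negative = np.where((C < -1e-12).any(axis=0))[0]
    for n in negative:
        C[:, n], rnorm = nnls(E, A[:, n])
        resid[n] = rnorm
    conc = {ch: C[k] for k, ch in enumerate(chromophores)}
    return ChromophoreMap(
        Hb=conc.get("Hb", np.zeros(n_nodes)),
        HbO2=conc.get("HbO2", np.zeros(n_nodes)),
        wavelengths_nm=wavelengths,
        residual=resid,
        extinction=E,
        meta={"chromophores": tuple(chromophores)},
    )


def threshold_tumor_region(cmap: ChromophoreMap) -> np.ndarray:
    """Default tumor mask: nodes above half of (max - background) of HbT,
    with the background level taken as the median HbT."""
    hbt = cmap.HbT
    bg = float(np.median(hbt))
    level = bg + (float(hbt.max()) - bg) / 2.0
    return hbt >= level


def physiology_summary(
    cmap: ChromophoreMap, tumor_region: np.ndarray, background_region: np.ndarray
) -> dict[str, float]:
    """Tumor-to-background contrast (mean over tumor / mean over background)
    for Hb, HbO2, HbT and StO2."""
    tumor = np.asarray(tumor_region)
    background = np.asarray(background_region)
    if tumor.dtype == bool:
        tumor = np.where(tumor)[0]
    if background.dtype == bool:
        background = np.where(background)[0]
    if len(tumor) == 0 or len(background) == 0:
        raise RegionError("tumor and background regions must be non-empty")
    out = {}
    for q in ("Hb", "HbO2", "HbT", "StO2"):
        v = cmap.quantity(q)
        num = float(np.nanmean(v[tumor]))
        den = float(np.nanmean(v[background]))
        out[q] = num / den if den != 0 else float("nan")
    return out
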