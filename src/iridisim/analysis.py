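"""End-to-end pipelines: simulation grids and plumage spectra to color tables.

Glue between the optics simulator, the spectral pre-processing and the visual
model: run a set of structures through the transfer-matrix engine and summarise
each spectrum as avian color variables, or take measured/synthetic plumage
spectra through smoothing, rescaling, brightest-spectrum selection and
replicate quality control to the same color variables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .optics import THIN_LAYER_CUTOFF_NM
from .spectra import SpectraTable, qc_pairwise, rescale_nonneg, select_brightest, smooth
from .structures import PhotonicCrystalSpec, derived_metrics
from .tmm import Spectrum, peak_reflectance, simulate_spectrum
from .vision import ConeSet, double_cone_brightness, quantum_catch, to_color_point

__all__ = [
    "color_variables",
    "simulate_color_table",
    "modification_predictors",
    "process_plumage",
]


def color_variables(s: Spectrum, cones: ConeSet) -> dict[str, float]:
    """Cone catches, tetrahedral coordinates, saturation and brightness."""
    catches = [
        quantum_catch(s, curve, cones.wavelengths, von_kries=True)
        for curve in cones.curves
    ]
    point = to_color_point(catches)
    peak = peak_reflectance(s)
    return {
        "u": point.catches[0], "s": point.catches[1],
        "m": point.catches[2], "l": point.catches[3],
        "x": point.xyz[0], "y": point.xyz[1], "z": point.xyz[2],
        "r": point.r,
        "double_cone": double_cone_brightness(s, cones),
        "lambda_peak": peak.lambda_peak,
        "peak_reflectance": peak.R_max,
    }


def modification_predictors(spec: PhotonicCrystalSpec) -> dict[str, int]:
    """Binary thin / hollow / platelet / interaction coding of one structure."""
    m = spec.melanosome
    thin = int(derived_metrics(m)["mt"] < THIN_LAYER_CUTOFF_NM)
    hollow = int(m.kind.is_hollow)
    platelet = int(m.kind.is_platelet)
    return {
        "thin": thin,
        "hollow": hollow,
        "platelet": platelet,
        "hollow_x_platelet": hollow * platelet,
    }


def simulate_color_table(
    specs: list[PhotonicCrystalSpec],
    system: str = "vs",
    step_nm: float = 2.0,
    slices_per_period: int = 40,
) -> pd.DataFrame:
    """Simulate every structure and collect color variables plus predictors.

    Adds the log-transformed brightness responses used by the effect models
    (``log_double_cone``, ``log_peak_reflectance``) and a ``saturation``
    alias for r.
    """
    cones = ConeSet.build(system, np.arange(300.0, 700.0 + step_nm / 2, step_nm))
    rows = []
    for i, spec in enumerate(specs):
        s = simulate_spectrum(spec, step_nm=step_nm, slices_per_period=slices_per_period)
        row = color_variables(s, cones)
        row.update(modification_predictors(spec))
        m = spec.melanosome
        row.update(
            structure_id=i, kind=m.kind.value, d_melsom=m.d_melsom,
            d_air=m.d_air, packing=spec.packing.value, a=spec.a, c=spec.c,
            mt=derived_metrics(m)["mt"],
        )
        rows.append(row)
    df = pd.DataFrame(rows)
    df["saturation"] = df["r"]
    tiny = 1e-12
    df["log_double_cone"] = np.log(df["double_cone"] + tiny)
    df["log_peak_reflectance"] = np.log(df["peak_reflectance"] + tiny)
    return df


def process_plumage(
    table: SpectraTable,
    system: str = "vs",
    span: float = 0.2,
    qc_threshold: float = 0.1,
) -> tuple[pd.DataFrame, list[str]]:
    """Plumage spectra to per-individual color variables plus QC flags.

    Per measurement: LOESS smoothing, shift-to-non-negative rescaling; per
    species/patch/individual the brightest (largest-area) spectrum across
    angles is kept; replicate individuals of a patch further apart than
    ``qc_threshold`` in color space are flagged.
    """
    cones = ConeSet.build(system, table.wavelengths)
    groups = table.meta.groupby(["species", "patch", "individual"]).groups
    rows = []
    points_per_patch: dict[str, list] = {}
    for (species, patch, individual), ids in sorted(groups.items()):
        cols = [c for c in table.data.columns if c in set(ids)]
        processed = {}
        for c in cols:
            y = smooth(table.data[c].to_numpy(), table.wavelengths, span)
            processed[c] = rescale_nonneg(y)
        sub = SpectraTable(
            table.wavelengths,
            pd.DataFrame(processed, columns=cols),
            table.meta.loc[cols],
        )
        best = select_brightest(sub)
        s = Spectrum(table.wavelengths, np.clip(sub.data[best].to_numpy(), 0, 100) / 100.0)
        row = color_variables(s, cones)
        row.update(species=species, patch=patch, individual=individual)
        rows.append(row)
        key = f"{species}:{patch}"
        points_per_patch.setdefault(key, []).append(
            to_color_point([row["u"], row["s"], row["m"], row["l"]])
        )
    flagged = qc_pairwise(points_per_patch, threshold=qc_threshold)
    return pd.DataFrame(rows), flagged
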