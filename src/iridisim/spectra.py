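"""Pre-processing of measured plumage reflectance spectra.

The pipeline mirrors standard museum-spectrophotometry practice: LOESS
smoothing to strip instrument noise, a shift to remove negative reflectance
artefacts, selection of the brightest (largest area-under-curve) spectrum per
plumage patch from the angle-resolved series, and a replicate-consistency
check that flags patches whose two individuals disagree by more than a
threshold distance in color space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .vision import ColorPoint

__all__ = [
    "SpectraTable",
    "smooth",
    "rescale_nonneg",
    "select_brightest",
    "qc_pairwise",
    "read_long_csv",
    "write_long_csv",
]

META_COLUMNS = ("species", "patch", "individual", "angle_deg")


@dataclass
class SpectraTable:
    """A wavelength grid with one reflectance column per measurement.

    ``data`` holds reflectance in percent, one column per measurement id;
    ``meta`` is indexed by measurement id with species / patch / individual /
    angle metadata.
    """

    wavelengths: np.ndarray
    data: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if len(self.wavelengths) != len(self.data):
            raise ValueError("wavelength grid and data rows differ in length")
        if not self.meta.index.is_unique:
            raise ValueError("metadata keys must be unique")
        missing = set(self.data.columns) - set(self.meta.index)
        if missing:
            raise ValueError(f"measurements without metadata: {sorted(missing)}")

    def columns_for(self, **filters) -> list[str]:
        mask = pd.Series(True, index=self.meta.index)
        for key, value in filters.items():
            mask &= self.meta[key] == value
        return [c for c in self.data.columns if mask.get(c, False)]


def smooth(
    reflectance: np.ndarray, wavelengths: np.ndarray, span: float = 0.2
) -> np.ndarray:
    """LOESS smoothing: local linear fits with tricube weights.

    ``span`` is the fraction of points in each local window.  Constant and
    linear inputs are reproduced exactly (up to numerical precision) because
    the local model is a line.
    """
    if not (0.0 < span <= 1.0):
        raise ValueError(f"span must lie in (0, 1], got {span}")
    y = np.asarray(reflectance, dtype=float)
    x = np.asarray(wavelengths, dtype=float)
    if y.size < 10:
        raise ValueError("at least 10 points required for smoothing")
    return lowess(y, x, frac=span, it=0, return_sorted=False)


def rescale_nonneg(
    reflectance: np.ndarray, mode: str = "shift", clip_max: float = 100.0
) -> np.ndarray:
    """Remove negative reflectance values.

    Default ("shift"): if the minimum is negative, shift the whole spectrum up
    so the minimum becomes zero, then clip at ``clip_max`` (values above 100%
    only arise from measurement artefacts).  Alternative ("stretch"): map
    [min, max] linearly onto [0, clip_max].  Non-negative spectra pass through
    the default unchanged.
    """
    y = np.asarray(reflectance, dtype=float)
    if mode == "shift":
        lo = y.min()
        if lo < 0:
            y = y - lo
        return np.clip(y, 0.0, clip_max)
    if mode == "stretch":
        lo, hi = y.min(), y.max()
        if hi == lo:
            return np.zeros_like(y)
        return (y - lo) / (hi - lo) * clip_max
    raise ValueError(f"unknown rescale mode {mode!r}")


def select_brightest(
    table: SpectraTable, columns: list[str] | None = None
) -> str:
    """Column id of the spectrum with the largest area under the curve.

    Ties are broken by column order, so the result is deterministic.
    """
    cols = list(table.data.columns) if columns is None else list(columns)
    if not cols:
        raise ValueError("no spectra to select from")
    areas = [
        np.trapezoid(table.data[c].to_numpy(), table.wavelengths) for c in cols
    ]
    return cols[int(np.argmax(areas))]


def qc_pairwise(
    points_per_patch: dict[str, list[ColorPoint]], threshold: float = 0.1
) -> list[str]:
    """Flag patches whose replicate color points are suspiciously far apart.

    Each patch is expected to carry the replicate (per-individual) color
    points; patches whose pairwise distance exceeds ``threshold`` (strictly)
    are returned for manual review.  Patches with a single replicate raise a
    warning but are not flagged.
    """
    flagged = []
    for patch, points in points_per_patch.items():
        if len(points) < 2:
            warnings.warn(f"patch {patch!r} has fewer than two replicates")
            continue
        xyz = np.array([p.xyz for p in points])
        dmax = max(
            float(np.linalg.norm(xyz[i] - xyz[j]))
            for i in range(len(xyz))
            for j in range(i + 1, len(xyz))
        )
        if dmax > threshold:
            flagged.append(patch)
    return flagged


def read_long_csv(path: str) -> SpectraTable:
    """Read a long-format spectra CSV.

    Expected columns: wavelength_nm, reflectance_pct, species, patch,
    individual, angle_deg.  Measurement ids are built as
    species:patch:individual:angle.
    """
    df = pd.read_csv(path)
    required = {"wavelength_nm", "reflectance_pct", "species", "patch", "individual"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"long-format CSV missing columns: {sorted(missing)}")
    if "angle_deg" not in df.columns:
        df["angle_deg"] = 90.0
    df["_id"] = (
        df["species"].astype(str)
        + ":" + df["patch"].astype(str)
        + ":" + df["individual"].astype(str)
        + ":" + df["angle_deg"].astype(str)
    )
    wl = np.sort(df["wavelength_nm"].unique())
    wide = df.pivot_table(
        index="wavelength_nm", columns="_id", values="reflectance_pct"
    ).reindex(wl)
    meta = (
        df.drop_duplicates("_id")
        .set_index("_id")[["species", "patch", "individual", "angle_deg"]]
    )
    return SpectraTable(wl, wide.reset_index(drop=True), meta)


def write_long_csv(table: SpectraTable, path: str) -> None:
    rows = []
    for col in table.data.columns:
        m = table.meta.loc[col]
        for wl, val in zip(table.wavelengths, table.data[col].to_numpy()):
            rows.append(
                dict(
                    wavelength_nm=wl, reflectance_pct=val, species=m["species"],
                    patch=m["patch"], individual=m["individual"],
                    angle_deg=m["angle_deg"],
                )
            )
    pd.DataFrame(rows).to_csv(path, index=False)
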