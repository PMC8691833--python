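"""Avian visual modelling and the tetrahedral color space.

A reflectance spectrum is mapped to the quantum catches of the four avian
single cones, normalised to relative catches, and placed in the regular
tetrahedron whose vertices correspond to exclusive stimulation of each cone
(circumradius 0.75, achromatic centre at the origin).  Distance from the
origin is the saturation r; diversity of a set of points is summarised by the
mean pairwise distance (color span) and by occupancy of a cubic voxel grid.
Achromatic "brightness" is modelled separately as the catch of the avian
double cone.

Cone sensitivities are built from the standard A1 visual-pigment template
(alpha plus beta band), peak-normalised; the violet-sensitive (VS) and
ultraviolet-sensitive (UVS) cone sets use the conventional "average" peak
wavelengths for the two avian visual systems.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field
from itertools import product as _iterproduct

import numpy as np
from scipy.optimize import linprog
from scipy.spatial.distance import pdist

from .tmm import Spectrum

__all__ = [
    "TETRA_VERTICES",
    "MAX_SATURATION",
    "ConeSet",
    "ColorPoint",
    "pigment_template",
    "quantum_catch",
    "to_color_point",
    "mean_color_span",
    "voxel_stats",
    "double_cone_brightness",
]

#: u, s, m, l vertices of the color tetrahedron (circumradius 0.75).
TETRA_VERTICES = np.array(
    [
        [0.0, 0.0, 0.75],
        [-0.61237, -0.35355, -0.25],
        [0.61237, -0.35355, -0.25],
        [0.0, 0.70711, -0.25],
    ]
)

MAX_SATURATION = 0.75

#: Single-cone peak wavelengths (u, s, m, l) for the two avian visual systems,
#: and the double-cone peak.
CONE_LAMBDA_MAX = {"vs": (416.0, 478.0, 542.0, 607.0), "uvs": (372.0, 456.0, 544.0, 609.0)}
DOUBLE_CONE_LAMBDA_MAX = 571.0


def pigment_template(lambda_max_nm: float, wavelengths: np.ndarray) -> np.ndarray:
    """A1 visual-pigment absorbance template, peak-normalised.

    Alpha band plus beta band of the Govardovskii-type rhodopsin template,
    valid for peak wavelengths from the near-UV through the red.
    """
    if not (330.0 <= lambda_max_nm <= 700.0):
        raise ValueError(
            f"lambda_max {lambda_max_nm} nm outside template validity range [330, 700]"
        )
    wl = np.asarray(wavelengths, dtype=float)
    x = lambda_max_nm / wl
    A, B, C, D = 69.7, 28.0, -14.9, 0.674
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max_nm - 300.0) ** 2) / 11940.0)
    alpha = 1.0 / (
        np.exp(A * (a - x)) + np.exp(B * (0.922 - x)) + np.exp(C * (1.104 - x)) + D
    )
    lmb = 189.0 + 0.315 * lambda_max_nm
    bwid = -40.5 + 0.195 * lambda_max_nm
    beta = 0.26 * np.exp(-(((wl - lmb) / bwid) ** 2))
    s = alpha + beta
    return s / s.max()


@dataclass
class ConeSet:
    """Sensitivity curves of the four single cones plus the double cone."""

    system: str
    lambda_max: tuple[float, float, float, float]
    double_cone_lambda_max: float
    wavelengths: np.ndarray
    curves: np.ndarray  # (4, n_wl)
    double_cone_curve: np.ndarray

    @classmethod
    def build(cls, system: str = "vs", wavelengths: np.ndarray | None = None) -> "ConeSet":
        system = system.lower()
        if system not in CONE_LAMBDA_MAX:
            raise ValueError(f"unknown visual system {system!r}; use 'vs' or 'uvs'")
        if wavelengths is None:
            wavelengths = np.arange(300.0, 701.0, 1.0)
        wl = np.asarray(wavelengths, dtype=float)
        lmax = CONE_LAMBDA_MAX[system]
        curves = np.array([pigment_template(l, wl) for l in lmax])
        dc = pigment_template(DOUBLE_CONE_LAMBDA_MAX, wl)
        return cls(system, lmax, DOUBLE_CONE_LAMBDA_MAX, wl, curves, dc)


@dataclass(frozen=True)
class ColorPoint:
    """Relative cone catches, tetrahedral coordinates and saturation."""

    catches: tuple[float, float, float, float]
    xyz: tuple[float, float, float]
    r: float


def _resample(spectrum_wl, values, target_wl) -> np.ndarray:
    if np.array_equal(spectrum_wl, target_wl):
        return values
    return np.interp(target_wl, spectrum_wl, values)


def quantum_catch(
    s: Spectrum,
    curve: np.ndarray,
    curve_wavelengths: np.ndarray | None = None,
    illuminant: np.ndarray | None = None,
    von_kries: bool = False,
) -> float:
    """Trapezoidal integral of reflectance x sensitivity x illuminant.

    The illuminant defaults to equal-energy (flat).  Sensitivity curves on a
    different grid are linearly resampled onto the spectrum's grid.  With
    ``von_kries=True`` the catch is divided by the catch of a perfect (100%)
    reflector, the usual chromatic-adaptation normalisation; a flat spectrum
    then stimulates all receptors equally and maps to the achromatic origin.
    """
    wl = s.wavelengths
    if curve_wavelengths is not None:
        curve = _resample(np.asarray(curve_wavelengths, float), curve, wl)
    curve = np.asarray(curve, dtype=float)
    if curve.shape != wl.shape:
        raise ValueError("sensitivity grid does not match the spectrum grid")
    illum = np.ones_like(wl) if illuminant is None else np.asarray(illuminant, float)
    if illum.shape != wl.shape:
        raise ValueError("illuminant grid does not match the spectrum grid")
    q = float(np.trapezoid(s.reflectance * curve * illum, wl))
    if von_kries:
        q /= float(np.trapezoid(curve * illum, wl))
    return q


def to_color_point(raw_catches) -> ColorPoint:
    """Map four non-negative cone catches to the tetrahedral color space."""
    q = np.asarray(raw_catches, dtype=float)
    if q.shape != (4,):
        raise ValueError("exactly four cone catches required")
    if np.any(q < 0):
        raise ValueError("cone catches must be non-negative")
    total = q.sum()
    if total <= 0:
        raise ValueError("at least one cone catch must be positive")
    rel = q / total
    xyz = rel @ TETRA_VERTICES
    r = float(np.linalg.norm(xyz))
    return ColorPoint(tuple(rel), tuple(xyz), r)


def mean_color_span(points: list[ColorPoint]) -> float:
    """Mean pairwise Euclidean distance between color points."""
    if len(points) < 2:
        raise ValueError("at least two points required for a color span")
    xyz = np.array([p.xyz for p in points])
    return float(pdist(xyz).mean())


def _tetra_halfspaces() -> tuple[np.ndarray, np.ndarray]:
    A, b = [], []
    for i in range(4):
        face = np.delete(np.arange(4), i)
        p0, p1, p2 = TETRA_VERTICES[face]
        nrm = np.cross(p1 - p0, p2 - p0)
        if np.dot(nrm, TETRA_VERTICES[i] - p0) < 0:
            nrm = -nrm
        A.append(-nrm)
        b.append(-np.dot(nrm, p0))
    return np.array(A), np.array(b)


@functools.lru_cache(maxsize=8)
def _total_voxels(resolution: float, rule: str) -> int:
    """Voxels of a cubic grid (anchored at the tetra bounding-box minimum)
    that belong to the tetrahedron under the given rule."""
    A, b = _tetra_halfspaces()
    lo = TETRA_VERTICES.min(axis=0)
    hi = TETRA_VERTICES.max(axis=0)
    nc = np.ceil((hi - lo) / resolution - 1e-9).astype(int)
    count = 0
    for ijk in _iterproduct(*(range(n) for n in nc)):
        cl = lo + np.array(ijk) * resolution
        ch = cl + resolution
        if rule == "center":
            ctr = cl + resolution / 2.0
            if np.all(A @ ctr <= b + 1e-12):
                count += 1
        elif rule == "intersect":
            res = linprog(
                c=[0.0, 0.0, 0.0], A_ub=A, b_ub=b,
                bounds=list(zip(cl, ch)), method="highs",
            )
            if res.status == 0:
                count += 1
        else:
            raise ValueError(f"unknown voxel rule {rule!r}")
    return count


def voxel_stats(
    points: list[ColorPoint], resolution: float = 0.1, rule: str = "intersect"
) -> dict[str, int]:
    """Occupied and total voxel counts of the color space at a resolution.

    The grid is axis-aligned with cubic cells of side ``resolution``, anchored
    at the minimum corner of the tetrahedron's bounding box.  ``total`` counts
    cells belonging to the tetrahedron under ``rule`` ("intersect": the cube
    meets the tetrahedron volume, the default; "center": the cube centre lies
    inside).  ``occupied`` counts cells containing at least one point.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    lo = TETRA_VERTICES.min(axis=0)
    hi = TETRA_VERTICES.max(axis=0)
    nc = np.ceil((hi - lo) / resolution - 1e-9).astype(int)
    occupied = 0
    if points:
        xyz = np.array([p.xyz for p in points])
        idx = np.floor((xyz - lo) / resolution - 1e-12).astype(int)
        idx = np.clip(idx, 0, nc - 1)
        occupied = int(np.unique(idx, axis=0).shape[0])
    return {"occupied": occupied, "total": _total_voxels(float(resolution), rule)}


def double_cone_brightness(s: Spectrum, cones: ConeSet) -> float:
    """Quantum catch against the double-cone sensitivity (achromatic channel)."""
    return quantum_catch(s, cones.double_cone_curve, cones.wavelengths)
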