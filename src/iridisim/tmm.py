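"""Normal-incidence reflectance of melanosome photonic crystals.

The two-dimensional unit cell of a structure is reduced to a stack of thin
homogeneous slabs by slicing it in depth and averaging the permittivity of
melanin, air and keratin over each slice (exact for fields parallel to the
layer interfaces at normal incidence).  Reflectance then follows from the
standard characteristic-matrix (transfer-matrix) product for a multilayer
between an air incident medium and a semi-infinite keratin substrate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .optics import DEFAULT_CONSTANTS, OpticalConstants, melanin_index
from .structures import (
    PhotonicCrystalSpec,
    cross_section_fractions,
    total_depth,
)

__all__ = [
    "LayerStack",
    "Spectrum",
    "effective_index",
    "build_stack",
    "tmm_reflectance",
    "tmm_rt",
    "simulate_spectrum",
    "peak_reflectance",
]


@dataclass
class Spectrum:
    """Reflectance (fraction) on an ascending wavelength grid in 300-700 nm."""

    wavelengths: np.ndarray
    reflectance: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if self.wavelengths.shape != self.reflectance.shape:
            raise ValueError("wavelength and reflectance grids differ in shape")
        if self.wavelengths.size and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(self.reflectance < -1e-12) or np.any(self.reflectance > 1 + 1e-12):
            raise ValueError("reflectance must lie in [0, 1]")
        self.reflectance = np.clip(self.reflectance, 0.0, 1.0)


@dataclass
class LayerStack:
    """Ordered slabs of (thickness nm, complex index) between two media."""

    thicknesses: np.ndarray
    indices: np.ndarray
    incident_medium: complex = 1.0
    exit_medium: complex = 1.56

    def __post_init__(self) -> None:
        self.thicknesses = np.asarray(self.thicknesses, dtype=float)
        self.indices = np.asarray(self.indices, dtype=complex)
        if self.thicknesses.shape[0] != self.indices.shape[0]:
            raise ValueError("one index per slab required")
        if np.any(self.thicknesses <= 0):
            raise ValueError("slab thicknesses must be positive")
        if np.any(self.indices.imag < -1e-12):
            raise ValueError("extinction (imaginary part) must be >= 0")


def effective_index(
    fractions: dict[str, float],
    wavelength_nm: float,
    constants: OpticalConstants = DEFAULT_CONSTANTS,
) -> complex:
    """Volume-averaged (permittivity-mixed) complex index of one slice."""
    f_mel = fractions["f_mel"]
    f_air = fractions["f_air"]
    f_ker = fractions["f_ker"]
    for name, f in (("f_mel", f_mel), ("f_air", f_air), ("f_ker", f_ker)):
        if not (-1e-12 <= f <= 1 + 1e-12):
            raise ValueError(f"{name}={f} outside [0, 1]")
    if abs(f_mel + f_air + f_ker - 1.0) > 1e-9:
        raise ValueError("area fractions must sum to 1")
    n_mel = melanin_index(wavelength_nm, constants) + 1j * constants.k_mel
    n_ker = constants.n_ker + 1j * constants.k_ker
    n_air = complex(constants.n_air)
    eps = f_mel * n_mel**2 + f_air * n_air**2 + f_ker * n_ker**2
    n = np.sqrt(eps)
    if n.imag < 0:
        n = -n
    return complex(n)


def _fraction_profile(
    spec: PhotonicCrystalSpec, slices_per_period: int
) -> tuple[np.ndarray, np.ndarray]:
    """Slice the structure below the cortex: (thicknesses, fractions (L,3))."""
    from .structures import vertical_period

    vp = vertical_period(spec)
    dz = vp / slices_per_period
    T = total_depth(spec)
    depth0 = spec.c
    n_slices = int(round((T - depth0) / dz))
    mids = depth0 + (np.arange(n_slices) + 0.5) * dz
    fr = np.empty((n_slices, 3))
    for i, z in enumerate(mids):
        f = cross_section_fractions(spec, min(z, T))
        fr[i] = (f["f_mel"], f["f_air"], f["f_ker"])
    return np.full(n_slices, dz), fr


def build_stack(
    spec: PhotonicCrystalSpec,
    wavelength_nm: float,
    slices_per_period: int = 80,
    constants: OpticalConstants = DEFAULT_CONSTANTS,
) -> LayerStack:
    """Depth-sliced effective-index stack for one structure at one wavelength."""
    if slices_per_period < 10:
        raise ValueError("slices_per_period must be >= 10")
    d, fr = _fraction_profile(spec, slices_per_period)
    idx = np.array(
        [
            effective_index(
                {"f_mel": f[0], "f_air": f[1], "f_ker": f[2]},
                wavelength_nm,
                constants,
            )
            for f in fr
        ]
    )
    if spec.c > 0:
        d = np.concatenate([[spec.c], d])
        idx = np.concatenate(
            [[complex(constants.n_ker, constants.k_ker)], idx]
        )
    return LayerStack(d, idx, incident_medium=1.0, exit_medium=constants.n_ker)


def _char_matrix_rt(
    thicknesses: np.ndarray,
    indices: np.ndarray,
    wavelengths: np.ndarray,
    n_in: complex,
    n_out: complex,
) -> tuple[np.ndarray, np.ndarray]:
    """Characteristic-matrix R and T, vectorised over wavelength.

    ``indices`` has shape (L,) or (L, W).  Uses the N = n - ik sign convention
    internally, so stored indices with non-negative imaginary parts are
    conjugated on entry.
    """
    wavelengths = np.atleast_1d(np.asarray(wavelengths, dtype=float))
    W = wavelengths.shape[0]
    idx = np.asarray(indices, dtype=complex)
    if idx.ndim == 1:
        idx = np.broadcast_to(idx[:, None], (idx.shape[0], W))
    N = idx.conj()  # n - ik
    eta0 = complex(n_in).conjugate()
    etas = complex(n_out).conjugate()

    B = np.ones(W, dtype=complex)
    C = np.full(W, etas, dtype=complex)
    for j in range(N.shape[0] - 1, -1, -1):
        if thicknesses[j] == 0:
            continue
        delta = 2.0 * np.pi * N[j] * thicknesses[j] / wavelengths
        cd = np.cos(delta)
        sd = np.sin(delta)
        eta = N[j]
        B, C = cd * B + 1j * sd / eta * C, 1j * eta * sd * B + cd * C
    denom = eta0 * B + C
    r = (eta0 * B - C) / denom
    R = np.abs(r) ** 2
    T = 4.0 * eta0.real * etas.real / np.abs(denom) ** 2
    return R, T


def tmm_rt(stack: LayerStack, wavelength_nm: float | np.ndarray) -> tuple:
    """Intensity reflectance and transmittance at normal incidence."""
    wl = np.atleast_1d(np.asarray(wavelength_nm, dtype=float))
    if np.any(wl <= 0):
        raise ValueError("wavelength must be positive")
    R, T = _char_matrix_rt(
        stack.thicknesses, stack.indices, wl, stack.incident_medium, stack.exit_medium
    )
    if np.any(np.isnan(R)) or np.any(np.isnan(T)):
        raise ArithmeticError("NaN encountered in transfer-matrix product")
    if np.isscalar(wavelength_nm):
        return float(R[0]), float(T[0])
    return R, T


def tmm_reflectance(stack: LayerStack, wavelength_nm: float) -> float:
    """Normal-incidence intensity reflectance of a stack; in [0, 1]."""
    R, _ = tmm_rt(stack, wavelength_nm)
    return float(np.clip(R, 0.0, 1.0))


def simulate_spectrum(
    spec: PhotonicCrystalSpec,
    step_nm: float = 1.0,
    constants: OpticalConstants = DEFAULT_CONSTANTS,
    slices_per_period: int = 80,
) -> Spectrum:
    """Reflectance spectrum of a structure over the bird-visible window.

    The geometric slicing is wavelength-independent, so the fraction profile is
    computed once and only the melanin dispersion varies across the grid.
    """
    if step_nm <= 0 or abs(400.0 / step_nm - round(400.0 / step_nm)) > 1e-9:
        raise ValueError("step_nm must evenly divide the 400 nm span")
    wl = np.arange(300.0, 700.0 + step_nm / 2.0, step_nm)
    d, fr = _fraction_profile(spec, slices_per_period)
    n_mel = np.array([melanin_index(w, constants) for w in wl]) + 1j * constants.k_mel
    n_ker = constants.n_ker + 1j * constants.k_ker
    eps = (
        fr[:, 0][:, None] * n_mel[None, :] ** 2
        + fr[:, 1][:, None] * constants.n_air**2
        + fr[:, 2][:, None] * n_ker**2
    )
    idx = np.sqrt(eps)
    idx = np.where(idx.imag < 0, -idx, idx)
    if spec.c > 0:
        d = np.concatenate([[spec.c], d])
        idx = np.vstack([np.full((1, wl.size), n_ker, dtype=complex), idx])
    R, _ = _char_matrix_rt(d, idx, wl, 1.0, constants.n_ker)
    return Spectrum(wl, np.clip(R, 0.0, 1.0))


class PeakReflectance(NamedTuple):
    lambda_peak: float
    R_max: float


def peak_reflectance(s: Spectrum) -> PeakReflectance:
    """Wavelength and value of maximum reflectance; ties go to the shortest."""
    if s.wavelengths.size == 0:
        raise ValueError("empty spectrum")
    i = int(np.argmax(s.reflectance))
    return PeakReflectance(float(s.wavelengths[i]), float(s.reflectance[i]))
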