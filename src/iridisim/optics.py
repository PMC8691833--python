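"""Multilayer interference conditions for melanin/keratin feather nanostructures.

A one-dimensional photonic crystal made of alternating melanin and keratin
layers produces its brightest (first-order) interference peak when the optical
thickness of one repeating unit is half a wavelength,

    t_mel * n_mel + t_ker * n_ker = lambda / 2,

and reflectance is maximal when the two layers each carry a quarter wavelength
of optical thickness.  Restricting the reinforced wavelength to the
bird-visible spectrum (300-700 nm) turns these conditions into closed-form
bounds on the melanin-layer and air-layer thicknesses that a feather structure
"tuned" for brilliant iridescence should respect.  This module provides those
bounds, the melanin dispersion model behind them, and the inverse problem
(which wavelength a given layer pair reinforces).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple

__all__ = [
    "OpticalConstants",
    "DEFAULT_CONSTANTS",
    "THIN_LAYER_CUTOFF_NM",
    "melanin_index",
    "half_wave_bound",
    "quarter_wave",
    "expected_melanin_range",
    "expected_air_range",
    "first_order_peak",
    "is_thin",
    "fdtd_points_per_wave",
]

#: Melanin layers thinner than this (nm) count as "thin"; the cut sits at the
#: antimode of the bimodal solid-rod diameter distribution.
THIN_LAYER_CUTOFF_NM = 190.0

_WL_MIN = 300.0
_WL_MAX = 700.0


@dataclass(frozen=True)
class OpticalConstants:
    """Refractive indices and extinction coefficients of the three materials.

    Melanin is dispersive: its real index is anchored at the two ends of the
    bird-visible spectrum and interpolated linearly in between (see
    :func:`melanin_index`).  Keratin is modelled as dispersion-free and
    lossless; air is vacuum-like.
    """

    n_mel_300: float = 2.0
    n_mel_700: float = 1.7
    k_mel: float = 0.1
    n_ker: float = 1.56
    k_ker: float = 0.0
    n_air: float = 1.0

    def __post_init__(self) -> None:
        for name in ("n_mel_300", "n_mel_700", "n_ker", "n_air"):
            if getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        for name in ("k_mel", "k_ker"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")

    def with_overrides(self, **kwargs: float) -> "OpticalConstants":
        """Return a copy with some fields replaced (used by YAML config)."""
        return replace(self, **kwargs)


DEFAULT_CONSTANTS = OpticalConstants()


def melanin_index(
    wavelength_nm: float, constants: OpticalConstants = DEFAULT_CONSTANTS
) -> float:
    """Real part of the melanin refractive index at ``wavelength_nm``.

    Linear interpolation between the anchors at 300 and 700 nm; raises for
    wavelengths outside the bird-visible window.
    """
    if not (_WL_MIN <= wavelength_nm <= _WL_MAX):
        raise ValueError(
            f"wavelength {wavelength_nm} nm outside bird-visible range "
            f"[{_WL_MIN:g}, {_WL_MAX:g}] nm"
        )
    frac = (wavelength_nm - _WL_MIN) / (_WL_MAX - _WL_MIN)
    return constants.n_mel_300 + frac * (constants.n_mel_700 - constants.n_mel_300)


def _melanin_index_clamped(wavelength_nm: float, constants: OpticalConstants) -> float:
    """Melanin index with anchor values held constant outside 300-700 nm."""
    wl = min(max(wavelength_nm, _WL_MIN), _WL_MAX)
    return melanin_index(wl, constants)


def half_wave_bound(wavelength_nm: float, n: float) -> float:
    """Strict upper bound lambda/(2n) on a single layer reinforcing ``wavelength_nm``.

    At this thickness the layer alone carries the whole half-wave optical
    thickness, leaving no room for the second material, so real structures must
    stay below it.
    """
    if wavelength_nm <= 0:
        raise ValueError(f"wavelength must be positive, got {wavelength_nm}")
    if n < 1:
        raise ValueError(f"refractive index must be >= 1, got {n}")
    return wavelength_nm / (2.0 * n)


def quarter_wave(wavelength_nm: float, n: float) -> float:
    """Quarter-wave thickness lambda/(4n): the maximal-reflectance condition."""
    if wavelength_nm <= 0:
        raise ValueError(f"wavelength must be positive, got {wavelength_nm}")
    if n < 1:
        raise ValueError(f"refractive index must be >= 1, got {n}")
    return wavelength_nm / (4.0 * n)


def expected_melanin_range(
    constants: OpticalConstants = DEFAULT_CONSTANTS,
) -> tuple[float, float]:
    """Expected melanin layer thickness range (nm) for bird-visible tuning.

    Lower end: quarter-wave thickness for 300 nm light (below which no
    bird-visible wavelength can be reinforced maximally).  Upper end: the
    half-wave bound for 700 nm light, rounded to the nearest integer nanometre
    as conventionally printed.
    """
    lo = quarter_wave(_WL_MIN, constants.n_mel_300)
    hi = round(half_wave_bound(_WL_MAX, constants.n_mel_700))
    return (lo, hi)


def expected_air_range(
    constants: OpticalConstants = DEFAULT_CONSTANTS,
) -> tuple[float, float]:
    """Expected air-layer (hollow interior) thickness range (nm), n_air = 1."""
    lo = quarter_wave(_WL_MIN, constants.n_air)
    hi = half_wave_bound(_WL_MAX, constants.n_air)
    return (lo, hi)


class FirstOrderPeak(NamedTuple):
    wavelength_nm: float
    within_visible: bool


def first_order_peak(
    t_mel_nm: float,
    t_ker_nm: float,
    constants: OpticalConstants = DEFAULT_CONSTANTS,
    tol: float = 1e-6,
    max_iter: int = 100,
    damping: float = 0.5,
) -> FirstOrderPeak:
    """Wavelength whose first-order condition a melanin/keratin pair satisfies.

    Solves ``lambda = 2 (t_mel * n_mel(lambda) + t_ker * n_ker)`` by damped
    fixed-point iteration; the melanin index is clamped to its anchor values
    outside 300-700 nm.  The result is flagged when it falls outside the
    bird-visible window.
    """
    if t_mel_nm < 0 or t_ker_nm < 0:
        raise ValueError("layer thicknesses must be non-negative")
    if t_mel_nm == 0 and t_ker_nm == 0:
        raise ValueError("at least one layer must have positive thickness")

    lam = 2.0 * (t_mel_nm * constants.n_mel_300 + t_ker_nm * constants.n_ker)
    for _ in range(max_iter):
        target = 2.0 * (
            t_mel_nm * _melanin_index_clamped(lam, constants)
            + t_ker_nm * constants.n_ker
        )
        new = (1.0 - damping) * lam + damping * target
        if abs(new - lam) < tol:
            lam = new
            break
        lam = new
    else:
        raise ArithmeticError(
            f"first-order peak iteration did not converge within {max_iter} steps"
        )
    return FirstOrderPeak(lam, _WL_MIN <= lam <= _WL_MAX)


def is_thin(melanin_layer_nm: float, doubled_wall: bool = False) -> bool:
    """Whether a melanin layer counts as "thin" (< 190 nm).

    ``doubled_wall=True`` applies the cut to twice the supplied thickness, for
    the reading in which two hollow-melanosome walls form one optical layer.
    """
    if melanin_layer_nm <= 0:
        raise ValueError(f"layer thickness must be positive, got {melanin_layer_nm}")
    t = 2.0 * melanin_layer_nm if doubled_wall else melanin_layer_nm
    return t < THIN_LAYER_CUTOFF_NM


def fdtd_points_per_wave(
    resolution_px_per_um: float = 80.0,
    wavelength_nm: float = 300.0,
    n: float = 2.0,
) -> float:
    """Grid points per wavelength for a finite-difference solver resolution.

    The wavelength inside a medium of index ``n`` is ``wavelength_nm / n``;
    at 80 px/um a 300 nm wave in melanin (n = 2) is sampled by 12 points.
    """
    if resolution_px_per_um <= 0 or wavelength_nm <= 0 or n < 1:
        raise ValueError("resolution and wavelength must be positive, n >= 1")
    return resolution_px_per_um * 1e-3 * wavelength_nm / n
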