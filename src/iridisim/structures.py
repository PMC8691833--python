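"""Melanosome geometry, photonic-crystal unit cells and simulation grids.

Melanosomes come in five forms: thick solid rods (the ancestral,
black-feather-like form), thin solid rods, hollow rods, solid platelets and
hollow platelets.  A photonic-crystal structure stacks layers of one form in
keratin, either as a plain multilayer (laminar) or on a two-dimensional
hexagonal lattice.  This module defines those objects, their derived metrics
(melanin layer thickness, hollowness, flatness), the Cartesian parameter grids
used for the reflectance simulations, and the depth-slicing geometry that
feeds the effective-index optics.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .optics import THIN_LAYER_CUTOFF_NM

__all__ = [
    "MelanosomeKind",
    "Packing",
    "Melanosome",
    "PhotonicCrystalSpec",
    "TABLE_GRID",
    "derived_metrics",
    "keratin_spacing",
    "classify_rod",
    "enumerate_grid",
    "cross_section_fractions",
    "vertical_period",
    "total_depth",
    "grid_to_frame",
    "grid_to_csv",
    "grid_from_csv",
    "read_structure_database",
]


class MelanosomeKind(str, enum.Enum):
    THICK_SOLID_ROD = "thick_solid_rod"
    THIN_SOLID_ROD = "thin_solid_rod"
    HOLLOW_ROD = "hollow_rod"
    SOLID_PLATELET = "solid_platelet"
    HOLLOW_PLATELET = "hollow_platelet"

    @property
    def is_hollow(self) -> bool:
        return self in (MelanosomeKind.HOLLOW_ROD, MelanosomeKind.HOLLOW_PLATELET)

    @property
    def is_platelet(self) -> bool:
        return self in (MelanosomeKind.SOLID_PLATELET, MelanosomeKind.HOLLOW_PLATELET)

    @property
    def is_rod(self) -> bool:
        return not self.is_platelet


class Packing(str, enum.Enum):
    LAMINAR = "laminar"
    HEXAGONAL = "hexagonal"


@dataclass(frozen=True)
class Melanosome:
    """Geometry of a single melanosome.

    ``d_melsom`` is the shortest-axis diameter, ``d_air`` the internal
    air-core diameter (0 for solid forms) and ``l_melsom`` the longest
    cross-section axis (equal to ``d_melsom`` for rods).
    """

    kind: MelanosomeKind
    d_melsom: float
    d_air: float = 0.0
    l_melsom: float | None = None

    def __post_init__(self) -> None:
        kind = MelanosomeKind(self.kind)
        object.__setattr__(self, "kind", kind)
        if self.d_melsom <= 0:
            raise ValueError(f"d_melsom must be positive, got {self.d_melsom}")
        if self.l_melsom is None:
            object.__setattr__(self, "l_melsom", self.d_melsom)
        if not (0 <= self.d_air < self.d_melsom):
            raise ValueError(
                f"d_air must satisfy 0 <= d_air < d_melsom, got {self.d_air}"
            )
        if self.l_melsom < self.d_melsom:
            raise ValueError("l_melsom must be >= d_melsom")
        if not kind.is_hollow and self.d_air != 0:
            raise ValueError(f"{kind.value} must have d_air = 0")
        if kind.is_hollow and self.d_air == 0:
            raise ValueError(f"{kind.value} must have d_air > 0")
        if kind.is_platelet and not self.l_melsom > self.d_melsom:
            raise ValueError("platelets must have l_melsom > d_melsom")
        if kind.is_rod and self.l_melsom != self.d_melsom:
            raise ValueError("rods must have l_melsom == d_melsom")


@dataclass(frozen=True)
class PhotonicCrystalSpec:
    """One simulated structure: a melanosome, its packing and stacking."""

    melanosome: Melanosome
    packing: Packing = Packing.LAMINAR
    a: float = 0.0  # lattice spacing, centre-to-centre (nm)
    c: float = 0.0  # keratin cortex thickness (nm)
    n_layers: int = 4

    def __post_init__(self) -> None:
        object.__setattr__(self, "packing", Packing(self.packing))
        d = self.melanosome.d_melsom
        if self.a < d:
            raise ValueError(
                f"lattice spacing a={self.a} smaller than melanosome diameter {d}"
            )
        if self.c < 0:
            raise ValueError("cortex thickness must be non-negative")
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if self.packing is Packing.HEXAGONAL and self.melanosome.kind.is_platelet:
            raise ValueError("hexagonal packing is only defined for rod kinds")

    @property
    def relative_spacing(self) -> float:
        """r_melsom / a; in (0, 0.5] by the a >= d invariant."""
        return (self.melanosome.d_melsom / 2.0) / self.a


def derived_metrics(m: Melanosome) -> dict[str, float]:
    """Melanin layer thickness, hollowness and flatness of one melanosome.

    The melanin layer thickness ``mt`` is the whole diameter for solid forms
    and a single wall, (d_melsom - d_air)/2, for hollow forms.
    """
    mt = m.d_melsom if not m.kind.is_hollow else (m.d_melsom - m.d_air) / 2.0
    return {
        "mt": mt,
        "hollowness": m.d_air / m.d_melsom,
        "flatness": m.l_melsom / m.d_melsom,
    }


def keratin_spacing(spec: PhotonicCrystalSpec) -> float:
    """Keratin thickness between melanosomes at the thinnest point: a - d."""
    ks = spec.a - spec.melanosome.d_melsom
    if ks < 0:
        raise ValueError("invariant violation: a < d_melsom")
    return ks


def classify_rod(diameter_nm: float) -> MelanosomeKind:
    """Thin vs thick solid rod by the 190 nm diameter cut."""
    if diameter_nm <= 0:
        raise ValueError(f"diameter must be positive, got {diameter_nm}")
    if diameter_nm < THIN_LAYER_CUTOFF_NM:
        return MelanosomeKind.THIN_SOLID_ROD
    return MelanosomeKind.THICK_SOLID_ROD


# Simulation grid: ranges (min, max, n_steps) per melanosome kind.  Evenly
# spaced inclusive sequences; flatness fixed per kind; hexagonal packing is
# added for rods only.
TABLE_GRID: Mapping[MelanosomeKind, dict] = {
    MelanosomeKind.THICK_SOLID_ROD: dict(
        diameter=(190.0, 300.0, 30), hollowness=(0.0, 0.0, 1),
        flatness=1.0, rel_spacing=(0.15, 0.5, 5), cortex=(5.0, 1000.0, 3),
        hexagonal=True,
    ),
    MelanosomeKind.THIN_SOLID_ROD: dict(
        diameter=(65.0, 180.0, 30), hollowness=(0.0, 0.0, 1),
        flatness=1.0, rel_spacing=(0.15, 0.5, 5), cortex=(5.0, 1000.0, 3),
        hexagonal=True,
    ),
    MelanosomeKind.HOLLOW_ROD: dict(
        diameter=(135.0, 440.0, 10), hollowness=(0.26, 0.69, 3),
        flatness=1.0, rel_spacing=(0.15, 0.5, 5), cortex=(5.0, 1000.0, 3),
        hexagonal=True,
    ),
    MelanosomeKind.SOLID_PLATELET: dict(
        diameter=(45.0, 140.0, 30), hollowness=(0.0, 0.0, 1),
        flatness=2.4, rel_spacing=(0.15, 0.5, 5), cortex=(5.0, 1000.0, 3),
        hexagonal=False,
    ),
    MelanosomeKind.HOLLOW_PLATELET: dict(
        diameter=(135.0, 280.0, 10), hollowness=(0.26, 0.69, 3),
        flatness=2.4, rel_spacing=(0.15, 0.5, 5), cortex=(5.0, 1000.0, 3),
        hexagonal=False,
    ),
}


def _steps(lo: float, hi: float, n: int) -> np.ndarray:
    if n == 1:
        return np.array([lo])
    return np.linspace(lo, hi, n)


def enumerate_grid(
    kind: MelanosomeKind | str,
    n_layers: int = 4,
    duplicate_laminar: bool = False,
) -> list[PhotonicCrystalSpec]:
    """All structures in the simulation grid for one melanosome kind.

    Cartesian product of the inclusive parameter sequences, crossed with both
    packings for rod kinds; platelet kinds are laminar-only and therefore
    enumerate to 450 structures rather than 900.  ``duplicate_laminar=True``
    lists each platelet structure twice to equalise the per-kind count; it is
    off by default so the grid is the literal product.
    """
    kind = MelanosomeKind(kind)
    g = TABLE_GRID[kind]
    packings = [Packing.LAMINAR]
    if g["hexagonal"]:
        packings.append(Packing.HEXAGONAL)
    specs: list[PhotonicCrystalSpec] = []
    for packing in packings:
        for d in _steps(*g["diameter"]):
            for h in _steps(*g["hollowness"]):
                for rel in _steps(*g["rel_spacing"]):
                    for c in _steps(*g["cortex"]):
                        m = Melanosome(
                            kind=kind,
                            d_melsom=float(d),
                            d_air=float(h * d),
                            l_melsom=float(g["flatness"] * d),
                        )
                        specs.append(
                            PhotonicCrystalSpec(
                                melanosome=m,
                                packing=packing,
                                a=float((d / 2.0) / rel),
                                c=float(c),
                                n_layers=n_layers,
                            )
                        )
    if duplicate_laminar and not g["hexagonal"]:
        specs = specs + specs
    return specs


def vertical_period(spec: PhotonicCrystalSpec) -> float:
    """Depth occupied by one melanosome layer: a (laminar) or a*sqrt(3)/2 (hex)."""
    if spec.packing is Packing.HEXAGONAL:
        return spec.a * math.sqrt(3.0) / 2.0
    return spec.a


def total_depth(spec: PhotonicCrystalSpec) -> float:
    """Total structure depth: cortex plus n_layers vertical periods."""
    return spec.c + spec.n_layers * vertical_period(spec)


def _chord(width: float, height: float, y: float) -> float:
    """Horizontal chord of an ellipse (axes width x height) at offset y from centre."""
    half = height / 2.0
    if abs(y) >= half:
        return 0.0
    return width * math.sqrt(1.0 - (y / half) ** 2)


def cross_section_fractions(
    spec: PhotonicCrystalSpec, depth_nm: float
) -> dict[str, float]:
    """Area fractions of melanin, air and keratin at one depth.

    Fractions are taken across one lateral period (the melanosome diameter for
    rods, the platelet width for platelets; melanosomes are laterally
    contiguous within a layer).  Rod cross-sections are circles (annuli when
    hollow); platelets are ellipses whose hollow core shares the shell's
    flatness.  In the hexagonal lattice successive rows are offset by half a
    period, which leaves the per-period fractions unchanged but halves the
    vertical row spacing to a*sqrt(3)/2.
    """
    T = total_depth(spec)
    if not (0.0 <= depth_nm <= T):
        raise ValueError(f"depth {depth_nm} outside structure [0, {T:.3f}] nm")
    m = spec.melanosome
    period = m.l_melsom if m.kind.is_platelet else m.d_melsom
    vp = vertical_period(spec)
    l_air = m.l_melsom * (m.d_air / m.d_melsom)

    w_mel = 0.0
    w_air = 0.0
    for i in range(spec.n_layers):
        z_i = spec.c + (i + 0.5) * vp
        y = depth_nm - z_i
        outer = _chord(m.l_melsom, m.d_melsom, y)
        inner = _chord(l_air, m.d_air, y) if m.kind.is_hollow else 0.0
        w_mel += outer - inner
        w_air += inner
    f_mel = min(w_mel / period, 1.0)
    f_air = min(w_air / period, 1.0 - f_mel)
    return {"f_mel": f_mel, "f_air": f_air, "f_ker": 1.0 - f_mel - f_air}


def grid_to_frame(specs: Iterable[PhotonicCrystalSpec]) -> pd.DataFrame:
    rows = []
    for s in specs:
        m = s.melanosome
        rows.append(
            dict(
                kind=m.kind.value, d_melsom=m.d_melsom, d_air=m.d_air,
                l_melsom=m.l_melsom, packing=s.packing.value, a=s.a, c=s.c,
                n_layers=s.n_layers,
            )
        )
    return pd.DataFrame(rows)


def grid_to_csv(specs: Iterable[PhotonicCrystalSpec], path: str) -> None:
    grid_to_frame(specs).to_csv(path, index=False)


def _spec_from_row(row: Mapping) -> PhotonicCrystalSpec:
    m = Melanosome(
        kind=MelanosomeKind(row["kind"]),
        d_melsom=float(row["d_melsom"]),
        d_air=float(row["d_air"]),
        l_melsom=float(row["l_melsom"]),
    )
    return PhotonicCrystalSpec(
        melanosome=m,
        packing=Packing(row["packing"]),
        a=float(row["a"]),
        c=float(row["c"]),
        n_layers=int(row["n_layers"]),
    )


def grid_from_csv(path: str) -> list[PhotonicCrystalSpec]:
    df = pd.read_csv(path)
    return [_spec_from_row(row) for _, row in df.iterrows()]


#: Canonical column names of the structure-parameter database schema.
DATABASE_COLUMNS = (
    "species", "kind", "d_melsom", "d_air", "l_melsom", "a", "ks", "c",
    "n_layers", "structure",
)


def read_structure_database(
    path: str, column_map: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Read a structure-parameter CSV, renaming columns to the canonical schema.

    ``column_map`` maps canonical names to the file's column names (e.g. from a
    YAML config); unmapped canonical columns must already be present under
    their own names or are left absent.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in ("species", "kind", "d_melsom") if c not in df.columns]
    if missing:
        raise ValueError(f"structure database missing required columns: {missing}")
    return df
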