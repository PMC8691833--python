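"""Download-free synthetic inputs with the structure the analysis assumes.

Three coupled artefacts are generated from one seed: a pure-birth (Yule)
phylogeny; a species-level structure database whose melanosome kinds cluster
phylogenetically (via a thresholded Brownian latent trait) and whose solid-rod
diameters follow a two-component mixture straddling the 190 nm thin/thick
cut; and noisy plumage-like reflectance spectra (two replicate "individuals"
per species patch) produced by running the transfer-matrix simulator on each
species' structure.  A configurable fraction of replicates is made to diverge
strongly in color, exercising the replicate quality-control step downstream.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml

from .structures import Melanosome, MelanosomeKind, Packing, PhotonicCrystalSpec
from .tmm import simulate_spectrum
from .phylostats import simulate_bm

__all__ = ["SynthConfig", "gen_tree", "gen_database", "gen_spectra", "write_fixtures"]

_KINDS = [k.value for k in MelanosomeKind]


@dataclass
class SynthConfig:
    """Generator settings; defaults are the study conditions the tests assume.

    The solid-rod mixture components (thin ~N(110, 20^2), thick ~N(250, 30^2),
    truncated to [40, 350] nm) straddle the 190 nm cut, matching the reported
    ~100 nm and ~200 nm varieties; the air-pocket range follows the observed
    50-251 nm span.
    """

    n_species: int = 64
    seed: int = 42
    birth_rate: float = 1.0
    thin_diameter_mean: float = 110.0
    thin_diameter_sd: float = 20.0
    thick_diameter_mean: float = 250.0
    thick_diameter_sd: float = 30.0
    diameter_bounds: tuple[float, float] = (40.0, 350.0)
    air_pocket_range: tuple[float, float] = (50.0, 251.0)
    noise_sd: float = 1.0  # reflectance %, per-wavelength Gaussian noise
    gain_sd: float = 0.05  # sd of the per-replicate multiplicative gain
    replicate_count: int = 2
    divergent_fraction: float = 0.05
    type_frequencies: dict = field(
        default_factory=lambda: {k: 0.2 for k in _KINDS}
    )

    def __post_init__(self) -> None:
        if self.thin_diameter_mean <= 0 or self.thick_diameter_mean <= 0:
            raise ValueError("mixture means must be positive")
        if self.thick_diameter_mean <= self.thin_diameter_mean:
            raise ValueError("thick mean must exceed thin mean")
        lo, hi = self.air_pocket_range
        if not (0 < lo < hi):
            raise ValueError("air pocket range must be positive and increasing")
        total = sum(self.type_frequencies.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("type frequencies must sum to 1")
        unknown = set(self.type_frequencies) - set(_KINDS)
        if unknown:
            raise ValueError(f"unknown melanosome kinds: {sorted(unknown)}")


def gen_tree(
    n_species: int, birth_rate: float = 1.0, seed: int | None = None
) -> dendropy.Tree:
    """Simulate a pure-birth (Yule) tree with ``n_species`` extant tips.

    Waiting times between speciation events are exponential with rate
    birth_rate x (number of lineages); the tree is grown to the requested tip
    count and tips are extended to the time of the next (unobserved) event,
    giving an ultrametric tree.  Tips are labelled sp001, sp002, ...
    """
    if n_species < 4:
        raise ValueError("at least 4 species required")
    if birth_rate <= 0:
        raise ValueError("birth rate must be positive")
    rng = np.random.default_rng(seed)
    # node: [birth_time, child_a, child_b]; tips have no children yet
    root = [0.0, None, None]
    tips = [root]
    t = 0.0
    while len(tips) < n_species:
        t += rng.exponential(1.0 / (birth_rate * len(tips)))
        i = rng.integers(len(tips))
        node = tips[i]
        a, b = [t, None, None], [t, None, None]
        node[1], node[2] = a, b
        tips[i] = a
        tips.append(b)
    t_end = t + rng.exponential(1.0 / (birth_rate * len(tips)))

    labels = iter(f"sp{i + 1:03d}" for i in range(n_species))

    # a node's edge runs from its birth to its split (tips: to the present)
    def newick(node) -> str:
        birth, a, b = node
        if a is None:
            return f"{next(labels)}:{t_end - birth:.6f}"
        split = a[0]
        return f"({newick(a)},{newick(b)}):{split - birth:.6f}"

    nwk = newick(root) + ";"
    return dendropy.Tree.get(data=nwk, schema="newick")


def _truncnorm(rng, mean, sd, lo, hi, size):
    out = np.empty(size)
    for i in range(size):
        v = rng.normal(mean, sd)
        while not (lo <= v <= hi):
            v = rng.normal(mean, sd)
        out[i] = v
    return out


def gen_database(tree: dendropy.Tree, config: SynthConfig) -> pd.DataFrame:
    """Species-level structure table with phylogenetically clustered kinds."""
    latent = simulate_bm(tree, rate=1.0, seed=config.seed + 1)["trait_0"]
    species = list(latent.index)
    order = latent.rank(method="first")  # 1..n, follows the latent BM trait
    n = len(species)
    cuts = np.cumsum([config.type_frequencies[k] for k in _KINDS])
    kind_of = {}
    for sp in species:
        q = (order[sp] - 0.5) / n
        kind_of[sp] = _KINDS[int(np.searchsorted(cuts, q))]

    rng = np.random.default_rng(config.seed + 2)
    lo_d, hi_d = config.diameter_bounds
    air_lo, air_hi = config.air_pocket_range
    rows = []
    for sp in species:
        kind = MelanosomeKind(kind_of[sp])
        if kind is MelanosomeKind.THIN_SOLID_ROD:
            d = float(
                _truncnorm(rng, config.thin_diameter_mean, config.thin_diameter_sd,
                           lo_d, 189.0, 1)[0]
            )
            d_air = 0.0
        elif kind is MelanosomeKind.THICK_SOLID_ROD:
            d = float(
                _truncnorm(rng, config.thick_diameter_mean, config.thick_diameter_sd,
                           190.0, hi_d, 1)[0]
            )
            d_air = 0.0
        elif kind is MelanosomeKind.HOLLOW_ROD:
            d = float(rng.uniform(135.0, 440.0))
            d_air = float(np.clip(rng.uniform(0.26, 0.69) * d, air_lo, min(air_hi, 0.9 * d)))
        elif kind is MelanosomeKind.SOLID_PLATELET:
            d = float(rng.uniform(45.0, 140.0))
            d_air = 0.0
        else:  # hollow platelet
            d = float(rng.uniform(135.0, 280.0))
            d_air = float(np.clip(rng.uniform(0.26, 0.69) * d, air_lo, min(air_hi, 0.9 * d)))
        flatness = 2.4 if kind.is_platelet else 1.0
        is_pc = rng.random() < (0.1 if kind is MelanosomeKind.THICK_SOLID_ROD else 0.9)
        n_layers = int(rng.integers(2, 9)) if is_pc else 1
        rel = float(rng.uniform(0.15, 0.5))
        rows.append(
            dict(
                species=sp,
                kind=kind.value,
                d_melsom=round(d, 3),
                d_air=round(d_air, 3),
                l_melsom=round(flatness * d, 3),
                a=round((d / 2.0) / rel, 3),
                c=round(float(rng.uniform(5.0, 1000.0)), 3),
                n_layers=n_layers,
                structure="photonic_crystal" if is_pc else "single_layer",
            )
        )
    df = pd.DataFrame(rows)
    df["ks"] = (df["a"] - df["d_melsom"]).round(3)
    return df[
        ["species", "kind", "d_melsom", "d_air", "l_melsom", "a", "ks", "c",
         "n_layers", "structure"]
    ]


def _spec_from_db_row(row) -> PhotonicCrystalSpec:
    m = Melanosome(
        kind=MelanosomeKind(row["kind"]),
        d_melsom=row["d_melsom"],
        d_air=row["d_air"],
        l_melsom=row["l_melsom"],
    )
    return PhotonicCrystalSpec(
        melanosome=m, packing=Packing.LAMINAR, a=row["a"], c=row["c"],
        n_layers=max(1, int(row["n_layers"])),
    )


def gen_spectra(
    database: pd.DataFrame,
    config: SynthConfig,
    step_nm: float = 2.0,
    slices_per_period: int = 40,
) -> pd.DataFrame:
    """Noisy replicate spectra (long format, %) for every database row.

    Each species-patch gets ``replicate_count`` copies of its simulated
    spectrum with a multiplicative gain and additive Gaussian noise; a
    ``divergent_fraction`` of patches has its second replicate chromatically
    distorted (a strong bump on the far side of the spectrum) so the
    downstream replicate check has something to find.
    """
    rng = np.random.default_rng(config.seed + 3)
    records = []
    n_rows = len(database)
    divergent = rng.random(n_rows) < config.divergent_fraction
    for pos, (_, row) in enumerate(database.iterrows()):
        spec = _spec_from_db_row(row)
        s = simulate_spectrum(spec, step_nm=step_nm, slices_per_period=slices_per_period)
        base = 100.0 * s.reflectance
        peak_wl = s.wavelengths[int(np.argmax(base))]
        for rep in range(config.replicate_count):
            gain = 1.0 + (rng.normal(0.0, config.gain_sd) if config.gain_sd else 0.0)
            noise = (
                rng.normal(0.0, config.noise_sd, base.shape)
                if config.noise_sd
                else 0.0
            )
            y = base * gain + noise
            if divergent[pos] and rep == config.replicate_count - 1:
                bump_wl = 350.0 if peak_wl > 500.0 else 650.0
                y = 0.5 * y + 60.0 * np.exp(
                    -0.5 * ((s.wavelengths - bump_wl) / 40.0) ** 2
                )
            for wl, val in zip(s.wavelengths, y):
                records.append(
                    dict(
                        wavelength_nm=wl,
                        reflectance_pct=round(float(val), 4),
                        species=row["species"],
                        patch="patch1",
                        individual=f"ind{rep + 1}",
                        angle_deg=90.0,
                    )
                )
    return pd.DataFrame(records)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_fixtures(out_dir: str, config: SynthConfig | None = None) -> dict:
    """Write tree.nwk, database.csv, spectra.csv, config.yaml and a manifest.

    The manifest records SHA-256 checksums and row/column counts; a rerun with
    the same configuration reproduces identical files.
    """
    config = config or SynthConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    tree = gen_tree(config.n_species, config.birth_rate, config.seed)
    nwk = tree.as_string(schema="newick").strip()
    (out / "tree.nwk").write_text(nwk + "\n")

    db = gen_database(tree, config)
    db.to_csv(out / "database.csv", index=False)

    spectra = gen_spectra(db, config)
    spectra.to_csv(out / "spectra.csv", index=False)

    cfg = asdict(config)
    cfg["air_pocket_range"] = list(config.air_pocket_range)
    cfg["diameter_bounds"] = list(config.diameter_bounds)
    (out / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))

    manifest = {
        "files": {
            name: {
                "sha256": _sha256(out / name),
                "bytes": (out / name).stat().st_size,
            }
            for name in ("tree.nwk", "database.csv", "spectra.csv", "config.yaml")
        },
        "database_rows": int(len(db)),
        "database_columns": int(db.shape[1]),
        "spectra_rows": int(len(spectra)),
        "spectra_columns": int(spectra.shape[1]),
        "n_species": config.n_species,
        "seed": config.seed,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
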