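"""Synthetic data generators with planted ground truth.

Produces multi-channel fluorescence fields (nuclei, lysosomal vesicles,
secondary-marker puncta), whole plates of wells with per-gene knockdown
effects, marker time courses, and SILAC-style protein quantification tables.
Every generator records what it planted, so downstream quantification can be
checked object-by-object.

Geometry conventions: nuclei and vesicles are uniform-intensity disks
convolved with a Gaussian PSF; cells are the nuclear-seeded Voronoi partition
of the field. Vesicle centers are rejected when closer than one combined
diameter to an already-placed vesicle (configurable). The camera model is
Poisson shot noise (scaled by a gain) followed by Gaussian read noise and
clipping to the bit-depth range.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage as ndi

from .core import CHANNEL_ROLES, SECONDARY_ROLES, ImageField

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "PlateDesign",
    "PlateDataset",
    "KineticsProfile",
    "MarkerCurve",
    "SilacSimConfig",
    "generate_field",
    "generate_plate",
    "default_plate_design",
    "generate_timecourse",
    "generate_silac_dataset",
]


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

def _default_positivity() -> dict[str, float]:
    return {
        "ubiquitin_FK2": 0.8,
        "ubiquitin_K48": 0.8,
        "ubiquitin_K63": 0.8,
        "gal3": 0.3,
        "poi": 0.3,
    }


def _default_amplitudes() -> dict[str, float]:
    amps = {role: 4000.0 for role in CHANNEL_ROLES}
    amps["nucleus"] = 3000.0
    return amps


def _default_background() -> dict[str, float]:
    return {role: 100.0 for role in CHANNEL_ROLES}


@dataclass
class SimulationConfig:
    """Parameters of one simulated field.

    Physical sizes are in µm; they are converted to pixels through
    ``pixel_size``. ``positivity_fraction`` gives, per secondary channel, the
    probability that a planted vesicle carries that marker.
    """

    rng_seed: int = 0
    image_shape: tuple[int, int] = (256, 256)
    pixel_size: float = 0.2
    n_cells: int = 12
    nucleus_radius: tuple[float, float] = (3.0, 0.3)  # µm (mean, sd)
    vesicles_per_cell_mean: float = 12.0  # Poisson mean
    vesicle_radius: tuple[float, float] = (math.log(0.5), 0.15)  # log-normal (µm)
    positivity_fraction: dict[str, float] = field(default_factory=_default_positivity)
    amplitudes: dict[str, float] = field(default_factory=_default_amplitudes)
    background: dict[str, float] = field(default_factory=_default_background)
    psf_sigma: float = 0.1  # µm
    noise_gaussian_sd: float = 10.0
    noise_poisson_gain: float = 2.0
    bit_depth: int = 16
    allow_vesicle_overlap: bool = False
    # uniform fills for nuclear/cytoplasmic translocation scenarios
    poi_nuclear_amp: float = 0.0
    poi_cytoplasm_amp: float = 0.0
    channels: tuple[str, ...] = ("nucleus", "lysosome", "ubiquitin_FK2", "ubiquitin_K48")

    def __post_init__(self) -> None:
        h, w = self.image_shape
        if h <= 0 or w <= 0:
            raise ValueError(f"image_shape must be positive, got {self.image_shape}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.nucleus_radius[0] <= 0 or self.vesicles_per_cell_mean < 0:
            raise ValueError("geometric parameters must be positive")
        if self.psf_sigma < 0:
            raise ValueError("psf_sigma must be >= 0")
        for role, p in self.positivity_fraction.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"positivity_fraction[{role!r}]={p} outside [0, 1]")
        unknown = set(self.channels) - set(CHANNEL_ROLES)
        if unknown:
            raise ValueError(f"unknown channel roles: {sorted(unknown)}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["image_shape"] = list(self.image_shape)
        d["channels"] = list(self.channels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "image_shape" in d:
            d["image_shape"] = tuple(d["image_shape"])
        if "nucleus_radius" in d:
            d["nucleus_radius"] = tuple(d["nucleus_radius"])
        if "vesicle_radius" in d:
            d["vesicle_radius"] = tuple(d["vesicle_radius"])
        if "channels" in d:
            d["channels"] = tuple(d["channels"])
        return cls(**d)


# --------------------------------------------------------------------------
# ground truth
# --------------------------------------------------------------------------

@dataclass
class PlantedCell:
    cell_id: int
    center: tuple[float, float]  # (row, col) px
    nucleus_radius_px: float


@dataclass
class PlantedVesicle:
    vesicle_id: int
    cell_id: int
    center: tuple[float, float]  # (row, col) px
    radius_px: float
    positive_for: dict[str, bool]


@dataclass
class GroundTruth:
    """Everything a generator planted — the oracle for recovery tests."""

    cells: list[PlantedCell] = field(default_factory=list)
    vesicles: list[PlantedVesicle] = field(default_factory=list)
    gene_effects: dict[str, float] = field(default_factory=dict)
    true_hits: list[str] = field(default_factory=list)
    hit_effect_cutoff: Optional[float] = None

    def __post_init__(self) -> None:
        cell_ids = {c.cell_id for c in self.cells}
        for v in self.vesicles:
            if v.cell_id not in cell_ids:
                raise ValueError(
                    f"vesicle {v.vesicle_id} references missing cell {v.cell_id}"
                )

    def realized_fraction(self, role: str) -> float:
        """Mean of planted Bernoulli labels for one marker role."""
        labels = [v.positive_for.get(role, False) for v in self.vesicles]
        if not labels:
            return float("nan")
        return float(np.mean(labels))

    def cell_label_map(self, shape: tuple[int, int]) -> np.ndarray:
        """Voronoi cell assignment of every pixel to its nearest nucleus."""
        lab = np.zeros(shape, dtype=np.int32)
        if not self.cells:
            return lab
        seeds = np.zeros(shape, dtype=np.int32)
        for c in self.cells:
            r, col = int(round(c.center[0])), int(round(c.center[1]))
            r = min(max(r, 0), shape[0] - 1)
            col = min(max(col, 0), shape[1] - 1)
            seeds[r, col] = c.cell_id
        _, (ir, ic) = ndi.distance_transform_edt(seeds == 0, return_indices=True)
        return seeds[ir, ic]

    def to_dict(self) -> dict:
        return {
            "cells": [asdict(c) for c in self.cells],
            "vesicles": [asdict(v) for v in self.vesicles],
            "gene_effects": dict(self.gene_effects),
            "true_hits": list(self.true_hits),
            "hit_effect_cutoff": self.hit_effect_cutoff,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            cells=[
                PlantedCell(
                    cell_id=c["cell_id"],
                    center=tuple(c["center"]),
                    nucleus_radius_px=c["nucleus_radius_px"],
                )
                for c in d.get("cells", [])
            ],
            vesicles=[
                PlantedVesicle(
                    vesicle_id=v["vesicle_id"],
                    cell_id=v["cell_id"],
                    center=tuple(v["center"]),
                    radius_px=v["radius_px"],
                    positive_for=dict(v["positive_for"]),
                )
                for v in d.get("vesicles", [])
            ],
            gene_effects=dict(d.get("gene_effects", {})),
            true_hits=list(d.get("true_hits", [])),
            hit_effect_cutoff=d.get("hit_effect_cutoff"),
        )

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# --------------------------------------------------------------------------
# field rendering
# --------------------------------------------------------------------------

def _disk_mask(shape: tuple[int, int], center: tuple[float, float], radius: float):
    """Index arrays of pixels inside a disk, clipped to the field."""
    r0, c0 = center
    rmin = max(int(math.floor(r0 - radius)), 0)
    rmax = min(int(math.ceil(r0 + radius)) + 1, shape[0])
    cmin = max(int(math.floor(c0 - radius)), 0)
    cmax = min(int(math.ceil(c0 + radius)) + 1, shape[1])
    rr, cc = np.mgrid[rmin:rmax, cmin:cmax]
    inside = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2
    return rr[inside], cc[inside]


def _add_disk(img: np.ndarray, center, radius: float, amplitude: float) -> None:
    rr, cc = _disk_mask(img.shape, center, radius)
    img[rr, cc] += amplitude


def _place_nuclei(cfg: SimulationConfig, rng: np.random.Generator) -> list[PlantedCell]:
    h, w = cfg.image_shape
    mean_r, sd_r = cfg.nucleus_radius
    cells: list[PlantedCell] = []
    min_sep_px = 2.5 * mean_r / cfg.pixel_size
    attempts = 0
    max_attempts = 2000 * max(cfg.n_cells, 1)
    while len(cells) < cfg.n_cells and attempts < max_attempts:
        attempts += 1
        radius_um = max(rng.normal(mean_r, sd_r), 0.2 * mean_r)
        radius_px = radius_um / cfg.pixel_size
        margin = radius_px + 2
        if 2 * margin >= min(h, w):
            raise ValueError("nucleus radius too large for image shape")
        r = rng.uniform(margin, h - margin)
        c = rng.uniform(margin, w - margin)
        if any(math.hypot(r - pc.center[0], c - pc.center[1]) < min_sep_px for pc in cells):
            continue
        cells.append(PlantedCell(cell_id=len(cells) + 1, center=(r, c), nucleus_radius_px=radius_px))
    if len(cells) < cfg.n_cells:
        raise ValueError(
            f"could only place {len(cells)}/{cfg.n_cells} nuclei; "
            "reduce n_cells or nucleus_radius"
        )
    return cells


def _place_vesicles(
    cfg: SimulationConfig,
    cells: list[PlantedCell],
    cell_map: np.ndarray,
    rng: np.random.Generator,
) -> list[PlantedVesicle]:
    h, w = cfg.image_shape
    mu, sigma = cfg.vesicle_radius
    vesicles: list[PlantedVesicle] = []
    for cell in cells:
        target = int(rng.poisson(cfg.vesicles_per_cell_mean))
        placed = 0
        attempts = 0
        while placed < target and attempts < 400 * max(target, 1):
            attempts += 1
            radius_px = float(rng.lognormal(mu, sigma)) / cfg.pixel_size
            margin = radius_px + 1
            r = rng.uniform(margin, h - margin)
            c = rng.uniform(margin, w - margin)
            if cell_map[int(r), int(c)] != cell.cell_id:
                continue
            d_nuc = math.hypot(r - cell.center[0], c - cell.center[1])
            if d_nuc < cell.nucleus_radius_px + radius_px + 1:
                continue
            if not cfg.allow_vesicle_overlap:
                # reject centers closer than one combined diameter
                too_close = any(
                    math.hypot(r - v.center[0], c - v.center[1])
                    < 2.0 * (radius_px + v.radius_px)
                    for v in vesicles
                )
                if too_close:
                    continue
            positive = {
                role: bool(rng.random() < cfg.positivity_fraction.get(role, 0.0))
                for role in SECONDARY_ROLES
                if role in cfg.channels or role in cfg.positivity_fraction
            }
            vesicles.append(
                PlantedVesicle(
                    vesicle_id=len(vesicles) + 1,
                    cell_id=cell.cell_id,
                    center=(r, c),
                    radius_px=radius_px,
                    positive_for=positive,
                )
            )
            placed += 1
    return vesicles


def _apply_camera(
    img: np.ndarray, cfg: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    out = img
    if cfg.noise_poisson_gain > 0:
        out = rng.poisson(out / cfg.noise_poisson_gain).astype(float) * cfg.noise_poisson_gain
    if cfg.noise_gaussian_sd > 0:
        out = out + rng.normal(0.0, cfg.noise_gaussian_sd, size=out.shape)
    maxval = 2**cfg.bit_depth - 1
    return np.clip(np.round(out), 0, maxval).astype(np.uint16)


def generate_field(
    config: SimulationConfig,
    overrides: Optional[dict[str, object]] = None,
) -> tuple[ImageField, GroundTruth]:
    """Render one multi-channel field and return it with its ground truth.

    Parameters
    ----------
    config
        Simulation parameters. Determinism: identical config + seed yields
        bit-identical output.
    overrides
        Optional per-channel positivity overrides: maps a secondary channel
        role either to a float (applies to all cells) or to a
        ``{cell_id: fraction}`` dict.
    """
    rng = np.random.default_rng(config.rng_seed)
    cfg = config
    if overrides:
        for role, val in overrides.items():
            if role not in SECONDARY_ROLES:
                raise ValueError(f"override for non-secondary role {role!r}")

    cells = _place_nuclei(cfg, rng)
    truth = GroundTruth(cells=cells)
    cell_map = truth.cell_label_map(cfg.image_shape)
    vesicles = _place_vesicles(cfg, cells, cell_map, rng)

    # apply positivity overrides by redrawing labels for affected vesicles
    if overrides:
        for role, val in overrides.items():
            for v in vesicles:
                if isinstance(val, dict):
                    if v.cell_id in val:
                        v.positive_for[role] = bool(rng.random() < float(val[v.cell_id]))
                else:
                    v.positive_for[role] = bool(rng.random() < float(val))

    truth.vesicles = vesicles

    psf_px = cfg.psf_sigma / cfg.pixel_size
    channels: dict[str, np.ndarray] = {}
    for role in cfg.channels:
        img = np.zeros(cfg.image_shape, dtype=float)
        if role == "nucleus":
            for c in cells:
                _add_disk(img, c.center, c.nucleus_radius_px, cfg.amplitudes[role])
        elif role == "lysosome":
            for v in vesicles:
                _add_disk(img, v.center, v.radius_px, cfg.amplitudes[role])
        else:
            for v in vesicles:
                if v.positive_for.get(role, False):
                    _add_disk(img, v.center, v.radius_px, cfg.amplitudes[role])
            if role == "poi" and (cfg.poi_nuclear_amp > 0 or cfg.poi_cytoplasm_amp > 0):
                nuc_mask = np.zeros(cfg.image_shape, dtype=bool)
                for c in cells:
                    rr, cc = _disk_mask(cfg.image_shape, c.center, c.nucleus_radius_px)
                    nuc_mask[rr, cc] = True
                img[nuc_mask] += cfg.poi_nuclear_amp
                img[(cell_map > 0) & ~nuc_mask] += cfg.poi_cytoplasm_amp
        if psf_px > 0:
            img = ndi.gaussian_filter(img, psf_px)
        img += cfg.background.get(role, 0.0)
        channels[role] = _apply_camera(img, cfg, rng)

    return ImageField(channels=channels, pixel_size=cfg.pixel_size, bit_depth=cfg.bit_depth), truth


# --------------------------------------------------------------------------
# plate design and generation
# --------------------------------------------------------------------------

@dataclass
class WellSpec:
    well_id: str
    gene: str
    reagent: str  # "pool" or "single_k"
    treatment: str  # "damaged" | "untreated"
    replicate: int


@dataclass
class PlateDesign:
    """Layout of one screening plate."""

    wells: list[WellSpec]

    def __post_init__(self) -> None:
        seen = set()
        for w in self.wells:
            if w.well_id in seen:
                raise ValueError(f"duplicate well id {w.well_id}")
            seen.add(w.well_id)
            if w.treatment not in ("damaged", "untreated"):
                raise ValueError(f"bad treatment {w.treatment!r} in {w.well_id}")

    @property
    def genes(self) -> list[str]:
        out: list[str] = []
        for w in self.wells:
            if w.gene not in out:
                out.append(w.gene)
        return out

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame([asdict(w) for w in self.wells])

    @classmethod
    def from_frame(cls, df) -> "PlateDesign":
        required = {"well_id", "gene", "reagent", "treatment", "replicate"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"plate design missing columns: {sorted(missing)}")
        wells = [
            WellSpec(
                well_id=str(r.well_id),
                gene=str(r.gene),
                reagent=str(r.reagent),
                treatment=str(r.treatment),
                replicate=int(r.replicate),
            )
            for r in df.itertuples()
        ]
        return cls(wells=wells)


#: genes whose wells are controls rather than library samples
NEGATIVE_CONTROL_GENE = "NTC"
POSITIVE_CONTROL_GENE = "POSCTRL"
CONTROL_GENES = (NEGATIVE_CONTROL_GENE, POSITIVE_CONTROL_GENE)


def _well_ids(n: int) -> list[str]:
    rows = "ABCDEFGHIJKLMNOP"
    out = []
    for i in range(n):
        out.append(f"{rows[i // 24]}{i % 24 + 1:02d}")
    return out


def default_plate_design(
    n_genes: int = 37,
    replicates: int = 4,
    reagent: str = "pool",
    n_control_wells: int = 4,
    n_untreated_wells: int = 4,
    genes: Optional[Sequence[str]] = None,
) -> PlateDesign:
    """Quadruplicate library wells plus non-targeting, positive-shift and
    untreated control wells, on 384-well-style coordinates."""
    if genes is None:
        genes = [f"E2G{i + 1:02d}" for i in range(n_genes)]
    genes = list(genes)
    reagents = [reagent] if reagent == "pool" else [f"single_{k + 1}" for k in range(4)]
    wells: list[WellSpec] = []
    for g in genes:
        for rgt in reagents:
            for rep in range(1, replicates + 1):
                wells.append(WellSpec("", g, rgt, "damaged", rep))
    for rep in range(1, n_control_wells + 1):
        wells.append(WellSpec("", NEGATIVE_CONTROL_GENE, "ctrl", "damaged", rep))
        wells.append(WellSpec("", POSITIVE_CONTROL_GENE, "ctrl", "damaged", rep))
    for rep in range(1, n_untreated_wells + 1):
        wells.append(WellSpec("", NEGATIVE_CONTROL_GENE, "ctrl", "untreated", rep))
    ids = _well_ids(len(wells))
    for w, wid in zip(wells, ids):
        w.well_id = wid
    return PlateDesign(wells=wells)


@dataclass
class PlateDataset:
    """Output of :func:`generate_plate`.

    ``fidelity`` is ``"metric"`` (per-cell readout tables drawn from the same
    distributions the image path realizes) or ``"image"`` (rendered fields).
    """

    design: PlateDesign
    fidelity: str
    gene_effects: dict[str, float]
    planted_fraction: dict[str, dict[str, float]]  # well_id -> staining -> fraction
    cell_table: Optional[object] = None  # pandas DataFrame (metric fidelity)
    fields: Optional[dict[str, tuple[ImageField, GroundTruth]]] = None  # image fidelity
    true_hits: list[str] = field(default_factory=list)
    hit_effect_cutoff: float = 0.75

    def truth(self) -> GroundTruth:
        return GroundTruth(
            gene_effects=dict(self.gene_effects),
            true_hits=list(self.true_hits),
            hit_effect_cutoff=self.hit_effect_cutoff,
        )


PLATE_STAININGS = ("ubiquitin_FK2", "ubiquitin_K48")


def generate_plate(
    design: PlateDesign,
    config: SimulationConfig,
    gene_effects: Optional[dict[str, float]] = None,
    fidelity: str = "metric",
    cells_per_well: int = 100,
    well_fraction_sd: float = 0.05,
    untreated_fraction: float = 0.05,
    positive_control_effect: float = 1.2,
    hit_effect_cutoff: float = 0.75,
    stainings: Sequence[str] = PLATE_STAININGS,
) -> PlateDataset:
    """Simulate a whole screening plate.

    Each damaged library well's planted positive fraction is
    ``clip(baseline × gene_effect + N(0, well_fraction_sd), 0, 1)``, drawn
    independently per staining; per-cell vesicle counts are Poisson and
    positives are binomial at the well fraction. The untreated wells sit at
    ``untreated_fraction``; the positive-shift control at
    ``baseline × positive_control_effect``.
    """
    import pandas as pd

    gene_effects = dict(gene_effects or {})
    known = set(design.genes)
    for g in gene_effects:
        if g not in known:
            raise ValueError(f"gene_effects contains unknown gene {g!r}")
    if fidelity not in ("metric", "image"):
        raise ValueError(f"fidelity must be 'metric' or 'image', got {fidelity!r}")

    rng = np.random.default_rng(config.rng_seed)
    planted: dict[str, dict[str, float]] = {}
    rows = []
    fields: dict[str, tuple[ImageField, GroundTruth]] = {}

    for well in design.wells:
        fracs: dict[str, float] = {}
        for staining in stainings:
            baseline = config.positivity_fraction.get(staining, 0.8)
            if well.treatment == "untreated":
                base = untreated_fraction
            elif well.gene == POSITIVE_CONTROL_GENE:
                base = baseline * positive_control_effect
            elif well.gene == NEGATIVE_CONTROL_GENE:
                base = baseline
            else:
                base = baseline * gene_effects.get(well.gene, 1.0)
            frac = float(np.clip(base + rng.normal(0.0, well_fraction_sd), 0.0, 1.0))
            fracs[staining] = frac
        planted[well.well_id] = fracs

        if fidelity == "metric":
            n_ves = rng.poisson(config.vesicles_per_cell_mean, size=cells_per_well)
            rec: dict[str, object] = {}
            for staining in stainings:
                rec[staining] = rng.binomial(n_ves, fracs[staining])
            for i in range(cells_per_well):
                row = {
                    "well_id": well.well_id,
                    "cell_id": i + 1,
                    "n_vesicles": int(n_ves[i]),
                }
                for staining in stainings:
                    npos = int(rec[staining][i])
                    row[f"n_pos_{staining}"] = npos
                    row[f"pct_{staining}"] = (
                        100.0 * npos / n_ves[i] if n_ves[i] > 0 else np.nan
                    )
                rows.append(row)
        else:
            well_cfg = SimulationConfig.from_dict(
                {
                    **config.to_dict(),
                    "rng_seed": int(rng.integers(0, 2**31 - 1)),
                    "positivity_fraction": {
                        **config.positivity_fraction,
                        **{s: fracs[s] for s in stainings},
                    },
                }
            )
            fields[well.well_id] = generate_field(well_cfg)

    # truth: hits are genes whose effect falls below the cutoff
    effects = {g: gene_effects.get(g, 1.0) for g in design.genes if g not in CONTROL_GENES}
    true_hits = [g for g, e in effects.items() if e <= hit_effect_cutoff]

    return PlateDataset(
        design=design,
        fidelity=fidelity,
        gene_effects=effects,
        planted_fraction=planted,
        cell_table=pd.DataFrame(rows) if fidelity == "metric" else None,
        fields=fields or None,
        true_hits=true_hits,
        hit_effect_cutoff=hit_effect_cutoff,
    )


# --------------------------------------------------------------------------
# kinetics
# --------------------------------------------------------------------------

@dataclass
class MarkerCurve:
    """Gamma-shaped response curve for one marker.

    ``fraction(t) = baseline`` for ``t <= onset`` and
    ``baseline + (peak_fraction - baseline) * (u * exp(1 - u))**decay`` with
    ``u = (t - onset) / (peak_time - onset)`` otherwise — it peaks exactly at
    ``peak_time`` and relaxes back at a rate set by ``decay``.
    """

    baseline: float
    onset: float  # minutes
    peak_time: float  # minutes
    peak_fraction: float
    decay: float = 2.0

    def fraction(self, t: float) -> float:
        if self.peak_time <= self.onset:
            raise ValueError("peak_time must exceed onset")
        if t <= self.onset:
            val = self.baseline
        else:
            u = (t - self.onset) / (self.peak_time - self.onset)
            val = self.baseline + (self.peak_fraction - self.baseline) * (
                u * math.exp(1.0 - u)
            ) ** self.decay
        if not 0.0 <= val <= 1.0:
            raise ValueError(f"curve fraction {val:.3f} outside [0, 1] at t={t}")
        return val


@dataclass
class KineticsProfile:
    """Time course of marker positivity after damage.

    Default profile: K63-like and p62-like responses rise early and peak
    within the first hour; K48-like and the protein-of-interest response
    peak between 2 and 3 h.
    """

    time_points: tuple[float, ...] = (0.0, 30.0, 60.0, 120.0, 180.0)
    curves: dict[str, MarkerCurve] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if list(self.time_points) != sorted(self.time_points):
            raise ValueError("time_points must be sorted ascending")
        if not self.curves:
            self.curves = {
                "ubiquitin_K63": MarkerCurve(0.05, 10.0, 60.0, 0.80),
                "gal3": MarkerCurve(0.05, 10.0, 60.0, 0.70),  # p62-like early marker
                "ubiquitin_K48": MarkerCurve(0.05, 30.0, 150.0, 0.75),
                "poi": MarkerCurve(0.05, 30.0, 150.0, 0.70),
            }

    def fractions_at(self, t: float) -> dict[str, float]:
        return {role: curve.fraction(t) for role, curve in self.curves.items()}


def generate_timecourse(
    profile: KineticsProfile, config: SimulationConfig
) -> list[tuple[float, ImageField, GroundTruth]]:
    """Render one field per time point, with marker positivity following the
    profile curves. Fields use independent seeds derived from the config seed."""
    out = []
    root = np.random.default_rng(config.rng_seed)
    roles = tuple(
        dict.fromkeys(("nucleus", "lysosome") + tuple(profile.curves))
    )
    for t in profile.time_points:
        fracs = profile.fractions_at(t)
        cfg = SimulationConfig.from_dict(
            {
                **config.to_dict(),
                "rng_seed": int(root.integers(0, 2**31 - 1)),
                "channels": list(roles),
                "positivity_fraction": {**config.positivity_fraction, **fracs},
            }
        )
        fld, truth = generate_field(cfg)
        out.append((t, fld, truth))
    return out


# --------------------------------------------------------------------------
# SILAC tables
# --------------------------------------------------------------------------

@dataclass
class SilacSimConfig:
    """Parameters for a synthetic SILAC protein-quantification table.

    The null population is centered at log2 H/L = 0 (1:1 mixing); enriched
    proteins carry the true mean log2 effects in ``enriched_set``.
    """

    rng_seed: int = 0
    n_proteins: int = 1000
    n_replicates: int = 4
    null_log2_sd: float = 0.3
    enriched_set: dict[str, float] = field(default_factory=dict)  # id -> true log2
    contaminant_fraction: float = 0.0
    reverse_fraction: float = 0.0
    site_only_fraction: float = 0.0
    missingness: float = 0.0  # per-replicate probability a protein is NOT detected
    base_intensity_log10: tuple[float, float] = (7.0, 0.5)

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2 (t-test undefined otherwise)")
        for name in ("contaminant_fraction", "reverse_fraction", "site_only_fraction", "missingness"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        ids = {protein_id(i) for i in range(self.n_proteins)}
        unknown = set(self.enriched_set) - ids
        if unknown:
            raise ValueError(f"enriched_set contains unknown protein ids: {sorted(unknown)[:5]}")


def protein_id(i: int) -> str:
    return f"P{i + 1:05d}"


def generate_silac_dataset(config: SilacSimConfig):
    """Simulate a protein-groups-style table plus truth labels.

    Returns ``(table, truth)`` pandas DataFrames. The table has one row per
    protein with boolean ``contaminant``/``reverse``/``site_only`` flags and
    per-replicate ``intensity_H_k`` / ``intensity_L_k`` columns (NaN where the
    replicate did not detect the protein). Truth carries the planted mean
    log2 H/L per protein and the enrichment label.
    """
    import pandas as pd

    cfg = config
    rng = np.random.default_rng(cfg.rng_seed)
    n, k = cfg.n_proteins, cfg.n_replicates
    ids = [protein_id(i) for i in range(n)]
    true_log2 = np.array([cfg.enriched_set.get(pid, 0.0) for pid in ids])

    mu10, sd10 = cfg.base_intensity_log10
    base_light = 10.0 ** rng.normal(mu10, sd10, size=n)

    noise = (
        rng.normal(0.0, cfg.null_log2_sd, size=(n, k))
        if cfg.null_log2_sd > 0
        else np.zeros((n, k))
    )
    rep_log2 = true_log2[:, None] + noise

    light = base_light[:, None] * np.ones((n, k))
    heavy = light * 2.0**rep_log2
    detected = rng.random(size=(n, k)) >= cfg.missingness
    light = np.where(detected, light, np.nan)
    heavy = np.where(detected, heavy, np.nan)

    # flags are drawn per protein, independently per flag; a row can carry
    # several flags. Enriched proteins are never flagged (truth stays clean).
    enriched_mask = np.array([pid in cfg.enriched_set for pid in ids])
    flags = {}
    for name, frac in (
        ("contaminant", cfg.contaminant_fraction),
        ("reverse", cfg.reverse_fraction),
        ("site_only", cfg.site_only_fraction),
    ):
        f = rng.random(size=n) < frac
        f &= ~enriched_mask
        flags[name] = f

    table = pd.DataFrame({"protein_id": ids, "gene_symbol": [f"GENE{i + 1:05d}" for i in range(n)]})
    for name, f in flags.items():
        table[name] = f
    for j in range(k):
        table[f"intensity_H_{j + 1}"] = heavy[:, j]
        table[f"intensity_L_{j + 1}"] = light[:, j]

    truth = pd.DataFrame(
        {
            "protein_id": ids,
            "true_log2": true_log2,
            "is_enriched": enriched_mask,
            "flagged": flags["contaminant"] | flags["reverse"] | flags["site_only"],
        }
    )
    return table, truth
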