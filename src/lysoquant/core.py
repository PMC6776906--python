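"""Shared domain types: image fields, label maps, and object records.

Coordinates are 0-based ``(row, col)`` pixels; object areas are in pixels;
physical sizes are converted through ``pixel_size`` (µm/pixel).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Recognized channel roles. Secondary marker channels are everything except
#: the nucleus and lysosome (vesicle) channels.
CHANNEL_ROLES = (
    "nucleus",
    "lysosome",
    "ubiquitin_FK2",
    "ubiquitin_K48",
    "ubiquitin_K63",
    "gal3",
    "poi",
)

SECONDARY_ROLES = tuple(r for r in CHANNEL_ROLES if r not in ("nucleus", "lysosome"))


@dataclass
class ImageField:
    """One multi-channel 2D field of view.

    Parameters
    ----------
    channels
        Mapping from channel role to a 2D intensity array. All channels must
        share one shape and contain non-negative intensities.
    pixel_size
        Physical pixel size in µm/pixel.
    bit_depth
        Nominal camera bit depth (intensities live in ``[0, 2**bit_depth - 1]``).
    """

    channels: dict[str, np.ndarray]
    pixel_size: float
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("ImageField requires at least one channel")
        shapes = {np.asarray(a).shape for a in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels have inconsistent shapes: {shapes}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        for role, arr in self.channels.items():
            if np.asarray(arr).min() < 0:
                raise ValueError(f"channel {role!r} contains negative intensities")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def channel(self, role: str) -> np.ndarray:
        if role not in self.channels:
            raise KeyError(
                f"channel role {role!r} not present (have {sorted(self.channels)})"
            )
        return np.asarray(self.channels[role], dtype=float)


@dataclass
class LabelMap:
    """Integer label image (0 = background)."""

    labels: np.ndarray
    kind: str  # "nucleus" | "cell" | "puncta"
    channel_role: Optional[str] = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative integers")

    @property
    def n_objects(self) -> int:
        return int(self.labels.max())

    def ids(self) -> np.ndarray:
        vals = np.unique(self.labels)
        return vals[vals > 0]


@dataclass
class VesicleRecord:
    """One detected punctum/vesicle with per-channel measurements."""

    vesicle_id: int
    cell_id: int
    channel_role: str
    centroid: tuple[int, int]
    radius_px: float
    area: float
    mean_intensity: dict[str, float] = field(default_factory=dict)
    corrected_mean: dict[str, float] = field(default_factory=dict)
    positive_for: dict[str, bool] = field(default_factory=dict)


@dataclass
class CellRecord:
    """One cell: nucleus + cytoplasm regions and aggregate measurements.

    ``cytoplasm`` is the cell region minus the nucleus; the two are disjoint
    by construction.
    """

    cell_id: int
    nucleus_centroid: tuple[float, float]
    nucleus_area: float
    cell_area: float
    edge_touching: bool = False
    nuclear_mean: dict[str, float] = field(default_factory=dict)
    cytoplasm_mean: dict[str, float] = field(default_factory=dict)
    nuclear_corrected: dict[str, float] = field(default_factory=dict)
    cytoplasm_corrected: dict[str, float] = field(default_factory=dict)
    vesicle_counts: dict[str, int] = field(default_factory=dict)


def robust_sigma(values: np.ndarray) -> float:
    """Normal-consistent robust scale: 1.4826 × median absolute deviation."""
    values = np.asarray(values, dtype=float)
    med = np.median(values)
    return float(1.4826 * np.median(np.abs(values - med)))
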