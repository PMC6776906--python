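"""Per-cell readouts: percent marker-positive vesicles, Pearson
colocalization, puncta-count classification, and nuclear/cytoplasmic ratios.

The default "positive vesicle" criterion is object overlap — a detected
marker punctum whose centroid falls inside the vesicle mask. An
intensity-based criterion (background-corrected marker mean above ``k``
robust noise units) is offered as an alternative. Cells excluded from a
readout (no vesicles, edge cells) are counted and flagged, never silently
dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np

from .core import CellRecord, ImageField, VesicleRecord, robust_sigma

__all__ = [
    "PccResult",
    "CellReadout",
    "vesicle_is_positive",
    "mark_positive_vesicles",
    "percent_positive_vesicles",
    "pearson_per_cell",
    "count_and_classify_puncta",
    "nuclear_cytoplasmic_ratio",
    "fold_change_normalize",
]


class PccResult(NamedTuple):
    """Pearson correlation with an explicit defined flag (constant channels
    yield ``defined=False``, never a silent 0)."""

    value: float
    defined: bool


@dataclass
class CellReadout:
    cell_id: int
    percent_positive: dict[str, float] = field(default_factory=dict)  # marker -> %
    excluded: dict[str, bool] = field(default_factory=dict)  # marker -> no-vesicle flag
    pcc: dict[tuple[str, str], PccResult] = field(default_factory=dict)
    puncta_count: dict[str, int] = field(default_factory=dict)
    puncta_class_positive: dict[tuple[str, int], bool] = field(default_factory=dict)
    nc_ratio: dict[str, float] = field(default_factory=dict)
    vesicle_count: int = 0


def vesicle_is_positive(
    vesicle: VesicleRecord,
    marker_role: str,
    criterion: str = "overlap",
    marker_puncta: Optional[Sequence[VesicleRecord]] = None,
    k: float = 5.0,
    noise_scale: Optional[float] = None,
) -> bool:
    """Decide whether a vesicle carries a marker.

    ``overlap``: at least one detected marker punctum centroid lies inside
    the vesicle disk. ``intensity``: the background-corrected marker mean on
    the vesicle exceeds ``k × noise_scale``.
    """
    if criterion == "overlap":
        if marker_puncta is None:
            raise ValueError("overlap criterion requires detected marker puncta")
        r0, c0 = vesicle.centroid
        rad = vesicle.radius_px
        for p in marker_puncta:
            pr, pc = p.centroid
            if (pr - r0) ** 2 + (pc - c0) ** 2 <= rad**2:
                return True
        return False
    if criterion == "intensity":
        if marker_role not in vesicle.corrected_mean:
            raise ValueError(f"marker {marker_role!r} not measured on vesicle")
        if noise_scale is None:
            raise ValueError("intensity criterion requires a noise_scale")
        return vesicle.corrected_mean[marker_role] > k * noise_scale
    raise ValueError(f"unknown criterion {criterion!r}")


def mark_positive_vesicles(
    vesicles: Sequence[VesicleRecord],
    marker_role: str,
    criterion: str = "overlap",
    marker_puncta: Optional[Sequence[VesicleRecord]] = None,
    field_: Optional[ImageField] = None,
    k: float = 5.0,
) -> list[VesicleRecord]:
    """Set ``positive_for[marker_role]`` on every vesicle record in place."""
    noise_scale = None
    if criterion == "intensity":
        if field_ is None:
            raise ValueError("intensity criterion requires the image field")
        noise_scale = robust_sigma(field_.channel(marker_role))
    for v in vesicles:
        v.positive_for[marker_role] = vesicle_is_positive(
            v, marker_role, criterion, marker_puncta, k=k, noise_scale=noise_scale
        )
    return list(vesicles)


def percent_positive_vesicles(
    cells: Sequence[CellRecord] | Sequence[int],
    vesicles: Sequence[VesicleRecord],
    marker_role: str,
) -> dict[int, Optional[float]]:
    """Per-cell 100 × positive/total vesicles.

    Cells with zero vesicles map to ``None`` (undefined — excluded from any
    aggregation, with the exclusion recorded by the caller).
    """
    cell_ids = [c.cell_id if isinstance(c, CellRecord) else int(c) for c in cells]
    totals: dict[int, int] = {cid: 0 for cid in cell_ids}
    positives: dict[int, int] = {cid: 0 for cid in cell_ids}
    for v in vesicles:
        if v.cell_id not in totals:
            continue
        totals[v.cell_id] += 1
        if v.positive_for.get(marker_role, False):
            positives[v.cell_id] += 1
    return {
        cid: (100.0 * positives[cid] / totals[cid] if totals[cid] > 0 else None)
        for cid in cell_ids
    }


def pearson_per_cell(
    field: ImageField,
    role_a: str,
    role_b: str,
    cell_mask: np.ndarray,
    mode: str = "whole_cell",
    background_nsd: float = 3.0,
) -> PccResult:
    """Pearson correlation of two channels over one cell's pixels.

    ``whole_cell`` uses every pixel of the mask; ``above_background`` keeps
    pixels where either channel exceeds its in-cell median by
    ``background_nsd`` robust noise units. A channel constant over the pixel
    set gives an undefined result (``defined=False``).
    """
    if mode not in ("whole_cell", "above_background"):
        raise ValueError(f"unknown mode {mode!r}")
    a = field.channel(role_a)[cell_mask].astype(float)
    b = field.channel(role_b)[cell_mask].astype(float)
    if a.size < 2:
        return PccResult(float("nan"), False)
    if mode == "above_background":
        keep = np.zeros(a.shape, dtype=bool)
        for arr in (a, b):
            med = np.median(arr)
            sig = robust_sigma(arr)
            keep |= arr > med + background_nsd * sig
        a, b = a[keep], b[keep]
        if a.size < 2:
            return PccResult(float("nan"), False)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return PccResult(float("nan"), False)
    a = a - a.mean()
    b = b - b.mean()
    value = float(np.dot(a, b) / math.sqrt(np.dot(a, a) * np.dot(b, b)))
    return PccResult(value, True)


def count_and_classify_puncta(
    counts: dict[int, int] | Sequence[int],
    threshold: int = 3,
) -> tuple[dict[int, bool], float]:
    """Classify cells by a strict puncta-count rule and report the
    population percentage.

    A cell is positive iff its count is strictly greater than ``threshold``
    (count 4 at threshold 3 → positive; count 3 → negative). Returns
    ``(per-cell booleans, 100 × positive / classified)``.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if not isinstance(counts, dict):
        counts = {i + 1: int(c) for i, c in enumerate(counts)}
    classes = {cid: (c > threshold) for cid, c in counts.items()}
    if not classes:
        return classes, float("nan")
    pct = 100.0 * sum(classes.values()) / len(classes)
    return classes, pct


def nuclear_cytoplasmic_ratio(cell: CellRecord, role: str) -> Optional[float]:
    """Cytoplasmic / nuclear mean-intensity ratio on background-corrected
    intensities; ``None`` (undefined) when the nuclear mean is ≤ 0 after
    correction."""
    if cell.nucleus_area <= 0:
        raise ValueError(f"cell {cell.cell_id} has an empty nucleus region")
    if cell.cell_area - cell.nucleus_area <= 0:
        raise ValueError(f"cell {cell.cell_id} has an empty cytoplasm region")
    nuc = cell.nuclear_corrected.get(role)
    cyto = cell.cytoplasm_corrected.get(role)
    if nuc is None or cyto is None:
        raise ValueError(f"channel {role!r} not measured on cell {cell.cell_id}")
    if nuc <= 0 or math.isnan(cyto):
        return None
    return cyto / nuc


def fold_change_normalize(
    values: Sequence[float],
    reference_values: Sequence[float],
    mode: str = "fold",
) -> np.ndarray:
    """Normalize condition values to a reference condition.

    ``fold``: value / mean(reference) — fold increase over untreated
    control. ``percent``: 100 × value / mean(reference) — percent of the
    treated control (reference set to 100%).
    """
    if mode not in ("fold", "percent"):
        raise ValueError(f"unknown mode {mode!r}")
    ref = float(np.mean(np.asarray(reference_values, dtype=float)))
    if ref <= 0:
        raise ValueError(f"reference mean must be positive, got {ref}")
    vals = np.asarray(values, dtype=float)
    out = vals / ref
    return out * 100.0 if mode == "percent" else out
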