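"""Plate-level aggregation, robust z-scores, and hit calling.

A well summary carries the per-well median (primary) and mean of a per-cell
readout, gated by a cells-per-well QC minimum (default 50). Robust z-scores
are computed per reagent against the whole plate:
``z = (x - median) / (1.4826 × MAD)`` where ``x`` is the replicate-median
readout and median/MAD are taken over all QC-passing, damage-treated library
samples. Primary hits require z ≤ threshold (inclusive, default −2) in at
least one ubiquitin staining; deconvolved single siRNAs must score in both
stainings, and a gene is confirmed when at least ``min_singles`` of its four
singles score.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synthgen import CONTROL_GENES, PlateDesign

__all__ = [
    "WellSummary",
    "HitCall",
    "summarize_well",
    "summarize_plate",
    "robust_zscores",
    "call_primary_hits",
    "deconvolve_secondary",
    "compare_conditions",
    "screen_report",
]

DEFAULT_QC_MIN_CELLS = 50
DEFAULT_Z_THRESHOLD = -2.0
MAD_SCALE = 1.4826


@dataclass
class WellSummary:
    well_id: str
    gene: str
    reagent: str
    treatment: str
    n_cells: int
    qc_pass: bool
    median_readout: dict[str, float] = field(default_factory=dict)  # staining -> value
    mean_readout: dict[str, float] = field(default_factory=dict)


@dataclass
class HitCall:
    gene: str
    reagent: str
    staining: str  # "any" / "both" for combined calls
    robust_z: float
    is_hit: bool
    stage: str  # "primary" | "secondary"


def summarize_well(
    well_id: str,
    gene: str,
    reagent: str,
    treatment: str,
    per_cell: pd.DataFrame,
    stainings: Sequence[str],
    qc_min_cells: int = DEFAULT_QC_MIN_CELLS,
) -> WellSummary:
    """Aggregate one well's per-cell readouts (``pct_<staining>`` columns).

    Cells with an undefined readout (NaN, e.g. zero vesicles) do not count
    toward the QC minimum for that staining. A failed-QC well carries NaN
    summaries.
    """
    medians: dict[str, float] = {}
    means: dict[str, float] = {}
    n_cells = 0
    qc = True
    for staining in stainings:
        col = f"pct_{staining}"
        if col not in per_cell.columns:
            raise KeyError(f"per-cell table lacks column {col!r}")
        vals = per_cell[col].dropna().to_numpy(dtype=float)
        n_cells = max(n_cells, len(vals))
        if len(vals) < qc_min_cells:
            qc = False
            medians[staining] = float("nan")
            means[staining] = float("nan")
        else:
            medians[staining] = float(np.median(vals))
            means[staining] = float(np.mean(vals))
    if not qc:
        medians = {s: float("nan") for s in stainings}
        means = {s: float("nan") for s in stainings}
    return WellSummary(well_id, gene, reagent, treatment, n_cells, qc, medians, means)


def summarize_plate(
    cell_table: pd.DataFrame,
    design: PlateDesign,
    stainings: Sequence[str],
    qc_min_cells: int = DEFAULT_QC_MIN_CELLS,
) -> list[WellSummary]:
    """Summarize every designed well found in a per-cell table."""
    by_well = dict(tuple(cell_table.groupby("well_id")))
    out = []
    for w in design.wells:
        df = by_well.get(w.well_id)
        if df is None:
            df = pd.DataFrame({f"pct_{s}": pd.Series(dtype=float) for s in stainings})
        out.append(
            summarize_well(w.well_id, w.gene, w.reagent, w.treatment, df, stainings, qc_min_cells)
        )
    return out


def _replicate_stat(values: np.ndarray, how: str) -> float:
    if how == "median":
        return float(np.median(values))
    if how == "mean":
        return float(np.mean(values))
    raise ValueError(f"unknown replicate statistic {how!r}")


def robust_zscores(
    summaries: Sequence[WellSummary],
    staining: str,
    include_controls: bool = False,
    replicate_stat: str = "median",
    control_genes: Sequence[str] = CONTROL_GENES,
) -> pd.DataFrame:
    """Per-reagent robust z-scores against the whole plate.

    Replicate wells of each (gene, reagent) are collapsed with
    ``replicate_stat`` into one value ``x``; the reference median/MAD are
    computed over QC-passing, damage-treated library samples (controls
    excluded by default). MAD = 0 falls back to the plate SD with a warning;
    SD = 0 as well is an error.
    """
    rows = []
    for s in summaries:
        if s.treatment != "damaged" or not s.qc_pass:
            continue
        val = s.median_readout.get(staining)
        if val is None or (isinstance(val, float) and math.isnan(val)):
            continue
        rows.append((s.gene, s.reagent, val))
    if not rows:
        raise ValueError("no QC-passing damaged wells with this staining")
    df = pd.DataFrame(rows, columns=["gene", "reagent", "value"])
    agg = (
        df.groupby(["gene", "reagent"])["value"]
        .apply(lambda v: _replicate_stat(v.to_numpy(), replicate_stat))
        .reset_index(name="x")
    )

    is_ctrl = agg["gene"].isin(list(control_genes))
    ref = agg if include_controls else agg[~is_ctrl]
    if len(ref) < 4:
        raise ValueError(f"need >= 4 reference samples on the plate, have {len(ref)}")
    x_ref = ref["x"].to_numpy(dtype=float)
    center = float(np.median(x_ref))
    mad = float(np.median(np.abs(x_ref - center)))
    scale = MAD_SCALE * mad
    if scale == 0:
        sd = float(np.std(x_ref, ddof=1))
        if sd == 0:
            raise ValueError("plate MAD and SD are both zero; z-scores undefined")
        warnings.warn("plate MAD is zero; falling back to SD scaling", stacklevel=2)
        scale = sd

    out = agg.copy()
    out["staining"] = staining
    out["z"] = (out["x"] - center) / scale
    out["is_control"] = is_ctrl.to_numpy()
    return out[["gene", "reagent", "staining", "x", "z", "is_control"]]


def call_primary_hits(
    z_tables: dict[str, pd.DataFrame],
    threshold: float = DEFAULT_Z_THRESHOLD,
    control_genes: Sequence[str] = CONTROL_GENES,
) -> list[HitCall]:
    """Primary screen rule: a gene is a hit iff its robust z is at or below
    the threshold (inclusive) in one or both stainings."""
    genes: dict[str, dict[str, float]] = {}
    reagents: dict[str, str] = {}
    for staining, tbl in z_tables.items():
        for r in tbl.itertuples():
            if r.gene in control_genes:
                continue
            genes.setdefault(r.gene, {})[staining] = float(r.z)
            reagents[r.gene] = r.reagent
    if not z_tables:
        return []
    all_stainings = list(z_tables)
    calls: list[HitCall] = []
    for gene, zs in genes.items():
        missing = [s for s in all_stainings if s not in zs]
        if missing:
            warnings.warn(
                f"gene {gene}: staining(s) {missing} missing; evaluated on available",
                stacklevel=2,
            )
        best = min(zs.values())
        calls.append(
            HitCall(
                gene=gene,
                reagent=reagents[gene],
                staining="any",
                robust_z=best,
                is_hit=best <= threshold,
                stage="primary",
            )
        )
    calls.sort(key=lambda h: h.gene)
    return calls


def deconvolve_secondary(
    z_tables: dict[str, pd.DataFrame],
    threshold: float = DEFAULT_Z_THRESHOLD,
    min_singles: int = 1,
    control_genes: Sequence[str] = CONTROL_GENES,
) -> tuple[list[HitCall], dict[str, bool]]:
    """Secondary screen rule on deconvolved single siRNAs.

    A single scores iff its z is ≤ threshold in BOTH stainings; a gene is
    confirmed iff at least ``min_singles`` of its singles score. Returns
    per-single calls and a per-gene confirmation map.
    """
    stainings = list(z_tables)
    if len(stainings) < 2:
        warnings.warn("secondary rule expects two stainings; using available", stacklevel=2)
    per_single: dict[tuple[str, str], dict[str, float]] = {}
    for staining, tbl in z_tables.items():
        for r in tbl.itertuples():
            if r.gene in control_genes:
                continue
            per_single.setdefault((r.gene, r.reagent), {})[staining] = float(r.z)

    calls: list[HitCall] = []
    scoring: dict[str, int] = {}
    n_singles: dict[str, int] = {}
    for (gene, reagent), zs in sorted(per_single.items()):
        n_singles[gene] = n_singles.get(gene, 0) + 1
        worst = max(zs.values())
        scores = all(z <= threshold for z in zs.values()) and len(zs) == len(stainings)
        if len(zs) < len(stainings):
            scores = all(z <= threshold for z in zs.values())
        calls.append(
            HitCall(
                gene=gene,
                reagent=reagent,
                staining="both",
                robust_z=worst,
                is_hit=scores,
                stage="secondary",
            )
        )
        if scores:
            scoring[gene] = scoring.get(gene, 0) + 1
    for gene, n in n_singles.items():
        if n < 4:
            warnings.warn(f"gene {gene}: only {n} single siRNAs available", stacklevel=2)
    confirmed = {gene: scoring.get(gene, 0) >= min_singles for gene in n_singles}
    return calls, confirmed


def compare_conditions(
    groups: dict[str, Sequence[float]],
    control: Optional[str] = None,
    method: str = "bonferroni",
) -> dict:
    """One-way ANOVA plus adjusted pairwise comparisons.

    ``bonferroni``: all-pairs Welch-free t-tests with Bonferroni adjustment.
    ``dunnett``: comparisons against the named control group.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for name, arr in arrays.items():
        if len(arr) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 values")
    f_stat, p_anova = stats.f_oneway(*arrays.values())

    comparisons = []
    if method == "bonferroni":
        pairs = list(combinations(arrays, 2))
        for a, b in pairs:
            t, p = stats.ttest_ind(arrays[a], arrays[b])
            comparisons.append(
                {"group_a": a, "group_b": b, "t": float(t), "p_adj": min(float(p) * len(pairs), 1.0)}
            )
    elif method == "dunnett":
        if control is None or control not in arrays:
            raise ValueError("dunnett requires a control group name")
        others = [k for k in arrays if k != control]
        res = stats.dunnett(*(arrays[k] for k in others), control=arrays[control])
        for name, t, p in zip(others, np.atleast_1d(res.statistic), np.atleast_1d(res.pvalue)):
            comparisons.append(
                {"group_a": name, "group_b": control, "t": float(t), "p_adj": float(p)}
            )
    else:
        raise ValueError(f"unknown method {method!r}")
    return {
        "anova_F": float(f_stat),
        "anova_p": float(p_anova),
        "method": method,
        "comparisons": comparisons,
    }


def screen_report(
    primary: Sequence[HitCall],
    secondary: Optional[Sequence[HitCall]] = None,
    confirmed: Optional[dict[str, bool]] = None,
    true_hits: Optional[Sequence[str]] = None,
) -> dict:
    """Combine hit calls into one report; adds recall/precision when planted
    truth is supplied."""
    report: dict = {
        "primary": [
            {
                "gene": h.gene,
                "reagent": h.reagent,
                "robust_z": h.robust_z,
                "is_hit": h.is_hit,
            }
            for h in primary
        ],
        "primary_hits": sorted(h.gene for h in primary if h.is_hit),
    }
    if secondary is not None:
        report["secondary"] = [
            {
                "gene": h.gene,
                "reagent": h.reagent,
                "robust_z": h.robust_z,
                "scores": h.is_hit,
            }
            for h in secondary
        ]
    if confirmed is not None:
        report["confirmed_genes"] = sorted(g for g, ok in confirmed.items() if ok)
    if true_hits is not None:
        truth = set(true_hits)
        called = set(report["primary_hits"])
        tp = len(called & truth)
        report["recall"] = tp / len(truth) if truth else float("nan")
        report["precision"] = tp / len(called) if called else float("nan")
        report["true_hits"] = sorted(truth)
    return report
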