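"""Comparative SILAC proximity-proteomics analysis.

Workflow: remove contaminant/reverse/site-only rows, compute per-replicate
log2 heavy/light ratios, run a one-sample two-sided t-test of each protein's
ratios against the 1:1-mixing null (log2 = 0), and gate the volcano into
enriched / depleted / not-significant classes with an inclusive fold-change
cutoff of |mean log2| ≥ 1.5 and p < 0.05. No multiple-testing correction is
applied to the classification; a Benjamini–Hochberg FDR column is emitted
for reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FLAG_COLUMNS",
    "VolcanoResult",
    "filter_quant_table",
    "ratio_columns",
    "compute_log2_ratios",
    "test_enrichment",
    "classify_volcano",
    "volcano_table",
    "replicate_agreement",
]

FLAG_COLUMNS = ("contaminant", "reverse", "site_only")
DEFAULT_FC_CUT = 1.5
DEFAULT_P_CUT = 0.05


class TestResult(NamedTuple):
    p_value: float
    t_stat: float
    degenerate: bool  # zero-variance sample; p is the limiting value


@dataclass
class VolcanoResult:
    protein_id: str
    n_replicates_used: int
    mean_log2: float
    p_value: float
    passes_fc: bool
    passes_p: bool
    volcano_class: str  # enriched_heavy | depleted_heavy | not_significant
    degenerate: bool = False


def filter_quant_table(table: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop rows flagged contaminant, reverse, or site-only.

    Returns the filtered table and a removal log counting each reason (a row
    with several flags is removed once but logged under every reason).
    Idempotent: filtering a filtered table changes nothing.
    """
    missing = [c for c in FLAG_COLUMNS if c not in table.columns]
    if missing:
        raise KeyError(f"quant table lacks flag columns: {missing}")
    flags = table[list(FLAG_COLUMNS)].isin([True, 1, "+"])  # NaN -> False
    log = {c: int(flags[c].sum()) for c in FLAG_COLUMNS}
    drop = flags.any(axis=1)
    log["rows_removed"] = int(drop.sum())
    return table[~drop].reset_index(drop=True), log


def ratio_columns(table: pd.DataFrame) -> list[int]:
    """Replicate indices present as intensity_H_k / intensity_L_k pairs."""
    reps = []
    k = 1
    while f"intensity_H_{k}" in table.columns and f"intensity_L_{k}" in table.columns:
        reps.append(k)
        k += 1
    if not reps:
        raise KeyError("no intensity_H_k/intensity_L_k column pairs found")
    return reps


def compute_log2_ratios(
    table: pd.DataFrame, min_replicates: int = 2
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-protein per-replicate log2(H/L) plus the per-protein mean.

    A replicate contributes only when both intensities are present and > 0;
    L = 0 with H > 0 is excluded and counted (no infinities are emitted).
    Proteins with fewer than ``min_replicates`` contributing replicates are
    dropped and counted.
    """
    reps = ratio_columns(table)
    ratios = np.full((len(table), len(reps)), np.nan)
    n_zero_light = 0
    for j, k in enumerate(reps):
        h = table[f"intensity_H_{k}"].to_numpy(dtype=float)
        light = table[f"intensity_L_{k}"].to_numpy(dtype=float)
        ok = np.isfinite(h) & np.isfinite(light) & (h > 0) & (light > 0)
        n_zero_light += int(np.sum(np.isfinite(h) & (h > 0) & np.isfinite(light) & (light == 0)))
        ratios[ok, j] = np.log2(h[ok] / light[ok])

    n_used = np.sum(np.isfinite(ratios), axis=1)
    keep = n_used >= min_replicates
    out = pd.DataFrame({"protein_id": table["protein_id"].to_numpy()[keep]})
    if "gene_symbol" in table.columns:
        out["gene_symbol"] = table["gene_symbol"].to_numpy()[keep]
    kept = ratios[keep]
    for j, k in enumerate(reps):
        out[f"log2_ratio_{k}"] = kept[:, j]
    out["n_replicates_used"] = n_used[keep].astype(int)
    with np.errstate(invalid="ignore"):
        out["mean_log2"] = np.nanmean(kept, axis=1)
    log = {
        "replicates_excluded_zero_light": n_zero_light,
        "proteins_dropped_min_replicates": int(np.sum(~keep)),
    }
    return out, log


def test_enrichment(log2_ratios: Sequence[float]) -> TestResult:
    """Two-sided one-sample t-test of log2 ratios against 0.

    Degrees of freedom are n − 1. A zero-variance sample is flagged
    degenerate and reported at the limiting p (0 for a nonzero mean, 1 for a
    zero mean) rather than silently.
    """
    x = np.asarray([v for v in log2_ratios if np.isfinite(v)], dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError(f"t-test needs >= 2 contributing replicates, got {n}")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        return TestResult(0.0 if mean != 0 else 1.0, math.inf if mean != 0 else 0.0, True)
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 1))
    return TestResult(p, float(t), False)


def classify_volcano(
    mean_log2: float,
    p_value: float,
    fc_cut: float = DEFAULT_FC_CUT,
    p_cut: float = DEFAULT_P_CUT,
    fc_inclusive: bool = True,
) -> str:
    """Joint fold-change / significance gate.

    ``enriched_heavy`` iff mean log2 ≥ fc_cut (inclusive by default) and
    p < p_cut; ``depleted_heavy`` symmetrically at ≤ −fc_cut; otherwise
    ``not_significant``.
    """
    if not (np.isfinite(mean_log2) and np.isfinite(p_value)):
        raise ValueError("classify_volcano requires finite inputs")
    if fc_inclusive:
        up, down = mean_log2 >= fc_cut, mean_log2 <= -fc_cut
    else:
        up, down = mean_log2 > fc_cut, mean_log2 < -fc_cut
    sig = p_value < p_cut
    if up and sig:
        return "enriched_heavy"
    if down and sig:
        return "depleted_heavy"
    return "not_significant"


def volcano_table(
    table: pd.DataFrame,
    fc_cut: float = DEFAULT_FC_CUT,
    p_cut: float = DEFAULT_P_CUT,
    min_replicates: int = 2,
    fc_inclusive: bool = True,
    prefiltered: bool = False,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Full pipeline: filter, ratios, t-tests, classification.

    Returns the volcano table (one row per retained protein, with an
    auxiliary BH-FDR column) and the combined removal/exclusion log.
    """
    log: dict[str, int] = {}
    if not prefiltered:
        table, flog = filter_quant_table(table)
        log.update(flog)
    ratios, rlog = compute_log2_ratios(table, min_replicates=min_replicates)
    log.update(rlog)

    rep_cols = [c for c in ratios.columns if c.startswith("log2_ratio_")]
    results: list[VolcanoResult] = []
    for row in ratios.itertuples():
        vals = [getattr(row, c) for c in rep_cols]
        res = test_enrichment(vals)
        mean = float(row.mean_log2)
        cls = classify_volcano(mean, res.p_value, fc_cut, p_cut, fc_inclusive)
        if res.degenerate and mean == 0.0:
            cls = "not_significant"
        results.append(
            VolcanoResult(
                protein_id=row.protein_id,
                n_replicates_used=int(row.n_replicates_used),
                mean_log2=mean,
                p_value=res.p_value,
                passes_fc=abs(mean) >= fc_cut if fc_inclusive else abs(mean) > fc_cut,
                passes_p=res.p_value < p_cut,
                volcano_class=cls,
                degenerate=res.degenerate,
            )
        )
    out = pd.DataFrame([vars(r) for r in results])
    if len(out):
        out["fdr_bh"] = _benjamini_hochberg(out["p_value"].to_numpy())
    return out, log


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(ranked, 0, 1)
    return out


def replicate_agreement(
    table: pd.DataFrame, min_common: int = 2
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Pairwise replicate Pearson correlations and Venn overlap counts.

    Correlations are computed on log2 ratios over proteins detected in both
    replicates of a pair (NaN and flagged when fewer than ``min_common``
    proteins are shared, or a column is constant). Venn counts give, for
    every nonempty replicate subset, the number of proteins detected in
    exactly that subset.
    """
    reps = ratio_columns(table)
    if len(reps) < 2:
        raise ValueError("replicate agreement needs >= 2 replicates")
    ratios = {}
    for k in reps:
        h = table[f"intensity_H_{k}"].to_numpy(dtype=float)
        light = table[f"intensity_L_{k}"].to_numpy(dtype=float)
        ok = np.isfinite(h) & np.isfinite(light) & (h > 0) & (light > 0)
        r = np.full(len(table), np.nan)
        r[ok] = np.log2(h[ok] / light[ok])
        ratios[k] = r

    corr = pd.DataFrame(index=reps, columns=reps, dtype=float)
    for a in reps:
        corr.loc[a, a] = 1.0
    for i, a in enumerate(reps):
        for b in reps[i + 1 :]:
            both = np.isfinite(ratios[a]) & np.isfinite(ratios[b])
            if both.sum() < min_common or np.ptp(ratios[a][both]) == 0 or np.ptp(ratios[b][both]) == 0:
                corr.loc[a, b] = corr.loc[b, a] = float("nan")
                continue
            r = np.corrcoef(ratios[a][both], ratios[b][both])[0, 1]
            corr.loc[a, b] = corr.loc[b, a] = float(r)

    detected = np.stack([np.isfinite(ratios[k]) for k in reps], axis=1)
    venn: dict[str, int] = {}
    for pattern in range(1, 2 ** len(reps)):
        members = [reps[j] for j in range(len(reps)) if pattern >> j & 1]
        sel = np.ones(len(table), dtype=bool)
        for j in range(len(reps)):
            want = bool(pattern >> j & 1)
            sel &= detected[:, j] == want
        venn["&".join(str(m) for m in members)] = int(sel.sum())
    return corr, venn
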