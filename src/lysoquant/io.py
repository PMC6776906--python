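"""File formats and provenance.

Images travel as multi-page 16-bit TIFF (one page per channel) with a
sidecar JSON naming the channel roles and pixel size; ground truth as JSON;
object/design/quant tables as CSV or TSV; run configuration as YAML. Every
writer has a reader with round-trip fidelity (bit-exact for integers, full
float precision for reals).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import ImageField, VesicleRecord
from .synthgen import GroundTruth, PlateDesign

__all__ = [
    "write_field",
    "read_field",
    "write_truth",
    "read_truth",
    "write_design",
    "read_design",
    "write_objects",
    "read_objects",
    "write_quant",
    "read_quant",
    "load_config",
    "write_provenance",
]


def write_field(field: ImageField, tiff_path, sidecar_path=None) -> None:
    tiff_path = Path(tiff_path)
    roles = list(field.channels)
    stack = np.stack([np.asarray(field.channels[r]) for r in roles]).astype(np.uint16)
    tifffile.imwrite(tiff_path, stack, photometric="minisblack")
    sidecar = Path(sidecar_path) if sidecar_path else tiff_path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "channel_roles": roles,
                "pixel_size_um": field.pixel_size,
                "bit_depth": field.bit_depth,
            },
            indent=1,
        )
    )


def read_field(tiff_path, sidecar_path=None) -> ImageField:
    tiff_path = Path(tiff_path)
    sidecar = Path(sidecar_path) if sidecar_path else tiff_path.with_suffix(".json")
    if not tiff_path.exists():
        raise FileNotFoundError(tiff_path)
    if not sidecar.exists():
        raise FileNotFoundError(f"channel-map sidecar missing: {sidecar}")
    meta = json.loads(sidecar.read_text())
    stack = tifffile.imread(tiff_path)
    if stack.ndim == 2:
        stack = stack[None]
    roles = meta["channel_roles"]
    if len(roles) != stack.shape[0]:
        raise ValueError(
            f"sidecar lists {len(roles)} roles but TIFF has {stack.shape[0]} pages"
        )
    return ImageField(
        channels={r: stack[i] for i, r in enumerate(roles)},
        pixel_size=float(meta["pixel_size_um"]),
        bit_depth=int(meta.get("bit_depth", 16)),
    )


def write_truth(truth: GroundTruth, path) -> None:
    truth.to_json(path)


def read_truth(path) -> GroundTruth:
    return GroundTruth.from_json(path)


def write_design(design: PlateDesign, path) -> None:
    design.to_frame().to_csv(path, index=False)


def read_design(path) -> PlateDesign:
    return PlateDesign.from_frame(pd.read_csv(path))


OBJECT_COLUMNS = [
    "vesicle_id",
    "cell_id",
    "channel_role",
    "centroid_row",
    "centroid_col",
    "radius_px",
    "area",
]


def write_objects(records: Sequence[VesicleRecord], path) -> None:
    rows = []
    for r in records:
        row = {
            "vesicle_id": r.vesicle_id,
            "cell_id": r.cell_id,
            "channel_role": r.channel_role,
            "centroid_row": r.centroid[0],
            "centroid_col": r.centroid[1],
            "radius_px": r.radius_px,
            "area": r.area,
        }
        for role, v in r.mean_intensity.items():
            row[f"mean_{role}"] = v
        for role, v in r.corrected_mean.items():
            row[f"corrected_{role}"] = v
        for role, v in r.positive_for.items():
            row[f"positive_{role}"] = bool(v)
        rows.append(row)
    pd.DataFrame(rows, columns=None if rows else OBJECT_COLUMNS).to_csv(path, index=False)


def read_objects(path) -> list[VesicleRecord]:
    df = pd.read_csv(path)
    missing = [c for c in OBJECT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"objects CSV {path} missing column(s): {missing}")
    out = []
    for row in df.itertuples():
        rec = VesicleRecord(
            vesicle_id=int(row.vesicle_id),
            cell_id=int(row.cell_id),
            channel_role=str(row.channel_role),
            centroid=(int(row.centroid_row), int(row.centroid_col)),
            radius_px=float(row.radius_px),
            area=float(row.area),
        )
        for col in df.columns:
            if col.startswith("mean_"):
                rec.mean_intensity[col[5:]] = float(getattr(row, col))
            elif col.startswith("corrected_"):
                rec.corrected_mean[col[10:]] = float(getattr(row, col))
            elif col.startswith("positive_"):
                rec.positive_for[col[9:]] = bool(getattr(row, col))
        out.append(rec)
    return out


def write_quant(table: pd.DataFrame, path) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    table.to_csv(path, sep=sep, index=False)


def read_quant(path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    if "protein_id" not in df.columns:
        raise ValueError(f"quant table {path} missing column 'protein_id'")
    return df


DEFAULT_CONFIG = {
    "seed": 0,
    "thresholds": {
        "robust_z": -2.0,
        "puncta_count": 3,
        "fold_change_log2": 1.5,
        "p_value": 0.05,
    },
    "qc": {"min_cells_per_well": 50},
    "synthgen": {},
    "imgquant": {},
    "screen": {"min_singles": 1},
    "proximity": {"min_replicates": 2},
}


def load_config(path: Optional[str] = None) -> dict:
    """Load run configuration, filling defaults (all paper-rule thresholds
    are present even in a bare run)."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError(f"malformed config {path}: expected a mapping")
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    return cfg


def write_provenance(out_dir, config: dict, seed: int, extra: Optional[dict] = None) -> Path:
    """Write a machine-readable provenance JSON next to stage outputs."""
    import lysoquant

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    canonical = json.dumps(config, sort_keys=True)
    payload = {
        "config": config,
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
        "seed": seed,
        "versions": {
            "lysoquant": lysoquant.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    if extra:
        payload.update(extra)
    path = out_dir / "provenance.json"
    path.write_text(json.dumps(payload, indent=1))
    return path
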