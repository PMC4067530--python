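"""Tabular I/O, schema validation and run manifests.

Coordinate convention in every file: long axis x with the old pole at x = 0
and the new pole at x = l0; y centered on the cell axis; units um and s.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "read_spot_table",
    "read_cell_meta",
    "validate_spot_table",
    "write_run_trajectories",
    "write_ensemble_summary",
    "RunManifest",
    "build_manifest",
    "write_manifest",
]

SPOT_COLUMNS = ["cell_id", "frame", "t_s", "x_um", "y_um"]
META_COLUMNS = ["cell_id", "length_um", "width_um", "old_pole_at_zero"]


class SchemaError(ValueError):
    """A tabular input violated its declared schema."""


def validate_spot_table(df: pd.DataFrame, meta: pd.DataFrame | None = None) -> pd.DataFrame:
    """Check the spot-table invariants; returns the validated frame.

    Frames must be strictly increasing per cell, with at most two spots per
    cell per frame; when per-cell geometry is supplied, positions must lie
    within the cell bounds.
    """
    missing = set(SPOT_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"spot table lacks columns {sorted(missing)}")
    if df[SPOT_COLUMNS].isna().any().any():
        bad = int(df[SPOT_COLUMNS].isna().any(axis=1).idxmax())
        raise SchemaError(f"row {bad}: missing value")
    for cell, g in df.groupby("cell_id"):
        counts = g.groupby("frame").size()
        if (counts > 2).any():
            f = int(counts.idxmax())
            raise SchemaError(
                f"cell {cell}, frame {f}: {counts.max()} spots violate the "
                "<=2 spots per cell per frame invariant"
            )
        per_spot = g.groupby(g.get("spot_id", pd.Series(0, index=g.index)))
        for _, track in per_spot:
            frames = track["frame"].to_numpy()
            if np.any(np.diff(frames) <= 0):
                raise SchemaError(f"cell {cell}: frame column not strictly increasing")
    if meta is not None:
        merged = df.merge(meta, on="cell_id", how="left", validate="many_to_one")
        if merged["length_um"].isna().any():
            cell = merged.loc[merged["length_um"].isna(), "cell_id"].iloc[0]
            raise SchemaError(f"cell {cell}: no metadata row")
        out_x = (merged["x_um"] < 0) | (merged["x_um"] > merged["length_um"])
        out_y = merged["y_um"].abs() > merged["width_um"] / 2
        if (out_x | out_y).any():
            cell = merged.loc[out_x | out_y, "cell_id"].iloc[0]
            raise SchemaError(f"cell {cell}: spot position outside cell bounds")
    return df


def read_spot_table(path: str | Path, meta: pd.DataFrame | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return validate_spot_table(df, meta=meta)


def read_cell_meta(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(META_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"cell metadata lacks columns {sorted(missing)}")
    if df["cell_id"].duplicated().any():
        raise SchemaError("duplicate cell_id in metadata")
    return df


# ---------------------------------------------------------------------------
# simulation outputs
# ---------------------------------------------------------------------------


def write_run_trajectories(path: str | Path, runs) -> None:
    """Per-run trajectory TSV with header ``run t_s x_um y_um n_bound``."""
    frames = []
    for res in runs:
        f = res.frame.copy()
        f.insert(0, "run", res.run_index)
        frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def write_ensemble_summary(path: str | Path, ensemble) -> None:
    """Ensemble CSV with columns ``t_s, mean_x_um, completion_fraction``."""
    ensemble.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record sufficient to re-execute a run."""

    command: str
    config: dict[str, Any]
    seed: int | None
    package_version: str
    created_utc: str
    python: str = field(default_factory=platform.python_version)
    inputs: dict[str, str] = field(default_factory=dict)    # path -> sha256
    outputs: dict[str, str] = field(default_factory=dict)


def build_manifest(command, config, seed=None, inputs=(), outputs=()) -> RunManifest:
    from . import __version__

    return RunManifest(
        command=command,
        config=dict(config),
        seed=seed,
        package_version=__version__,
        created_utc=datetime.now(timezone.utc).isoformat(),
        inputs={str(p): _sha256(Path(p)) for p in inputs},
        outputs={str(p): _sha256(Path(p)) for p in outputs},
    )


def write_manifest(path: str | Path, manifest: RunManifest) -> None:
    Path(path).write_text(json.dumps(asdict(manifest), indent=2) + "\n")
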