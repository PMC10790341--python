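"""CSV/YAML/mask input-output and run manifests.

Conventions: UTF-8 comma-separated CSV with a header row, '.' decimal;
diameters in um, volumes in um^3, labeling indices as fractions in [0, 1]
(percent inputs must be divided by 100 at the boundary).  Masks are
single-channel PNG or TIFF images of integer class codes with ROI polygons
in a GeoJSON-style JSON sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml
from imageio.v3 import imread, imwrite

from . import __version__
from .histology import ATRESIA_CRITERIA, RegionOfInterest

__all__ = [
    "read_follicle_table",
    "write_follicle_table",
    "read_mask",
    "write_mask",
    "read_roi",
    "write_roi",
    "write_manifest",
    "write_provenance",
]

_REQUIRED_COLUMNS = ("follicle_id", "animal_id", "cycle_stage", "li")


def read_follicle_table(path: str | Path) -> pd.DataFrame:
    """Read a follicle CSV, validating schema and value ranges.

    Accepts either a ``pseudodiameter_um`` column or an ``area_um2`` column
    (converted on the fly).  Malformed rows are reported with their CSV row
    numbers; nothing is silently dropped.
    """
    from .histology import pseudodiameter

    df = pd.read_csv(path)
    missing = set(_REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if "pseudodiameter_um" not in df.columns:
        if "area_um2" not in df.columns:
            raise ValueError(
                f"{path}: need a pseudodiameter_um or area_um2 column"
            )
        df["pseudodiameter_um"] = [
            pseudodiameter(a) for a in df["area_um2"].to_numpy(dtype=float)
        ]
    bad = df.index[
        (df["pseudodiameter_um"] <= 0)
        | (df["li"] < 0)
        | (df["li"] > 1)
        | df["pseudodiameter_um"].isna()
        | df["li"].isna()
    ]
    if len(bad):
        rows = [int(i) + 2 for i in bad[:10]]  # +2: header + 1-based
        raise ValueError(
            f"{path}: invalid pseudodiameter/li values at CSV rows {rows}"
        )
    if "atretic" not in df.columns:
        flag_cols = [f"atresia_{c}" for c in ATRESIA_CRITERIA]
        present = [c for c in flag_cols if c in df.columns]
        if present:
            df["atretic"] = df[present].astype(bool).any(axis=1)
        else:
            df["atretic"] = False
    if "included" not in df.columns:
        df["included"] = True
    return df


def write_follicle_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.8g")


def read_mask(path: str | Path) -> np.ndarray:
    arr = np.asarray(imread(path))
    if arr.ndim == 3:  # palette/RGB exports of class codes: take one channel
        if not (arr == arr[..., :1]).all():
            raise ValueError(f"{path}: multi-channel image is not a class mask")
        arr = arr[..., 0]
    return arr.astype(np.uint8)


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    imwrite(path, np.asarray(mask, dtype=np.uint8))


def read_roi(path: str | Path) -> RegionOfInterest:
    """ROI sidecar: {"basal_lamina": [[r, c], ...], "cumulus_exclusions": [...]}"""
    data = json.loads(Path(path).read_text())
    return RegionOfInterest(
        basal_lamina_polygon=np.asarray(data["basal_lamina"], dtype=float),
        cumulus_exclusion_polygons=tuple(
            np.asarray(p, dtype=float) for p in data.get("cumulus_exclusions", [])
        ),
    )


def write_roi(roi: RegionOfInterest, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    data = {
        "basal_lamina": np.asarray(roi.basal_lamina_polygon).tolist(),
        "cumulus_exclusions": [
            np.asarray(p).tolist() for p in roi.cumulus_exclusion_polygons
        ],
    }
    Path(path).write_text(json.dumps(data))


def write_manifest(
    path: str | Path,
    subcommand: str,
    inputs: dict[str, Any],
    parameters: dict[str, Any],
    seed: int | None,
    outputs: list[str],
) -> None:
    """JSON run manifest sufficient to reproduce the run (minus timestamps)."""
    manifest = {
        "package": "follisim",
        "version": __version__,
        "subcommand": subcommand,
        "inputs": inputs,
        "parameters": parameters,
        "seed": seed,
        "outputs": outputs,
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))


def write_provenance(path: str | Path, config: Any, seed: int | None) -> None:
    """Echo generator settings to a provenance YAML next to synthetic data."""
    import dataclasses

    def plain(obj: Any) -> Any:
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {
                f.name: plain(getattr(obj, f.name))
                for f in dataclasses.fields(obj)
            }
        if isinstance(obj, (tuple, list)):
            return [plain(x) for x in obj]
        if isinstance(obj, np.generic):
            return obj.item()
        return obj

    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(
        yaml.safe_dump({"config": plain(config), "seed": seed}, sort_keys=False)
    )
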