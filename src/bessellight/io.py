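"""File formats: ThunderSTORM-dialect localization CSV, TIFF stacks, masks.

The CSV dialect is header-compatible with ThunderSTORM exports; the reader
tolerates column subsets and fills what is missing.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .localize import RECORD_COLUMNS, LocalizationTable
from .region_quant import RegionMask

__all__ = [
    "write_localizations_csv",
    "read_localizations_csv",
    "write_stack_tiff",
    "read_stack_tiff",
    "write_mask_tiff",
    "read_mask_tiff",
    "load_yaml_config",
]

# internal column -> ThunderSTORM header
_CSV_COLUMNS = {
    "frame": "frame",
    "x": "x [nm]",
    "y": "y [nm]",
    "z": "z [nm]",
    "sigma_x": "sigma1 [nm]",
    "sigma_y": "sigma2 [nm]",
    "photons": "intensity [photon]",
    "background": "offset [photon]",
    "uncertainty_xy": "uncertainty [nm]",
    "keep": "keep",
}
_CSV_REVERSE = {v: k for k, v in _CSV_COLUMNS.items()}


def write_localizations_csv(table: LocalizationTable, path: str | Path) -> None:
    df = table.df.copy()
    cols = [c for c in _CSV_COLUMNS if c in df.columns]
    df[cols].rename(columns=_CSV_COLUMNS).to_csv(path, index=False)


def read_localizations_csv(path: str | Path, pixel_size: float = 100.0) -> LocalizationTable:
    raw = pd.read_csv(path)
    df = raw.rename(columns={c: _CSV_REVERSE.get(c.strip(), c.strip())
                             for c in raw.columns})
    for col in ("frame", "x", "y"):
        if col not in df.columns:
            raise ValueError(f"localization CSV lacks required column {col!r}")
    for col in RECORD_COLUMNS:
        if col not in df.columns:
            df[col] = True if col == "keep" else np.nan
    if "ellipticity" not in raw.columns:
        with np.errstate(invalid="ignore", divide="ignore"):
            df["ellipticity"] = df["sigma_x"] / df["sigma_y"]
    df["keep"] = df["keep"].fillna(True).astype(bool)
    return LocalizationTable(df[RECORD_COLUMNS], pixel_size=pixel_size)


def write_stack_tiff(frames: np.ndarray, path: str | Path,
                     pixel_size: float | None = None) -> None:
    """Write a T x H x W stack as multi-page 16-bit TIFF (counts clipped to
    the uint16 range)."""
    arr = np.clip(np.asarray(frames), 0, np.iinfo(np.uint16).max)
    meta = {"pixel_size_nm": pixel_size} if pixel_size else None
    tifffile.imwrite(path, arr.astype(np.uint16),
                     metadata=meta, photometric="minisblack")


def read_stack_tiff(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    return arr


def write_mask_tiff(mask: RegionMask, path: str | Path,
                    names_path: str | Path | None = None) -> None:
    tifffile.imwrite(path, mask.labels.astype(np.uint16),
                     photometric="minisblack")
    if names_path is not None:
        payload = {
            "voxel_size_um": list(mask.voxel_size),
            "region_names": {str(k): v for k, v in mask.region_names.items()},
        }
        Path(names_path).write_text(json.dumps(payload, indent=1))


def read_mask_tiff(path: str | Path,
                   names_path: str | Path | None = None,
                   voxel_size: tuple[float, float, float] = (0.1, 0.1, 0.1),
                   ) -> RegionMask:
    labels = read_stack_tiff(path).astype(int)
    names: dict[int, str] = {}
    if names_path is not None:
        payload = json.loads(Path(names_path).read_text())
        names = {int(k): v for k, v in payload.get("region_names", {}).items()}
        voxel_size = tuple(payload.get("voxel_size_um", voxel_size))
    return RegionMask(labels=labels, voxel_size=voxel_size, region_names=names)


def load_yaml_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
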