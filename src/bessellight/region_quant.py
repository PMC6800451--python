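"""Mask-based quantification of localizations in labeled volumes.

Localizations are classified against a labeled 3D voxel volume (e.g. the
DPM-neurite mask, or the 15 mushroom-body sectors): a record is *inside* a
region iff the voxel containing it carries that region's label, using the
half-open voxel convention [i*s, (i+1)*s) per axis.  Region volumes are the
labeled voxel counts times the voxel volume — integer arithmetic times a
rational constant, so exact up to float rounding.  Group differences are
summarised as mean +/- SEM with a Welch two-sample t-test (unequal
variances); no multiple-testing correction is applied by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RegionMask",
    "RegionReport",
    "classify_by_mask",
    "threshold_volume",
    "region_density",
    "compare_groups",
]


@dataclass
class RegionMask:
    """Labeled voxel volume: ``labels[iz, iy, ix]`` with 0 = background.

    ``voxel_size`` is (x, y, z) in um; ``region_names`` maps label id to a
    display name (e.g. the mushroom-body sectors alpha1..gamma5).
    """

    labels: np.ndarray
    voxel_size: tuple[float, float, float]
    region_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D volume")
        if np.any(self.labels < 0):
            raise ValueError("labels must be non-negative")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be positive per axis")
        # names for labels absent from the volume are allowed (reported empty);
        # the converse — unnamed labels under a non-empty name map — errors in
        # region_density, where the mismatch would corrupt the report.

    @property
    def voxel_volume(self) -> float:
        """um^3 per voxel."""
        sx, sy, sz = self.voxel_size
        return sx * sy * sz

    def label_at(self, x_nm: np.ndarray, y_nm: np.ndarray, z_nm: np.ndarray) -> np.ndarray:
        """Label of the voxel containing each point; -1 when out of bounds.

        Point-in-voxel by floor(coordinate / voxel_size) with half-open
        voxels, so a point exactly on a boundary belongs to the upper voxel.
        """
        sx, sy, sz = self.voxel_size
        ix = np.floor(np.asarray(x_nm, float) / (sx * 1000.0)).astype(int)
        iy = np.floor(np.asarray(y_nm, float) / (sy * 1000.0)).astype(int)
        iz = np.floor(np.asarray(z_nm, float) / (sz * 1000.0)).astype(int)
        nz, ny, nx = self.labels.shape
        inside = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny) & (iz >= 0) & (iz < nz)
        out = np.full(len(ix), -1, dtype=int)
        out[inside] = self.labels[iz[inside], iy[inside], ix[inside]]
        return out


@dataclass
class RegionReport:
    """Per-region localization counts, volumes (um^3) and densities (/um^3)."""

    counts: dict[int, int]
    volumes: dict[int, float]
    densities: dict[int, float]
    empty_regions: list[int]
    inside_count: int
    outside_count: int

    @property
    def total(self) -> int:
        return self.inside_count + self.outside_count


def classify_by_mask(
    df: pd.DataFrame, mask: RegionMask, reference_id: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition kept localizations into inside/outside a reference region.

    A record is inside iff its containing voxel carries ``reference_id``
    (the 3D digital-intersection rule); out-of-bounds records count as
    outside.  The partition is exhaustive and disjoint.
    """
    if reference_id <= 0 or not np.any(mask.labels == reference_id):
        raise ValueError(f"mask contains no voxels labeled {reference_id}")
    kept = df[df["keep"]] if "keep" in df.columns else df
    z = kept["z"].to_numpy(float) if "z" in kept.columns else np.zeros(len(kept))
    lab = mask.label_at(kept["x"].to_numpy(float), kept["y"].to_numpy(float), z)
    inside = lab == reference_id
    return kept[inside], kept[~inside]


def threshold_volume(volume: np.ndarray, lower_bound: float) -> np.ndarray:
    """Binary mask ``volume >= lower_bound`` (inclusive lower bound).

    For integer volumes the bound must lie within the dtype's range.
    Returns a boolean array; surviving-voxel count is its sum.
    """
    volume = np.asarray(volume)
    if np.issubdtype(volume.dtype, np.integer):
        info = np.iinfo(volume.dtype)
        if not (info.min <= lower_bound <= info.max):
            raise ValueError(
                f"bound {lower_bound} outside {volume.dtype} range "
                f"[{info.min}, {info.max}]"
            )
    return volume >= lower_bound


def region_density(df: pd.DataFrame, mask: RegionMask) -> RegionReport:
    """Per-region localization density: count / (voxel count x voxel volume).

    Regions present in the mask (or named in ``region_names``) but holding
    no voxels are flagged rather than divided by zero.  Inside/outside
    totals (inside = any non-zero label) conserve the kept-record count
    exactly.
    """
    present = set(int(v) for v in np.unique(mask.labels)) - {0}
    if mask.region_names:
        unnamed = present - set(mask.region_names)
        if unnamed:
            raise ValueError(f"mask labels {sorted(unnamed)} have no region name")
    region_ids = sorted(present | {k for k in mask.region_names if k != 0})
    kept = df[df["keep"]] if "keep" in df.columns else df
    z = kept["z"].to_numpy(float) if "z" in kept.columns else np.zeros(len(kept))
    lab = mask.label_at(kept["x"].to_numpy(float), kept["y"].to_numpy(float), z)
    vox_counts = np.bincount(mask.labels.ravel())
    counts: dict[int, int] = {}
    volumes: dict[int, float] = {}
    densities: dict[int, float] = {}
    empty: list[int] = []
    for rid in region_ids:
        c = int(np.sum(lab == rid))
        nvox = int(vox_counts[rid]) if rid < len(vox_counts) else 0
        vol = nvox * mask.voxel_volume
        counts[rid] = c
        volumes[rid] = vol
        if nvox == 0:
            empty.append(rid)
            densities[rid] = 0.0
        else:
            densities[rid] = c / vol
    inside = int(np.sum(lab > 0))
    outside = int(len(lab) - inside)
    return RegionReport(counts=counts, volumes=volumes, densities=densities,
                        empty_regions=empty, inside_count=inside,
                        outside_count=outside)


def compare_groups(
    group_a: Sequence[Mapping[str, float] | Mapping[int, float]],
    group_b: Sequence[Mapping[str, float] | Mapping[int, float]],
    region_scope: Sequence | None = None,
) -> pd.DataFrame:
    """Per-region mean +/- SEM and Welch t-test between two conditions.

    Each group is a sequence of replicate mappings region -> density (n >= 2
    replicates required).  Returns a DataFrame with mean/SEM per group, the
    difference, and the two-sided Welch p-value.  No multiple-testing
    correction is applied.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need >= 2 replicates per condition")
    if region_scope is None:
        region_scope = sorted(set(group_a[0]) & set(group_b[0]),
                              key=lambda k: str(k))
    rows = []
    for region in region_scope:
        a = np.array([float(rep[region]) for rep in group_a])
        b = np.array([float(rep[region]) for rep in group_b])
        sem_a = a.std(ddof=1) / np.sqrt(len(a))
        sem_b = b.std(ddof=1) / np.sqrt(len(b))
        if np.allclose(a, b) and a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            p = 1.0
        else:
            p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
            if np.isnan(p):
                p = 1.0
        rows.append({
            "region": region,
            "mean_a": a.mean(), "sem_a": sem_a,
            "mean_b": b.mean(), "sem_b": sem_b,
            "difference": b.mean() - a.mean(),
            "p_value": p,
        })
    return pd.DataFrame(rows)
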