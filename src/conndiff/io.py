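"""File formats: TSV tables, NIfTI images and run manifests.

Long-format edge TSV is the canonical interchange for networks (robust to
atlas reordering); square CSV is a convenience view. Time series are TSV
with one column per region (header = region ids in atlas order) and one row
per timepoint.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .atlas import RegionAtlas
from .structural import VoxelGrid

__all__ = [
    "read_timeseries_tsv",
    "write_timeseries_tsv",
    "read_subjects_tsv",
    "write_subjects_tsv",
    "save_voxel_grid",
    "load_voxel_grid",
    "write_manifest",
]


class FormatError(ValueError):
    """Malformed input file."""


def write_timeseries_tsv(path, ts: pd.DataFrame) -> None:
    ts.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_timeseries_tsv(path, atlas: RegionAtlas) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != list(atlas.region_ids):
        raise FormatError(
            f"{path}: time-series columns do not match the atlas region "
            f"order ({len(df.columns)} columns vs {atlas.r} regions)"
        )
    return df


def write_subjects_tsv(path, subjects: pd.DataFrame) -> None:
    subjects.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_subjects_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "subject_id" not in df.columns or "group" not in df.columns:
        raise FormatError(f"{path}: needs subject_id and group columns")
    return df


def save_voxel_grid(grid: VoxelGrid, prefix) -> dict[str, str]:
    """Write labels/FA/cost as NIfTI next to each other; returns the paths."""
    prefix = Path(prefix)
    affine = np.diag(list(grid.voxel_size) + [1.0])
    out = {}
    for name, arr, dtype in (
        ("labels", grid.labels, np.int32),
        ("fa", grid.fa, np.float32),
        ("cost", grid.cost, np.float32),
    ):
        p = f"{prefix}_{name}.nii.gz"
        nib.save(nib.Nifti1Image(np.asarray(arr, dtype=dtype), affine), p)
        out[name] = p
    return out


def load_voxel_grid(prefix) -> VoxelGrid:
    prefix = Path(prefix)
    imgs = {}
    for name in ("labels", "fa", "cost"):
        p = Path(f"{prefix}_{name}.nii.gz")
        if not p.exists():
            raise FormatError(f"missing image file {p}")
        imgs[name] = nib.load(str(p))
    zooms = imgs["fa"].header.get_zooms()[:3]
    return VoxelGrid(
        labels=np.asarray(imgs["labels"].dataobj).astype(np.int32),
        fa=np.asarray(imgs["fa"].dataobj, dtype=float),
        cost=np.asarray(imgs["cost"].dataobj, dtype=float),
        voxel_size=tuple(float(z) for z in zooms),
    )


def write_manifest(path, config_dict: dict, seed: int, stage: str) -> None:
    """Reproducibility record: config hash, seed and library versions."""
    import conndiff

    blob = json.dumps(config_dict, sort_keys=True, default=str).encode()
    manifest = {
        "stage": stage,
        "seed": int(seed),
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "config": config_dict,
        "versions": {
            "conndiff": conndiff.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
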