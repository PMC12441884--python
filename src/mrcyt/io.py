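"""File I/O: NIfTI image stacks, protocol JSON, CSV tables and run manifests.

Synthetic lesions are written as 4-D NIfTI signal stacks (x, y, z,
acquisition) with a companion binary mask volume; voxels inside a lesion are
packed into the smallest near-cubic grid.  Every output directory gets a JSON
manifest listing each written file with its SHA-256 checksum, the
configuration and the seeds, so reruns are auditable.
"""

from __future__ import annotations

import hashlib
import json
import math
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import FormatError
from .protocol import Protocol
from .synthetic_data import LesionDataset

__all__ = [
    "pack_voxels",
    "write_lesion",
    "read_dwi_stack",
    "write_tables",
    "write_manifest",
    "cohort_manifest",
]

_AFFINE = np.diag([2.0, 2.0, 2.0, 1.0])  # 2 mm isotropic research voxels


def _package_version() -> str:
    try:
        return version("mrcyt")
    except PackageNotFoundError:  # pragma: no cover
        return "unknown"


def pack_voxels(n_voxels: int) -> tuple[tuple[int, int, int], np.ndarray]:
    """Smallest near-cubic grid holding n voxels; returns (shape, 3-D mask)."""
    nx = max(1, int(math.ceil(n_voxels ** (1.0 / 3.0))))
    ny = max(1, int(math.ceil(math.sqrt(n_voxels / nx))))
    nz = int(math.ceil(n_voxels / (nx * ny)))
    shape = (nx, ny, nz)
    mask = np.zeros(nx * ny * nz, dtype=bool)
    mask[:n_voxels] = True
    return shape, mask.reshape(shape)


def write_lesion(dataset: LesionDataset, outdir: Path) -> dict[str, Path]:
    """Write one lesion as dwi 4-D NIfTI + mask NIfTI; returns written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    n_vox, n_acq = dataset.signals.shape
    shape, mask = pack_voxels(n_vox)
    vol = np.zeros(shape + (n_acq,))
    vol[mask, :] = dataset.signals
    dwi_path = outdir / f"{dataset.lesion_id}_dwi.nii"
    mask_path = outdir / f"{dataset.lesion_id}_mask.nii"
    nib.save(nib.Nifti1Image(vol, _AFFINE), dwi_path)
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), _AFFINE), mask_path)
    return {"dwi": dwi_path, "mask": mask_path}


def read_dwi_stack(dwi_path, mask_path, protocol: Protocol):
    """Load a 4-D signal stack and return (signals, mask, n_dropped).

    ``signals`` is (n_masked_voxels, n_acquisitions) in protocol order with
    voxel order following C-order flattening of the mask grid (0-based, as
    stored).  A volume-count mismatch raises FormatError naming both counts;
    non-finite voxels are dropped from the mask and counted.
    """
    img = nib.load(str(dwi_path))
    data = np.array(img.dataobj, dtype=float)  # copy: never hold the file mmap
    if data.ndim != 4:
        raise FormatError(f"expected a 4-D stack, got shape {data.shape}")
    n_vols = data.shape[3]
    if n_vols != len(protocol):
        raise FormatError(
            f"stack has {n_vols} volumes but protocol lists "
            f"{len(protocol)} acquisitions"
        )
    mask_img = nib.load(str(mask_path))
    mask = np.asarray(mask_img.dataobj).astype(bool)
    if mask.shape != data.shape[:3]:
        raise FormatError(
            f"mask grid {mask.shape} != image grid {data.shape[:3]}"
        )
    signals = data[mask, :]
    finite = np.all(np.isfinite(signals), axis=1)
    n_dropped = int(np.sum(~finite))
    return signals[finite], mask, n_dropped


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_tables(outdir: Path, tables: dict[str, pd.DataFrame],
                 force: bool = False) -> list[Path]:
    """Write DataFrames as CSV with deterministic formatting; refuse to
    overwrite existing files unless ``force``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.items():
        path = outdir / name
        if path.exists() and not force:
            raise FileExistsError(f"{path} exists; pass force=True to overwrite")
        df.to_csv(path, index=False, float_format="%.10g")
        written.append(path)
    return written


def write_manifest(outdir: Path, config: dict, force: bool = False) -> Path:
    """JSON manifest of every file in ``outdir`` with checksum + run config."""
    outdir = Path(outdir)
    path = outdir / "manifest.json"
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass force=True to overwrite")
    files = sorted(
        p for p in outdir.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "package_version": _package_version(),
        "config": config,
        "files": [
            {"path": str(p.relative_to(outdir)), "sha256": _sha256(p)}
            for p in files
        ],
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return path


def cohort_manifest(cohort: list[LesionDataset]) -> pd.DataFrame:
    """Cohort table: one row per lesion with labels, seed and true parameter means."""
    rows = []
    for ds in cohort:
        row: dict = {"lesion_id": ds.lesion_id, "subtype": ds.subtype}
        row.update({k: int(v) for k, v in ds.labels.items()})
        row["seed"] = ds.seed
        for col in ds.true_params.columns:
            row[f"true_{col.lower()}"] = float(ds.true_params[col].mean())
        rows.append(row)
    return pd.DataFrame(rows)
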