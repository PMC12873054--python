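"""NIfTI / TSV / JSON plumbing between the pipeline and the filesystem.

Study directory layout (written by ``renalperf simulate``, read by
``renalperf fit``)::

    study/
      manifest.json          # frame duration, animal ids/groups, file paths
      truth.tsv              # generating parameters (phantom studies only)
      <animal_id>/
        series.nii.gz        # 4D dynamic series
        masks.nii.gz         # labeled integer volume
        labels.json          # {"1": "aorta", ...}

The frame duration recorded in the manifest overrides the NIfTI TR.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .kinetic import TimeGrid
from .pipeline import DynamicSeries, ParameterMap, ROIMask
from .simulate import PhantomStudy

__all__ = [
    "save_study",
    "load_manifest",
    "load_series",
    "load_masks",
    "save_parameter_map",
    "write_table",
    "read_summary_table",
]

_MASK_LABEL_ORDER = ("aorta", "transplant", "left_native", "right_native")


def _affine(voxel_size: tuple[float, float, float]) -> np.ndarray:
    return np.diag([*voxel_size, 1.0])


def save_series(series: DynamicSeries, path: Path) -> None:
    img = nib.Nifti1Image(series.voxels.astype(np.float32), _affine(series.voxel_size))
    img.header.set_zooms((*series.voxel_size, series.grid.dt))
    nib.save(img, str(path))


def load_series(path: Path, dt: float, t0: float = 0.0) -> DynamicSeries:
    """Load a 4D NIfTI series; ``dt`` (seconds per frame) is authoritative."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"series file not found: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path} is not a 4-D series (shape {data.shape})")
    zooms = img.header.get_zooms()
    grid = TimeGrid(n_frames=data.shape[3], dt=dt, t0=t0)
    return DynamicSeries(data, grid, voxel_size=tuple(float(z) for z in zooms[:3]))


def save_masks(masks: dict[str, ROIMask], path: Path, labels_path: Path) -> None:
    labels = [lab for lab in _MASK_LABEL_ORDER if lab in masks]
    labels += [lab for lab in masks if lab not in labels]
    first = next(iter(masks.values()))
    vol = np.zeros(first.mask.shape, dtype=np.int16)
    for value, lab in enumerate(labels, start=1):
        vol[masks[lab].mask] = value
    img = nib.Nifti1Image(vol, np.eye(4))
    nib.save(img, str(path))
    labels_path.write_text(
        json.dumps({str(v): lab for v, lab in enumerate(labels, start=1)}, indent=2)
    )


def load_masks(path: Path, labels_path: Path) -> dict[str, ROIMask]:
    path, labels_path = Path(path), Path(labels_path)
    for p in (path, labels_path):
        if not p.exists():
            raise FileNotFoundError(f"mask file not found: {p}")
    vol = np.asarray(nib.load(str(path)).dataobj)
    label_map = json.loads(labels_path.read_text())
    return {
        lab: ROIMask(lab, vol == int(value)) for value, lab in label_map.items()
    }


def save_study(study: PhantomStudy, out_dir: Path) -> Path:
    """Write a phantom study as a ready-to-analyze directory; returns the
    manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for animal in study.animals:
        adir = out_dir / animal.animal_id
        adir.mkdir(exist_ok=True)
        save_series(animal.series, adir / "series.nii.gz")
        save_masks(animal.masks, adir / "masks.nii.gz", adir / "labels.json")
        entries.append(
            {
                "animal_id": animal.animal_id,
                "group": animal.group,
                "series": f"{animal.animal_id}/series.nii.gz",
                "masks": f"{animal.animal_id}/masks.nii.gz",
                "labels": f"{animal.animal_id}/labels.json",
            }
        )
    write_table(study.truth_table, out_dir / "truth.tsv")
    manifest = {
        "frame_duration_s": study.config.grid.dt,
        "n_frames": study.config.grid.n_frames,
        "seed": study.config.seed,
        "animals": entries,
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest_path


def load_manifest(path: Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    manifest = json.loads(path.read_text())
    for key in ("frame_duration_s", "animals"):
        if key not in manifest:
            raise ValueError(f"manifest {path} lacks required field {key!r}")
    root = path.parent
    for entry in manifest["animals"]:
        for key in ("series", "masks", "labels"):
            ref = root / entry[key]
            if not ref.exists():
                raise FileNotFoundError(
                    f"manifest entry {entry.get('animal_id')!r} references a "
                    f"missing file: {ref}"
                )
    ids = [e["animal_id"] for e in manifest["animals"]]
    if len(ids) != len(set(ids)):
        raise ValueError("animal ids in manifest are not unique")
    manifest["_root"] = str(root)
    return manifest


def save_parameter_map(pmap: ParameterMap, out_dir: Path, prefix: str) -> None:
    out_dir = Path(out_dir)
    for name, data in (
        ("ktrans", pmap.ktrans_map),
        ("vp", pmap.vp_map),
        ("flags", pmap.flags),
    ):
        arr = data.astype(np.float32) if data.dtype != np.uint8 else data
        nib.save(
            nib.Nifti1Image(arr, np.eye(4)),
            str(out_dir / f"{prefix}_{name}.nii.gz"),
        )


def write_table(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_summary_table(path: Path) -> pd.DataFrame:
    """Read and validate a per-animal ROI summary TSV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"summary table not found: {path}")
    df = pd.read_csv(path, sep="\t")
    required = ("animal_id", "group", "roi_label", "median_ktrans", "median_vp")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"summary table {path} lacks columns: {missing}")
    for col in ("median_ktrans", "median_vp"):
        values = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[values.isna() & df[col].notna()]
        if len(bad):
            raise ValueError(
                f"summary table {path}: non-numeric value in column {col!r} "
                f"at row {int(bad[0]) + 2} (1-based, counting the header)"
            )
        df[col] = values
    return df
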