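"""File formats: NIfTI volumes, the TSV subject table, YAML configuration."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .cohort import ICNTemplateSet, Scan4D, SubjectRecord, MHE, NMHE

__all__ = [
    "SUBJECT_TABLE_COLUMNS",
    "GridMismatchError",
    "RunConfig",
    "save_templates",
    "load_templates",
    "save_scan",
    "load_scan",
    "save_subject_table",
    "load_subject_table",
    "save_zmaps",
]

SUBJECT_TABLE_COLUMNS = [
    "subject_id",
    "group",
    "tmt_a",
    "tmt_b",
    "dst",
    "bdt",
    "child_pugh",
    "age",
    "gender",
    "education",
    "movement",
]


class GridMismatchError(ValueError):
    """Volumes in one run do not share a common grid."""


def _affine(voxel_size_mm=(3.0, 3.0, 3.0)) -> np.ndarray:
    return np.diag(list(voxel_size_mm) + [1.0])


def save_templates(templates: ICNTemplateSet, directory: Path) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    aff = _affine(templates.voxel_size_mm)
    for name, vol in zip(templates.names, templates.maps):
        p = directory / f"{name}.nii.gz"
        nib.save(nib.Nifti1Image(vol.astype(np.float32), aff), p)
        paths.append(p)
    return paths


def load_templates(directory: Path) -> ICNTemplateSet:
    directory = Path(directory)
    paths = sorted(directory.glob("*.nii.gz")) + sorted(directory.glob("*.nii"))
    if not paths:
        raise FileNotFoundError(f"no NIfTI templates under {directory}")
    names, maps, zooms = [], [], set()
    for p in paths:
        img = nib.load(p)
        vol = np.asarray(img.dataobj, dtype=float)
        if vol.ndim != 3:
            raise GridMismatchError(f"{p.name} is not a 3-D volume")
        names.append(p.name.removesuffix(".nii.gz").removesuffix(".nii"))
        maps.append(vol)
        zooms.add(tuple(round(z, 6) for z in img.header.get_zooms()[:3]))
    shapes = {m.shape for m in maps}
    if len(shapes) != 1:
        raise GridMismatchError(f"templates on differing grids: {sorted(shapes)}")
    voxel = tuple(zooms.pop()) if len(zooms) == 1 else (3.0, 3.0, 3.0)
    return ICNTemplateSet(names=names, maps=np.stack(maps), voxel_size_mm=voxel)


def save_scan(scan: Scan4D, path: Path, voxel_size_mm=(3.0, 3.0, 3.0)) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(scan.data.astype(np.float32), _affine(voxel_size_mm))
    img.header.set_zooms(tuple(voxel_size_mm) + (scan.tr_seconds,))
    nib.save(img, path)
    return path


def load_scan(path: Path) -> Scan4D:
    img = nib.load(Path(path))
    data = np.asarray(img.dataobj, dtype=np.float32)
    if data.ndim != 4:
        raise GridMismatchError(f"{path} is not a 4-D volume")
    if not np.isfinite(data).all():
        raise ValueError(f"{path} contains non-finite values")
    zooms = img.header.get_zooms()
    tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 2.5
    return Scan4D(data=data, tr_seconds=tr)


def save_subject_table(records: list[SubjectRecord], path: Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame([r.__dict__ for r in records])[SUBJECT_TABLE_COLUMNS]
    df.to_csv(path, sep="\t", index=False)
    return path


def load_subject_table(path: Path) -> list[SubjectRecord]:
    df = pd.read_csv(Path(path), sep="\t")
    missing = set(SUBJECT_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"subject table missing columns: {sorted(missing)}")
    if df[SUBJECT_TABLE_COLUMNS].isna().any().any():
        raise ValueError("subject table contains missing values")
    records = []
    for row in df.to_dict("records"):
        group = str(row["group"]).upper()
        if group not in (MHE, NMHE):
            raise ValueError(f"unknown group label {row['group']!r}")
        row["group"] = group
        records.append(SubjectRecord(**{k: row[k] for k in SUBJECT_TABLE_COLUMNS}))
    return records


def save_zmaps(
    maps: np.ndarray, names: list[str], subject_id: str, directory: Path,
    voxel_size_mm=(3.0, 3.0, 3.0),
) -> list[Path]:
    """One z-map NIfTI per network, named {subject}_{icn}_z.nii.gz."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = []
    for name, vol in zip(names, maps):
        p = directory / f"{subject_id}_{name}_z.nii.gz"
        nib.save(nib.Nifti1Image(vol.astype(np.float32), _affine(voxel_size_mm)), p)
        out.append(p)
    return out


@dataclass
class RunConfig:
    """Configuration for a full pipeline run."""

    output_dir: str = "icnmhe_run"
    templates_dir: str | None = None  # None -> simulate
    scans_dir: str | None = None
    subject_table: str | None = None
    thresholds: list[float] = field(
        default_factory=lambda: [1.0, 1.25, 1.5, 1.75, 2.0, 2.25, 2.5, 2.75, 3.0]
    )
    gamma: dict = field(default_factory=dict)  # GammaParams overrides
    classifiers: list[str] = field(default_factory=lambda: ["SVM", "MLP", "TREE"])
    cv_folds: int = 10
    seed: int = 0
    acc_cut: float = 85.0
    p_cut: float = 70.0
    bonferroni_m: int = 3
    covariates: list[str] = field(
        default_factory=lambda: ["movement", "age", "gender", "education"]
    )
    simulate: dict = field(default_factory=dict)  # SimulationConfig overrides

    @classmethod
    def from_yaml(cls, path: Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=False)
        return path
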