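"""Spatial data model and NIfTI / manifest I/O.

Everything downstream (simulation, preprocessing, amplitude maps, statistics)
shares the small set of containers defined here: a :class:`VolumeGrid` tying a
voxel lattice to millimetre (MNI-style) coordinates through a NIfTI affine, a
:class:`BoldRun` holding one subject's 4D time series, a boolean
:class:`BrainMask`, and the cohort manifest types.

Conventions
-----------
* Voxel indices are 0-based and map to voxel *centers* in mm through the
  affine, following the NIfTI standard.
* Volumes are stored and written as NIfTI-1 (``.nii`` / ``.nii.gz``).
* Manifests are tab-separated UTF-8 tables with a mandatory header row and
  ``.`` for missing values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "VolumeGrid",
    "BoldRun",
    "BrainMask",
    "MotionSummary",
    "SubjectRecord",
    "CohortManifest",
    "read_volume",
    "write_volume",
    "read_manifest",
    "write_manifest",
    "MANIFEST_COLUMNS",
]

GROUP_LABELS = ("patient", "control")


@dataclass(frozen=True, eq=False)
class VolumeGrid:
    """A 3D voxel lattice with its voxel-to-mm affine.

    Parameters
    ----------
    dims : tuple of int
        Number of voxels along each axis.
    voxel_size_mm : tuple of float
        Edge length of a voxel along each axis, in mm.
    affine : ndarray, shape (4, 4)
        Maps homogeneous 0-based voxel indices to mm coordinates. The upper
        3x3 block's column norms must equal ``voxel_size_mm``.
    """

    dims: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float]
    affine: np.ndarray

    def __post_init__(self) -> None:
        dims = tuple(int(d) for d in self.dims)
        vs = tuple(float(v) for v in self.voxel_size_mm)
        object.__setattr__(self, "dims", dims)
        object.__setattr__(self, "voxel_size_mm", vs)
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {aff.shape}")
        object.__setattr__(self, "affine", aff)
        if len(dims) != 3 or any(d <= 0 for d in dims):
            raise ValueError(f"dims must be 3 positive integers, got {dims}")
        if any(v <= 0 for v in vs):
            raise ValueError(f"voxel sizes must be positive, got {vs}")
        col_norms = np.linalg.norm(aff[:3, :3], axis=0)
        if not np.allclose(col_norms, vs, atol=1e-6):
            raise ValueError(
                f"affine column norms {col_norms} do not match voxel sizes {vs}"
            )
        if abs(np.linalg.det(aff)) < 1e-12:
            raise ValueError("affine is singular")

    @classmethod
    def default(
        cls,
        dims: Sequence[int],
        voxel_size_mm: Sequence[float] = (3.0, 3.0, 3.0),
    ) -> "VolumeGrid":
        """RAS-aligned grid with the origin at the volume center."""
        dims = tuple(int(d) for d in dims)
        vs = tuple(float(v) for v in voxel_size_mm)
        aff = np.diag([*vs, 1.0])
        aff[:3, 3] = [-(d - 1) / 2.0 * v for d, v in zip(dims, vs)]
        return cls(dims, vs, aff)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))

    def voxel_to_mm(self, ijk: np.ndarray) -> np.ndarray:
        """Map 0-based voxel indices (..., 3) to mm coordinates (..., 3)."""
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def mm_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def coordinate_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """mm coordinates of every voxel center, one 3D array per axis."""
        idx = np.indices(self.dims, dtype=float)
        ijk = np.stack(idx, axis=-1)
        xyz = self.voxel_to_mm(ijk)
        return xyz[..., 0], xyz[..., 1], xyz[..., 2]

    def matches(self, other: "VolumeGrid", atol: float = 1e-4) -> bool:
        return self.dims == other.dims and np.allclose(
            self.affine, other.affine, atol=atol
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VolumeGrid):
            return NotImplemented
        return self.dims == other.dims and np.array_equal(self.affine, other.affine)

    def __hash__(self) -> int:
        return hash((self.dims, self.affine.tobytes()))


@dataclass
class BoldRun:
    """One subject's 4D BOLD time series on a common grid."""

    grid: VolumeGrid
    data: np.ndarray  # (x, y, z, t)
    tr_s: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"BOLD data must be 4D, got ndim={self.data.ndim}")
        if self.data.shape[:3] != self.grid.dims:
            raise ValueError(
                f"data shape {self.data.shape[:3]} does not match grid {self.grid.dims}"
            )
        if self.data.shape[3] < 2:
            raise ValueError("a BOLD run needs at least 2 time points")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("BOLD data contains non-finite values")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def nyquist_hz(self) -> float:
        return 1.0 / (2.0 * self.tr_s)


@dataclass
class BrainMask:
    """Boolean analysis mask on a grid."""

    grid: VolumeGrid
    include: np.ndarray

    def __post_init__(self) -> None:
        self.include = np.asarray(self.include).astype(bool)
        if self.include.shape != self.grid.dims:
            raise ValueError(
                f"mask shape {self.include.shape} does not match grid {self.grid.dims}"
            )

    @property
    def n_voxels(self) -> int:
        return int(self.include.sum())

    def require_nonempty(self) -> "BrainMask":
        if self.n_voxels < 1:
            raise ValueError("mask is empty; statistics need at least 1 voxel")
        return self


@dataclass(frozen=True)
class MotionSummary:
    """Per-axis maxima of the realignment parameters, as screened."""

    max_translation_mm: tuple[float, float, float]
    max_rotation_deg: tuple[float, float, float]

    def __post_init__(self) -> None:
        t = tuple(float(v) for v in self.max_translation_mm)
        r = tuple(float(v) for v in self.max_rotation_deg)
        object.__setattr__(self, "max_translation_mm", t)
        object.__setattr__(self, "max_rotation_deg", r)
        vals = t + r
        if len(t) != 3 or len(r) != 3:
            raise ValueError("motion summary needs 3 translations and 3 rotations")
        if not all(np.isfinite(v) and v >= 0 for v in vals):
            raise ValueError(f"motion entries must be finite and >= 0, got {vals}")


@dataclass
class SubjectRecord:
    subject_id: str
    group: str  # 'patient' | 'control'
    age_y: float
    sex: str  # 'male' | 'female'
    education_y: float
    handedness: str  # 'right' | 'left'
    hrsd_total: float
    hama_total: float = float("nan")  # patients only
    illness_duration_months: float = float("nan")  # patients only
    motion: MotionSummary = field(
        default_factory=lambda: MotionSummary((0, 0, 0), (0, 0, 0))
    )
    bold_path: str = ""
    gm_path: str = ""

    def __post_init__(self) -> None:
        if self.group not in GROUP_LABELS:
            raise ValueError(
                f"unknown group label {self.group!r} for subject {self.subject_id!r}"
            )
        if self.hrsd_total < 0:
            raise ValueError(f"hrsd_total must be >= 0 for {self.subject_id!r}")
        if self.age_y < 0:
            raise ValueError(f"age must be >= 0 for {self.subject_id!r}")
        if np.isfinite(self.illness_duration_months) and self.illness_duration_months < 0:
            raise ValueError(f"illness duration must be >= 0 for {self.subject_id!r}")


MANIFEST_COLUMNS = [
    "subject_id",
    "group",
    "age_y",
    "sex",
    "education_y",
    "handedness",
    "hrsd_total",
    "hama_total",
    "illness_duration_months",
    "max_trans_x_mm",
    "max_trans_y_mm",
    "max_trans_z_mm",
    "max_rot_x_deg",
    "max_rot_y_deg",
    "max_rot_z_deg",
    "bold_path",
    "gm_path",
]


@dataclass
class CohortManifest:
    records: list[SubjectRecord]

    def __post_init__(self) -> None:
        ids = [r.subject_id for r in self.records]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate subject ids in manifest: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.records)

    def group_counts(self) -> dict[str, int]:
        counts = {g: 0 for g in GROUP_LABELS}
        for r in self.records:
            counts[r.group] += 1
        return counts

    def patients(self) -> list[SubjectRecord]:
        return [r for r in self.records if r.group == "patient"]

    def controls(self) -> list[SubjectRecord]:
        return [r for r in self.records if r.group == "control"]

    def require_both_groups(self) -> "CohortManifest":
        counts = self.group_counts()
        missing = [g for g, n in counts.items() if n < 1]
        if missing:
            raise ValueError(f"manifest has no subjects in group(s): {missing}")
        return self

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "subject_id": r.subject_id,
                    "group": r.group,
                    "age_y": r.age_y,
                    "sex": r.sex,
                    "education_y": r.education_y,
                    "handedness": r.handedness,
                    "hrsd_total": r.hrsd_total,
                    "hama_total": r.hama_total,
                    "illness_duration_months": r.illness_duration_months,
                    "max_trans_x_mm": r.motion.max_translation_mm[0],
                    "max_trans_y_mm": r.motion.max_translation_mm[1],
                    "max_trans_z_mm": r.motion.max_translation_mm[2],
                    "max_rot_x_deg": r.motion.max_rotation_deg[0],
                    "max_rot_y_deg": r.motion.max_rotation_deg[1],
                    "max_rot_z_deg": r.motion.max_rotation_deg[2],
                    "bold_path": r.bold_path,
                    "gm_path": r.gm_path,
                }
            )
        return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)


def _grid_from_img(img: nib.Nifti1Image) -> VolumeGrid:
    aff = np.asarray(img.affine, dtype=float)
    dims = tuple(int(d) for d in img.shape[:3])
    voxel_size = tuple(float(v) for v in np.linalg.norm(aff[:3, :3], axis=0))
    return VolumeGrid(dims, voxel_size, aff)


def read_volume(path: str | Path) -> tuple[VolumeGrid, np.ndarray]:
    """Read a 3D or 4D NIfTI-1 volume.

    Returns the grid populated from the header and the data array in voxel
    order consistent with the affine. Rejects non-3D/4D payloads and
    non-finite values with a diagnostic.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume not found: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several file-format errors
        raise ValueError(f"{path} is not a readable NIfTI volume: {exc}") from exc
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim not in (3, 4):
        raise ValueError(f"{path}: expected 3D or 4D payload, got ndim={data.ndim}")
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path}: volume contains non-finite values")
    return _grid_from_img(img), data


def write_volume(
    grid: VolumeGrid,
    data: np.ndarray,
    path: str | Path,
    tr_s: float | None = None,
) -> Path:
    """Write a 3D or 4D array as NIfTI-1; round-trips with :func:`read_volume`.

    Data is stored as float32 (round-trip identical to <= 1e-6 relative for
    typical map magnitudes). For 4D data, ``tr_s`` is stored in the header.
    """
    data = np.asarray(data)
    if data.ndim not in (3, 4):
        raise ValueError(f"data must be 3D or 4D, got ndim={data.ndim}")
    if tuple(data.shape[:3]) != grid.dims:
        raise ValueError(
            f"data shape {data.shape[:3]} does not match grid dims {grid.dims}"
        )
    img = nib.Nifti1Image(data.astype(np.float32), grid.affine)
    img.header.set_xyzt_units("mm", "sec")
    if data.ndim == 4 and tr_s is not None:
        zooms = list(img.header.get_zooms())
        zooms[3] = tr_s
        img.header.set_zooms(zooms)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.name.endswith(".nii.gz"):
        # gzip with mtime=0 so identical volumes are byte-identical on disk
        import gzip

        with open(path, "wb") as fh:
            with gzip.GzipFile(fileobj=fh, mode="wb", mtime=0) as gz:
                gz.write(img.to_bytes())
    else:
        nib.save(img, str(path))
    return path


def read_bold(path: str | Path, tr_s: float | None = None) -> BoldRun:
    """Read a 4D NIfTI as a :class:`BoldRun`; TR from header unless given."""
    grid, data = read_volume(path)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D BOLD run, got ndim={data.ndim}")
    if tr_s is None:
        img = nib.load(str(Path(path)))
        zooms = img.header.get_zooms()
        tr_s = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 0.0
    if tr_s <= 0:
        raise ValueError(f"{path}: no repetition time in header; pass tr_s explicitly")
    return BoldRun(grid, data, tr_s)


def _record_from_row(row: pd.Series, base_dir: Path) -> SubjectRecord:
    motion = MotionSummary(
        (row["max_trans_x_mm"], row["max_trans_y_mm"], row["max_trans_z_mm"]),
        (row["max_rot_x_deg"], row["max_rot_y_deg"], row["max_rot_z_deg"]),
    )

    def _path(col: str) -> str:
        v = row.get(col, "")
        if not isinstance(v, str) or v == "":
            return ""
        p = Path(v)
        return str(p if p.is_absolute() else base_dir / p)

    return SubjectRecord(
        subject_id=str(row["subject_id"]),
        group=str(row["group"]),
        age_y=float(row["age_y"]),
        sex=str(row["sex"]),
        education_y=float(row["education_y"]),
        handedness=str(row["handedness"]),
        hrsd_total=float(row["hrsd_total"]),
        hama_total=float(row["hama_total"]),
        illness_duration_months=float(row["illness_duration_months"]),
        motion=motion,
        bold_path=_path("bold_path"),
        gm_path=_path("gm_path"),
    )


def read_manifest(path: str | Path) -> CohortManifest:
    """Read a tab-separated cohort manifest.

    Relative ``bold_path`` / ``gm_path`` entries are resolved against the
    manifest's directory. Raises on duplicate ids, unknown group labels and
    missing required columns.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    try:
        df = pd.read_csv(path, sep="\t", na_values=["."], keep_default_na=True)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"manifest {path} is empty") from exc
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} is missing required columns: {missing}")
    if len(df) == 0:
        raise ValueError(f"manifest {path} has a header but no subject rows")
    records = []
    for i, row in df.iterrows():
        try:
            records.append(_record_from_row(row, path.parent))
        except ValueError as exc:
            raise ValueError(f"manifest {path}, row {i}: {exc}") from exc
    return CohortManifest(records)


def write_manifest(manifest: CohortManifest, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = manifest.to_dataframe()
    df.to_csv(path, sep="\t", index=False, na_rep=".", float_format="%.4g")
    return path
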