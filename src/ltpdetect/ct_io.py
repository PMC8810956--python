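"""Reading and writing CT volumes and lesion annotations.

Coordinate conventions used throughout the package:

* Voxel indices are 0-based ``(x, y, z)`` = (column, row, axial slice), and
  volume arrays are indexed ``voxels[x, y, z]``.
* Physical coordinates are RAS millimetres (right-anterior-superior, the
  native space of 3D Slicer fiducials).  DICOM geometry, which is LPS, is
  sign-converted on load.
* The affine maps voxel indices to RAS mm; axial slices ascend along the
  third grid axis.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom

__all__ = [
    "CTVolume",
    "LesionAnnotation",
    "read_dicom_series",
    "read_nifti",
    "write_nifti",
    "ras_to_voxel",
    "voxel_to_ras",
    "read_fiducials",
    "read_coordinate_table",
    "write_coordinate_table",
]

# RAS = diag(-1,-1,1) . LPS : flips the first two axes of DICOM geometry.
_LPS_TO_RAS = np.diag([-1.0, -1.0, 1.0])


@dataclass
class CTVolume:
    """A scalar CT volume in Hounsfield units with its geometry.

    Parameters
    ----------
    voxels : ndarray, shape (nx, ny, nz)
        HU values, rescale slope/intercept already applied.
    affine : ndarray, shape (4, 4)
        Voxel-to-RAS-mm affine.
    """

    voxels: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.voxels.ndim}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if np.any(self.spacing_mm <= 0):
            raise ValueError("voxel spacing must be strictly positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def spacing_mm(self) -> np.ndarray:
        """Per-axis voxel spacing in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def origin_mm(self) -> np.ndarray:
        """RAS position of voxel (0, 0, 0)."""
        return self.affine[:3, 3].copy()

    @property
    def orientation(self) -> np.ndarray:
        """Direction cosines: unit columns of the affine's 3x3 block."""
        return self.affine[:3, :3] / self.spacing_mm

    slice_axis: int = 2


@dataclass
class LesionAnnotation:
    """A lesion-center landmark tied to a case."""

    case_id: str
    p_ras_mm: tuple[float, float, float]
    p_voxel: tuple[int, int, int] | None = None

    def resolve(self, volume: CTVolume) -> "LesionAnnotation":
        """Return a copy with ``p_voxel`` derived from ``p_ras_mm``."""
        return LesionAnnotation(
            self.case_id, self.p_ras_mm, ras_to_voxel(self.p_ras_mm, volume)
        )


def voxel_to_ras(index, volume: CTVolume) -> np.ndarray:
    """Physical RAS-mm position of a voxel index under the volume affine."""
    idx = np.asarray(index, dtype=float)
    return volume.affine[:3, :3] @ idx + volume.affine[:3, 3]


def ras_to_voxel(p_ras_mm, volume: CTVolume) -> tuple[int, int, int]:
    """Nearest voxel index of an RAS-mm point; rejects out-of-extent points."""
    p = np.asarray(p_ras_mm, dtype=float)
    inv = np.linalg.inv(volume.affine)
    cont = inv[:3, :3] @ p + inv[:3, 3]
    idx = np.rint(cont).astype(int)
    shape = np.asarray(volume.shape)
    # half-voxel slack: points within the outermost voxel's extent are valid
    if np.any(cont < -0.5) or np.any(cont > shape - 0.5):
        bad = np.where((cont < -0.5) | (cont > shape - 0.5))[0][0]
        raise ValueError(
            f"point {tuple(p)} lies outside the volume extent along axis {bad} "
            f"(continuous index {cont[bad]:.2f}, size {shape[bad]})"
        )
    idx = np.clip(idx, 0, shape - 1)
    return int(idx[0]), int(idx[1]), int(idx[2])


# ---------------------------------------------------------------------------
# DICOM


def read_dicom_series(directory) -> CTVolume:
    """Read a single axial CT series from a directory of DICOM files.

    Slices are sorted by their spatial position along the slice normal (never
    by file name), and rescale slope/intercept are applied so voxel values
    are HU.  Mixed series, missing rescale tags and non-uniform slice
    spacing raise ``ValueError``.
    """
    directory = Path(directory)
    paths = sorted(p for p in directory.iterdir() if p.is_file())
    datasets = []
    for p in paths:
        try:
            ds = pydicom.dcmread(str(p))
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            datasets.append(ds)
    if not datasets:
        raise ValueError(f"no DICOM image files found in {directory}")

    uids = {ds.SeriesInstanceUID for ds in datasets}
    if len(uids) > 1:
        raise ValueError(
            f"directory {directory} holds {len(uids)} series; expected exactly one"
        )
    for ds in datasets:
        if "RescaleSlope" not in ds or "RescaleIntercept" not in ds:
            raise ValueError("missing RescaleSlope/RescaleIntercept; cannot form HU")

    ref = datasets[0]
    iop = np.asarray(ref.ImageOrientationPatient, dtype=float)
    row_dir, col_dir = iop[:3], iop[3:]
    normal = np.cross(row_dir, col_dir)
    datasets.sort(key=lambda ds: float(normal @ np.asarray(ds.ImagePositionPatient)))

    positions = np.array(
        [normal @ np.asarray(ds.ImagePositionPatient, dtype=float) for ds in datasets]
    )
    if len(datasets) > 1:
        gaps = np.diff(positions)
        if np.any(gaps <= 0):
            raise ValueError("duplicate or non-increasing slice positions")
        if np.ptp(gaps) > 0.01 * gaps.mean():
            raise ValueError(f"non-uniform slice spacing: gaps range {gaps.min():.3f}"
                             f"-{gaps.max():.3f} mm")
        dz = float(gaps.mean())
    else:
        dz = float(getattr(ref, "SliceThickness", 1.0))

    slices = []
    for ds in datasets:
        hu = ds.pixel_array.astype(np.float32) * float(ds.RescaleSlope) + float(
            ds.RescaleIntercept
        )
        slices.append(hu)
    # pixel_array is (row, col); internal order is (x=col, y=row, z=slice)
    voxels = np.stack([s.T for s in slices], axis=2)

    dr, dc = (float(v) for v in ref.PixelSpacing)  # (row, col) spacing
    ipp0 = np.asarray(datasets[0].ImagePositionPatient, dtype=float)
    lps = np.eye(4)
    lps[:3, 0] = row_dir * dc       # step along columns (x)
    lps[:3, 1] = col_dir * dr       # step along rows (y)
    lps[:3, 2] = normal * dz
    lps[:3, 3] = ipp0
    affine = lps.copy()
    affine[:3, :] = _LPS_TO_RAS @ lps[:3, :]

    axial = np.abs(affine[:3, 2]) / np.linalg.norm(affine[:3, 2])
    if axial[2] < 0.99:
        raise ValueError("non-axial acquisition; only axial series are supported")
    return CTVolume(voxels, affine)


# ---------------------------------------------------------------------------
# NIfTI


def read_nifti(path) -> CTVolume:
    """Read a 3D NIfTI volume (voxels assumed to be HU)."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D NIfTI image, got ndim={data.ndim}")
    return CTVolume(data.astype(np.float32), np.asarray(img.affine))


def write_nifti(volume: CTVolume, path) -> None:
    img = nib.Nifti1Image(np.asarray(volume.voxels, dtype=np.float32), volume.affine)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# 3D Slicer fiducials (FCSV) and plain coordinate tables


def read_fiducials(path_fcsv, case_id: str | None = None) -> list[LesionAnnotation]:
    """Parse a 3D Slicer FCSV fiducial file into lesion annotations.

    Coordinates are stored as RAS mm.  The header's coordinate-system flag is
    honoured: LPS files (``# CoordinateSystem = LPS`` or ``= 1``) are
    sign-converted to RAS.  Malformed rows raise with their line number.
    """
    path_fcsv = Path(path_fcsv)
    cid = case_id if case_id is not None else path_fcsv.stem
    coord_system = "RAS"
    annotations: list[LesionAnnotation] = []
    with open(path_fcsv) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.lower().startswith("coordinatesystem"):
                    value = body.split("=", 1)[1].strip()
                    if value in ("LPS", "1"):
                        coord_system = "LPS"
                    elif value in ("RAS", "0"):
                        coord_system = "RAS"
                    else:
                        raise ValueError(
                            f"{path_fcsv}:{lineno}: unknown coordinate system {value!r}"
                        )
                continue
            fields = line.split(",")
            if len(fields) < 4:
                raise ValueError(
                    f"{path_fcsv}:{lineno}: fiducial row has {len(fields)} fields, "
                    "expected at least id,x,y,z"
                )
            try:
                x, y, z = (float(v) for v in fields[1:4])
            except ValueError as exc:
                raise ValueError(f"{path_fcsv}:{lineno}: non-numeric coordinate") from exc
            if coord_system == "LPS":
                x, y = -x, -y
            annotations.append(LesionAnnotation(cid, (x, y, z)))
    return annotations


def write_coordinate_table(annotations, path) -> None:
    """Write lesion centers as a plain CSV of voxel indices."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["case_id", "x", "y", "z"])
        for ann in annotations:
            if ann.p_voxel is None:
                raise ValueError(f"annotation for {ann.case_id} has no voxel index")
            writer.writerow([ann.case_id, *ann.p_voxel])


def read_coordinate_table(path) -> list[LesionAnnotation]:
    """Read a plain CSV coordinate table (case_id,x,y,z voxel indices)."""
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            voxel = (int(row["x"]), int(row["y"]), int(row["z"]))
            out.append(LesionAnnotation(row["case_id"], (np.nan,) * 3, voxel))
    return out
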