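"""Rule-based 3D patch sampling and axial-plane augmentation.

Patches are 32×32 in-plane × 8 axial slices × 3 window channels.  Positive
patches are re-sampled in-plane around an annotated lesion center ``p`` so
that every footprint still contains ``p``; their slice stack is fixed to the
8 slices centered on ``p``'s slice (z−4 … z+3, center biased low).  Negative
patches come from two sources: lesion-bearing cases, sampled anywhere whose
center lies strictly outside an exclusion sphere of radius ``r`` voxels
around each lesion; and lesion-free control cases, sampled uniformly within
the body.

Patch arrays are channel-first ``(3, 8, 32, 32)`` = (channel, z, y, x).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np
from scipy import ndimage

from .windowing import MultiChannelVolume

__all__ = [
    "PATCH_SIZE",
    "PATCH_DEPTH",
    "Patch",
    "SamplingConfig",
    "extract_patch_at",
    "extract_positive_patches",
    "extract_negative_patches_lesion_case",
    "extract_negative_patches_control",
    "augment",
    "apply_axial_transform",
    "sample_cohort_patches",
    "PatchSet",
    "write_patch_archive",
    "read_patch_archive",
]

PATCH_SIZE = 32   # in-plane extent (x and y)
PATCH_DEPTH = 8   # axial slices
_HALF = PATCH_SIZE // 2        # 16
_Z_LO, _Z_HI = 4, 3            # stack spans z-4 .. z+3 (center biased low)


@dataclass
class Patch:
    """One labeled sample: ``data`` is uint8 (3, 8, 32, 32)."""

    data: np.ndarray
    center: tuple[int, int, int]
    label: int                   # 1 = positive (LTP), 0 = negative
    case_id: str
    patch_id: str
    augmented: bool = False


@dataclass
class SamplingConfig:
    """Sampling rates and geometry.

    ``patches_per_lesion`` positives per annotated lesion;
    ``negatives_per_case`` negatives per case (twice the per-lesion positive
    rate by default); ``exclusion_radius`` in voxels; in-plane jitter drawn
    uniformly from ``[-jitter_limit, jitter_limit]`` per axis.
    """

    patches_per_lesion: int = 20
    negatives_per_case: int = 40
    exclusion_radius: float = 15.0
    jitter_limit: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.exclusion_radius <= 0:
            raise ValueError("exclusion_radius must be positive")
        if not (0 <= self.jitter_limit <= _HALF - 1):
            raise ValueError(
                f"jitter_limit must be in [0, {_HALF - 1}] so the lesion center "
                "stays inside the patch footprint"
            )


def _check_z(p, shape, case_id):
    z = p[2]
    if z - _Z_LO < 0 or z + _Z_HI >= shape[2]:
        raise ValueError(
            f"case {case_id}: lesion at z={z} is too close to the axial boundary "
            f"for an {PATCH_DEPTH}-slice stack (volume has {shape[2]} slices); "
            "refusing to pad"
        )


def extract_patch_at(mcv: MultiChannelVolume, center, case_id="case",
                     label=0, patch_id="p0", augmented=False) -> Patch:
    """Cut the (3, 8, 32, 32) patch whose footprint is centered on ``center``.

    The in-plane footprint spans ``[c - 16, c + 16)`` per axis and the slice
    stack spans ``z-4 .. z+3``; the footprint must lie fully inside the
    volume (no padding).
    """
    cx, cy, cz = (int(v) for v in center)
    nx, ny, nz = mcv.shape
    x0, y0, z0 = cx - _HALF, cy - _HALF, cz - _Z_LO
    if x0 < 0 or y0 < 0 or z0 < 0 or x0 + PATCH_SIZE > nx or y0 + PATCH_SIZE > ny \
            or z0 + PATCH_DEPTH > nz:
        raise ValueError(
            f"case {case_id}: patch footprint at center {(cx, cy, cz)} exceeds "
            f"volume shape {mcv.shape}"
        )
    sub = mcv.channels[:, x0:x0 + PATCH_SIZE, y0:y0 + PATCH_SIZE, z0:z0 + PATCH_DEPTH]
    data = np.ascontiguousarray(sub.transpose(0, 3, 2, 1))  # (c, z, y, x)
    return Patch(data, (cx, cy, cz), int(label), case_id, patch_id, augmented)


def _valid_center_bounds(shape):
    # half-open valid-center intervals: in-plane c in [16, n-16) keeps the
    # footprint [c-16, c+16) inside with a symmetric margin; axially the
    # stack is biased low (z-4 .. z+3), so z ranges over [4, nz-3)
    nx, ny, nz = shape
    return (_HALF, nx - _HALF), (_HALF, ny - _HALF), (_Z_LO, nz - _Z_LO + 1)


def extract_positive_patches(
    mcv: MultiChannelVolume, p, cfg: SamplingConfig, case_id: str = "case",
    rng: np.random.Generator | None = None,
) -> list[Patch]:
    """Sample ``patches_per_lesion`` positives whose footprints contain ``p``.

    Jitter is in-plane only; all patches share the 8-slice stack centered on
    ``p``'s slice.  Lesions too close to the axial boundary raise.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    px, py, pz = (int(v) for v in p)
    nx, ny, _ = mcv.shape
    _check_z((px, py, pz), mcv.shape, case_id)
    (xlo, xhi), (ylo, yhi), _ = _valid_center_bounds(mcv.shape)
    patches = []
    for k in range(cfg.patches_per_lesion):
        for _attempt in range(1000):
            dx, dy = rng.integers(-cfg.jitter_limit, cfg.jitter_limit + 1, size=2)
            cx, cy = px + int(dx), py + int(dy)
            if xlo <= cx < xhi and ylo <= cy < yhi:
                break
        else:
            raise ValueError(
                f"case {case_id}: cannot place a positive patch around {p} "
                "inside the volume"
            )
        patches.append(
            extract_patch_at(mcv, (cx, cy, pz), case_id, label=1,
                             patch_id=f"{case_id}:pos:{px},{py},{pz}:{k}")
        )
    return patches


def _sample_negative_centers(shape, n, rng, exclude=None, radius=0.0, mask=None,
                             case_id="case"):
    (xlo, xhi), (ylo, yhi), (zlo, zhi) = _valid_center_bounds(shape)
    if xhi <= xlo or yhi <= ylo or zhi <= zlo:
        raise ValueError(f"case {case_id}: volume {shape} too small for patches")
    exclude = np.asarray(exclude, dtype=float).reshape(-1, 3) if exclude is not None \
        else np.empty((0, 3))
    centers = []
    attempts = 0
    while len(centers) < n:
        attempts += 1
        if attempts > 10000 * n:
            raise ValueError(
                f"case {case_id}: cannot sample {n} negative centers; the "
                "exclusion geometry leaves too little room"
            )
        c = np.array([rng.integers(xlo, xhi), rng.integers(ylo, yhi),
                      rng.integers(zlo, zhi)])
        if exclude.size and np.min(np.linalg.norm(exclude - c, axis=1)) <= radius:
            continue
        if mask is not None and not mask[tuple(c)]:
            continue
        centers.append(tuple(int(v) for v in c))
    return centers


def extract_negative_patches_lesion_case(
    mcv: MultiChannelVolume, p, cfg: SamplingConfig, case_id: str = "case",
    rng: np.random.Generator | None = None,
) -> list[Patch]:
    """Negatives from a lesion-bearing case, outside the exclusion sphere(s).

    ``p`` is one lesion center or an array of them; every sampled center's
    Euclidean voxel distance to each lesion strictly exceeds
    ``cfg.exclusion_radius``.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    centers = _sample_negative_centers(
        mcv.shape, cfg.negatives_per_case, rng,
        exclude=p, radius=cfg.exclusion_radius, case_id=case_id,
    )
    return [
        extract_patch_at(mcv, c, case_id, label=0, patch_id=f"{case_id}:neg:{k}")
        for k, c in enumerate(centers)
    ]


def extract_negative_patches_control(
    mcv: MultiChannelVolume, cfg: SamplingConfig, case_id: str = "case",
    body_mask: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> list[Patch]:
    """Random negatives from a lesion-free control case.

    ``body_mask`` (same shape as the volume, e.g. source HU > −500) restricts
    centers to the body; without it the whole valid interior is used.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    centers = _sample_negative_centers(
        mcv.shape, cfg.negatives_per_case, rng, mask=body_mask, case_id=case_id
    )
    return [
        extract_patch_at(mcv, c, case_id, label=0, patch_id=f"{case_id}:neg:{k}")
        for k, c in enumerate(centers)
    ]


def body_mask_from_hu(hu_volume, threshold: float = -500.0) -> np.ndarray:
    """Boolean body mask: voxels denser than ``threshold`` HU (excludes air)."""
    vox = hu_volume.voxels if hasattr(hu_volume, "voxels") else np.asarray(hu_volume)
    return vox > threshold


# ---------------------------------------------------------------------------
# axial-plane augmentation


def apply_axial_transform(
    patch: Patch,
    *,
    flip: bool = False,
    shift: tuple[float, float] = (0.0, 0.0),
    shear_deg: float = 0.0,
    zoom: float = 1.0,
    rotation_deg: float = 0.0,
) -> Patch:
    """Apply one in-plane transform identically to every slice and channel.

    The transform acts on the axial (x, y) plane about the patch center:
    horizontal flip (x → −x), translation ``shift`` = (tx, ty) pixels, shear
    along x, uniform zoom, and counter-clockwise rotation.  Shape and label
    are unchanged; the result is flagged augmented.
    """
    theta = np.deg2rad(rotation_deg)
    s = np.tan(np.deg2rad(shear_deg))
    if zoom <= 0:
        raise ValueError("zoom must be positive")
    # forward content map in (x, y): p' = R Z S Fl (p - c) + c + t
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    shear = np.array([[1.0, s], [0.0, 1.0]])
    fl = np.diag([-1.0, 1.0]) if flip else np.eye(2)
    fwd = rot @ (zoom * np.eye(2)) @ shear @ fl
    inv = np.linalg.inv(fwd)
    center = (PATCH_SIZE - 1) / 2.0
    t = np.asarray(shift, dtype=float)

    # scipy's affine_transform maps output coords to input coords; our plane
    # arrays are (y, x), so conjugate the (x, y) matrix with the axis swap
    swap = np.array([[0.0, 1.0], [1.0, 0.0]])
    m_yx = swap @ inv @ swap
    offset = swap @ (-inv @ (np.array([center, center]) + t) + np.array([center, center]))

    planes = patch.data.reshape(-1, PATCH_SIZE, PATCH_SIZE).astype(np.float64)
    out = np.empty_like(planes)
    for i, plane in enumerate(planes):
        out[i] = ndimage.affine_transform(
            plane, m_yx, offset=offset, order=1, mode="nearest"
        )
    data = np.clip(np.floor(out + 0.5), 0, 255).astype(np.uint8).reshape(patch.data.shape)
    return replace(patch, data=data, augmented=True)


def augment(patch: Patch, seed: int | np.random.Generator = 0) -> Patch:
    """Randomly flip / shift / shear / zoom / rotate a patch in-plane.

    Each of the five transforms is applied with probability ½ with magnitude
    drawn uniformly: shift ≤ 4 px per axis, shear ≤ 10°, zoom 0.9–1.1,
    rotation ≤ 15°.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    kwargs = dict(flip=False, shift=(0.0, 0.0), shear_deg=0.0, zoom=1.0,
                  rotation_deg=0.0)
    if rng.random() < 0.5:
        kwargs["flip"] = True
    if rng.random() < 0.5:
        kwargs["shift"] = tuple(rng.uniform(-4, 4, size=2))
    if rng.random() < 0.5:
        kwargs["shear_deg"] = float(rng.uniform(-10, 10))
    if rng.random() < 0.5:
        kwargs["zoom"] = float(rng.uniform(0.9, 1.1))
    if rng.random() < 0.5:
        kwargs["rotation_deg"] = float(rng.uniform(-15, 15))
    return apply_axial_transform(patch, **kwargs)


# ---------------------------------------------------------------------------
# cohort-level sampling


@dataclass
class PatchSet:
    """Arrays of patches with their labels, case ids and split names."""

    data: np.ndarray          # (n, 3, 8, 32, 32) uint8
    labels: np.ndarray        # (n,) int8
    case_ids: np.ndarray      # (n,) str
    splits: np.ndarray        # (n,) str
    centers: np.ndarray       # (n, 3) int
    patch_ids: np.ndarray     # (n,) str

    def subset(self, split: str) -> "PatchSet":
        m = self.splits == split
        return PatchSet(self.data[m], self.labels[m], self.case_ids[m],
                        self.splits[m], self.centers[m], self.patch_ids[m])

    def __len__(self) -> int:
        return len(self.labels)


def _as_patchset(patches, split_of) -> PatchSet:
    return PatchSet(
        data=np.stack([p.data for p in patches]),
        labels=np.array([p.label for p in patches], dtype=np.int8),
        case_ids=np.array([p.case_id for p in patches]),
        splits=np.array([split_of[p.case_id] for p in patches]),
        centers=np.array([p.center for p in patches], dtype=int),
        patch_ids=np.array([p.patch_id for p in patches]),
    )


def sample_cohort_patches(cases, split, cfg: SamplingConfig,
                          windows=None) -> PatchSet:
    """Window every case and apply the full sampling rule set.

    Per lesion-bearing (LTP) case: ``patches_per_lesion`` positives per
    lesion plus ``negatives_per_case`` exclusion-sphere negatives.  Per
    control case: ``negatives_per_case`` body-masked random negatives.
    Split membership is inherited from the case (never assigned per patch).
    """
    from .windowing import DEFAULT_WINDOWS, compose_channels

    windows = windows if windows is not None else DEFAULT_WINDOWS
    rng = np.random.default_rng(cfg.seed)
    patches: list[Patch] = []
    for case in cases:
        mcv = compose_channels(case.volume, windows)
        if case.lesion_centers:
            for p in case.lesion_centers:
                patches.extend(
                    extract_positive_patches(mcv, p, cfg, case.case_id, rng=rng)
                )
            patches.extend(
                extract_negative_patches_lesion_case(
                    mcv, np.array(case.lesion_centers), cfg, case.case_id, rng=rng
                )
            )
        else:
            mask = body_mask_from_hu(case.volume)
            patches.extend(
                extract_negative_patches_control(
                    mcv, cfg, case.case_id, body_mask=mask, rng=rng
                )
            )
    return _as_patchset(patches, split.assignment)


# ---------------------------------------------------------------------------
# archives (HDF5 + CSV index)

_ARCHIVE_VERSION = 1


def write_patch_archive(ps: PatchSet, path, csv_index=None) -> None:
    """Write a PatchSet as HDF5 (datasets: data, label, center, case_id,
    split, patch_id) with an optional CSV index of the metadata."""
    with h5py.File(path, "w") as fh:
        fh.attrs["version"] = _ARCHIVE_VERSION
        fh.attrs["layout"] = "data: (n, channel, z, y, x) uint8"
        fh.create_dataset("data", data=ps.data, compression="gzip")
        fh.create_dataset("label", data=ps.labels)
        fh.create_dataset("center", data=ps.centers)
        str_dt = h5py.string_dtype()
        fh.create_dataset("case_id", data=ps.case_ids.astype(object), dtype=str_dt)
        fh.create_dataset("split", data=ps.splits.astype(object), dtype=str_dt)
        fh.create_dataset("patch_id", data=ps.patch_ids.astype(object), dtype=str_dt)
    if csv_index is not None:
        import pandas as pd

        pd.DataFrame({
            "patch_id": ps.patch_ids, "case_id": ps.case_ids, "split": ps.splits,
            "label": ps.labels, "x": ps.centers[:, 0], "y": ps.centers[:, 1],
            "z": ps.centers[:, 2],
        }).to_csv(csv_index, index=False)


def read_patch_archive(path) -> PatchSet:
    with h5py.File(path, "r") as fh:
        return PatchSet(
            data=fh["data"][...],
            labels=fh["label"][...],
            case_ids=fh["case_id"].asstr()[...],
            splits=fh["split"].asstr()[...],
            centers=fh["center"][...],
            patch_ids=fh["patch_id"].asstr()[...],
        )
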