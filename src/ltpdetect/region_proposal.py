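"""Bounding-box region proposals from per-patch probabilities.

During sampling, every candidate patch's center coordinate is stored in a
dictionary keyed by patch id.  After prediction, patches whose probability
reaches the operating threshold are summarized as proposal records: case,
(x, y, z) center, probability, axial slice number, the 32×32 in-plane box
matching the patch footprint, and the z-range of the 8-slice stack.
Proposals can be rendered as annotated axial slices (prediction maps).

``grid_candidates`` adds an annotation-free screening mode — a regular 3D
grid of patch centers covering the volume interior — for applying a
trained classifier to a whole volume.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np

from .sampling import PATCH_DEPTH, PATCH_SIZE, Patch, extract_patch_at
from .windowing import MultiChannelVolume

__all__ = [
    "CandidateIndex",
    "ProposalRecord",
    "build_candidate_index",
    "propose_regions",
    "render_prediction_map",
    "grid_candidates",
    "write_proposals_csv",
]

_HALF = PATCH_SIZE // 2
_Z_LO, _Z_HI = 4, 3


@dataclass
class CandidateIndex:
    """Patch id → (case_id, (x, y, z) center), one entry per candidate."""

    entries: dict[str, tuple[str, tuple[int, int, int]]]

    def __len__(self) -> int:
        return len(self.entries)

    def center_of(self, patch_id: str) -> tuple[int, int, int]:
        return self.entries[patch_id][1]

    def case_of(self, patch_id: str) -> str:
        return self.entries[patch_id][0]


@dataclass
class ProposalRecord:
    """One above-threshold patch, localized in the source volume."""

    case_id: str
    center: tuple[int, int, int]
    probability: float
    slice_number: int
    box: tuple[int, int, int, int]          # (x0, y0, x1, y1), half-open
    neighbor_slices: tuple[int, int]        # inclusive z-range of the stack


def build_candidate_index(patches) -> CandidateIndex:
    """Index patches by id; duplicate ids are rejected."""
    entries: dict[str, tuple[str, tuple[int, int, int]]] = {}
    ids = patches.patch_ids if hasattr(patches, "patch_ids") else \
        [p.patch_id for p in patches]
    cases = patches.case_ids if hasattr(patches, "case_ids") else \
        [p.case_id for p in patches]
    centers = patches.centers if hasattr(patches, "centers") else \
        [p.center for p in patches]
    for pid, cid, c in zip(ids, cases, centers):
        if pid in entries:
            raise ValueError(f"duplicate patch id {pid!r}")
        entries[str(pid)] = (str(cid), tuple(int(v) for v in c))
    return CandidateIndex(entries)


def _box_of(center) -> tuple[int, int, int, int]:
    x, y, _ = center
    return (x - _HALF, y - _HALF, x + _HALF, y + _HALF)


def propose_regions(model, index: CandidateIndex, patches,
                    threshold: float) -> list[ProposalRecord]:
    """Score candidates and keep those with probability ≥ threshold.

    ``model`` is a fitted classifier results object (or anything with a
    ``predict_proba``).  Records carry the probability exactly as
    predicted and are sorted by descending probability.
    """
    ids = patches.patch_ids if hasattr(patches, "patch_ids") else \
        [p.patch_id for p in patches]
    missing = [pid for pid in ids if str(pid) not in index.entries]
    if missing:
        raise ValueError(f"patches missing from the candidate index: "
                         f"{missing[:5]}")
    probs = np.asarray(model.predict_proba(patches)).ravel()
    records = []
    for pid, prob in zip(ids, probs):
        if prob >= threshold:
            case_id, center = index.entries[str(pid)]
            records.append(ProposalRecord(
                case_id=case_id, center=center, probability=float(prob),
                slice_number=center[2], box=_box_of(center),
                neighbor_slices=(center[2] - _Z_LO, center[2] + _Z_HI),
            ))
    records.sort(key=lambda r: -r.probability)
    return records


def grid_candidates(mcv: MultiChannelVolume, stride_xy: int = 32,
                    stride_z: int = 8, case_id: str = "case"):
    """Regular grid of candidate patches covering the volume interior.

    Centers start at the smallest valid position and step by the stride;
    every footprint lies fully inside the volume.  Returns ``(patches,
    index)`` ready for :func:`propose_regions`.
    """
    if stride_xy < 1 or stride_z < 1:
        raise ValueError("strides must be >= 1")
    nx, ny, nz = mcv.shape
    if nx < PATCH_SIZE or ny < PATCH_SIZE or nz < PATCH_DEPTH:
        raise ValueError(f"volume {mcv.shape} smaller than one patch")
    if stride_xy > max(nx, ny) or stride_z > nz:
        raise ValueError(f"stride exceeds volume extent {mcv.shape}")
    # same valid-center intervals as the sampler: [16, n-16) in-plane,
    # [4, nz-3) axially (the stack is biased low)
    xs = np.arange(_HALF, nx - _HALF, stride_xy)
    ys = np.arange(_HALF, ny - _HALF, stride_xy)
    zs = np.arange(_Z_LO, nz - _Z_LO + 1, stride_z)
    patches: list[Patch] = []
    for z in zs:
        for y in ys:
            for x in xs:
                pid = f"{case_id}:grid:{x},{y},{z}"
                patches.append(
                    extract_patch_at(mcv, (x, y, z), case_id, label=0,
                                     patch_id=pid)
                )
    return patches, build_candidate_index(patches)


def render_prediction_map(mcv: MultiChannelVolume, proposals, out_dir=None,
                          include_neighbors: bool = True):
    """Render axial slices with proposal boxes, slice numbers, and
    probabilities drawn on the composed RGB image.

    Every slice inside a proposal's 8-slice stack is rendered when
    ``include_neighbors`` (the box is drawn on each, per its record).
    Out-of-bounds boxes are clipped for display only.  Returns the mapping
    z → matplotlib figure; figures are also written to ``out_dir`` as PNG
    when given.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    by_slice: dict[int, list[ProposalRecord]] = {}
    for rec in proposals:
        z0, z1 = (rec.neighbor_slices if include_neighbors
                  else (rec.slice_number, rec.slice_number))
        for z in range(max(0, z0), min(mcv.shape[2] - 1, z1) + 1):
            by_slice.setdefault(z, []).append(rec)

    figures: dict[int, "plt.Figure"] = {}
    for z in sorted(by_slice):
        rgb = mcv.channels[:, :, :, z]           # (3, nx, ny)
        img = np.transpose(rgb, (2, 1, 0))       # (ny, nx, 3) for imshow
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.imshow(img, origin="lower")
        for rec in by_slice[z]:
            x0, y0, x1, y1 = rec.box
            cx0, cy0 = max(0, x0), max(0, y0)
            cx1, cy1 = min(mcv.shape[0], x1), min(mcv.shape[1], y1)
            ax.add_patch(Rectangle((cx0, cy0), cx1 - cx0, cy1 - cy0,
                                   fill=False, edgecolor="red", lw=1.2))
            ax.text(cx0, cy1 + 1, f"p={rec.probability:.2f}",
                    color="red", fontsize=7)
        ax.set_title(f"slice {z}")
        ax.set_axis_off()
        figures[z] = fig
        if out_dir is not None:
            from pathlib import Path

            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            fig.savefig(out / f"slice_{z:03d}.png", dpi=120,
                        bbox_inches="tight")
            plt.close(fig)
    return figures


def lesion_hit_rate(proposals, lesions_by_case: dict) -> float:
    """Fraction of true lesions localized by at least one proposal.

    A lesion (x, y, z) counts as hit when some proposal of its case has
    ``slice_number == z`` and an in-plane box containing (x, y).
    """
    lesions = [(cid, tuple(c)) for cid, centers in lesions_by_case.items()
               for c in centers]
    if not lesions:
        raise ValueError("no lesions to evaluate")
    hits = 0
    for cid, (x, y, z) in lesions:
        for rec in proposals:
            if rec.case_id != cid or rec.slice_number != z:
                continue
            x0, y0, x1, y1 = rec.box
            if x0 <= x < x1 and y0 <= y < y1:
                hits += 1
                break
    return hits / len(lesions)


def write_proposals_csv(proposals, path) -> None:
    """Export proposals as CSV (0-based voxel coordinates)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["case_id", "x", "y", "z", "probability"])
        for rec in proposals:
            writer.writerow([rec.case_id, *rec.center,
                             f"{rec.probability:.6f}"])
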