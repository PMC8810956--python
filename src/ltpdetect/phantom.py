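"""Synthetic post-ablation arterial-phase CT phantoms.

Each phantom is a liver-like parenchyma block containing a hypodense
spherical ablation zone, optional arterially enhancing nodules seated on
the ablation-zone boundary (the imaging signature of local tumor
progression, LTP), bright tubular vessels as distractors, and additive
Gaussian HU noise.  Ground-truth lesion centers are recorded so every
downstream stage — windowing, patch sampling, training, evaluation,
region proposal — can be exercised without patient data.

Default HU values are chosen to satisfy the window-setting geometry used
by the classifier: the ablation zone is darker than parenchyma, lesions
fall inside the narrow tumor window (WL=120/WW=40), and vessels saturate
it.  They are not fitted to patient statistics.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .ct_io import CTVolume, LesionAnnotation, voxel_to_ras, write_nifti

__all__ = [
    "PhantomParams",
    "PhantomCase",
    "CohortSplit",
    "generate_case",
    "generate_cohort",
    "write_case",
    "write_cohort_manifest",
]

SPLIT_NAMES = ("train", "val", "test")


@dataclass
class PhantomParams:
    """Parameters of one synthetic case.

    HU defaults obey the contrast ordering
    ``ablation_hu < liver_hu_mean < lesion_hu <= vessel_hu``.
    """

    volume_shape: tuple[int, int, int] = (128, 128, 40)
    spacing_mm: tuple[float, float, float] = (0.7, 0.7, 3.0)
    liver_hu_mean: float = 80.0
    liver_hu_noise_sd: float = 10.0
    ablation_center: tuple[int, int, int] | None = None  # default: volume center
    ablation_radius_mm: float = 15.0
    ablation_hu: float = 40.0
    n_lesions: int = 1
    lesion_diameter_mm: float = 12.0
    lesion_hu: float = 120.0
    n_vessels: int = 3
    vessel_hu: float = 150.0
    vessel_radius_mm: float = 2.0
    lesion_jitter_mm: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.ablation_hu < self.liver_hu_mean < self.lesion_hu <= self.vessel_hu):
            raise ValueError(
                "HU contrast ordering violated: need "
                "ablation_hu < liver_hu_mean < lesion_hu <= vessel_hu, got "
                f"{self.ablation_hu}, {self.liver_hu_mean}, {self.lesion_hu}, "
                f"{self.vessel_hu}"
            )
        if self.n_lesions < 0 or self.n_vessels < 0:
            raise ValueError("structure counts must be non-negative")

    def resolved_center(self) -> np.ndarray:
        if self.ablation_center is not None:
            return np.asarray(self.ablation_center, dtype=int)
        return np.asarray(self.volume_shape, dtype=int) // 2


@dataclass
class PhantomCase:
    """A generated case: volume, ground-truth lesion centers, group label."""

    volume: CTVolume
    lesion_centers: list[tuple[int, int, int]]
    group_label: str  # "LTP" | "no-LTP"
    case_id: str
    params: PhantomParams | None = None

    def __post_init__(self) -> None:
        is_ltp = len(self.lesion_centers) > 0
        if (self.group_label == "LTP") != is_ltp:
            raise ValueError(
                f"group_label {self.group_label!r} inconsistent with "
                f"{len(self.lesion_centers)} lesion centers"
            )


@dataclass
class CohortSplit:
    """Case-level train/val/test assignment."""

    assignment: dict[str, str] = field(default_factory=dict)

    def cases(self, split: str) -> list[str]:
        return [cid for cid, s in self.assignment.items() if s == split]

    def __getitem__(self, case_id: str) -> str:
        return self.assignment[case_id]


# ---------------------------------------------------------------------------
# geometry helpers (all computed in physical mm on the voxel grid)


def _grid_mm(shape, spacing):
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def _paint_sphere(vol, grid, center_vox, radius_mm, spacing, value):
    c = np.asarray(center_vox, dtype=float) * np.asarray(spacing)
    d2 = sum((g - ci) ** 2 for g, ci in zip(grid, c))
    vol[d2 <= radius_mm**2] = value


def _paint_cylinder(vol, grid, point_mm, direction, radius_mm, value):
    """Set ``value`` inside an infinite cylinder through ``point_mm``."""
    d = np.asarray(direction, dtype=float)
    d /= np.linalg.norm(d)
    rel = [g - p for g, p in zip(grid, point_mm)]
    proj = sum(r * di for r, di in zip(rel, d))
    d2 = sum((r - proj * di) ** 2 for r, di in zip(rel, d))
    vol[d2 <= radius_mm**2] = value


def _check_fits(params: PhantomParams) -> None:
    shape = np.asarray(params.volume_shape)
    spacing = np.asarray(params.spacing_mm)
    center = params.resolved_center()
    reach_mm = params.ablation_radius_mm + params.lesion_diameter_mm / 2 + params.lesion_jitter_mm
    reach_vox = np.ceil(reach_mm / spacing).astype(int)
    if np.any(center - reach_vox < 0) or np.any(center + reach_vox >= shape):
        raise ValueError(
            f"ablation zone (+lesions) of reach {reach_mm:.1f} mm around "
            f"{tuple(center)} exceeds volume shape {tuple(shape)}"
        )


def generate_case(params: PhantomParams, case_id: str = "case") -> PhantomCase:
    """Generate one phantom case, deterministic for a fixed ``params.seed``.

    Structures are painted in the order liver → ablation → vessels →
    lesions, so a lesion-center voxel holds exactly ``lesion_hu`` before
    noise; Gaussian noise is added last.
    """
    _check_fits(params)
    rng = np.random.default_rng(params.seed)
    shape = tuple(params.volume_shape)
    spacing = np.asarray(params.spacing_mm, dtype=float)
    grid = _grid_mm(shape, spacing)
    extent_mm = (np.asarray(shape) - 1) * spacing

    vol = np.full(shape, params.liver_hu_mean, dtype=np.float32)
    center_vox = params.resolved_center()
    _paint_sphere(vol, grid, center_vox, params.ablation_radius_mm, spacing, params.ablation_hu)

    # vessels: straight bright tubes crossing the block, mostly along z with
    # a random tilt, kept away from the ablation zone center
    center_mm = center_vox * spacing
    for _ in range(params.n_vessels):
        for _attempt in range(50):
            point = rng.uniform(0.15, 0.85, size=3) * extent_mm
            margin = params.ablation_radius_mm + params.lesion_diameter_mm + params.vessel_radius_mm
            if np.linalg.norm((point - center_mm)[:2]) > margin:
                break
        else:
            raise ValueError("could not place a vessel clear of the ablation zone")
        tilt = rng.normal(scale=0.3, size=2)
        direction = np.array([tilt[0], tilt[1], 1.0])
        _paint_cylinder(vol, grid, point, direction, params.vessel_radius_mm, params.vessel_hu)

    # lesions: nodules seated on the ablation-sphere surface, +/- radial jitter
    lesion_centers: list[tuple[int, int, int]] = []
    lesion_r_mm = params.lesion_diameter_mm / 2.0
    for _ in range(params.n_lesions):
        for _attempt in range(200):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            radial = params.ablation_radius_mm + rng.uniform(
                -params.lesion_jitter_mm, params.lesion_jitter_mm
            )
            c_mm = center_mm + radial * u
            c_vox = np.rint(c_mm / spacing).astype(int)
            if np.all(c_vox >= 0) and np.all(c_vox < shape):
                break
        else:
            raise ValueError("could not place a lesion inside the volume")
        _paint_sphere(vol, grid, c_vox, lesion_r_mm, spacing, params.lesion_hu)
        lesion_centers.append(tuple(int(v) for v in c_vox))
    # repaint centers last so overlapping structures never overwrite a center
    for c in lesion_centers:
        vol[c] = params.lesion_hu

    if params.liver_hu_noise_sd > 0:
        vol += rng.normal(scale=params.liver_hu_noise_sd, size=shape).astype(np.float32)

    affine = np.diag([*spacing, 1.0])
    group = "LTP" if lesion_centers else "no-LTP"
    return PhantomCase(CTVolume(vol, affine), lesion_centers, group, case_id, params)


# ---------------------------------------------------------------------------
# cohorts


def _resolve_split_counts(n: int, split, what: str) -> list[int]:
    split = list(split)
    if len(split) != len(SPLIT_NAMES):
        raise ValueError(f"{what}: expected {len(SPLIT_NAMES)} splits, got {len(split)}")
    if all(isinstance(s, (int, np.integer)) for s in split):
        counts = [int(s) for s in split]
    else:
        if not np.isclose(sum(split), 1.0):
            raise ValueError(f"{what}: split fractions must sum to one, got {split}")
        counts = [int(np.floor(f * n)) for f in split]
        for i in np.argsort([f * n - c for f, c in zip(split, counts)])[::-1]:
            if sum(counts) == n:
                break
            counts[int(i)] += 1
    if sum(counts) != n:
        raise ValueError(f"{what}: split counts {counts} do not sum to {n}")
    if min(counts) < 0:
        raise ValueError(f"{what}: negative split count in {counts}")
    return counts


def _assign_lesion_constrained(
    lesions_per_case: list[int], case_counts: list[int], lesion_counts: list[int], rng
) -> list[int]:
    """Assign cases (given their lesion counts) to splits so that both the
    per-split case counts and per-split lesion totals are met exactly.

    Greedy: splits are filled in order of tightest lesion surplus, taking
    the largest remaining lesion counts first while keeping the remaining
    cases able to cover the remaining lesions.  Raises if infeasible.
    """
    n = len(lesions_per_case)
    if sum(case_counts) != n:
        raise ValueError("case split counts do not sum to the number of cases")
    if sum(lesion_counts) != sum(lesions_per_case):
        raise ValueError(
            f"lesion split counts {lesion_counts} do not sum to "
            f"{sum(lesions_per_case)} lesions"
        )
    order = rng.permutation(n)
    pool = sorted(order, key=lambda i: -lesions_per_case[i])
    assignment = [-1] * n
    # process splits by descending lesions-per-case demand
    split_order = sorted(
        range(len(case_counts)),
        key=lambda s: -(lesion_counts[s] / case_counts[s] if case_counts[s] else 0),
    )
    for s in split_order:
        need_cases, need_lesions = case_counts[s], lesion_counts[s]
        chosen = []
        for i in list(pool):
            if need_cases == 0:
                break
            # taking case i must leave the remaining lesion total reachable
            # by the need_cases-1 smallest .. largest remaining cases
            k = lesions_per_case[i]
            rest = sorted((lesions_per_case[j] for j in pool if j != i), reverse=True)
            lo = sum(sorted(rest)[: need_cases - 1])
            hi = sum(rest[: need_cases - 1])
            if lo <= need_lesions - k <= hi:
                chosen.append(i)
                pool.remove(i)
                need_cases -= 1
                need_lesions -= k
        if need_cases != 0 or need_lesions != 0:
            raise ValueError(
                f"cannot satisfy lesion split {lesion_counts} with the given "
                "per-case lesion counts"
            )
        for i in chosen:
            assignment[i] = s
    return assignment


def generate_cohort(
    n_ltp: int,
    n_noltp: int,
    lesions_per_case,
    split_fractions=(0.6, 0.2, 0.2),
    seed: int = 0,
    *,
    control_split=None,
    lesion_split_counts=None,
    base_params: PhantomParams | None = None,
) -> tuple[list[PhantomCase], CohortSplit]:
    """Generate a cohort of LTP and control phantoms with a case-level split.

    Parameters
    ----------
    lesions_per_case : int or sequence of int
        Lesion count for each of the ``n_ltp`` LTP cases (scalar = same for
        all).  Every LTP case must have at least one lesion.
    split_fractions : fractions or integer counts per (train, val, test)
        Applied to the LTP group; ``control_split`` (defaults to the same
        value) applies to the control group.
    lesion_split_counts : optional (train, val, test) lesion totals
        When given, case assignment is constrained so per-split lesion
        totals match exactly.
    """
    if n_ltp < 0 or n_noltp < 0:
        raise ValueError("cohort sizes must be non-negative")
    if np.isscalar(lesions_per_case):
        lesions_per_case = [int(lesions_per_case)] * n_ltp
    lesions_per_case = [int(v) for v in lesions_per_case]
    if len(lesions_per_case) != n_ltp:
        raise ValueError(
            f"lesions_per_case has {len(lesions_per_case)} entries for {n_ltp} LTP cases"
        )
    if n_ltp and min(lesions_per_case) < 1:
        raise ValueError("every LTP case needs at least one lesion")

    rng = np.random.default_rng(seed)
    base = base_params if base_params is not None else PhantomParams()

    ltp_counts = _resolve_split_counts(n_ltp, split_fractions, "LTP group")
    if control_split is None:
        # integer LTP counts are group-specific; reuse them as proportions
        split = list(split_fractions)
        if all(isinstance(s, (int, np.integer)) for s in split) and sum(split):
            control_split = [s / sum(split) for s in split]
        else:
            control_split = split
    ctrl_counts = _resolve_split_counts(n_noltp, control_split, "control group")

    if lesion_split_counts is not None:
        ltp_assign = _assign_lesion_constrained(
            lesions_per_case, ltp_counts, list(lesion_split_counts), rng
        )
    else:
        ltp_assign = rng.permutation(
            np.repeat(np.arange(len(SPLIT_NAMES)), ltp_counts)
        ).tolist()

    ctrl_assign = rng.permutation(
        np.repeat(np.arange(len(SPLIT_NAMES)), ctrl_counts)
    ).tolist()

    cases: list[PhantomCase] = []
    split = CohortSplit()
    for i in range(n_ltp):
        cid = f"ltp{i:03d}"
        params = replace(
            base, n_lesions=lesions_per_case[i], seed=int(rng.integers(2**31))
        )
        cases.append(generate_case(params, cid))
        split.assignment[cid] = SPLIT_NAMES[ltp_assign[i]]
    for i in range(n_noltp):
        cid = f"ctl{i:03d}"
        params = replace(base, n_lesions=0, seed=int(rng.integers(2**31)))
        cases.append(generate_case(params, cid))
        split.assignment[cid] = SPLIT_NAMES[ctrl_assign[i]]
    return cases, split


#: the published cohort composition this pipeline reproduces: 34 LTP
#: patients carrying 49 lesions (15 patients with two lesions), case split
#: 21/5/8 with lesion split 36/5/8, and 40 lesion-free controls split 27/5/8
REFERENCE_COHORT = dict(
    n_ltp=34,
    n_noltp=40,
    lesions_per_case=[2] * 15 + [1] * 19,
    split_fractions=(21, 5, 8),
    control_split=(27, 5, 8),
    lesion_split_counts=(36, 5, 8),
)


def reference_cohort(seed: int = 0, base_params: PhantomParams | None = None):
    """Generate a phantom cohort with the reference patient/lesion split.

    The defaults use a compact per-case volume so the whole 74-case cohort
    generates in seconds; pass ``base_params`` to override.
    """
    if base_params is None:
        base_params = PhantomParams(
            volume_shape=(72, 72, 24), ablation_radius_mm=8.0,
            lesion_diameter_mm=6.0, n_vessels=2,
        )
    return generate_cohort(seed=seed, base_params=base_params,
                           **REFERENCE_COHORT)


# ---------------------------------------------------------------------------
# export


def write_case(case: PhantomCase, out_dir) -> None:
    """Write a case as NIfTI + FCSV fiducials + voxel-index CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_nifti(case.volume, out_dir / f"{case.case_id}.nii.gz")
    with open(out_dir / f"{case.case_id}.fcsv", "w") as fh:
        fh.write("# Markups fiducial file version = 4.11\n")
        fh.write("# CoordinateSystem = RAS\n")
        fh.write("# columns = id,x,y,z,label\n")
        for k, c in enumerate(case.lesion_centers):
            ras = voxel_to_ras(c, case.volume)
            fh.write(f"F{k},{ras[0]:.3f},{ras[1]:.3f},{ras[2]:.3f},lesion{k}\n")
    with open(out_dir / f"{case.case_id}_centers.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["case_id", "x", "y", "z"])
        for c in case.lesion_centers:
            writer.writerow([case.case_id, *c])


def write_cohort_manifest(cases, split: CohortSplit, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["case_id", "group", "split"])
        for case in cases:
            writer.writerow([case.case_id, case.group_label, split[case.case_id]])


def annotations_of(case: PhantomCase) -> list[LesionAnnotation]:
    """Lesion annotations of a phantom case, in both RAS mm and voxel indices."""
    out = []
    for c in case.lesion_centers:
        ras = voxel_to_ras(c, case.volume)
        out.append(LesionAnnotation(case.case_id, tuple(ras), tuple(c)))
    return out
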