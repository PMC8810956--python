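"""Patch extraction rules, exclusion sphere, augmentation, archives."""

import numpy as np
import pytest

from ltpdetect.ct_io import CTVolume
from ltpdetect.phantom import generate_cohort
from ltpdetect.sampling import (
    Patch,
    SamplingConfig,
    apply_axial_transform,
    augment,
    body_mask_from_hu,
    extract_negative_patches_control,
    extract_negative_patches_lesion_case,
    extract_positive_patches,
    read_patch_archive,
    sample_cohort_patches,
    write_patch_archive,
)
from ltpdetect.windowing import compose_channels

from conftest import small_params


@pytest.fixture(scope="module")
def lesion_center(phantom_case):
    return phantom_case.lesion_centers[0]


def test_positive_patch_count_shape_and_containment(mcv, lesion_center):
    cfg = SamplingConfig(seed=1)
    patches = extract_positive_patches(mcv, lesion_center, cfg, "c0")
    assert len(patches) == cfg.patches_per_lesion == 20
    px, py, pz = lesion_center
    for p in patches:
        assert p.data.shape == (3, 8, 32, 32)
        assert p.data.dtype == np.uint8
        assert p.label == 1
        cx, cy, cz = p.center
        assert cz == pz                       # stack fixed on the lesion slice
        assert cx - 16 <= px < cx + 16        # footprint contains (x, y) of p
        assert cy - 16 <= py < cy + 16


def test_zero_jitter_patches_identical_and_centered(mcv, lesion_center):
    cfg = SamplingConfig(jitter_limit=0, seed=1)
    patches = extract_positive_patches(mcv, lesion_center, cfg, "c0")
    assert all(p.center == tuple(lesion_center) for p in patches)
    for p in patches[1:]:
        np.testing.assert_array_equal(p.data, patches[0].data)


def test_positive_patch_voxels_match_source(mcv, lesion_center):
    cfg = SamplingConfig(jitter_limit=0, seed=1)
    (p, *_) = extract_positive_patches(mcv, lesion_center, cfg, "c0")
    x, y, z = lesion_center
    # patch (c, z, y, x) index of the lesion center is (4, 16, 16)
    np.testing.assert_array_equal(
        p.data[:, 4, 16, 16], mcv.channels[:, x, y, z]
    )


def test_lesion_near_axial_boundary_errors_with_case_name(mcv):
    cfg = SamplingConfig(seed=1)
    with pytest.raises(ValueError, match="caseX"):
        extract_positive_patches(mcv, (48, 48, 1), cfg, "caseX")


def test_exclusion_sphere_strictly_respected(mcv, phantom_case):
    """Brute-force distance check over a large sample of negatives."""
    cfg = SamplingConfig(negatives_per_case=1000, seed=3)
    lesions = np.array(phantom_case.lesion_centers, dtype=float)
    patches = extract_negative_patches_lesion_case(
        mcv, lesions, cfg, "c0"
    )
    assert len(patches) == 1000
    dmin = min(
        np.linalg.norm(lesions - np.asarray(p.center, float), axis=1).min()
        for p in patches
    )
    assert dmin > cfg.exclusion_radius
    # centers at and just outside the radius behave per the rule
    assert all(p.label == 0 for p in patches)


def test_control_negatives_count_and_determinism(mcv):
    cfg = SamplingConfig(seed=5)
    a = extract_negative_patches_control(mcv, cfg, "ctl")
    b = extract_negative_patches_control(mcv, cfg, "ctl")
    assert len(a) == cfg.negatives_per_case == 40
    assert [p.center for p in a] == [p.center for p in b]


def test_control_negatives_respect_body_mask():
    hu = np.full((96, 96, 32), 80.0, np.float32)
    hu[48:, :, :] = -1000.0          # right half is air
    vol = CTVolume(hu, np.diag([0.7, 0.7, 3.0, 1.0]))
    mcv = compose_channels(vol)
    mask = body_mask_from_hu(vol)
    cfg = SamplingConfig(negatives_per_case=200, seed=2)
    patches = extract_negative_patches_control(mcv, cfg, "c", body_mask=mask)
    assert all(p.center[0] < 48 for p in patches)


def test_unsatisfiable_exclusion_geometry_reported(mcv):
    cfg = SamplingConfig(exclusion_radius=500.0, negatives_per_case=5, seed=0)
    with pytest.raises(ValueError, match="cannot sample"):
        extract_negative_patches_lesion_case(mcv, (48, 48, 16), cfg, "c0")


# ---------------------------------------------------------------------------
# augmentation


def _point_patch(y, x, value=255):
    data = np.zeros((3, 8, 32, 32), np.uint8)
    data[:, :, y, x] = value
    return Patch(data, (16, 16, 16), 1, "c", "p")


def test_flip_is_an_involution():
    p = _point_patch(3, 7)
    back = apply_axial_transform(apply_axial_transform(p, flip=True), flip=True)
    np.testing.assert_array_equal(back.data, p.data)
    once = apply_axial_transform(p, flip=True)
    assert once.data[0, 0, 3, 31 - 7] == 255


def test_rotation_90_moves_corner_as_derived():
    """CCW 90° about the in-plane center maps (x,y)=(0,0) to (31,0)."""
    p = _point_patch(0, 0)
    out = apply_axial_transform(p, rotation_deg=90.0)
    ys, xs = np.nonzero(out.data[0, 0])
    assert (ys.tolist(), xs.tolist()) == ([0], [31])
    # identically applied on every slice and channel
    for c in range(3):
        for z in range(8):
            np.testing.assert_array_equal(out.data[c, z], out.data[0, 0])


def test_augment_preserves_label_shape_and_flags():
    rng_patch = _point_patch(10, 12)
    for seed in range(6):
        out = augment(rng_patch, seed)
        assert out.data.shape == rng_patch.data.shape
        assert out.label == rng_patch.label
        assert out.case_id == rng_patch.case_id
        assert out.augmented
    # same seed reproduces the same transform
    a, b = augment(rng_patch, 3), augment(rng_patch, 3)
    np.testing.assert_array_equal(a.data, b.data)


# ---------------------------------------------------------------------------
# cohort-level counts and hygiene


@pytest.fixture(scope="module")
def small_cohort():
    cases, split = generate_cohort(
        4, 3, [2, 1, 1, 1], split_fractions=(2, 1, 1),
        control_split=(1, 1, 1), seed=21, base_params=small_params(),
    )
    return cases, split


def test_count_conservation_and_class_ratio(small_cohort):
    cases, split = small_cohort
    cfg = SamplingConfig(seed=8)
    ps = sample_cohort_patches(cases, split, cfg)
    n_lesions = sum(len(c.lesion_centers) for c in cases)
    n_ltp_cases = sum(c.group_label == "LTP" for c in cases)
    n_ctl_cases = len(cases) - n_ltp_cases
    assert int(ps.labels.sum()) == n_lesions * cfg.patches_per_lesion
    negatives = len(ps) - int(ps.labels.sum())
    assert negatives == (n_ltp_cases + n_ctl_cases) * cfg.negatives_per_case
    # per case, negatives are twice the per-lesion positive rate
    assert cfg.negatives_per_case == 2 * cfg.patches_per_lesion


def test_patches_never_cross_splits(small_cohort):
    cases, split = small_cohort
    ps = sample_cohort_patches(cases, split, SamplingConfig(seed=8))
    for cid, s in zip(ps.case_ids, ps.splits):
        assert split[cid] == s
    case_to_splits = {}
    for cid, s in zip(ps.case_ids, ps.splits):
        case_to_splits.setdefault(cid, set()).add(s)
    assert all(len(v) == 1 for v in case_to_splits.values())


def test_archive_round_trip(small_cohort, tmp_path):
    cases, split = small_cohort
    ps = sample_cohort_patches(cases[:2], split, SamplingConfig(seed=8))
    path = tmp_path / "patches.h5"
    write_patch_archive(ps, path, csv_index=tmp_path / "index.csv")
    back = read_patch_archive(path)
    np.testing.assert_array_equal(back.data, ps.data)
    np.testing.assert_array_equal(back.labels, ps.labels)
    assert back.case_ids.tolist() == ps.case_ids.tolist()
    assert back.splits.tolist() == ps.splits.tolist()
    assert (tmp_path / "index.csv").read_text().count("\n") == len(ps) + 1


def test_config_invariants():
    with pytest.raises(ValueError):
        SamplingConfig(exclusion_radius=0)
    with pytest.raises(ValueError):
        SamplingConfig(jitter_limit=16)
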