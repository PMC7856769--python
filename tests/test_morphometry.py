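import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from rootseg import morphometry
from rootseg.errors import FrameFitError, RootSeparationError
from rootseg.morphometry import fit_tooth_frame, measure_volumes, separate_roots
from rootseg.volume_io import LabelMap


def _frame_from_truth(truth, side="test", lab=None):
    lm = truth.landmarks(side)
    if lab is None:
        nh = truth.spec.grid_shape[1] // 2
        sl = slice(0, nh) if side == "test" else slice(nh, None)
        lab = LabelMap(
            np.ascontiguousarray(truth.labels.labels[:, sl, :]), dict(truth.labels.legend), truth.spec.voxel_size
        )
    return (
        fit_tooth_frame(
            lab,
            lm["cej_points"],
            {"mesial": lm["mesial_contact"], "distal": lm["distal_contact"]},
            palatal_hint=lm["palatal_hint"],
        ),
        lab,
        lm,
    )


class TestFrameFit:
    def test_aligned_phantom_gives_cej_plane_and_45_degree_contacts(self, default_truth):
        frame, _, lm = _frame_from_truth(default_truth)
        # CEJ plane normal is the occlusal axis of the grid
        assert np.allclose(np.abs(frame.occlusal_dir), [0, 0, 1], atol=1e-9)
        assert frame.occlusal_dir[2] > 0  # crown on +Z
        assert frame.origin[2] == pytest.approx(default_truth.spec.cej_height_um)
        angle = frame.contact_angle_deg(lm["mesial_contact"], lm["distal_contact"])
        assert angle == pytest.approx(45.0, abs=0.5)
        # anatomical axes match the phantom's conventions on the test side
        assert np.allclose(frame.mesial_dir, [1, 0, 0], atol=1e-9)
        assert np.allclose(frame.palatal_dir, [0, 1, 0], atol=1e-9)

    def test_rotated_landmarks_recover_the_rotation(self, default_truth):
        frame0, lab, lm = _frame_from_truth(default_truth)
        R = Rotation.from_euler("xyz", [3.0, -4.0, 10.0], degrees=True).as_matrix()
        pivot = frame0.origin

        def rot(p):
            return (np.atleast_2d(p) - pivot) @ R.T + pivot

        frame1 = fit_tooth_frame(
            lab,
            rot(lm["cej_points"]),
            {"mesial": rot(lm["mesial_contact"])[0], "distal": rot(lm["distal_contact"])[0]},
            palatal_hint=rot(lm["palatal_hint"])[0],
        )
        # the fitted axes must be the rotated originals
        for a0, a1 in [
            (frame0.mesial_dir, frame1.mesial_dir),
            (frame0.occlusal_dir, frame1.occlusal_dir),
        ]:
            ang = np.degrees(np.arccos(np.clip(np.dot(R @ a0, a1), -1, 1)))
            assert ang <= 0.5

    def test_collinear_cej_points_rejected(self, default_truth):
        _, lab, lm = _frame_from_truth(default_truth)
        pts = np.outer(np.linspace(0, 1, 5), [100.0, 0, 0]) + [200.0, 300.0, 400.0]
        with pytest.raises(FrameFitError, match="collinear"):
            fit_tooth_frame(lab, pts, {"mesial": lm["mesial_contact"], "distal": lm["distal_contact"]})

    def test_identical_contacts_rejected(self, default_truth):
        _, lab, lm = _frame_from_truth(default_truth)
        with pytest.raises(FrameFitError, match="distinct"):
            fit_tooth_frame(lab, lm["cej_points"], {"mesial": lm["mesial_contact"], "distal": lm["mesial_contact"]})


class TestSeparateRoots:
    def test_cut_depth_in_physical_units(self):
        # 30 voxels at 10.4 μm put the cutting plane 312 μm below the CEJ
        assert 30 * 10.4 == pytest.approx(312.0)

    def test_truth_labels_reproduce_truth_volumes(self, default_truth):
        """Separating roots from the merged molar recovers each named root
        within 2 % of the analytic ground truth."""
        frame, lab, _ = _frame_from_truth(default_truth)
        separated = separate_roots(lab, frame, cut_depth_voxels=30)
        morph = measure_volumes(separated)
        for role in ("root_mesial", "root_distal", "root_palatal"):
            truth_v = default_truth.true_root_volumes["test"][role]
            assert morph.volumes[role] == pytest.approx(truth_v, rel=0.02)

    def test_partition_preserves_molar_voxel_count(self, default_truth):
        frame, lab, _ = _frame_from_truth(default_truth)
        before = int(lab.molar_mask().sum())
        separated = separate_roots(lab, frame, cut_depth_voxels=30)
        after = int(separated.molar_mask().sum())
        assert after == before

    def test_naming_stable_under_small_frame_tilt(self, default_truth):
        frame0, lab, lm = _frame_from_truth(default_truth)
        R = Rotation.from_euler("y", 2.0, degrees=True).as_matrix()
        pivot = frame0.origin

        def rot(p):
            return (np.atleast_2d(p) - pivot) @ R.T + pivot

        frame1 = fit_tooth_frame(
            lab,
            rot(lm["cej_points"]),
            {"mesial": rot(lm["mesial_contact"])[0], "distal": rot(lm["distal_contact"])[0]},
            palatal_hint=rot(lm["palatal_hint"])[0],
        )
        m0 = measure_volumes(separate_roots(lab, frame0))
        m1 = measure_volumes(separate_roots(lab, frame1))
        for role in ("root_mesial", "root_distal", "root_palatal"):
            assert m1.volumes[role] == pytest.approx(m0.volumes[role], rel=0.05)

    def test_cut_below_tooth_is_an_error(self, default_truth):
        frame, lab, _ = _frame_from_truth(default_truth)
        with pytest.raises(RootSeparationError, match="no roots below cut"):
            separate_roots(lab, frame, cut_depth_voxels=300)


class TestMeasureVolumes:
    def test_voxel_count_arithmetic(self):
        labels = np.zeros((20, 20, 20), np.int32)
        labels.ravel()[:1000] = 1
        lab = LabelMap(labels, {1: "root_mesial"}, 10.0)
        morph = measure_volumes(lab)
        assert morph.volumes["root_mesial"] == pytest.approx(1e6)  # μm³ = 0.001 mm³
        assert morph.to_dict()["volumes_mm3"]["root_mesial"] == pytest.approx(0.001)

    def test_missing_root_label_measures_zero(self):
        labels = np.ones((4, 4, 4), np.int32)
        lab = LabelMap(labels, {1: "crown"}, 10.4)
        morph = measure_volumes(lab)
        assert morph.volumes["root_distal"] == 0.0

    def test_whole_tooth_volume_in_reported_murine_range(self, default_truth, default_seg):
        frame, _, _ = _frame_from_truth(default_truth)
        nh = default_truth.spec.grid_shape[1] // 2
        lab = LabelMap(
            np.ascontiguousarray(default_seg.labels[:, :nh, :]), dict(default_seg.legend), default_seg.voxel_size
        )
        morph = measure_volumes(lab)
        assert 0.3 <= morph.volumes["whole_tooth"] * 1e-9 <= 0.8  # mm³


def test_volume_invariant_under_frame_resampling(default_truth):
    """Rigid resampling into a tilted frame changes root volumes < 2 %."""
    frame0, lab, lm = _frame_from_truth(default_truth)
    R = Rotation.from_euler("xz", [4.0, 7.0], degrees=True).as_matrix()
    pivot = frame0.origin

    def rot(p):
        return (np.atleast_2d(p) - pivot) @ R.T + pivot

    frame1 = fit_tooth_frame(
        lab,
        rot(lm["cej_points"]),
        {"mesial": rot(lm["mesial_contact"])[0], "distal": rot(lm["distal_contact"])[0]},
        palatal_hint=rot(lm["palatal_hint"])[0],
    )
    res = morphometry.resample_to_frame(lab, frame1, output_shape=lab.shape)
    v0 = int(lab.molar_mask().sum())
    v1 = int(res.molar_mask().sum())
    assert abs(v1 - v0) / v0 <= 0.02
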