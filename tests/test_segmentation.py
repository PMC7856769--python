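import numpy as np
import pytest

from oracles import dice, minimax_labels, sobel_magnitude_dense
from rootseg import phantom, segmentation
from rootseg.errors import SegmentationError
from rootseg.segmentation import MarkerSet, correct_contacts, markers_from_truth, segment_tooth
from rootseg.volume_io import LabelMap, Volume3D


def _edges(data, voxel=10.4):
    return segmentation.sobel_gradient_magnitude(Volume3D(np.asarray(data, float), voxel))


def _markers(markers, legend=None, voxel=10.4):
    markers = np.asarray(markers, np.int32)
    if legend is None:
        legend = {int(l): "molar" if int(l) == 1 else "bone" for l in np.unique(markers) if l}
    return MarkerSet(LabelMap(markers, legend, voxel))


class TestSobel:
    def test_constant_volume_has_zero_gradient(self):
        out = _edges(np.full((5, 6, 7), 3.7))
        assert np.allclose(out.gradient.data, 0.0)

    def test_matches_dense_convolution_oracle(self, rng):
        for _ in range(5):
            vol = rng.random((7, 7, 7))
            ours = _edges(vol).gradient.data
            assert np.allclose(ours, sobel_magnitude_dense(vol), atol=1e-6)

    def test_equivariant_under_axis_rotations(self, rng):
        vol = rng.random((6, 6, 6))
        out = _edges(vol).gradient.data
        for k in (1, 2, 3):
            rot = np.rot90(vol, k=k, axes=(0, 1))
            assert np.allclose(_edges(rot).gradient.data, np.rot90(out, k=k, axes=(0, 1)), atol=1e-9)

    def test_degenerate_extent_rejected(self):
        with pytest.raises(SegmentationError):
            _edges(np.zeros((2, 5, 5)))


class TestWatershed:
    def test_markers_covering_grid_are_returned_unchanged(self, rng):
        m = rng.integers(1, 4, size=(4, 4, 4))
        out = segmentation.watershed_grow(_edges(rng.random((4, 4, 4))), _markers(m, {1: "molar", 2: "bone", 3: "air"}))
        assert np.array_equal(out.labels, m)

    def test_single_marker_floods_everything(self, rng):
        m = np.zeros((5, 5, 5), int)
        m[2, 2, 2] = 1
        out = segmentation.watershed_grow(_edges(rng.random((5, 5, 5))), _markers(m))
        assert np.all(out.labels == 1)

    def test_bright_ridge_plane_splits_two_seeds(self):
        vol = np.zeros((5, 5, 5))
        vol[2, :, :] = 100.0  # ridge plane at x = 2
        m = np.zeros((5, 5, 5), int)
        m[0, 2, 2] = 1
        m[4, 2, 2] = 2
        edges = _edges(vol)
        out = segmentation.watershed_grow(edges, _markers(m))
        # regions grow freely on their own side and meet at the ridge
        assert np.all(out.labels[:2] == 1)
        assert np.all(out.labels[4:] == 2)
        # on the symmetric ridge shoulder the stated tie-break applies:
        # equal path costs go to the lower label id
        assert np.all(out.labels[2] == 1)
        oracle = minimax_labels(edges.gradient.data, m)
        assert np.array_equal(out.labels, oracle)

    def test_matches_exhaustive_minimax_oracle(self, rng):
        """Priority flood equals brute-force minimax-path assignment on
        random gradient landscapes with unique path costs."""
        from rootseg.segmentation import EdgeMap
        from oracles import per_label_minimax_costs

        for trial in range(30):
            shape = tuple(int(s) for s in rng.integers(4, 7, size=3))
            n = int(np.prod(shape))
            cost_img = rng.permutation(n).reshape(shape).astype(float)  # unique costs
            nlab = int(rng.integers(2, 4))
            m = np.zeros(shape, int)
            for lbl in range(1, nlab + 1):
                m[tuple(rng.integers(0, s) for s in shape)] = lbl
            edges = EdgeMap(Volume3D(cost_img, 10.4))
            out = segmentation.watershed_grow(edges, _markers(m, {i: "molar" for i in np.unique(m) if i}))
            assert np.array_equal(out.labels, minimax_labels(cost_img, m)), f"trial {trial}"
            # independent semantic check: wherever one label's unconstrained
            # minimax cost is strictly smallest, the flood must pick it
            costs = per_label_minimax_costs(cost_img, m)
            labs = sorted(costs)
            stacked = np.stack([costs[l] for l in labs])
            order = np.sort(stacked, axis=0)
            strict = order[0] < order[1] if len(labs) > 1 else np.ones(shape, bool)
            argmin = np.array(labs)[np.argmin(stacked, axis=0)]
            assert np.array_equal(out.labels[strict], argmin[strict])

    def test_every_voxel_is_assigned(self, rng):
        m = np.zeros((6, 6, 6), int)
        m[0, 0, 0] = 1
        m[5, 5, 5] = 2
        out = segmentation.watershed_grow(_edges(rng.random((6, 6, 6))), _markers(m))
        assert np.all(out.labels != 0)

    def test_adding_a_seed_never_shrinks_its_label(self, rng):
        for _ in range(10):
            vol = rng.random((5, 5, 5))
            m = np.zeros((5, 5, 5), int)
            m[0, 0, 0] = 1
            m[4, 4, 4] = 2
            edges = _edges(vol)
            base = segmentation.watershed_grow(edges, _markers(m))
            count1 = (base.labels == 1).sum()
            m2 = m.copy()
            free = np.argwhere(m2 == 0)
            m2[tuple(free[rng.integers(len(free))])] = 1
            grown = segmentation.watershed_grow(edges, _markers(m2))
            assert (grown.labels == 1).sum() >= count1

    def test_deterministic_across_runs(self, rng):
        vol = rng.random((6, 6, 6))
        m = np.zeros((6, 6, 6), int)
        m[0, 0, 0] = 1
        m[5, 5, 5] = 2
        a = segmentation.watershed_grow(_edges(vol), _markers(m))
        b = segmentation.watershed_grow(_edges(vol), _markers(m))
        assert np.array_equal(a.labels, b.labels)

    def test_empty_marker_set_rejected(self):
        with pytest.raises(SegmentationError):
            _markers(np.zeros((3, 3, 3), int))


class TestCorrections:
    def test_no_corrections_is_identity(self, default_seg):
        out, audit = correct_contacts(default_seg, [])
        assert np.array_equal(out.labels, default_seg.labels)
        assert audit == []

    def test_box_correction_audits_changed_voxels(self):
        labels = np.ones((6, 6, 6), np.int32)
        seg = LabelMap(labels, {1: "molar", 2: "bone"}, 10.4)
        out, audit = correct_contacts(seg, [(((0, 2, 0, 2, 0, 2)), 2)])
        assert audit[0]["voxels_changed"] == 8
        assert (out.labels == 2).sum() == 8

    def test_unknown_label_rejected(self, default_seg):
        with pytest.raises(SegmentationError, match="unknown label"):
            correct_contacts(default_seg, [((0, 1, 0, 1, 0, 1), 99)])


def test_touching_molars_need_contact_correction():
    """At an interproximal contact there is no gradient edge; corrections
    taken from the reference labels in the contact slab restore the truth."""
    spec = phantom.PhantomSpec(
        seed=6,
        grid_shape=(176, 176, 176),
        x_center_frac=0.66,
        include_second_molar=True,
        second_molar_gap_um=0.0,
    )
    truth = phantom.generate_hemijaw_pair(spec)
    markers = markers_from_truth(truth.labels, erosion=3)
    raw = segment_tooth(truth.volume, markers)
    first_id = 1  # molar marker label for the first molar
    truth_first = truth.labels.mask_for_role("crown", "root_mesial", "root_distal", "root_palatal")
    # contact slab: around the plane between the two crowns
    c_x = spec.x_center_frac * (spec.grid_shape[0] - 1) * spec.voxel_size
    x_contact = int(round((c_x - spec.crown_semi_axes[0]) / spec.voxel_size))
    sl = slice(max(0, x_contact - 8), x_contact + 9)
    slab = np.zeros(truth_first.shape, bool)
    slab[sl] = True
    truth_second = truth.labels.labels == phantom.LBL_SECOND_MOLAR
    corrections = [
        (slab & (truth.labels.labels == phantom.LBL_BONE), 2),
        (slab & ~truth_first & ~truth_second & (truth.labels.labels != phantom.LBL_BONE), 5),
        (slab & truth_first, first_id),
        (slab & truth_second, 4),
    ]
    corrected, audit = correct_contacts(raw, corrections)
    fixed = segment_tooth(truth.volume, markers, corrections=corrections)
    in_slab_equal = np.array_equal((fixed.labels == first_id)[sl], truth_first[sl])
    assert in_slab_equal
    # the correction should have actually repaired leaked voxels
    assert sum(a["voxels_changed"] for a in audit) > 0
    assert dice(fixed.labels == first_id, truth_first) >= dice(raw.labels == first_id, truth_first)
    assert dice(fixed.labels == first_id, truth_first) >= 0.95


def test_markers_only_for_air_yield_single_label(default_truth):
    air = (default_truth.labels.labels == 0).astype(np.int32)
    from scipy.ndimage import binary_erosion

    seeds = binary_erosion(air.astype(bool), iterations=3).astype(np.int32) * 5
    ms = MarkerSet(LabelMap(seeds, {5: "air"}, 10.4))
    out = segment_tooth(default_truth.volume, ms)
    assert set(np.unique(out.labels)) == {5}
    assert not out.molar_mask().any()


def test_segmentation_accuracy_on_phantom(default_truth, default_seg):
    truth_molar = default_truth.labels.molar_mask()
    seg_molar = default_seg.molar_mask()
    assert dice(seg_molar, truth_molar) >= 0.95
    assert abs(int(seg_molar.sum()) - int(truth_molar.sum())) / truth_molar.sum() <= 0.05
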