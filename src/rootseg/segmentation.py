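"""Automated tooth segmentation: seeds → Sobel edges → watershed growth.

The three-step procedure segments structures with overlapping intensity
histograms (dentine vs. alveolar bone) by growing labeled seed regions over
the Sobel gradient-magnitude landscape until they meet at gradient ridges.
Failed edges (e.g. interproximal contacts, where adjacent enamel surfaces
touch and no gradient ridge exists) are repaired by explicit corrections, a
programmatic stand-in for interactive slice editing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from ._flood import flood
from .errors import SegmentationError
from .volume_io import LabelMap, MOLAR_ROLES, Volume3D


@dataclass
class MarkerSet:
    """Seed voxels for each structure, as a sparse label map."""

    markers: LabelMap

    def __post_init__(self) -> None:
        labs = self.markers.labels
        present = set(np.unique(labs).tolist()) - {0}
        if not present:
            raise SegmentationError("marker set is empty")
        # disjointness of seeds is implied by a single-valued label array


@dataclass
class EdgeMap:
    """Non-negative gradient-magnitude volume."""

    gradient: Volume3D

    def __post_init__(self) -> None:
        if np.any(self.gradient.data < 0):
            raise SegmentationError("edge map must be non-negative")


def sobel_gradient_magnitude(vol: Volume3D) -> EdgeMap:
    """3-D Sobel gradient magnitude with edge-replicated borders.

    Per axis, the separable 3×3×3 kernel applies the derivative stencil
    [−1, 0, 1] along the axis and the smoothing stencil [1, 2, 1] along the
    two transverse axes; the three directional responses are combined as the
    Euclidean norm.
    """
    if min(vol.shape) < 3:
        raise SegmentationError(f"volume extents must be >= 3, got {vol.shape}")
    data = np.asarray(vol.data, dtype=np.float64)
    sq = np.zeros_like(data)
    for axis in range(3):
        g = ndimage.sobel(data, axis=axis, mode="nearest")
        sq += g * g
    return EdgeMap(Volume3D(np.sqrt(sq), vol.voxel_size))


def watershed_grow(edges: EdgeMap, markers: MarkerSet) -> LabelMap:
    """Grow every marker over the gradient landscape until regions meet.

    Each voxel receives the label of the marker reached by the
    minimax-gradient path (simultaneous priority flood, 6-connectivity).
    Ties are broken by lower label id, then lexicographic voxel order, so the
    result is deterministic.  Every voxel is assigned: watershed lines are
    not kept as a separate label, so region volumes tile the grid.
    """
    m = markers.markers
    if m.shape != edges.gradient.shape:
        raise SegmentationError(f"marker shape {m.shape} does not match edge map {edges.gradient.shape}")
    out = flood(edges.gradient.data, m.labels)
    return LabelMap(out.astype(np.int32), dict(m.legend), m.voxel_size)


def correct_contacts(
    seg: LabelMap, corrections: Sequence[tuple] | None
) -> tuple[LabelMap, list[dict]]:
    """Overwrite listed voxel regions with given labels.

    ``corrections`` is a sequence of ``(region, label)`` pairs where
    ``region`` is either a boolean mask of the full grid or an index box
    ``(x0, x1, y0, y1, z0, z1)`` (half-open).  Returns the corrected map and
    an audit log with the number of voxels actually changed per correction.
    """
    labels = seg.labels.copy()
    audit: list[dict] = []
    for region, label in corrections or ():
        label = int(label)
        if label != 0 and label not in seg.legend:
            raise SegmentationError(f"unknown label {label} in correction")
        if isinstance(region, np.ndarray) and region.dtype == bool:
            if region.shape != labels.shape:
                raise SegmentationError("correction mask shape does not match grid")
            mask = region
        else:
            x0, x1, y0, y1, z0, z1 = (int(v) for v in region)
            if not (0 <= x0 <= x1 <= labels.shape[0] and 0 <= y0 <= y1 <= labels.shape[1] and 0 <= z0 <= z1 <= labels.shape[2]):
                raise SegmentationError(f"correction box {region} outside grid {labels.shape}")
            mask = np.zeros(labels.shape, dtype=bool)
            mask[x0:x1, y0:y1, z0:z1] = True
        changed = int(np.count_nonzero(labels[mask] != label))
        labels[mask] = label
        audit.append({"label": label, "voxels_in_region": int(mask.sum()), "voxels_changed": changed})
    return LabelMap(labels, dict(seg.legend), seg.voxel_size), audit


def _despeckle_molar(seg: LabelMap, min_component: int) -> LabelMap:
    """Reassign small connected components of molar-role labels to the
    label most common on their boundary."""
    labels = seg.labels.copy()
    struct = ndimage.generate_binary_structure(3, 1)
    for lbl in seg.labels_for_role(*MOLAR_ROLES):
        mask = labels == lbl
        comp, ncomp = ndimage.label(mask, structure=struct)
        if ncomp <= 1:
            continue
        sizes = np.bincount(comp.ravel())
        for ci in range(1, ncomp + 1):
            if sizes[ci] >= min_component or sizes[ci] == sizes[1:].max():
                continue
            m = comp == ci
            ring = ndimage.binary_dilation(m, structure=struct) & ~m
            neigh = labels[ring]
            neigh = neigh[neigh != lbl]
            fill = 0 if neigh.size == 0 else int(np.bincount(neigh).argmax())
            labels[m] = fill
    return LabelMap(labels, dict(seg.legend), seg.voxel_size)


def segment_tooth(
    vol: Volume3D,
    markers: MarkerSet,
    corrections: Sequence[tuple] | None = None,
    min_component: int = 50,
) -> LabelMap:
    """Full automated tooth segmentation pipeline.

    Sobel gradient → marker watershed → contact corrections → removal of
    molar-label connected components smaller than ``min_component`` voxels
    (reassigned to the surrounding label).
    """
    edges = sobel_gradient_magnitude(vol)
    seg = watershed_grow(edges, markers)
    if corrections:
        seg, _ = correct_contacts(seg, corrections)
    return _despeckle_molar(seg, min_component)


def markers_from_truth(
    truth_labels: LabelMap,
    erosion: int = 3,
    keep_fraction: float = 1.0,
    seed: int | None = None,
) -> MarkerSet:
    """Reproducible stand-in for interactive seed scribbles.

    Each structure's truth mask is eroded by ``erosion`` voxels; optionally a
    random subset (``keep_fraction``) of the eroded voxels is kept, which
    emulates operator-to-operator seed variability across repeats.  The
    molar (crown + roots) is seeded as one label; bone, spring, any second
    molar and air are seeded separately.
    """
    src = truth_labels
    groups: list[tuple[int, np.ndarray, str]] = []
    molar_ids = src.labels_for_role("crown", "root_mesial", "root_distal", "root_palatal")
    if molar_ids:
        groups.append((1, np.isin(src.labels, molar_ids), "molar"))
    for role, mid in (("bone", 2), ("spring", 3), ("molar", 4)):
        ids = [k for k, v in src.legend.items() if v == role and k not in molar_ids]
        if ids:
            groups.append((mid, np.isin(src.labels, ids), role))
    air_mask = src.labels == 0
    groups.append((5, air_mask, "air"))

    rng = np.random.default_rng(seed)
    out = np.zeros(src.shape, dtype=np.int32)
    legend: dict[int, str] = {}
    for mid, mask, role in groups:
        if not mask.any():
            continue
        er = ndimage.binary_erosion(mask, iterations=erosion) if erosion > 0 else mask
        if not er.any():
            er = mask  # structure thinner than the erosion radius: keep raw seeds
        if keep_fraction < 1.0:
            keep = rng.random(int(er.sum())) < keep_fraction
            idx = np.argwhere(er)
            er = np.zeros_like(er)
            sel = idx[keep]
            er[sel[:, 0], sel[:, 1], sel[:, 2]] = True
            if not er.any():
                er[tuple(idx[0])] = True
        out[er] = mid
        legend[mid] = role
    return MarkerSet(LabelMap(out, legend, src.voxel_size))
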