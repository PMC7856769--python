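"""Uniform tooth coordinate frame, root separation and volumetry.

The segmented molar is placed into a standard frame in which the
cementum-enamel junction (CEJ) plane is the XY plane (+Z occlusal) and the
mesio-distal contact line bisects the X and Y axes (45° to each).  Roots are
digitally separated from the crown by a cutting plane a fixed number of
voxels (default 30, ≈300 μm at 10.4 μm voxels) below the CEJ, partitioned
into connected components and named mesial / distal / palatal by their
centroid position in the frame.  Volumes are voxel counts × voxel_size³,
kept internally in μm³ and reported in both μm³ and mm³.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import FrameFitError, RootSeparationError
from .volume_io import LabelMap, MOLAR_ROLES, ROOT_ROLES, Volume3D, voxel_centers_um


@dataclass
class ToothFrame:
    """Rigid map from grid coordinates (μm) into the standard tooth frame.

    ``rotation`` has rows X, Y, Z of the frame expressed in world
    coordinates; frame coordinates of a world point p are
    ``rotation @ (p - origin)``.  The anatomical unit vectors (world coords)
    are kept alongside because the 45° contact-line convention places the
    mesio-distal axis between frame X and Y.
    """

    origin: np.ndarray
    rotation: np.ndarray
    mesial_dir: np.ndarray
    palatal_dir: np.ndarray
    occlusal_dir: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.rotation = np.asarray(self.rotation, dtype=float)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-8):
            raise FrameFitError("frame rotation must be orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise FrameFitError("frame rotation must be proper (det +1)")

    def to_frame(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = (pts - self.origin) @ self.rotation.T
        return out[0] if np.asarray(points).ndim == 1 else out

    def contact_angle_deg(self, mesial_contact, distal_contact) -> float:
        """Angle between the contact line and the frame X axis (degrees)."""
        u = self.to_frame(np.asarray(mesial_contact, float)) - self.to_frame(np.asarray(distal_contact, float))
        u[2] = 0.0
        u /= np.linalg.norm(u)
        return float(np.degrees(np.arccos(abs(u[0]))))


def fit_tooth_frame(
    seg: LabelMap,
    cej_points: np.ndarray,
    contacts: dict,
    palatal_hint: np.ndarray | None = None,
) -> ToothFrame:
    """Fit the standard tooth frame from CEJ landmarks and contact points.

    A least-squares plane through ``cej_points`` defines the Z axis
    (oriented so the crown lies on +Z, checked against the molar label
    centroid); the in-plane rotation is chosen so the mesio-distal contact
    line makes 45° with both X and Y, with the mesial direction in the
    (−X, −Y) quadrant.  ``palatal_hint`` (a point on the palatal side)
    disambiguates the sign of the palatal axis; without it the right-handed
    choice Z × mesial is used.
    """
    pts = np.asarray(cej_points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3 or pts.shape[1] != 3:
        raise FrameFitError("need at least 3 CEJ points")
    origin = pts.mean(axis=0)
    centered = pts - origin
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    if svals[1] < 1e-9 * max(svals[0], 1.0):
        raise FrameFitError("CEJ points are collinear")
    normal = vt[2]

    mesial_c = np.asarray(contacts["mesial"], dtype=float)
    distal_c = np.asarray(contacts["distal"], dtype=float)
    if np.allclose(mesial_c, distal_c):
        raise FrameFitError("contact points must be distinct")

    # orient Z towards the crown
    molar_mask = seg.molar_mask()
    if not molar_mask.any():
        raise FrameFitError("no molar label present to orient the frame")
    centroid = voxel_centers_um(np.argwhere(molar_mask).mean(axis=0), seg.voxel_size)
    if np.dot(centroid - origin, normal) < 0:
        normal = -normal
    z_axis = normal / np.linalg.norm(normal)

    u = mesial_c - distal_c
    u = u - np.dot(u, z_axis) * z_axis
    nu = np.linalg.norm(u)
    if nu < 1e-9:
        raise FrameFitError("contact line is parallel to the CEJ plane normal")
    m = u / nu  # mesial-ward, in plane
    w = np.cross(z_axis, m)
    if palatal_hint is not None:
        h = np.asarray(palatal_hint, dtype=float) - origin
        if np.dot(h, w) < 0:
            w = -w
    p = w  # palatal-ward
    # contact line bisects X and Y; mesial lies in the (-X, -Y) quadrant
    x_axis = (w - m) / np.sqrt(2.0)
    y_axis = np.cross(z_axis, x_axis)
    rotation = np.stack([x_axis, y_axis, z_axis])
    if np.linalg.det(rotation) < 0:  # enforce proper rotation
        y_axis = -y_axis
        rotation = np.stack([x_axis, y_axis, z_axis])
    return ToothFrame(origin=origin, rotation=rotation, mesial_dir=m, palatal_dir=p, occlusal_dir=z_axis)


@dataclass
class RootMorphometry:
    """Per-root and whole-tooth volumes in μm³."""

    volumes: dict
    cut_depth_voxels: int
    voxel_size: float

    def __post_init__(self) -> None:
        if self.cut_depth_voxels <= 0:
            raise RootSeparationError("cut_depth_voxels must be positive")
        if any(v < 0 for v in self.volumes.values()):
            raise RootSeparationError("volumes must be non-negative")

    def to_records(self) -> list[dict]:
        rows = []
        for key in (*ROOT_ROLES, "whole_tooth"):
            if key in self.volumes:
                v = self.volumes[key]
                rows.append({"structure": key, "volume_um3": v, "volume_mm3": v * 1e-9})
        return rows

    def to_dict(self) -> dict:
        return {
            "volumes_um3": dict(self.volumes),
            "volumes_mm3": {k: v * 1e-9 for k, v in self.volumes.items()},
            "cut_depth_voxels": self.cut_depth_voxels,
            "voxel_size_um": self.voxel_size,
        }


def separate_roots(seg: LabelMap, frame: ToothFrame, cut_depth_voxels: int = 30) -> LabelMap:
    """Split the molar label at the cutting plane below the CEJ.

    Molar voxels with frame z below ``-cut_depth_voxels × voxel_size`` are
    relabeled as roots; the root region is partitioned into 6-connected
    components, and components are named by frame-X centroid: most −X-ward
    is mesial, most +X-ward is distal, the remaining one palatal.
    """
    if cut_depth_voxels <= 0:
        raise RootSeparationError("cut_depth_voxels must be positive")
    molar = seg.molar_mask()
    if not molar.any():
        raise RootSeparationError("no molar label present")
    idx = np.argwhere(molar)
    zf = frame.to_frame(voxel_centers_um(idx, seg.voxel_size))[:, 2]
    cut = -cut_depth_voxels * seg.voxel_size
    below = zf < cut
    if not below.any():
        raise RootSeparationError("no roots below cut")

    root_mask = np.zeros(seg.shape, dtype=bool)
    bidx = idx[below]
    root_mask[bidx[:, 0], bidx[:, 1], bidx[:, 2]] = True
    comp, ncomp = ndimage.label(root_mask, structure=ndimage.generate_binary_structure(3, 1))
    sizes = np.bincount(comp.ravel())[1:]
    keep = [i + 1 for i in range(ncomp) if sizes[i] >= 8]  # drop sub-resolution crumbs
    if len(keep) < 3:
        raise RootSeparationError(f"expected 3 root components below the cut, found {len(keep)}")
    keep = sorted(keep, key=lambda ci: -sizes[ci - 1])[:3]

    xcent = []
    for ci in keep:
        cidx = np.argwhere(comp == ci)
        xcent.append(frame.to_frame(voxel_centers_um(cidx.mean(axis=0), seg.voxel_size))[0])
    order = np.argsort(xcent)  # ascending frame-X: mesial, palatal, distal
    names = {keep[order[0]]: "root_mesial", keep[order[1]]: "root_palatal", keep[order[2]]: "root_distal"}

    max_label = max(seg.legend) if seg.legend else 0
    new_ids = {"root_mesial": max_label + 1, "root_distal": max_label + 2, "root_palatal": max_label + 3}
    crown_id = max_label + 4
    labels = seg.labels.copy()
    legend = dict(seg.legend)
    molar_ids = seg.labels_for_role(*MOLAR_ROLES)
    labels[molar] = crown_id
    legend[crown_id] = "crown"
    for ci, role in names.items():
        labels[comp == ci] = new_ids[role]
        legend[new_ids[role]] = role
    # tiny dropped crumbs below the cut stay with the crown label
    for mid in molar_ids:
        legend.pop(mid, None)
    legend = {k: v for k, v in legend.items() if k in np.unique(labels) or k in new_ids.values() or k == crown_id}
    return LabelMap(labels, legend, seg.voxel_size)


def measure_volumes(seg: LabelMap, cut_depth_voxels: int = 30) -> RootMorphometry:
    """Volumes (voxel count × voxel_size³, μm³) per root and whole tooth."""
    v3 = seg.voxel_size**3
    volumes = {}
    for role in ROOT_ROLES:
        volumes[role] = float(seg.mask_for_role(role).sum() * v3)
    volumes["whole_tooth"] = float(seg.molar_mask().sum() * v3)
    return RootMorphometry(volumes=volumes, cut_depth_voxels=cut_depth_voxels, voxel_size=seg.voxel_size)


def resample_to_frame(obj: Volume3D | LabelMap, frame: ToothFrame, output_shape=None, output_origin_um=None):
    """Rigidly resample a volume or label map into the tooth frame.

    Labels use nearest-neighbour interpolation to preserve volumetry;
    intensities use trilinear.  ``output_origin_um`` gives the frame
    coordinate of output voxel (0,0,0); by default the output grid reuses the
    input shape, centred on the frame origin.
    """
    is_labels = isinstance(obj, LabelMap)
    data = obj.labels if is_labels else obj.data
    v = obj.voxel_size
    shape = tuple(output_shape) if output_shape is not None else data.shape
    if output_origin_um is None:
        output_origin_um = -(np.array(shape) - 1) * v / 2.0
    origin = np.asarray(output_origin_um, dtype=float)
    # world point of output index i: R^T (i*v + origin) + frame.origin
    A = frame.rotation.T / v  # maps output μm coords to input index units
    matrix = A * v  # output index -> input index rotation
    offset = (frame.rotation.T @ origin + frame.origin) / v
    out = ndimage.affine_transform(
        np.asarray(data, dtype=np.float64 if not is_labels else data.dtype),
        matrix=matrix,
        offset=offset,
        output_shape=shape,
        order=0 if is_labels else 1,
        mode="constant",
        cval=0,
    )
    if is_labels:
        return LabelMap(out.astype(obj.labels.dtype), dict(obj.legend), v)
    return Volume3D(out, v)
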