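"""Synthetic mirror-symmetric hemi-jaw μCT phantom with ground truth.

The phantom emulates the imaging situation of a murine split-mouth
protraction experiment: two mirror-symmetric hemi-maxillae, each carrying a
three-rooted first molar (mesial, distal and palatal roots) embedded in
alveolar bone, with

* a bright enamel crown over a dentine core,
* dentine and bone intensity distributions that overlap by a controlled
  amount (the difficulty that motivates gradient-based segmentation),
* a thin dark periodontal-ligament gap between root and bone,
* Gaussian blur emulating partial-volume blur and additive Gaussian noise,
* an optional bright nickel-titanium spring,
* a known rigid protraction of the test-side molar and known per-root
  resorption fractions carved as surface craters.

Axis conventions (test side): +x mesial (anterior), +y palatal (towards the
mid-sagittal plane), +z occlusal.  The mirror plane is the mid-sagittal grid
plane between the two hemi-jaws; the control side is the exact voxelwise
mirror of the untreated test side, including the noise realisation, so that
mirror symmetry of the untreated pair is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import ndimage
from scipy.special import ndtri  # inverse normal CDF

from .errors import PhantomGeometryError
from .volume_io import LabelMap, Volume3D

# truth label ids
LBL_CROWN = 1
LBL_ROOT_MESIAL = 2
LBL_ROOT_DISTAL = 3
LBL_ROOT_PALATAL = 4
LBL_BONE = 5
LBL_SPRING = 6
LBL_SECOND_MOLAR = 7

TRUTH_LEGEND = {
    LBL_CROWN: "crown",
    LBL_ROOT_MESIAL: "root_mesial",
    LBL_ROOT_DISTAL: "root_distal",
    LBL_ROOT_PALATAL: "root_palatal",
    LBL_BONE: "bone",
    LBL_SPRING: "spring",
    LBL_SECOND_MOLAR: "molar",
}

ROOT_LABELS = {"mesial": LBL_ROOT_MESIAL, "distal": LBL_ROOT_DISTAL, "palatal": LBL_ROOT_PALATAL}

# material ids used for intensity rendering (distinct from truth labels)
_M_AIR, _M_BONE, _M_DENTINE, _M_ENAMEL, _M_SPRING = 0, 1, 2, 3, 4
_MATERIAL_NAMES = {_M_AIR: "air", _M_BONE: "bone", _M_DENTINE: "dentine", _M_ENAMEL: "enamel", _M_SPRING: "spring"}


@dataclass
class PhantomSpec:
    """Parameters of the synthetic hemi-jaw pair.

    Geometric parameters are in μm.  Defaults are murine first-molar scale:
    control-side root volumes land near reported medians for mouse M1 roots
    (~0.8–2.2 × 10⁶ μm³) and the whole tooth in 0.3–0.8 mm³.
    """

    grid_shape: tuple[int, int, int] = (144, 176, 176)
    voxel_size: float = 10.4
    intensity_means: dict = field(
        default_factory=lambda: {"air": 200.0, "bone": 1000.0, "dentine": 1100.0, "enamel": 1800.0, "spring": 3200.0}
    )
    intensity_sds: dict = field(default_factory=lambda: {"air": 30.0, "enamel": 60.0, "spring": 80.0})
    blur_sigma: float = 6.0  # μm, partial-volume PSF
    root_radii: dict = field(default_factory=lambda: {"mesial": 38.0, "distal": 29.0, "palatal": 29.0})
    root_lengths: dict = field(default_factory=lambda: {"mesial": 700.0, "distal": 650.0, "palatal": 650.0})
    crown_height: float = 400.0
    bone_histogram_overlap: float = 0.5  # target intersection of bone vs dentine intensity histograms
    include_spring: bool = False
    include_second_molar: bool = False
    second_molar_gap_um: float = 60.0
    seed: int = 0

    # geometry details (fixed anatomy of the model molar)
    crown_semi_axes: tuple[float, float] = (580.0, 380.0)  # mesio-distal, bucco-palatal
    enamel_thickness: float = 100.0
    trunk_semi_axes: tuple[float, float] = (460.0, 300.0)
    trunk_depth: float = 312.0  # CEJ to the root cutting plane, = 30 voxels at 10.4 μm
    furcation_depth_um: float = 290.0  # CEJ to furcation (just above the cut)
    root_offsets: dict = field(
        default_factory=lambda: {"mesial": (300.0, 0.0), "distal": (-300.0, 0.0), "palatal": (0.0, 230.0)}
    )
    root_tip_fraction: float = 0.75  # tip radius / cervical radius (murine roots are blunt)
    pdl_gap: float = 31.2  # periodontal gap thickness, μm (>= 1 voxel)
    bone_crest_drop: float = 50.0  # crest sits this far apical of the CEJ
    x_center_frac: float = 0.5  # tooth centre along x as a fraction of grid extent
    y_center_um: float = 446.0  # tooth centre in the test hemi-jaw (local y)
    cej_height_um: float = 1300.0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or min(self.grid_shape) < 8:
            raise PhantomGeometryError(f"grid_shape must be 3 positive extents, got {self.grid_shape}")
        if self.grid_shape[1] % 2:
            raise PhantomGeometryError("grid y extent must be even (mid-sagittal mirror plane)")
        if self.voxel_size <= 0:
            raise PhantomGeometryError("voxel_size must be positive")
        for k in ("mesial", "distal", "palatal"):
            if self.root_radii[k] <= 0 or self.root_lengths[k] <= 0:
                raise PhantomGeometryError(f"root {k} must have positive radius and length")
        if self.intensity_means["enamel"] <= self.intensity_means["dentine"]:
            raise PhantomGeometryError("enamel must be brighter than dentine")
        if not (0.01 <= self.bone_histogram_overlap <= 0.95):
            raise PhantomGeometryError(
                f"bone/dentine histogram overlap target {self.bone_histogram_overlap} unrealizable"
            )
        if self.pdl_gap < self.voxel_size:
            raise PhantomGeometryError("periodontal gap must be at least one voxel")

    @property
    def half_shape(self) -> tuple[int, int, int]:
        nx, ny, nz = self.grid_shape
        return nx, ny // 2, nz

    def tissue_sds(self) -> dict:
        """Noise SDs per material; bone/dentine SDs realize the overlap target.

        For two normals with equal SD σ and mean gap δ the histogram overlap
        is 2Φ(−δ/2σ), so σ = δ / (2 Φ⁻¹(1 − overlap/2)).
        """
        delta = self.intensity_means["dentine"] - self.intensity_means["bone"]
        if delta <= 0:
            raise PhantomGeometryError("dentine mean must exceed bone mean")
        z = ndtri(1.0 - self.bone_histogram_overlap / 2.0)
        sigma = delta / (2.0 * z)
        sds = dict(self.intensity_sds)
        sds["bone"] = sigma
        sds["dentine"] = sigma
        return sds


def clinical_to_grid_mm(mesial: float, palatal: float, intrusion: float) -> np.ndarray:
    """Map clinical displacement components (mm) to a grid-axis vector (mm).

    Positive mesial moves the tooth along +x, positive palatal along +y and
    positive intrusion apically, i.e. along −z (test side).
    """
    return np.array([mesial, palatal, -intrusion], dtype=float)


def grid_to_clinical_mm(d: np.ndarray) -> dict:
    d = np.asarray(d, dtype=float)
    return {"mesial": float(d[0]), "palatal": float(d[1]), "intrusion": float(-d[2])}


@dataclass
class PhantomTruth:
    """Rendered phantom pair plus everything a validation needs to know."""

    spec: PhantomSpec
    volume: Volume3D
    labels: LabelMap
    materials: np.ndarray  # per-voxel material id, full grid
    cej_plane: dict  # {"point": (x,y,z) μm (test local), "normal": unit vector}
    contact_points: dict  # side -> {"mesial": point, "distal": point} (half-local μm)
    applied_motion: "object"  # RigidMotion (grid axes, mm)
    applied_resorption: dict  # root name -> fraction
    true_root_volumes: dict  # side -> {root role / whole_tooth: μm³}

    @property
    def half_shape(self) -> tuple[int, int, int]:
        return self.spec.half_shape

    def half(self, side: str) -> tuple[Volume3D, LabelMap]:
        """Extract one hemi-jaw ('test' or 'control') as its own grid."""
        nh = self.spec.grid_shape[1] // 2
        sl = slice(0, nh) if side == "test" else slice(nh, None)
        vol = Volume3D(np.ascontiguousarray(self.volume.data[:, sl, :]), self.spec.voxel_size)
        lab = LabelMap(
            np.ascontiguousarray(self.labels.labels[:, sl, :]), dict(self.labels.legend), self.spec.voxel_size
        )
        return vol, lab

    def landmarks(self, side: str) -> dict:
        """CEJ ring, contact points and a palatal hint, in half-local μm.

        Test-side landmarks follow the applied protraction; control-side
        landmarks are the mirror image of the untreated geometry.
        """
        s = self.spec
        cx = s.x_center_frac * (s.grid_shape[0] - 1) * s.voxel_size
        cy, cz = s.y_center_um, s.cej_height_um
        ax, ay = s.crown_semi_axes
        theta = np.linspace(0.0, 2.0 * np.pi, 8, endpoint=False)
        ring = np.stack([cx + ax * np.cos(theta), cy + ay * np.sin(theta), np.full(8, cz)], axis=1)
        mesial = np.array([cx + ax, cy, cz])
        distal = np.array([cx - ax, cy, cz])
        palatal_hint = np.array([cx, cy + ay, cz])
        pts = {"cej_points": ring, "mesial_contact": mesial, "distal_contact": distal, "palatal_hint": palatal_hint}
        if side == "test":
            rot = np.asarray(self.applied_motion.rotation)
            t_um = np.asarray(self.applied_motion.translation) * 1000.0
            pivot = np.array([cx, cy, cz - s.crown_height / 2.0])  # see _tooth_local_coords
            out = {}
            for k, v in pts.items():
                v = np.atleast_2d(v)
                moved = (v - pivot) @ rot.T + pivot + t_um
                out[k] = moved[0] if moved.shape[0] == 1 else moved
            return out
        # control side: mirror y within the half-local frame
        nh = s.grid_shape[1] // 2
        ymax = (nh - 1) * s.voxel_size
        out = {}
        for k, v in pts.items():
            v = np.array(v, dtype=float, copy=True)
            v[..., 1] = ymax - v[..., 1]
            out[k] = v
        return out


# ---------------------------------------------------------------------------
# geometry rendering
# ---------------------------------------------------------------------------


def _tooth_center(spec: PhantomSpec) -> np.ndarray:
    cx = spec.x_center_frac * (spec.grid_shape[0] - 1) * spec.voxel_size
    return np.array([cx, spec.y_center_um, spec.cej_height_um])


def _tooth_pivot(spec: PhantomSpec) -> np.ndarray:
    c = _tooth_center(spec)
    return c + np.array([0.0, 0.0, -spec.crown_height / 2.0])


def _half_coords(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    nx, nh, nz = spec.half_shape
    v = spec.voxel_size
    x = np.arange(nx)[:, None, None] * v
    y = np.arange(nh)[None, :, None] * v
    z = np.arange(nz)[None, None, :] * v
    return x, y, z


def _tooth_masks(spec: PhantomSpec, motion_rot: np.ndarray, motion_t_um: np.ndarray) -> dict:
    """Boolean masks of tooth sub-structures on the test half grid.

    The rigid motion (rotation about the mid-crown pivot, then translation)
    is applied analytically by evaluating all shapes in moved coordinates.
    """
    x, y, z = _half_coords(spec)
    pivot = _tooth_pivot(spec)
    inv = motion_rot.T
    # p_local = R^-1 (p - pivot - t) + pivot
    dx, dy, dz = x - pivot[0] - motion_t_um[0], y - pivot[1] - motion_t_um[1], z - pivot[2] - motion_t_um[2]
    X = inv[0, 0] * dx + inv[0, 1] * dy + inv[0, 2] * dz + pivot[0]
    Y = inv[1, 0] * dx + inv[1, 1] * dy + inv[1, 2] * dz + pivot[1]
    Z = inv[2, 0] * dx + inv[2, 1] * dy + inv[2, 2] * dz + pivot[2]

    c = _tooth_center(spec)
    ax, ay = spec.crown_semi_axes
    az = spec.crown_height
    zc = spec.cej_height_um
    above = Z >= zc
    outer = ((X - c[0]) / ax) ** 2 + ((Y - c[1]) / ay) ** 2 + ((Z - zc) / az) ** 2 <= 1.0
    t = spec.enamel_thickness
    inner = ((X - c[0]) / (ax - t)) ** 2 + ((Y - c[1]) / (ay - t)) ** 2 + ((Z - zc) / (az - t * 0.9)) ** 2 <= 1.0
    crown_outer = above & outer
    crown_inner = above & inner
    enamel = crown_outer & ~crown_inner

    tx, ty = spec.trunk_semi_axes
    zf = zc - spec.furcation_depth_um
    trunk = (((X - c[0]) / tx) ** 2 + ((Y - c[1]) / ty) ** 2 <= 1.0) & (Z < zc) & (Z >= zf)

    def root_membership(name, PX, PY, PZ):
        ox, oy = spec.root_offsets[name]
        R = spec.root_radii[name]
        L = spec.root_lengths[name]
        rx, ry = c[0] + ox, c[1] + oy
        s = (zf - PZ) / L
        radius = R * (1.0 - (1.0 - spec.root_tip_fraction) * np.clip(s, 0.0, 1.0))
        d2 = (PX - rx) ** 2 + (PY - ry) ** 2
        shaft = (s >= 0.0) & (s <= 1.0) & (d2 <= radius**2)
        tip_r = R * spec.root_tip_fraction
        cap = (d2 + (PZ - (zf - L)) ** 2 <= tip_r**2) & (PZ < zf - L)
        return shaft | cap

    # roots are only a few voxels across, so they are voxelised by area
    # sampling (3x3x3 subsamples, coverage >= 1/2): sub-voxel tooth motion
    # then leaves the voxel-counted root volume essentially unchanged
    v = spec.voxel_size
    offsets = (np.arange(3) - 1.0) * (v / 3.0)
    roots = {}
    for name in ("mesial", "distal", "palatal"):
        coarse = root_membership(name, X, Y, Z)
        idx = np.argwhere(np.broadcast_to(coarse, spec.half_shape))
        if idx.size == 0:
            roots[name] = np.zeros(spec.half_shape, dtype=bool)
            continue
        lo = np.maximum(idx.min(axis=0) - 2, 0)
        hi = np.minimum(idx.max(axis=0) + 3, spec.half_shape)
        bx = np.arange(lo[0], hi[0]) * v
        by = np.arange(lo[1], hi[1]) * v
        bz = np.arange(lo[2], hi[2]) * v
        cover = np.zeros((hi[0] - lo[0], hi[1] - lo[1], hi[2] - lo[2]), dtype=np.int16)
        for ox_ in offsets:
            for oy_ in offsets:
                for oz_ in offsets:
                    px = bx[:, None, None] + ox_ - pivot[0] - motion_t_um[0]
                    py = by[None, :, None] + oy_ - pivot[1] - motion_t_um[1]
                    pz = bz[None, None, :] + oz_ - pivot[2] - motion_t_um[2]
                    PX = inv[0, 0] * px + inv[0, 1] * py + inv[0, 2] * pz + pivot[0]
                    PY = inv[1, 0] * px + inv[1, 1] * py + inv[1, 2] * pz + pivot[1]
                    PZ = inv[2, 0] * px + inv[2, 1] * py + inv[2, 2] * pz + pivot[2]
                    cover += root_membership(name, PX, PY, PZ)
        full = np.zeros(spec.half_shape, dtype=bool)
        full[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = cover >= 14
        roots[name] = full
    return {"enamel": enamel, "crown_dentine": crown_inner, "trunk": trunk, "roots": roots, "z_local": Z}


def _second_molar_mask(spec: PhantomSpec) -> np.ndarray:
    x, y, z = _half_coords(spec)
    c = _tooth_center(spec)
    ax, _ = spec.crown_semi_axes
    semi = (300.0, 280.0, 280.0)
    cx2 = c[0] - (ax + semi[0] + spec.second_molar_gap_um)
    zc = spec.cej_height_um
    m = (
        ((x - cx2) / semi[0]) ** 2 + ((y - c[1]) / semi[1]) ** 2 + ((z - zc) / semi[2]) ** 2 <= 1.0
    ) & (z >= zc)
    return m


def _spring_mask(spec: PhantomSpec) -> np.ndarray:
    x, y, z = _half_coords(spec)
    c = _tooth_center(spec)
    zc = spec.cej_height_um + 250.0
    r = 60.0
    x0 = c[0] + 300.0
    x1 = min(c[0] + 1000.0, (spec.half_shape[0] - 3) * spec.voxel_size)
    m = ((y - c[1]) ** 2 + (z - zc) ** 2 <= r**2) & (x >= x0) & (x <= x1)
    return m


def _render_half(spec: PhantomSpec, motion_rot: np.ndarray, motion_t_um: np.ndarray):
    """Render one hemi-jaw: (labels, materials) on the half grid."""
    parts = _tooth_masks(spec, motion_rot, motion_t_um)
    tooth = parts["enamel"] | parts["crown_dentine"] | parts["trunk"]
    for m in parts["roots"].values():
        tooth |= m

    border = np.zeros(spec.half_shape, dtype=bool)
    border[0, :, :] = border[-1, :, :] = True
    border[:, 0, :] = border[:, -1, :] = True
    border[:, :, 0] = border[:, :, -1] = True
    if np.any(tooth & border):
        raise PhantomGeometryError("tooth does not fit inside the grid (touches a border)")
    for name, m in parts["roots"].items():
        if not np.any(m):
            raise PhantomGeometryError(f"root {name} vanished at this resolution")

    second = _second_molar_mask(spec) if spec.include_second_molar else np.zeros(spec.half_shape, bool)
    spring = _spring_mask(spec) if spec.include_spring else np.zeros(spec.half_shape, bool)
    spring &= ~tooth
    if np.any(tooth & second):
        raise PhantomGeometryError("molar collides with the second molar")

    # periodontal gap: soft-tissue shell around the tooth
    dist = ndimage.distance_transform_edt(~tooth, sampling=spec.voxel_size)
    pdl = (dist <= spec.pdl_gap) & ~tooth
    if spec.include_second_molar:
        dist2 = ndimage.distance_transform_edt(~second, sampling=spec.voxel_size)
        pdl |= (dist2 <= spec.pdl_gap) & ~second

    _, _, z = _half_coords(spec)
    below_crest = np.broadcast_to(z < spec.cej_height_um - spec.bone_crest_drop, spec.half_shape)
    bone = below_crest & ~tooth & ~pdl & ~second & ~spring

    materials = np.zeros(spec.half_shape, dtype=np.uint8)
    materials[bone] = _M_BONE
    materials[parts["trunk"]] = _M_DENTINE
    materials[parts["crown_dentine"]] = _M_DENTINE
    materials[parts["enamel"]] = _M_ENAMEL
    for m in parts["roots"].values():
        materials[m] = _M_DENTINE
    materials[second] = _M_ENAMEL
    materials[spring] = _M_SPRING

    labels = np.zeros(spec.half_shape, dtype=np.int32)
    labels[bone] = LBL_BONE
    # the cutting plane is anchored at the CEJ, so it moves with the tooth:
    # split crown from roots in tooth-local coordinates
    zcut = spec.cej_height_um - spec.trunk_depth
    zlocal = parts["z_local"]
    crown_side = tooth & (zlocal >= zcut)
    labels[crown_side] = LBL_CROWN
    for name, m in parts["roots"].items():
        labels[m & (zlocal < zcut)] = ROOT_LABELS[name]
    # any tooth voxel below the cut not inside a root frustum joins the
    # nearest root by axis distance (degenerate trunk/cut combinations)
    stray = tooth & (zlocal < zcut) & (labels == 0)
    if np.any(stray):
        c = _tooth_center(spec)
        idx = np.argwhere(stray)
        pts = idx * spec.voxel_size
        best = None
        dists = []
        for name in ("mesial", "distal", "palatal"):
            ox, oy = spec.root_offsets[name]
            dists.append((pts[:, 0] - (c[0] + ox)) ** 2 + (pts[:, 1] - (c[1] + oy)) ** 2)
        choice = np.argmin(np.stack(dists), axis=0)
        for i, name in enumerate(("mesial", "distal", "palatal")):
            sel = idx[choice == i]
            labels[sel[:, 0], sel[:, 1], sel[:, 2]] = ROOT_LABELS[name]
    labels[second] = LBL_SECOND_MOLAR
    labels[spring] = LBL_SPRING
    return labels, materials


def _carve_resorption(
    labels: np.ndarray,
    materials: np.ndarray,
    spec: PhantomSpec,
    fractions: Mapping[str, float],
    reference_counts: Mapping[str, int] | None = None,
) -> None:
    """Carve surface craters into the test-side roots, in place.

    Voxels are removed until each root holds ``round((1-f) * N_ref)``
    voxels, where ``N_ref`` is the untreated (control-side) count — so the
    applied fraction is exact relative to the contralateral reference even
    when sub-voxel tooth motion has slightly re-quantised the test root.
    Loss is carved as apical shortening plus cervical-third surface pits;
    a thin axial spine is protected so the root stays connected.
    """
    rng = np.random.default_rng([int(spec.seed) % (2**31), 913])
    c = _tooth_center(spec)
    v = spec.voxel_size
    for name, f in fractions.items():
        f = float(f)
        if not (0.0 <= f < 1.0):
            raise PhantomGeometryError(f"resorption fraction for {name} must be in [0,1), got {f}")
        if f == 0.0:
            continue
        lbl = ROOT_LABELS[name]
        mask = labels == lbl
        n0 = int(mask.sum())
        n_ref = int(reference_counts[name]) if reference_counts else n0
        n_remove = n0 - int(round((1.0 - f) * n_ref))
        if n_remove <= 0:
            continue
        idx = np.argwhere(mask)
        pts = idx * v
        ox, oy = spec.root_offsets[name]
        axis_xy = np.array([c[0] + ox, c[1] + oy])
        axial_d = np.hypot(pts[:, 0] - axis_xy[0], pts[:, 1] - axis_xy[1])
        protected = axial_d <= 1.3 * v
        carvable = ~protected
        if n_remove > 0.8 * n0 or (n_remove - int(round(0.8 * n_remove))) > int(carvable.sum()):
            raise PhantomGeometryError(
                f"resorption fraction {f} for root {name} unreachable at resolution "
                f"({n_remove} of {n0} voxels to remove)"
            )
        # resorption = apical shortening (the dominant, well-resolved loss)
        # plus smaller craters pitting the cervical-third surface; craters
        # below ~2.5 voxel radius are not resolvable after partial-volume blur
        # (they read as a weak spot in the wall, not a crater), so small
        # budgets go entirely into apical loss
        n_apical = int(round(0.8 * n_remove))
        if n_remove - n_apical < 64:
            n_apical = n_remove
        zorder = np.argsort(pts[:, 2] + 1e-3 * v * rng.random(len(pts)), kind="stable")
        apical_sel = np.zeros(len(pts), dtype=bool)
        apical_sel[zorder[:n_apical]] = True

        remaining = n_remove - n_apical
        crater_sel = np.zeros(len(pts), dtype=bool)
        if remaining > 0:
            eroded = ndimage.binary_erosion(mask)
            surf = mask & ~eroded
            sidx = np.argwhere(surf)
            spts = sidx * v
            zvals = spts[:, 2]
            zlo, zhi = zvals.min(), zvals.max()
            cervical = spts[zvals >= zhi - (zhi - zlo) / 3.0]
            # one pit per root: splitting the budget further would push each
            # pit below the partial-volume resolution limit
            pick = rng.choice(len(cervical), size=1, replace=False)
            pit_pts = cervical[pick]
            d_to_pit = np.min(
                np.linalg.norm(pts[:, None, :] - pit_pts[None, :, :], axis=2), axis=1
            ) + 0.3 * v * rng.random(len(pts))
            d_to_pit[protected | apical_sel] = np.inf
            order = np.argsort(d_to_pit, kind="stable")
            crater_sel[order[:remaining]] = True
        removed = idx[apical_sel | crater_sel]
        labels[removed[:, 0], removed[:, 1], removed[:, 2]] = 0
        materials[removed[:, 0], removed[:, 1], removed[:, 2]] = _M_AIR


def _assemble(spec: PhantomSpec, labels_test, mats_test, labels_base, mats_base):
    """Mirror the untreated base half onto the control side and render intensity."""
    nx, ny, nz = spec.grid_shape
    nh = ny // 2
    labels = np.zeros((nx, ny, nz), dtype=np.int32)
    materials = np.zeros((nx, ny, nz), dtype=np.uint8)
    labels[:, :nh, :] = labels_test
    labels[:, nh:, :] = labels_base[:, ::-1, :]
    materials[:, :nh, :] = mats_test
    materials[:, nh:, :] = mats_base[:, ::-1, :]

    means = spec.intensity_means
    sds = spec.tissue_sds()
    mean_lut = np.array([means[_MATERIAL_NAMES[i]] for i in range(5)], dtype=np.float32)
    sd_lut = np.array([sds.get(_MATERIAL_NAMES[i], 0.0) for i in range(5)], dtype=np.float32)

    def half_intensity(mats, noise):
        clean = mean_lut[mats]
        blurred = ndimage.gaussian_filter(clean, sigma=spec.blur_sigma / spec.voxel_size, mode="nearest")
        return blurred + sd_lut[mats] * noise

    rng = np.random.default_rng([int(spec.seed) % (2**31), 7])
    noise = rng.standard_normal(spec.half_shape).astype(np.float32)
    data = np.zeros((nx, ny, nz), dtype=np.float32)
    data[:, :nh, :] = half_intensity(mats_test, noise)
    data[:, nh:, :] = half_intensity(mats_base, noise)[:, ::-1, :]
    return data, labels, materials


def _root_volumes(labels: np.ndarray, spec: PhantomSpec) -> dict:
    nh = spec.grid_shape[1] // 2
    v3 = spec.voxel_size**3
    out = {}
    for side, sl in (("test", slice(0, nh)), ("control", slice(nh, None))):
        half = labels[:, sl, :]
        vols = {}
        for name, lbl in ROOT_LABELS.items():
            vols[f"root_{name}"] = float((half == lbl).sum() * v3)
        tooth = np.isin(half, [LBL_CROWN, LBL_ROOT_MESIAL, LBL_ROOT_DISTAL, LBL_ROOT_PALATAL])
        vols["whole_tooth"] = float(tooth.sum() * v3)
        out[side] = vols
    return out


def _render(spec: PhantomSpec, rotation: np.ndarray, translation_mm: np.ndarray, fractions: Mapping[str, float]):
    from .splitmouth import RigidMotion

    rotation = np.asarray(rotation, dtype=float)
    t_um = np.asarray(translation_mm, dtype=float) * 1000.0
    identity = np.allclose(rotation, np.eye(3)) and np.allclose(t_um, 0.0)
    labels_base, mats_base = _render_half(spec, np.eye(3), np.zeros(3))
    if identity:
        labels_test, mats_test = labels_base.copy(), mats_base.copy()
    else:
        labels_test, mats_test = _render_half(spec, rotation, t_um)
        if spec.include_spring and np.any((labels_test == LBL_CROWN) & (labels_base == LBL_SPRING)):
            raise PhantomGeometryError("moved molar collides with the spring")
    fractions = {k: float(v) for k, v in dict(fractions).items() if float(v) != 0.0}
    if fractions:
        ref_counts = {name: int((labels_base == lbl).sum()) for name, lbl in ROOT_LABELS.items()}
        _carve_resorption(labels_test, mats_test, spec, fractions, reference_counts=ref_counts)
    data, labels, materials = _assemble(spec, labels_test, mats_test, labels_base, mats_base)

    cej = {"point": _tooth_center(spec).tolist(), "normal": [0.0, 0.0, 1.0]}
    motion = RigidMotion(rotation=rotation, translation=np.asarray(translation_mm, dtype=float), reflection_applied=False)
    truth = PhantomTruth(
        spec=spec,
        volume=Volume3D(data, spec.voxel_size),
        labels=LabelMap(labels, dict(TRUTH_LEGEND), spec.voxel_size),
        materials=materials,
        cej_plane=cej,
        contact_points={},
        applied_motion=motion,
        applied_resorption={k: float(v) for k, v in dict(fractions).items()},
        true_root_volumes=_root_volumes(labels, spec),
    )
    truth.contact_points = {
        side: {"mesial": truth.landmarks(side)["mesial_contact"], "distal": truth.landmarks(side)["distal_contact"]}
        for side in ("test", "control")
    }
    return truth


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def generate_hemijaw_pair(spec: PhantomSpec) -> PhantomTruth:
    """Render the untreated, exactly mirror-symmetric hemi-jaw pair."""
    return _render(spec, np.eye(3), np.zeros(3), {})


def apply_protraction(truth: PhantomTruth, displacement_mm, rotation: np.ndarray | None = None) -> PhantomTruth:
    """Rigidly move the test-side molar by ``displacement_mm`` (grid axes).

    ``displacement_mm`` is a 3-vector in mm along the grid axes (+x mesial,
    +y palatal, −z intrusion; see :func:`clinical_to_grid_mm`).  An optional
    small proper rotation about the mid-crown pivot models tipping.  The
    hemi-jaw is re-rendered, so bone is refilled behind and carved ahead of
    the moved tooth and the periodontal gap is preserved by construction.
    """
    d = np.asarray(displacement_mm, dtype=float)
    if d.shape != (3,):
        raise PhantomGeometryError("displacement must be a 3-vector in mm")
    extent_mm = np.array(truth.spec.grid_shape) * truth.spec.voxel_size / 1000.0
    if np.any(np.abs(d) >= extent_mm):
        raise PhantomGeometryError("displacement exceeds the grid extent")
    rot = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
    if not np.allclose(rot @ rot.T, np.eye(3), atol=1e-8) or np.linalg.det(rot) < 0:
        raise PhantomGeometryError("rotation must be a proper rotation matrix")
    new_rot = rot @ truth.applied_motion.rotation
    new_t = truth.applied_motion.translation + d
    return _render(truth.spec, new_rot, new_t, truth.applied_resorption)


def apply_resorption(truth: PhantomTruth, fractions: Mapping[str, float]) -> PhantomTruth:
    """Carve per-root resorption craters into the test-side roots.

    ``fractions`` maps root names (mesial/distal/palatal) to the fraction of
    root volume removed, each in [0, 1).
    """
    merged = dict(truth.applied_resorption)
    for k, f in dict(fractions).items():
        if k not in ROOT_LABELS:
            raise PhantomGeometryError(f"unknown root {k!r}")
        if not (0.0 <= float(f) < 1.0):
            raise PhantomGeometryError(f"fraction for {k} must be in [0,1), got {f}")
        merged[k] = float(f)
    return _render(truth.spec, truth.applied_motion.rotation, truth.applied_motion.translation, merged)


def measured_histogram_overlap(truth: PhantomTruth, bins: int = 80) -> float:
    """Histogram intersection of bone vs dentine intensities on truth masks.

    Masks are eroded by two voxels so partial-volume boundary voxels do not
    contaminate the tissue distributions.
    """
    bone = ndimage.binary_erosion(truth.materials == _M_BONE, iterations=2)
    dent = ndimage.binary_erosion(truth.materials == _M_DENTINE, iterations=2)
    a = truth.volume.data[bone]
    b = truth.volume.data[dent]
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    ha, _ = np.histogram(a, bins=bins, range=(lo, hi), density=False)
    hb, _ = np.histogram(b, bins=bins, range=(lo, hi), density=False)
    pa = ha / ha.sum()
    pb = hb / hb.sum()
    return float(np.minimum(pa, pb).sum())
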