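# Methods

This note documents the models, conventions and numerical choices behind
`rootseg`, and what the phantom-based validation does and does not show.

## Segmentation model

The automated tooth segmentation is a three-step, edge-driven procedure
designed for images where dentine and bone intensities overlap:

1. **Markers.** Each structure (molar, bone, spring, air, optionally a
   second molar) gets at least one labelled seed region. In the phantom
   workflows, seeds are produced by eroding the reference masks by 3
   voxels, optionally keeping a random subset, which emulates operator
   scribbles; the watershed result is invariant to which interior voxels
   are seeded, which is why repeated runs yield an ICC of 1.0.
2. **Edges.** Per-axis 3-D Sobel derivatives (separable 3×3×3 kernel:
   derivative stencil [−1, 0, 1] on the axis, smoothing [1, 2, 1] on the
   two transverse axes; borders edge-replicated) combined as the Euclidean
   norm.
3. **Watershed growth.** A simultaneous priority flood over the gradient
   magnitude with 6-connectivity. A voxel is assigned the label of the
   seed whose minimax path reaches it first: the flood pops the heap entry
   with the lexicographically smallest (path cost, label id, linear voxel
   index), where path cost is the maximum gradient value along the path
   including both endpoints. The tie-break order makes the output
   deterministic and is pinned by a brute-force selection-Dijkstra oracle
   in the test suite; every voxel is assigned (no watershed-line label),
   so region volumes tile the grid. The flood is numba-compiled; only
   marker-boundary seeds are enqueued, which cannot change the result
   (an interior seed's path to any unlabeled voxel passes a boundary seed
   at no lower cost).

Interproximal contacts between touching enamel surfaces produce no
gradient ridge and the flood leaks; `correct_contacts` overwrites listed
regions with given labels and returns an audit log of changed voxel
counts. A final cleanup reassigns connected components of tooth labels
smaller than `min_component` (default 50 voxels, tunable) to the label
most common on their boundary.

## Tooth coordinate frame and volumetry

`fit_tooth_frame` builds the standard frame from landmarks: a
least-squares plane through ≥3 CEJ points defines Z (oriented so the
crown's label centroid lies on +Z); the in-plane rotation puts the
mesio-distal contact line at 45° to both X and Y, with the mesial
direction in the (−X, −Y) quadrant; a palatal hint point fixes the sign
of the palatal axis. Because the 45° convention mixes the anatomical
axes into frame X and Y, the frame also stores the mesial, palatal and
occlusal unit vectors, and all clinical components (tooth-movement
projections) use those anatomical axes, not raw frame X/Y.

`separate_roots` classifies molar voxels with frame z below
`−cut_depth_voxels × voxel_size` (default 30 voxels ≈ 312 μm at 10.4 μm)
as roots, partitions them into 6-connected components and names them by
frame-X centroid: most −X-ward mesial, most +X-ward distal, the remaining
one palatal. Fewer than three components is reported as an error, never
silently merged. Volumes are voxel counts × voxel_size³, kept in μm³ and
reported also in mm³. Landmark-based frame fitting (rather than automatic
CEJ detection) mirrors how such datasets are aligned in practice and keeps
the step verifiable.

## Split-mouth analysis

The control hemi-jaw is mirrored across the mid-sagittal grid plane
(an exact, lossless flip; applying it twice is the identity). Rigid
registration minimises the mean squared intensity difference restricted to
a mask of the reference structure, using a multi-resolution (shrink 4, 2)
regular-step gradient descent in SimpleITK, full metric sampling and one
thread (for bit-reproducibility), initialised by translating the moving
mask centroid onto the fixed one. Two details matter:

* For the **bone** stage the mask excludes bone within 16 voxels of either
  side's molar. Bone next to the moved tooth is remodelled (refilled
  behind, resorbed ahead) and genuinely differs between sides; including
  it drags the "anatomical" registration toward the tooth displacement.
* The **tooth** stage registers the bone-aligned control to the test side
  within a dilated molar mask; the OTM is this residual motion evaluated
  as the translation of the test molar centroid, projected onto the
  anatomical axes (positive mesial / palatal / intrusion = towards
  mesial / the palate / into the socket). The residual rotation (tipping)
  is reported separately in degrees and is not folded into the three
  translation components.

Root resorption per root: absolute `control − test` in μm³ and relative
`100·(control − test)/control` in %; the identity
`rr_rel = 100·rr_abs/control` holds exactly by construction.

## Statistics conventions

* Bland–Altman on differences d = a − b: mean difference, critical
  difference = 1.96 × sample SD (n−1 denominator), limits = mean ±
  critical. "Critical difference" is thus the half-width of the limits of
  agreement.
* ICC is the two-way, absolute-agreement, single-measurement form
  ICC(2,1) from the standard mean-squares decomposition (verified against
  pingouin's ICC(A,1) to 1e−9).
* Wilcoxon signed-rank: zero differences dropped, ties mid-ranked, exact
  null distribution for n ≤ 25 without ties, normal approximation with
  continuity correction otherwise. Paired t is the one-sample t on the
  differences.
* Regression reports the adjusted R², which can be negative for
  uninformative predictors (the plain R² cannot). For independent
  normal x, y its median at n = 14 is ≈ −0.04 although its expectation
  is exactly 0.

## The phantom

The phantom emulates a murine split-mouth protraction experiment on a
144 × 176 × 176 grid of 10.4 μm isotropic voxels (the two hemi-jaws share
one grid; the mid-sagittal mirror plane lies between the two central voxel
columns). The test hemi-jaw holds a first molar built from:

* a half-ellipsoid crown (semi-axes 580 × 380 μm, height 400 μm) with a
  100 μm enamel shell over a dentine core;
* an elliptical dentine trunk (460 × 300 μm) from the CEJ down to the
  furcation 290 μm below it;
* three tapered dentine roots (cervical radii 38/29/29 μm for
  mesial/distal/palatal, lengths 700/650/650 μm, tip/cervical radius
  ratio 0.75 — murine molar roots are blunt, and sharper tips would be
  sub-voxel) placed at mesial/distal/palatal offsets;
* a ≥3-voxel dark periodontal-ligament gap around the tooth below the
  alveolar crest (50 μm apical of the CEJ), bone everywhere below the
  crest, air above, and an optional bright NiTi spring and second molar.

Intensities are rendered per material (air 200, bone 1000, dentine 1100,
enamel 1800, spring 3200, arbitrary units), blurred with a Gaussian PSF of
σ = 6 μm (partial volume), then given additive Gaussian noise. The bone
and dentine noise SDs are derived from the target histogram-overlap
fraction (default 0.5): for equal SDs σ and mean gap δ the histogram
intersection is 2Φ(−δ/2σ). Noise is added after the blur so the realised
tissue distributions match the analytic overlap; a helper measures the
intersection on eroded truth masks and lands within ±0.05 of the target.
Control-side root volumes sit near reported murine first-molar medians
(~0.8–2.3 × 10⁶ μm³ per root, whole tooth ~0.32 mm³).

The control hemi-jaw is the exact voxelwise mirror of the untreated test
side, including the noise realisation, so pre-treatment mirror symmetry is
exact — matching how contralateral symmetry is exploited analytically.

**Protraction** re-renders the test side with the tooth geometry rigidly
displaced (sub-voxel, analytic; optional small rotation about a mid-crown
pivot). Bone is therefore refilled behind and carved ahead of the tooth
and the periodontal gap follows it by construction; landmarks move with
the tooth. Roots are voxelised by 3×3×3 area subsampling (a voxel belongs
to a root if ≥ half its subsamples fall inside), so sub-voxel motion
leaves truth root volumes essentially unchanged.

**Resorption** carves voxels out of each test-side root until it holds
`round((1−f) × N_control)` voxels, making the applied fraction exact
relative to the contralateral reference. The loss is carved as apical
shortening (80 %) plus a cervical-third surface pit (20 %); pit budgets
below ~64 voxels (≈2.5-voxel radius) are folded into the apical loss,
because after the partial-volume blur such pits do not read as craters —
they read as a weak spot in the root wall through which the watershed
leaks into the periodontal shell. A thin axial spine is protected so the
root stays connected; unreachable fractions at the given resolution raise
an error.

## What the validation shows — and does not

Passing the phantom suite shows that the implementation is internally
correct: the watershed matches its path-cost contract exactly, the
mirror/registration/frame chain recovers applied displacements to
≤0.01 mm per axis (typically ≤0.003 mm), per-root resorption fractions of
0–10 % are recovered within 1 percentage point when the tooth has not
moved, and the agreement statistics match closed forms and hold their
nominal error rates.

It does not show performance on real μCT, which additionally has beam
hardening and metal artefacts (only a crude bright-spring toggle here),
anatomical asymmetry between sides, textured trabecular bone, operator
variability in landmark picking, and true resorption crater morphology.
Two quantified resolution limits are worth knowing:

* Absolute root volumes carry a systematic ≈ +8–12 % boundary bias (the
  contested one-voxel gradient-ridge shell is claimed by the tooth on both
  sides). It cancels in test/control ratios, which is why relative
  resorption is accurate while absolute volumes are biased — and why the
  split-mouth ratio is the more robust readout.
* Under sub-voxel displacement the boundary shell re-quantises: in the
  combined protraction + resorption condition the relative-resorption
  readout of the two smaller roots (~3 voxel radius) can drift an
  additional ~1–2.5 percentage points. This is a limit of voxel counting
  at 10.4 μm on such small structures, not of the registration.

## Problem sizes and runtimes

Default grids are 4.4 M voxels; one phantom render takes ~1.5 s, a full
segmentation ~5 s, and a two-stage registration ~7 s. The validation
workflow uses 3 phantom pairs × 3 segmentation repeats; the tooth-movement
recovery checks use 11 phantoms; the statistics null-calibration uses
10,000 simulations at n = 20. The full test suite runs in ~4–5 minutes,
`scripts/acceptance.py` in ~1.5 minutes.
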