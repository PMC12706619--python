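# Methods

## The measurement

The Evans Index (EI) is the ratio of the maximal width of the frontal horns
of the lateral ventricles to the maximal inner-skull diameter measured at
the same axial level, with the head aligned to the anterior
commissure–posterior commissure (AC–PC) plane. EI ≥ 0.30 is the
conventional ventriculomegaly threshold used in normal pressure
hydrocephalus (NPH) work-ups.

The pipeline implemented here takes three inputs per case — a binary
lateral-ventricle (LV) mask, a binary intracranial-volume (ICV) mask, both
as NIfTI label volumes on a common axis-aligned RAS grid, and AC/PC/IVF
landmark coordinates in world millimetres — and performs:

1. **RAS canonicalization.** Grid axes are permuted/flipped to +Right,
   +Anterior, +Superior; world coordinates of every voxel are preserved
   exactly. Oblique grids (off-axis direction cosine > 0.2) are rejected
   rather than resampled: upstream registration is expected to have
   produced an axis-aligned grid, and silently resampling a label volume
   would introduce errors this package could not attribute.
2. **AC–PC realignment.** The unit vector v from PC to AC is taken onto the
   anterior axis ŷ by the minimal-angle rotation (axis v × ŷ, angle
   arccos v·ŷ), pivoted at the AC–PC midpoint. Two collinear landmarks
   cannot constrain rotation about their own axis, so roll (about the
   anterior–posterior axis) is left unchanged and documented as
   uncorrectable; this is exactly what the rotational-robustness protocol
   probes. Masks are resampled with nearest-neighbour lookup (labels are
   preserved exactly; linear interpolation would corrupt them), with
   round-half-up index rounding so results are deterministic.
3. **Mask postprocessing.** ICV: keep the largest connected component
   (foreground connectivity 26, ties broken by the component containing the
   lexicographically smallest voxel), then fill internal voids (background
   connectivity 6 — the standard dual choice avoiding topological
   paradoxes). LV: remove components smaller than 1 % of the LV foreground;
   a single-largest-component rule would delete one ventricle when the two
   are disconnected.
4. **Frontal-horn extraction.** LV voxels whose voxel-center world
   y-coordinate is strictly greater than the IVF's y (anterior to the
   foramen of Monro). The strict inequality on voxel centers is a
   documented convention; the boundary voxel layer is a sub-voxel effect.
5. **Width measurements.** For each axial slice with frontal-horn
   foreground, the left–right extent is (max − min voxel-center x) plus one
   x-spacing ("edge-to-edge"): manual calipers measure between ventricle
   walls, not voxel centers, and the pure center-to-center distance would
   bias EI low by about one voxel over the skull diameter. The maximal
   slice wins; ties go to the smallest z. The inner-skull width is measured
   on the same slice of the ICV mask with the same formula and the same
   left–right direction, keeping the two measurements parallel and
   perpendicular to the sagittal plane. A `center` width convention and an
   any-direction `max_chord` diameter are available behind configuration
   flags for sensitivity analysis; they are not defaults.
6. **EI and classification.** EI = width / diameter; `ventriculomegaly` is
   EI ≥ threshold (default 0.30; the exact boundary classifies positive).
   EI outside (0, 1) or a horn wider than the skull raises an implausible-
   geometry error rather than returning a value.

The LV/ICV volume ratio (foreground count × voxel volume) is provided as a
companion volumetric measure.

## Rotational-robustness protocol

Controlled rotations about three orthogonal axes — pitch (left–right, x),
yaw (inferior–superior, z), roll (anterior–posterior, y) — at ±5°, ±10°,
±15°, ±20° about the AC–PC midpoint, measured in two modes:

* **corrected** — landmarks rotate with the volume (as if re-detected), so
  AC–PC realignment undoes pitch and yaw exactly and only resampling noise
  remains; roll passes through untouched.
* **blind** — the stale neutral-frame landmarks are used; no realignment
  occurs and the measurement sees the full rotation.

Per (axis, angle) the report gives the median and IQR of
|EI_rotated − EI_neutral| and a Wilcoxon signed-rank test of the blind-mode
absolute errors against the corrected-mode residuals. The comparator needs
a word: with a deterministic pipeline the neutral-orientation error is
identically zero, so corrected-mode residuals (pure discretization noise)
stand in for the neutral error distribution. For roll the corrected and
blind measurements coincide by construction, so the per-axis comparison is
degenerate there; the headline test pools the ±20° cells of all three axes
(n = 180 pairs).

## Statistics

* **Bland–Altman** agreement with differences oriented auto − manual
  (positive bias = automated overestimates), sample SD (n − 1), and 95 %
  limits of agreement at bias ± 1.96 SD.
* **Pearson r** via the standard product-moment formula; constant input is
  an error, not a silent zero.
* **Wilcoxon signed-rank**: zeros dropped, tied magnitudes mid-ranked,
  W = positive-rank sum. For n_eff ≤ 25 the two-sided p is exact — the full
  2^n enumeration collapsed into a subset-sum count over doubled (integer)
  mid-ranks, so ties are handled exactly; beyond that, a normal
  approximation with tie correction and 0.5 continuity correction.
  Two-sided p is 2·min(P(W ≤ w), P(W ≥ w)) capped at 1.
* **Covariate screens**: continuous covariates → Pearson r with its t-based
  p; binary covariates → Welch two-sample t-test on |error|.

## Synthetic phantoms

The phantom generator is the package's test bed and stands in for clinical
cohorts. A phantom is: an ellipsoidal inner skull (semi-axes a, b, c;
defaults 50, 65, 55 mm), two mirrored frontal-horn spheres (radius r,
centers (±x_h, y_h, 0)), and tapered posterior ventricle bodies (narrow at
the foramen level, widening posteriorly, strictly posterior of the IVF
plane and always narrower than the horn span). Horns sit on the skull's
equatorial plane z = 0, so the matched-slice diameter is exactly 2a and the
ground truth is closed form:

    W = 2 (x_h + r),   D = 2a,   EI = W / D.

Defaults give EI = 0.30 exactly. Voxelization is a voxel-center
inside-or-on test on a cell-centered lattice (voxel centers at
half-integer multiples of the spacing, default 1 mm isotropic, 25 mm
padding). Cell centering matters: with integer-centered voxels the
default phantom's integer radii put analytic surfaces exactly on voxel
centers, creating measure-zero boundary voxels that any rotation destroys
and inflating rotation residuals by a voxel for degenerate geometries.

Rotated phantoms are voxelized directly in the rotated frame (shapes
rotated analytically before sampling, landmarks rotated exactly), so the
fixture itself carries no resampling error — any deviation measured on it
is attributable to the pipeline. A zero-angle rotation takes the identical
code path and is voxel-identical to the unrotated phantom.

Cohorts sample true EI uniformly on 0.22–0.42 (straddling the 0.30
threshold, normal through NPH-like), with mild variation in skull semi-axes
(a ∈ 46–54, b ∈ 60–70, c ∈ 50–60 mm), horn radius (4–6 mm) and horn height
(12–16 mm) so voxelization noise decorrelates across cases. All randomness
flows through explicit integer seeds; the robustness studies use a cohort
of n = 30.

What the phantoms do **not** emulate: real segmentation-boundary noise
(available separately via `jitter_mask`), asymmetric or lobulated ventricle
shape, partial-volume effects, non-equatorial horn placement, tilted AC–PC
lines in the native frame, or intensity data of any kind. Consequences
worth knowing: because the phantom is mirror-symmetric and the horns sit on
the skull equator, blind-mode *pitch* rotations barely change the measured
EI (the two horns' extreme points share an axial slice under any rotation
about x, and the diameter is first-order flat at the equator), so the pitch
sensitivity the protocol shows on phantoms is a floor, not an estimate of
clinical pitch sensitivity. Yaw and roll produce the large, monotonically
growing errors. Passing phantom tests demonstrates the geometry engine and
the protocol logic, not segmentation robustness on real scans.

## Numerical choices and degenerate inputs

* Voxel indices 0-based; affines map voxel centers (NIfTI convention);
  world space RAS mm. `world_to_voxel` rounds half up per axis.
* Rigid transforms are validated to 1e-10 (orthonormality, det +1);
  alignment below 1e-9 radians short-circuits to the identity, so already-
  aligned inputs are never resampled.
* Width-slice ties break to the smallest z; component-size ties to the
  lexicographically smallest member voxel; both documented and tested.
* Empty masks, reversed AC/PC, oblique affines, non-binary masks, 4D
  volumes, and EI outside (0, 1) raise typed errors (`IO`, `GEOMETRY`,
  `EMPTY_MASK`) that the CLI maps to exit codes; batch runs isolate
  failures per case.
* Problem sizes: the default phantom grid is 150 × 180 × 160 voxels at
  1 mm; the acceptance and test runs use 20 recovery phantoms, 16
  alignment-invariance cells, and the 30-case cohort with blind mode at all
  24 (axis, angle) cells and corrected mode at ±20°, which keeps a full run
  in the minutes range on one CPU.

## Known limitations

* Only axis-aligned grids are supported; oblique acquisitions must be
  registered upstream.
* The AC–PC realignment cannot observe roll; a true roll correction would
  need a third non-collinear landmark or the upstream template
  registration.
* The edge-to-edge width convention adds exactly one x-spacing; at coarse
  resolution this is the dominant (and documented) bias term.
* The inner-skull "diameter" is the left–right extent at the matched slice,
  not the maximal any-direction chord (available via `diameter_mode`).
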