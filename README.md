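# evansindex

Automated **Evans Index** measurement from segmented brain MRI.

The Evans Index (EI) is the classical linear marker of ventricular
enlargement: the ratio of the maximal width of the frontal horns of the
lateral ventricles to the maximal inner-skull diameter at the same axial
level, measured with the head aligned to the anterior commissure–posterior
commissure (AC–PC) plane,

```
EI = max frontal-horn width / inner-skull diameter at the matched slice,
EI >= 0.30  =>  ventriculomegaly (conventional threshold)
```

Manual EI measurement is slice- and alignment-dependent and varies between
observers, which matters in normal pressure hydrocephalus (NPH) screening
and in large cohorts. This package implements the measurement end of an
automated pipeline for researchers who already have segmentations and
landmarks (from any source): it takes a lateral-ventricle (LV) mask, an
intracranial-volume (ICV) mask and AC/PC/IVF landmark coordinates, and
performs AC–PC rigid realignment, mask postprocessing (spurious-cluster
removal, void filling), frontal-horn extraction anterior to the
interventricular foramen (IVF), paired width measurements and threshold
classification. Around the core measurement it provides:

* a **rotational-robustness protocol** (pitch/yaw/roll at ±5…±20°, blind
  vs landmark-corrected modes) quantifying how head mis-positioning
  corrupts EI;
* **agreement statistics** for method comparison: Bland–Altman bias and
  95 % limits of agreement, MAE, Pearson r, an exact tie-aware Wilcoxon
  signed-rank test, and covariate bias screens;
* a **synthetic phantom generator** with closed-form ground truth
  (ellipsoidal skull, spherical frontal horns, tapered ventricle bodies),
  used by the test suite in place of clinical data.

See `docs/methods.md` for the model, conventions and limitations.

## Worked example

Generate a phantom with a known true EI of 0.34 and measure it:

```bash
evansindex phantom --out demo --target-ei 0.34
evansindex measure \
    --lv demo/phantom_lv.nii.gz \
    --icv demo/phantom_icv.nii.gz \
    --landmarks demo/phantom_landmarks.json \
    --out demo/result.json
```

`demo/result.json` (abridged):

```json
{
  "evans_index": 0.34,
  "frontal_horn_width_mm": 34.0,
  "inner_skull_diameter_mm": 100.0,
  "z_index": 78,
  "lv_endpoints_mm": [[-16.5, 12.5, -1.5], [16.5, 12.5, -1.5]],
  "icv_endpoints_mm": [[-49.5, -8.5, -1.5], [49.5, -8.5, -1.5]],
  "ventriculomegaly": true,
  "threshold": 0.3
}
```

The frontal horns span 34.0 mm edge-to-edge on axial slice 78, the inner
skull spans 100.0 mm on the same slice, so EI = 0.34 — at this phantom's
analytic truth — and the case classifies as ventriculomegalic at the 0.30
threshold. The endpoint coordinates are the outermost voxel centers in
world millimetres, useful for overlaying the virtual calipers on the scan.

The same measurement is available as a library call:

```python
from evansindex import compute_evans_index, read_landmarks, read_mask_volume

lv = read_mask_volume("demo/phantom_lv.nii.gz")
icv = read_mask_volume("demo/phantom_icv.nii.gz")
landmarks = read_landmarks("demo/phantom_landmarks.json")
result = compute_evans_index(lv, icv, landmarks)
print(result.evans_index)   # 0.34
```

Other subcommands: `evansindex batch` (manifest CSV of cases, per-case
error isolation), `evansindex perturb` (the rotational-robustness study for
one case), `evansindex agree` (Bland–Altman report from an
`ei_auto`/`ei_manual` CSV, optional covariate screen), `evansindex phantom
--n 30 --seed 7` (a phantom cohort with manifest).

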