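# limbicnet

Does cleaning up FDG-PET images — deblurring and denoising them, and
cropping them to the limbic system — make a deep-learning classifier for
Alzheimer's disease (AD) both more accurate and more trustworthy?
`limbicnet` is a tested, end-to-end pipeline for studying that question at
desk scale.  It is aimed at neuroimaging methods researchers who want a
reproducible sandbox for the interaction between image restoration,
anatomical cropping, 3-D CNN classification and explainability, without
access-gated clinical data: a synthetic phantom generator stands in for the
cohort, and every downstream stage operates exactly as it would on real
NIfTI volumes.

## What it implements

* **Phantom cohorts** (`limbicnet.phantoms`) — two-class brain phantoms on
  a geometric atlas (hippocampus, amygdala, thalamus, putamen, caudate,
  insula, middle frontal/temporal gyri, cortex), with AD-class regional
  hypometabolism, per-subject variability, and multi-scanner blur/noise/
  slice-count variability via the degradation model `g = psf ⊗⊗ f + N`
  with a 2-D Gaussian PSF `psf(m,n) ∝ exp(−(m²+n²)/2σ_b²)`.
* **Restoration** (`limbicnet.restoration`) — slice-wise **TV-l1
  deblurring**, `f* = argmin_f ‖psf ⊗⊗ f − g‖₁ + λ‖∇f‖₁` (λ = 0.01),
  solved by half-quadratic splitting with FFT subproblem solves; and the
  **median modified Wiener filter** (MMWF),
  `b = μ̄ + (σ_n²−γ²)/σ_n² · (Ω−μ̄)`, with γ² the mean of all local
  variances.
* **Limbic cropping** (`limbicnet.cropping`) — the axial slab covering the
  limbic regions, with a crop box for mapping results back to whole-volume
  coordinates.
* **Classifier** (`limbicnet.nn`) — a 3-D residual CNN
  (7³ stride-2 conv → BN → ReLU → 3³ max-pool → two residual stages →
  global average pooling → FC-128 → FC-2 → softmax) implemented entirely
  in NumPy with exact CPU reproducibility; trained with Adam on
  cross-entropy (batch 4, 20 epochs, lr 1e-4 by default).
* **Evaluation** (`limbicnet.evaluation`) — sensitivity, specificity,
  accuracy, F1 and the Matthews correlation coefficient
  `MCC = (tp·tn − fp·fn)/√((tp+fp)(tp+fn)(tn+fp)(tn+fn))` from stratified
  3-fold cross-validation (or a 70/30 split), reported mean ± sd.
* **Explainability** (`limbicnet.cam`) — AD-class activation maps from the
  final convolutional features, averaged over subjects, summarized per
  atlas region, including the *non-brain fraction* of positive weight.
* **Pipeline + CLI** (`limbicnet.pipeline`, `limbicnet` command) — the full
  10-condition matrix {raw, deblur σ_b∈{1,2}, denoise window∈{3,5}} ×
  {whole-brain, cropped}, from one YAML config, with metrics tables, loss
  curves, NIfTI activation maps and region rankings as outputs.

See `docs/methods.md` for the models, assumptions and numerical choices.

## Worked example

```python
import numpy as np
from limbicnet.phantoms import build_atlas, make_phantom, degrade, ScannerProfile
from limbicnet.restoration import RestorationConfig, restore_volume
from limbicnet.cropping import limbic_crop_box, crop

atlas = build_atlas((64, 64, 40))
rng = np.random.default_rng(0)
scanner = ScannerProfile("demo", blur_sigma=2.0, noise_sd=0.10, n_slices=40)

clean = make_phantom(atlas, "ad", {"hippocampus": 0.25}, rng)
observed = degrade(clean, scanner, rng)
restored = restore_volume(observed, RestorationConfig("deblur", sigma_b=2.0))
box = limbic_crop_box(atlas, margin=2)
cropped, box = crop(restored, box)

hip = atlas.mask("hippocampus")
print(f"hippocampus mean: clean {clean.data[hip].mean():.3f}, "
      f"observed {observed.data[hip].mean():.3f}, "
      f"restored {restored.data[hip].mean():.3f}")
print(f"crop slab: z = [{box.start[2]}, {box.stop[2]}) "
      f"-> cropped dims {cropped.dims}")
```

prints

```
hippocampus mean: clean 0.717, observed 0.828, restored 0.773
crop slab: z = [8, 22) -> cropped dims (64, 64, 14)
```

The AD phantom's hippocampal uptake (0.717 ≈ 0.95 baseline × 0.75 effect ×
a per-subject factor) is partially washed out by scanner blur mixing in
brighter neighbouring tissue (0.828); TV-l1 deblurring recovers roughly
half of the lost contrast (0.773).  The crop keeps the full in-plane grid
and the 14 axial slices containing the limbic regions.

A full experiment over the 10-condition matrix:

```bash
limbicnet run --config src/limbicnet/configs/default.yaml --out runs/full
limbicnet run --smoke --out runs/smoke   # tiny sanity run, a few seconds
```

which writes `metrics.csv` / `metrics.txt` (five metrics × conditions,
mean ± sd over folds), per-fold loss curves, and per-condition averaged
activation maps with region rankings.

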