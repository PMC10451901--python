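# historeg

Spatial co-registration of whole-mount prostate histopathology with in vivo
dual-tracer PET/MRI, bridged through an ex vivo MRI of the resected
specimen — together with the validation metrics (target registration
error, per-slice DICE, nonparametric step comparison) and a synthetic
ground-truth phantom that makes the whole pipeline testable without any
patient data.

**Who this is for.** Groups correlating prostate PET/MRI findings with
post-prostatectomy histology: the pathologist's whole-mount annotations end
up on the same millimetre grid as the PET lesion segmentations, so
diagnostic accuracy can be scored per lesion and per slice instead of read
qualitatively.

## The method

Histology sections and in vivo images are separated by resection, fixation
shrinkage, and slicing. The pipeline goes through the ex vivo MRI of the
fixed specimen, which shares deformation state with the sections and
modality with the in vivo scan, in five steps:

1. **Histology → ex vivo MRI** (per section): a closed-form similarity fit
   (rotation + translation + uniform scale, Procrustes/Umeyama) of paired
   fiducial landmarks — holes left by gadolinium-infused threads visible in
   both modalities — then embedding of the 512×512 section into the ex vivo
   3D grid at its slice index.
2. **In vivo T2w → ex vivo T2w**: automatic rigid + cubic-BSpline free-form
   registration maximizing mutual information.
3. The step-2 transform carries the first tracer's PET volume (acquired
   simultaneously with the in vivo T2w on a hybrid scanner, hence
   intrinsically aligned) into ex vivo space.
4. **Second-session MRAC → first-session MRAC**: the same rigid + BSpline
   machinery, with a landmark-affine rescue when fiducial residuals exceed
   a threshold.
5. Steps 4 ∘ 2 carry the second tracer's PET across; identical chains move
   the PET lesion segmentations (nearest-neighbour).

Validation: target registration error `TRE_i = ‖T(P1_i) − P0_i‖` on eight
held-out points per section for each registration pair, summarized as
median (IQR) and compared across pairs with Kruskal–Wallis plus pairwise
Wilcoxon signed-rank tests under Benjamini–Hochberg FDR correction; and
per-slice DICE `2|A∩B|/(|A|+|B|)` between the co-registered histology
lesion annotation and each tracer's PET lesion segmentation.

All transforms map reference-space world points into moving-space points
(pull-back), chains are evaluated pointwise, and every output volume is
produced by a single interpolation pass. See `docs/methods.md` for the
model details, parameter defaults, and known limitations.

## Worked example

```python
import numpy as np
from historeg import generate_phantom, run_workflow
from historeg.workflow import evaluate_workflow

study = generate_phantom(seed=1)          # 11 sections, full ground truth
result = run_workflow(study)              # estimates all five steps
report = evaluate_workflow(study, result)

print({k: round(v, 2) for k, v in report["tre_median_mm"].items()})
print({k: round(d, 2) for k, d in report["dice_rm2_per_slice"].items() if d > 0})
```

Output:

```
{'histology vs exvivo': 1.03, 'exvivo vs invivo': 0.77, 'histology vs invivo': 1.12}
{39: 0.8, 44: 0.85, 49: 0.9, 54: 0.84}
```

Reading this: the landmark step places histology on the ex vivo MRI with a
median error of 1.03 mm over the held-out targets, the deformable step
recovers the fixation shrinkage and warp to 0.77 mm (the 0.3 mm landmark
noise alone floors this metric at ~0.65 mm), and the full composed chain
lands at 1.12 mm. The per-slice DICE against the concordant PET lesion is
0.80–0.90 on the four substantial lesion cross-sections; the remaining
annotated section only grazes the lesion (a cross-section a couple of mm
wide, which a 2 mm PET grid cannot represent), which is why overlap is
scored on cross-sections of at least 10 mm equivalent diameter.

The same pipeline is scriptable from the shell:

```sh
historeg phantom --seed 1 --out study/
historeg run --manifest study/manifest.json --out results/
historeg evaluate --manifest study/manifest.json --results results/ --out report.json
```

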