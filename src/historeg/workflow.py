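"""Five-step orchestration: from raw study volumes and digitized sections
to co-registered images, masks, and transforms in the common ex vivo space.

Steps
  1. each histology section -> its ex vivo MRI slice (landmark similarity),
     embedded into the ex vivo 3D grid;
  2. in vivo T2w -> ex vivo T2w (automatic rigid + BSpline, mutual
     information); the ex vivo T2w shares the T1w grid, so no extra
     transform is needed between the two ex vivo contrasts;
  3. the step-2 transform applied to the RM2 PET (intrinsically aligned
     with the simultaneously acquired in vivo T2w), linear interpolation;
  4. PSMA-session water MRAC -> RM2-session water MRAC (rigid + BSpline,
     with the landmark-affine rescue available);
  5. step-4 then step-2 applied to the PSMA PET.  The identical chains are
     applied to the PET lesion segmentations with nearest-neighbour
     interpolation.

All transforms are pull-backs (reference-space points into moving space),
so a chain is evaluated pointwise and each output is produced by a single
resampling pass — one interpolation of the original voxels regardless of
how many members the chain has.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import LandmarkSet, Transform, Volume, compose, resample
from .deformable import RegistrationResult, RegistrationSettings, register_deformable
from .evaluation import per_slice_dice, tre
from .landmarks import LandmarkFit, estimate_similarity, embed_slice
from .phantom import PhantomStudy

__all__ = [
    "WorkflowResult",
    "fit_step1",
    "run_workflow",
    "propagate_mask",
    "step_tre_distances",
    "evaluate_workflow",
]


@dataclass
class WorkflowResult:
    """All products of the five steps, in the common ex vivo space."""

    step1: dict[int, LandmarkFit]  # keyed by ex vivo axial index
    step2: RegistrationResult
    step4: RegistrationResult
    histology_volume: Volume
    histology_annotation: Volume
    rm2_pet_exvivo: Volume
    psma_pet_exvivo: Volume
    rm2_mask_exvivo: Volume
    psma_mask_exvivo: Volume
    slice_indices: list[int]
    provenance: dict = field(default_factory=dict)

    def all_volumes(self) -> list[Volume]:
        return [
            self.histology_volume,
            self.histology_annotation,
            self.rm2_pet_exvivo,
            self.psma_pet_exvivo,
            self.rm2_mask_exvivo,
            self.psma_mask_exvivo,
        ]


def propagate_mask(mask: Volume, chain: Transform, reference: Volume) -> Volume:
    """Carry a binary segmentation through a transform chain onto the
    reference grid (nearest neighbour, stays binary)."""
    vox = np.asarray(mask.voxels)
    if not np.isin(np.unique(vox), (0, 1)).all():
        raise ValueError("mask must be binary")
    out = resample(mask, chain, reference, interpolation="nearest", fill=0.0)
    return reference.geometry_like((out.voxels > 0).astype(np.uint8))


def fit_step1(study: PhantomStudy, ground_truth_transforms: bool = False) -> dict[int, LandmarkFit]:
    """Per-section similarity fits from the noisy fiducial landmark pairs
    (fixed: ex vivo in-plane; moving: histology), keyed by ex vivo axial
    index."""
    step1: dict[int, LandmarkFit] = {}
    for truth in study.slices:
        if ground_truth_transforms:
            step1[truth.index] = LandmarkFit(truth.jitter, 0.0)
            continue
        fixed2d = LandmarkSet(
            truth.fiducials_exvivo_noisy.points[:, :2],
            truth.fiducials_exvivo_noisy.labels,
            "exvivo",
        )
        step1[truth.index] = estimate_similarity(
            fixed2d, truth.fiducials_histology_noisy, allow_scale=True
        )
    return step1


def run_workflow(
    study: PhantomStudy,
    settings: RegistrationSettings | None = None,
    settings_step4: RegistrationSettings | None = None,
    ground_truth_transforms: bool = False,
) -> WorkflowResult:
    """Execute the five steps on a study.

    ``settings`` drives step 2; step 4 defaults to the same settings with a
    coarser control lattice (the inter-session PET offset is near-rigid, so
    a fine free-form lattice is wasted there).  With
    ``ground_truth_transforms=True`` the phantom's known transforms replace
    every estimated one (an upper-bound oracle run); otherwise transforms
    are estimated from the noisy fiducial landmarks and the image
    intensities alone — ground truth is never touched.
    """
    from dataclasses import replace as _replace

    settings = settings or RegistrationSettings()
    if settings_step4 is None:
        settings_step4 = _replace(
            settings,
            control_spacing_mm=2 * settings.control_spacing_mm,
            bspline_shrink=(2,),
            bspline_sigmas_mm=(1.0,),
            bspline_iterations=10,
        )
    exvivo = study.exvivo_t1w
    t0 = time.time()

    step_name = "step1-landmark-registration"
    try:
        step1 = fit_step1(study, ground_truth_transforms)
        histo_img = np.zeros(exvivo.shape)
        histo_ann = np.zeros(exvivo.shape, dtype=np.uint8)
        for sl, truth in zip(study.histology, study.slices):
            pullback = step1[truth.index].transform.inverse()
            img_vol = embed_slice(sl, pullback, exvivo, truth.index, channel="image")
            ann_vol = embed_slice(sl, pullback, exvivo, truth.index, channel="annotation")
            histo_img[:, :, truth.index] = img_vol.voxels[:, :, truth.index]
            histo_ann[:, :, truth.index] = ann_vol.voxels[:, :, truth.index]

        step_name = "step2-deformable-invivo-to-exvivo"
        if ground_truth_transforms:
            step2 = RegistrationResult(study.gt_exvivo_to_invivo, 0.0, 0.0)
        else:
            step2 = register_deformable(study.exvivo_t2w, study.invivo_t2w, settings)

        step_name = "step3-resample-rm2-pet"
        rm2_pet_ex = resample(study.rm2_pet, step2.transform, exvivo, "linear")
        rm2_mask_ex = propagate_mask(study.rm2_lesion_mask, step2.transform, exvivo)

        step_name = "step4-deformable-psma-to-rm2-mrac"
        if ground_truth_transforms:
            step4 = RegistrationResult(study.gt_invivo_to_psma, 0.0, 0.0)
        else:
            step4 = register_deformable(study.rm2_mrac, study.psma_mrac, settings_step4)

        step_name = "step5-resample-psma-pet"
        chain = compose(step4.transform, step2.transform)
        psma_pet_ex = resample(study.psma_pet, chain, exvivo, "linear")
        psma_mask_ex = propagate_mask(study.psma_lesion_mask, chain, exvivo)
    except Exception as err:
        raise RuntimeError(f"workflow failed at {step_name}: {err}") from err

    return WorkflowResult(
        step1=step1,
        step2=step2,
        step4=step4,
        histology_volume=exvivo.geometry_like(histo_img),
        histology_annotation=exvivo.geometry_like(histo_ann),
        rm2_pet_exvivo=rm2_pet_ex,
        psma_pet_exvivo=psma_pet_ex,
        rm2_mask_exvivo=rm2_mask_ex,
        psma_mask_exvivo=psma_mask_ex,
        slice_indices=[t.index for t in study.slices],
        provenance={
            "settings": settings.__dict__.copy(),
            "seed": study.params.seed,
            "ground_truth_transforms": ground_truth_transforms,
            "elapsed_s": round(time.time() - t0, 2),
        },
    )


# --------------------------------------------------------------------------
# Validation against phantom ground truth


def step_tre_distances(
    study: PhantomStudy, step1: dict[int, LandmarkFit], step2_transform: Transform
) -> dict[str, np.ndarray]:
    """Pooled per-point TRE (mm) of the three registration pairs, computed
    on the eight noisy validation targets per section — points that were
    never used to fit any transform."""
    d1, d2, d3 = [], [], []
    for truth in study.slices:
        fit = step1[truth.index]
        histo2d = truth.targets_histology_noisy
        ex2d = LandmarkSet(
            truth.targets_exvivo_noisy.points[:, :2], truth.targets_exvivo_noisy.labels, "exvivo"
        )
        d1.append(tre(fit.transform, histo2d, ex2d))
        d2.append(tre(step2_transform, truth.targets_exvivo_noisy, truth.targets_invivo_noisy))
        # full chain: histology annotation -> step1 -> section plane -> step2
        mapped2d = fit.transform(histo2d.points)
        mapped3d = np.column_stack([mapped2d, np.full(len(mapped2d), truth.z_mm)])
        chain_pts = step2_transform(mapped3d)
        d3.append(np.linalg.norm(chain_pts - truth.targets_invivo_noisy.points, axis=1))
    return {
        "histology vs exvivo": np.concatenate(d1),
        "exvivo vs invivo": np.concatenate(d2),
        "histology vs invivo": np.concatenate(d3),
    }


def evaluate_workflow(study: PhantomStudy, result: WorkflowResult) -> dict:
    """TRE distributions per step plus per-slice DICE for both tracers."""
    groups = step_tre_distances(study, result.step1, result.step2.transform)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rm2 = per_slice_dice(result.histology_annotation, result.rm2_mask_exvivo, result.slice_indices)
        psma = per_slice_dice(result.histology_annotation, result.psma_mask_exvivo, result.slice_indices)
    return {
        "tre_mm": groups,
        "tre_median_mm": {k: float(np.median(v)) for k, v in groups.items()},
        "dice_rm2_per_slice": rm2,
        "dice_psma_per_slice": psma,
    }
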