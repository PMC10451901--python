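"""On-disk layout of a complete study (phantom or real): volumes as NIfTI,
histology as TIFF pairs, landmarks as CSV, transforms and parameters as
JSON, all indexed by a manifest.  ``save_study``/``load_study`` round-trip a
:class:`~historeg.phantom.PhantomStudy` through this layout, which is what
the command-line interface operates on."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

from .core import AffineTransform, load_transform, save_transform
from .io import StudyManifest, read_histology, read_landmarks, read_volume, write_histology, write_landmarks, write_volume
from .phantom import PhantomParameters, PhantomStudy, SliceTruth

_VOLUME_ATTRS = (
    "invivo_t2w",
    "exvivo_t1w",
    "exvivo_t2w",
    "rm2_mrac",
    "psma_mrac",
    "rm2_pet",
    "psma_pet",
    "rm2_lesion_mask",
    "psma_lesion_mask",
    "exvivo_gland_mask",
)

_SLICE_LANDMARK_ATTRS = (
    "fiducials_histology",
    "fiducials_exvivo",
    "fiducials_invivo",
    "fiducials_histology_noisy",
    "fiducials_exvivo_noisy",
    "targets_histology",
    "targets_exvivo",
    "targets_invivo",
    "targets_histology_noisy",
    "targets_exvivo_noisy",
    "targets_invivo_noisy",
)


def save_study(study: PhantomStudy, outdir) -> Path:
    """Write a study to ``outdir`` in the manifest layout; returns the
    manifest path."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for attr in _VOLUME_ATTRS:
        write_volume(getattr(study, attr), out / f"{attr}.nii.gz")

    histo_entries = []
    for i, (sl, truth) in enumerate(zip(study.histology, study.slices)):
        tag = f"slice{i:02d}"
        write_histology(sl, out / f"{tag}_image.tiff", out / f"{tag}_annotation.tiff")
        entry = {
            "image": f"{tag}_image.tiff",
            "annotation": f"{tag}_annotation.tiff",
            "exvivo_index": truth.index,
            "z_mm": truth.z_mm,
            "pixel_spacing_mm": sl.pixel_spacing,
            "landmarks_histology": f"{tag}_fiducials_histology_noisy.csv",
            "landmarks_exvivo": f"{tag}_fiducials_exvivo_noisy.csv",
        }
        for attr in _SLICE_LANDMARK_ATTRS:
            name = f"{tag}_{attr}.csv"
            write_landmarks(getattr(truth, attr), out / name)
            entry[attr] = name
        save_transform(truth.jitter, out / f"{tag}_jitter.json")
        entry["jitter"] = f"{tag}_jitter.json"
        histo_entries.append(entry)

    save_transform(study.gt_exvivo_to_invivo, out / "gt_exvivo_to_invivo.json")
    save_transform(study.gt_invivo_to_psma, out / "gt_invivo_to_psma.json")
    with open(out / "phantom_parameters.json", "w") as fh:
        json.dump(asdict(study.params), fh, indent=1)

    manifest = StudyManifest(
        root=out,
        histology=histo_entries,
        extra={
            "exvivo_gland_mask": "exvivo_gland_mask.nii.gz",
            "gt_exvivo_to_invivo": "gt_exvivo_to_invivo.json",
            "gt_invivo_to_psma": "gt_invivo_to_psma.json",
            "phantom_parameters": "phantom_parameters.json",
        },
    )
    return manifest.save()


def load_study(manifest_path) -> PhantomStudy:
    """Reconstruct a study (with its ground truth) from a manifest."""
    manifest = StudyManifest.load(manifest_path)
    root = Path(manifest.root)
    volumes = {attr: read_volume(root / f"{attr}.nii.gz") for attr in _VOLUME_ATTRS}

    with open(root / manifest.extra["phantom_parameters"]) as fh:
        raw = json.load(fh)
    raw["gland_semi_axes_mm"] = tuple(raw["gland_semi_axes_mm"])
    raw["lesion_center_mm"] = tuple(raw["lesion_center_mm"])
    params = PhantomParameters(**raw)

    histology, slices = [], []
    for entry in manifest.histology:
        sl = read_histology(
            root / entry["image"],
            root / entry["annotation"],
            nominal_spacing_mm=entry["pixel_spacing_mm"],
            section_index_hint=entry["exvivo_index"],
        )
        histology.append(sl)
        lsets = {}
        for attr in _SLICE_LANDMARK_ATTRS:
            space = "histology" if "histology" in attr else ("invivo" if "invivo" in attr else "exvivo")
            lsets[attr] = read_landmarks(root / entry[attr], space=space)
        jitter = load_transform(root / entry["jitter"])
        assert isinstance(jitter, AffineTransform)
        slices.append(
            SliceTruth(
                index=int(entry["exvivo_index"]),
                z_mm=float(entry["z_mm"]),
                jitter=jitter,
                **lsets,
            )
        )

    gt_e2i = load_transform(root / manifest.extra["gt_exvivo_to_invivo"])
    gt_i2p = load_transform(root / manifest.extra["gt_invivo_to_psma"])
    assert isinstance(gt_i2p, AffineTransform)
    return PhantomStudy(
        params=params,
        histology=histology,
        slices=slices,
        gt_exvivo_to_invivo=gt_e2i,
        gt_invivo_to_psma=gt_i2p,
        **volumes,
    )
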