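"""Readers and writers for every on-disk artifact the pipeline touches.

Volumes travel as NIfTI (.nii/.nii.gz) or NRRD (.nrrd) with full world
geometry (LPS mm, as SimpleITK reads them); histology sections as TIFF
resized to 512x512; landmarks as CSV in world mm; transforms and the study
manifest as JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import SimpleITK as sitk
import tifffile
from skimage.transform import resize

from .core import LandmarkSet, Volume

HISTOLOGY_MATRIX = 512  # digitized whole-mount sections are resized to 512x512
DEFAULT_HISTOLOGY_SPACING_MM = 0.1

_VOLUME_EXTS = (".nii", ".nii.gz", ".nrrd")


def _check_volume_ext(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(e) for e in _VOLUME_EXTS):
        raise ValueError(f"unknown volume extension for {path.name!r}; expected {_VOLUME_EXTS}")


def volume_to_sitk(volume: Volume) -> sitk.Image:
    # SimpleITK arrays are indexed [z, y, x]
    img = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(volume.voxels, (2, 1, 0))))
    img.SetSpacing(tuple(volume.spacing))
    img.SetOrigin(tuple(volume.origin))
    img.SetDirection(tuple(volume.direction.ravel()))
    return img


def sitk_to_volume(img: sitk.Image) -> Volume:
    voxels = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
    return Volume(
        voxels,
        np.array(img.GetSpacing()),
        np.array(img.GetOrigin()),
        np.array(img.GetDirection()).reshape(3, 3),
    )


def read_volume(path) -> Volume:
    path = Path(path)
    _check_volume_ext(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = sitk.ReadImage(str(path))
    if img.GetDimension() != 3:
        raise ValueError(f"{path.name}: expected a 3D volume, got {img.GetDimension()}D")
    return sitk_to_volume(img)  # Volume.__init__ enforces orthonormal direction


def write_volume(volume: Volume, path) -> None:
    path = Path(path)
    _check_volume_ext(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(volume_to_sitk(volume), str(path))


# --------------------------------------------------------------------------
# Histology


@dataclass
class HistologySlice:
    """One digitized whole-mount section: image, binary lesion annotation,
    nominal in-plane pixel spacing (mm), and an optional hint giving the
    ex vivo axial index this section was cut from."""

    image: np.ndarray
    annotation: np.ndarray
    pixel_spacing: float = DEFAULT_HISTOLOGY_SPACING_MM
    section_index_hint: int | None = None

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        self.annotation = np.asarray(self.annotation)
        if self.image.shape != self.annotation.shape:
            raise ValueError("image and annotation shapes differ")
        if self.image.ndim != 2:
            raise ValueError("histology slice must be 2D")
        self.annotation = (self.annotation > 0).astype(np.uint8)
        if self.pixel_spacing <= 0:
            raise ValueError("pixel spacing must be positive")

    def pixel_to_world(self, pixels: np.ndarray) -> np.ndarray:
        """Pixel indices (ix, iy) -> section-local world mm."""
        return np.asarray(pixels, dtype=float) * self.pixel_spacing

    def world_to_pixel(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) / self.pixel_spacing


def _to_grayscale(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 3:
        return arr.astype(float).mean(axis=-1)
    if arr.ndim != 2:
        raise ValueError(f"unsupported histology image with {arr.ndim} dimensions")
    return arr.astype(float)


def read_histology(
    image_path,
    annotation_path,
    nominal_spacing_mm: float = DEFAULT_HISTOLOGY_SPACING_MM,
    section_index_hint: int | None = None,
) -> HistologySlice:
    """Load a digitized section and its lesion annotation, both resized to
    512x512; RGB images are reduced to luminance (channel mean) and the
    annotation is binarized (>0)."""
    image = _to_grayscale(tifffile.imread(str(image_path)))
    annotation = _to_grayscale(tifffile.imread(str(annotation_path)))
    shape = (HISTOLOGY_MATRIX, HISTOLOGY_MATRIX)
    if image.shape != shape:
        image = resize(image, shape, order=1, anti_aliasing=True, preserve_range=True)
    if annotation.shape != shape:
        annotation = resize(annotation, shape, order=0, anti_aliasing=False, preserve_range=True)
    return HistologySlice(image, annotation, nominal_spacing_mm, section_index_hint)


def write_histology(slice_: HistologySlice, image_path, annotation_path) -> None:
    img = slice_.image
    lo, hi = float(img.min()), float(img.max())
    scaled = np.zeros_like(img) if hi <= lo else (img - lo) / (hi - lo)
    tifffile.imwrite(str(image_path), (scaled * 65535).astype(np.uint16))
    tifffile.imwrite(str(annotation_path), (slice_.annotation * 255).astype(np.uint8))


# --------------------------------------------------------------------------
# Landmarks (CSV, world mm)


def read_landmarks(path, space: str = "") -> LandmarkSet:
    df = pd.read_csv(path)
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    if "label" not in cols or "x" not in cols or "y" not in cols:
        raise ValueError(f"{path}: landmark CSV needs columns label,x,y[,z]")
    coord_cols = ["x", "y", "z"] if "z" in cols else ["x", "y"]
    if df.empty:
        return LandmarkSet(np.zeros((0, len(coord_cols))), [], space)
    coords = df[coord_cols].to_numpy(dtype=float)  # raises on non-numeric
    return LandmarkSet(coords, df["label"].astype(str).tolist(), space)


def write_landmarks(landmarks: LandmarkSet, path) -> None:
    coord_cols = ["x", "y", "z"][: landmarks.dim]
    df = pd.DataFrame(np.round(landmarks.points, 9), columns=coord_cols)
    df.insert(0, "label", landmarks.labels)
    df.to_csv(path, index=False, float_format="%.9f")


# --------------------------------------------------------------------------
# Study manifest


@dataclass
class StudyManifest:
    """Per-patient file layout of one study: the five MR/PET volumes, the
    two MRAC volumes, lesion masks, digitized histology with annotations and
    per-space landmark files, plus the ex vivo axial index of each section."""

    root: Path
    invivo_t2w: str = "invivo_t2w.nii.gz"
    exvivo_t1w: str = "exvivo_t1w.nii.gz"
    exvivo_t2w: str = "exvivo_t2w.nii.gz"
    rm2_pet: str = "rm2_pet.nii.gz"
    psma_pet: str = "psma_pet.nii.gz"
    rm2_mrac: str = "rm2_mrac.nii.gz"
    psma_mrac: str = "psma_mrac.nii.gz"
    rm2_lesion_mask: str = "rm2_lesion_mask.nii.gz"
    psma_lesion_mask: str = "psma_lesion_mask.nii.gz"
    histology: list[dict] = field(default_factory=list)
    # each: {image, annotation, exvivo_index, landmarks_histology, landmarks_exvivo}
    extra: dict = field(default_factory=dict)

    def path(self, name: str) -> Path:
        return Path(self.root) / name

    def validate(self) -> None:
        for attr in (
            "invivo_t2w", "exvivo_t1w", "exvivo_t2w", "rm2_pet", "psma_pet",
            "rm2_mrac", "psma_mrac", "rm2_lesion_mask", "psma_lesion_mask",
        ):
            p = self.path(getattr(self, attr))
            if not p.exists():
                raise FileNotFoundError(f"manifest entry {attr}: {p} does not exist")
        for entry in self.histology:
            for key in ("image", "annotation", "landmarks_histology", "landmarks_exvivo"):
                p = self.path(entry[key])
                if not p.exists():
                    raise FileNotFoundError(f"histology entry {key}: {p} does not exist")

    def save(self, path=None) -> Path:
        path = Path(path) if path is not None else Path(self.root) / "manifest.json"
        payload = {k: v for k, v in self.__dict__.items() if k != "root"}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=str)
        return path

    @classmethod
    def load(cls, path) -> "StudyManifest":
        path = Path(path)
        with open(path) as fh:
            payload = json.load(fh)
        manifest = cls(root=path.parent, **payload)
        manifest.validate()
        return manifest
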