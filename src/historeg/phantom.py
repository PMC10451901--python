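"""Synthetic prostate phantom with known ground truth.

The generator emulates the physical study the pipeline is built for:

* an ellipsoidal gland with peripheral/transition zone contrast and a focal
  lesion, imaged in vivo (T2w MRI, two PET tracers with their water MRAC
  volumes on a hybrid scanner);
* resection and formalin fixation, modelled as a uniform shrinkage plus a
  small rigid repositioning and a smooth free-form deformation, followed by
  ex vivo T1w/T2w MRI of the specimen at high resolution;
* strand-shaped fiducials threaded through the specimen (hyperintense in
  T1w, holes in histology), each a U-shaped Bezier curve so that every
  transverse cutting plane is crossed twice — three strands give six
  fiducial points per section whose configuration changes along the gland;
* step-sectioning of the specimen at 3 mm intervals after trimming 3 mm
  from the apical and basal margins, each section digitized at 512x512 with
  an unknown in-plane rotation/translation jitter;
* two PET tracer sessions related by a small rigid inter-session offset;
  PET uptake is the lesion/gland uptake map blurred with a Gaussian PSF.
  The second tracer's lesion segmentation can be mirrored across the
  midsagittal plane ("discordant" option) to emulate a false-positive
  uptake in the contralateral lobe.

Every stochastic draw flows from one seed through named substreams, so the
same seed always produces a bit-identical study.  All ground-truth
transforms are stored in the pull-back convention (reference-space world
points into moving-space world points), matching what the registration
stages estimate.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .core import (
    AffineTransform,
    BSplineTransform,
    CompositeTransform,
    LandmarkSet,
    Transform,
    Volume,
    compose,
    rotation_z,
    similarity_2d,
)
from .io import DEFAULT_HISTOLOGY_SPACING_MM, HISTOLOGY_MATRIX, HistologySlice

__all__ = ["PhantomParameters", "SliceTruth", "PhantomStudy", "generate_phantom", "make_tre_targets"]


@dataclass(frozen=True)
class PhantomParameters:
    """Knobs of the synthetic study.  Defaults are the standard conditions
    used by the test-suite and the acceptance run."""

    seed: int = 0
    gland_semi_axes_mm: tuple[float, float, float] = (22.0, 18.0, 20.0)
    lesion_center_mm: tuple[float, float, float] = (9.0, -4.0, 1.0)
    lesion_radius_mm: float = 7.0
    n_strands: int = 3
    invivo_voxel_mm: float = 1.0
    exvivo_voxel_mm: float = 0.6  # paper-resolution 0.3 is selectable
    pet_voxel_mm: float = 2.0
    pet_psf_fwhm_mm: float = 4.5
    fixation_scale: float = 0.95
    nonrigid_amplitude_mm: float = 2.0
    specimen_shift_max_mm: float = 2.0
    specimen_rotation_max_deg: float = 3.0
    section_thickness_mm: float = 3.0
    end_trim_mm: float = 3.0
    jitter_max_rotation_deg: float = 5.0
    jitter_max_translation_mm: float = 2.0
    landmark_noise_mm: float = 0.3
    tracer_concordance: str = "concordant"  # or "discordant_psma"
    noise_fraction: float = 0.02
    n_tre_targets: int = 8

    def __post_init__(self) -> None:
        if self.tracer_concordance not in ("concordant", "discordant_psma"):
            raise ValueError(f"unknown tracer concordance {self.tracer_concordance!r}")
        for name in (
            "lesion_radius_mm", "invivo_voxel_mm", "exvivo_voxel_mm", "pet_voxel_mm",
            "pet_psf_fwhm_mm", "fixation_scale", "section_thickness_mm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SliceTruth:
    """Ground truth attached to one histology section."""

    index: int  # ex vivo axial voxel index of the section plane
    z_mm: float  # ex vivo world z of the section plane
    jitter: AffineTransform  # in-plane truth: histology world -> ex vivo (x, y)
    fiducials_histology: LandmarkSet
    fiducials_exvivo: LandmarkSet
    fiducials_invivo: LandmarkSet
    fiducials_histology_noisy: LandmarkSet
    fiducials_exvivo_noisy: LandmarkSet
    targets_histology: LandmarkSet
    targets_exvivo: LandmarkSet
    targets_invivo: LandmarkSet
    targets_histology_noisy: LandmarkSet
    targets_exvivo_noisy: LandmarkSet
    targets_invivo_noisy: LandmarkSet


@dataclass
class PhantomStudy:
    """A complete synthetic study with ground truth."""

    params: PhantomParameters
    invivo_t2w: Volume
    exvivo_t1w: Volume
    exvivo_t2w: Volume
    rm2_mrac: Volume
    psma_mrac: Volume
    rm2_pet: Volume
    psma_pet: Volume
    rm2_lesion_mask: Volume
    psma_lesion_mask: Volume
    exvivo_gland_mask: Volume
    histology: list[HistologySlice]
    slices: list[SliceTruth]
    gt_exvivo_to_invivo: Transform
    gt_invivo_to_psma: AffineTransform

    @property
    def n_sections(self) -> int:
        return len(self.histology)


# --------------------------------------------------------------------------
# helpers


def _rng(seed: int, name: str) -> np.random.Generator:
    key = zlib.crc32(name.encode("ascii")) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def _ellipsoid_level(p: np.ndarray, center, semi) -> np.ndarray:
    q = (np.atleast_2d(p) - np.asarray(center)) / np.asarray(semi)
    return np.sqrt((q**2).sum(axis=1))


def _soft_inside(level: np.ndarray, width: float = 0.04) -> np.ndarray:
    return _sigmoid((1.0 - level) / width)


def _make_grid(extent_mm, voxel_mm: float, center=(0.0, 0.0, 0.0)) -> Volume:
    extent = np.asarray(extent_mm, dtype=float)
    n = np.maximum(np.ceil(extent / voxel_mm).astype(int), 1)
    origin = np.asarray(center) - (n - 1) * voxel_mm / 2.0
    return Volume(np.zeros(tuple(n)), np.full(3, voxel_mm), origin)


def _grid_world(vol: Volume) -> np.ndarray:
    nx, ny, nz = vol.shape
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    idx = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3).astype(float)
    return vol.voxel_to_world(idx)


def _fill(vol: Volume, values: np.ndarray) -> Volume:
    return vol.geometry_like(values.reshape(vol.shape))


# --------------------------------------------------------------------------
# anatomy scene (in vivo frame)


class _Scene:
    """Analytic intensity/uptake model in the in vivo anatomy frame."""

    def __init__(self, params: PhantomParameters, rng_anatomy: np.random.Generator):
        self.p = params
        self.axes = np.asarray(params.gland_semi_axes_mm)
        self.lesion_center = np.asarray(params.lesion_center_mm)
        self.lesion_mirrored = self.lesion_center * np.array([-1.0, 1.0, 1.0])
        self.tz_center = np.array([0.0, 4.0, 2.0])
        self.tz_axes = 0.55 * self.axes
        self.body_axes = 2.2 * self.axes
        # smooth low-frequency bias field (scanner shading)
        self.bias_phase = rng_anatomy.uniform(0, 2 * np.pi, size=3)
        lesion_level = _ellipsoid_level(self.lesion_center[None], (0, 0, 0), self.axes)[0]
        if lesion_level + params.lesion_radius_mm / self.axes.min() > 1.0:
            raise ValueError("lesion is not fully inside the gland")

    # indicator helpers -----------------------------------------------------

    def gland_level(self, p: np.ndarray) -> np.ndarray:
        return _ellipsoid_level(p, (0.0, 0.0, 0.0), self.axes)

    def lesion_inside(self, p: np.ndarray, mirrored: bool = False) -> np.ndarray:
        c = self.lesion_mirrored if mirrored else self.lesion_center
        return np.linalg.norm(np.atleast_2d(p) - c, axis=1) <= self.p.lesion_radius_mm

    def _bias(self, p: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(p)
        return 0.04 * np.sin(p / 37.0 + self.bias_phase).sum(axis=1)

    def _zones(self, p: np.ndarray, zones=None):
        if zones is not None:
            return zones
        g = _soft_inside(self.gland_level(p))
        tz = _soft_inside(_ellipsoid_level(p, self.tz_center, self.tz_axes))
        lc = self.lesion_center
        les = _soft_inside(np.linalg.norm(np.atleast_2d(p) - lc, axis=1) / self.p.lesion_radius_mm, 0.06)
        return g, tz, les

    # modality contrasts ----------------------------------------------------

    def t2w(self, p: np.ndarray, zones=None) -> np.ndarray:
        g, tz, les = self._zones(p, zones)
        val = 0.05 + g * (0.75 - 0.30 * tz)
        val = val * (1.0 - les) + 0.25 * les * g
        return val + self._bias(p)

    def t1w(self, p: np.ndarray, zones=None) -> np.ndarray:
        g, tz, les = self._zones(p, zones)
        val = 0.05 + g * (0.35 + 0.25 * tz)
        val = val * (1.0 - les) + 0.48 * les * g
        return val + self._bias(p)

    def mrac(self, p: np.ndarray, zones=None) -> np.ndarray:
        body = _soft_inside(_ellipsoid_level(p, (0.0, 0.0, 0.0), self.body_axes))
        g, tz, _ = self._zones(p, zones)
        return 0.02 + 0.33 * body + g * (0.25 + 0.10 * tz) + self._bias(p)

    def histology(self, p: np.ndarray, zones=None) -> np.ndarray:
        g, tz, les = self._zones(p, zones)
        val = 0.10 + g * (0.70 - 0.20 * tz)
        return val * (1.0 - 0.35 * les)

    def uptake(self, p: np.ndarray, mirrored_lesion: bool = False) -> np.ndarray:
        g, tz, _ = self._zones(p)
        c = self.lesion_mirrored if mirrored_lesion else self.lesion_center
        les = _soft_inside(np.linalg.norm(np.atleast_2d(p) - c, axis=1) / self.p.lesion_radius_mm, 0.06)
        return 0.05 + 0.95 * g + 5.0 * les * g


# --------------------------------------------------------------------------
# strands


@dataclass
class _Strand:
    """U-shaped quadratic Bezier fiducial thread in the ex vivo frame; both
    endpoints sit near the basal face so every transverse plane inside the
    sectioned range is crossed twice."""

    p0: np.ndarray
    ctrl: np.ndarray
    p1: np.ndarray

    def point(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)[:, None]
        return (1 - t) ** 2 * self.p0 + 2 * t * (1 - t) * self.ctrl + t**2 * self.p1

    def plane_crossings(self, z: float) -> np.ndarray:
        """The two (x, y) crossings of the plane at height z, ordered by t."""
        z0, zc = self.p0[2], self.ctrl[2]
        a = 2.0 * (z0 - zc)
        disc = 1.0 - 4.0 * (z0 - z) / a
        if disc < 0:
            raise ValueError(f"strand does not reach plane z={z:.2f}")
        root = np.sqrt(disc)
        ts = np.array([(1 - root) / 2.0, (1 + root) / 2.0])
        return self.point(ts)[:, :2]


def _build_strands(
    params: PhantomParameters,
    rng: np.random.Generator,
    exvivo_gland_semi: np.ndarray,
    z_sections: np.ndarray,
) -> list[_Strand]:
    a, b, c = exvivo_gland_semi
    z_bottom_needed = min(z_sections.min() - 1.5, -0.5 * c)
    strands = []
    for j in range(params.n_strands):
        # varied tops, radii, spans and bends: the crossing-point pattern
        # then changes *shape* (not just scale) from section to section,
        # which is what disambiguates cutting planes
        z_top = rng.uniform(0.88, 0.96) * c
        phi = 2 * np.pi * j / params.n_strands + rng.uniform(-0.4, 0.4)
        dphi = rng.uniform(0.8, 1.7)
        ring = np.sqrt(max(1.0 - (z_top / c) ** 2, 0.0))
        r0 = rng.uniform(0.55, 0.8)
        r1 = rng.uniform(0.55, 0.8)
        p0 = np.array([r0 * a * ring * np.cos(phi), r0 * b * ring * np.sin(phi), z_top])
        p1 = np.array([r1 * a * ring * np.cos(phi + dphi), r1 * b * ring * np.sin(phi + dphi), z_top])
        zc = 2.0 * z_bottom_needed - z_top
        ctrl = np.array([rng.uniform(-6.0, 6.0), rng.uniform(-6.0, 6.0), zc])
        strands.append(_Strand(p0, ctrl, p1))
    return strands


# --------------------------------------------------------------------------
# generation


def _rasterize_strands(
    grid: Volume, samples: np.ndarray, radius: float = 0.45, edge_mm: float = 0.08
) -> np.ndarray:
    """Soft indicator of the strand tubes on an axis-aligned grid, painted
    as the union of small spheres around dense curve samples."""
    out = np.zeros(grid.shape)
    inv_spacing = 1.0 / grid.spacing
    reach = radius + 4.0 * edge_mm
    half = np.ceil(reach * inv_spacing).astype(int)
    shape = np.asarray(grid.shape)
    for p in samples:
        c = (p - grid.origin) * inv_spacing
        lo = np.maximum(np.ceil(c - half).astype(int), 0)
        hi = np.minimum(np.floor(c + half).astype(int), shape - 1)
        if np.any(lo > hi):
            continue
        ax = [np.arange(lo[d], hi[d] + 1) * grid.spacing[d] + grid.origin[d] - p[d] for d in range(3)]
        d2 = (
            ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2 + ax[2][None, None, :] ** 2
        )
        blob = _sigmoid((radius - np.sqrt(d2)) / edge_mm)
        region = (slice(lo[0], hi[0] + 1), slice(lo[1], hi[1] + 1), slice(lo[2], hi[2] + 1))
        np.maximum(out[region], blob, out=out[region])
    return out


def _deformation_field(
    params: PhantomParameters, rng: np.random.Generator, domain_halfwidth: np.ndarray
) -> BSplineTransform | None:
    amp = params.nonrigid_amplitude_mm
    if amp <= 0:
        return None
    spacing = np.full(3, 12.0)
    n = np.ceil(2 * domain_halfwidth / spacing).astype(int) + 4
    origin = -(n - 1) * spacing / 2.0
    control = rng.normal(0.0, amp / 2.0, size=(*n, 3))
    np.clip(control, -amp, amp, out=control)
    return BSplineTransform(control, origin, spacing)


def _add_noise(values: np.ndarray, rng: np.random.Generator, fraction: float) -> np.ndarray:
    span = float(values.max() - values.min())
    if span == 0 or fraction <= 0:
        return values
    return values + rng.normal(0.0, fraction * span, size=values.shape)


def _noisy(points: np.ndarray, rng: np.random.Generator, sigma: float) -> np.ndarray:
    if sigma <= 0:
        return points.copy()
    return points + rng.normal(0.0, sigma, size=points.shape)


def generate_phantom(params: PhantomParameters | None = None, **overrides) -> PhantomStudy:
    """Generate a complete synthetic study; fully determined by the seed."""
    if params is None:
        params = PhantomParameters()
    if overrides:
        params = replace(params, **overrides)
    rng_anat = _rng(params.seed, "anatomy")
    rng_def = _rng(params.seed, "deformation")
    rng_jit = _rng(params.seed, "jitter")
    rng_noise = _rng(params.seed, "noise")
    rng_lm = _rng(params.seed, "landmarks")

    scene = _Scene(params, rng_anat)
    axes = scene.axes
    s = params.fixation_scale

    # -- ground-truth specimen transform (pull-back: ex vivo -> in vivo) ----
    # forward (in vivo -> ex vivo specimen frame): shrink by s, small rigid
    # repositioning of the specimen in the mold, then free-form deformation.
    theta = rng_def.uniform(-params.specimen_rotation_max_deg, params.specimen_rotation_max_deg)
    shift = rng_def.uniform(-params.specimen_shift_max_mm, params.specimen_shift_max_mm, size=3)
    forward_affine = compose(
        AffineTransform(s * np.eye(3), shift), rotation_z(theta)
    )  # p_in -> s*R p + d
    affine_pullback = forward_affine.inverse()
    bspline = _deformation_field(params, rng_def, s * axes + 6.0)
    gt_exvivo_to_invivo: Transform
    if bspline is None:
        gt_exvivo_to_invivo = affine_pullback
    else:
        gt_exvivo_to_invivo = CompositeTransform([bspline, affine_pullback])

    # -- in vivo volumes ----------------------------------------------------
    invivo_t2w = _make_grid(2 * axes + 16.0, params.invivo_voxel_mm)
    pts_iv = _grid_world(invivo_t2w)
    invivo_t2w = _fill(invivo_t2w, _add_noise(scene.t2w(pts_iv), rng_noise, params.noise_fraction))

    # -- ex vivo volumes ----------------------------------------------------
    exvivo = _make_grid(2 * s * axes + 12.0, params.exvivo_voxel_mm)
    pts_ex = _grid_world(exvivo)
    mapped = gt_exvivo_to_invivo(pts_ex)
    gland_level_ex = scene.gland_level(mapped)
    gland_mask = (gland_level_ex <= 1.0).reshape(exvivo.shape)
    exvivo_gland_mask = exvivo.geometry_like(gland_mask.astype(np.uint8))

    # -- sectioning ---------------------------------------------------------
    kz = np.flatnonzero(gland_mask.any(axis=(0, 1)))
    if kz.size == 0:
        raise ValueError("empty specimen: gland does not intersect the ex vivo grid")
    z_centers = np.array([exvivo.slice_world_z(int(k)) for k in kz])
    vz = params.exvivo_voxel_mm
    z_min, z_max = z_centers.min() - vz / 2, z_centers.max() + vz / 2
    length = z_max - z_min
    n_sections = int(np.floor((length - 2 * params.end_trim_mm) / params.section_thickness_mm))
    if n_sections < 1:
        raise ValueError("specimen too short to section after trimming the margins")
    z_first = z_min + params.end_trim_mm + params.section_thickness_mm / 2.0
    z_sections_nominal = z_first + params.section_thickness_mm * np.arange(n_sections)
    # snap section planes onto ex vivo voxel centers (<= half a voxel)
    k_sections = np.array(
        [int(np.round(exvivo.world_to_voxel(np.array([0.0, 0.0, z]))[2])) for z in z_sections_nominal]
    )
    z_sections = np.array([exvivo.slice_world_z(int(k)) for k in k_sections])

    # -- fiducial strands (ex vivo frame) ------------------------------------
    strands = _build_strands(params, rng_anat, s * axes, z_sections)
    t_dense = np.linspace(0.0, 1.0, 300)
    strand_samples = np.concatenate([st.point(t_dense) for st in strands])
    in_section_range = (strand_samples[:, 2] >= z_sections.min() - 1.0) & (
        strand_samples[:, 2] <= z_sections.max() + 1.0
    )
    strand_levels = scene.gland_level(gt_exvivo_to_invivo(strand_samples[in_section_range]))
    if np.any(strand_levels > 1.0):
        raise ValueError("fiducial strand leaves the gland inside the sectioned range")

    boost = _rasterize_strands(exvivo, strand_samples).reshape(-1)
    zones_ex = scene._zones(mapped)
    t1_vals = scene.t1w(mapped, zones_ex) + 0.45 * boost  # gadobutrol-infused: hyperintense
    t2_vals = scene.t2w(mapped, zones_ex) - 0.10 * boost
    exvivo_t1w = _fill(exvivo, _add_noise(t1_vals, rng_noise, params.noise_fraction))
    exvivo_t2w = _fill(exvivo, _add_noise(t2_vals, rng_noise, params.noise_fraction))

    # -- PET sessions ---------------------------------------------------------
    # PSMA session frame differs from the RM2/in vivo frame by a small rigid
    # inter-session offset; its pull-back (in vivo -> PSMA session) is the
    # step-4 ground truth.
    sess_theta = rng_def.uniform(-1.0, 1.0)
    sess_shift = rng_def.uniform(-1.0, 1.0, size=3)
    gt_invivo_to_psma = compose(AffineTransform(np.eye(3), sess_shift), rotation_z(sess_theta))
    psma_to_anat = gt_invivo_to_psma.inverse()

    pet_grid = _make_grid(2 * scene.body_axes + 8.0, params.pet_voxel_mm)
    pts_pet = _grid_world(pet_grid)
    sigma_vox = params.pet_psf_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / params.pet_voxel_mm
    mirrored = params.tracer_concordance == "discordant_psma"

    def pet_volume(anat_points: np.ndarray, mirrored_lesion: bool, rng) -> Volume:
        raw = scene.uptake(anat_points, mirrored_lesion).reshape(pet_grid.shape)
        blurred = ndimage.gaussian_filter(raw, sigma_vox)
        return _fill(pet_grid, _add_noise(blurred.ravel(), rng, params.noise_fraction))

    rm2_pet = pet_volume(pts_pet, False, rng_noise)
    psma_pet = pet_volume(psma_to_anat(pts_pet), mirrored, rng_noise)
    rm2_mrac = _fill(pet_grid, _add_noise(scene.mrac(pts_pet), rng_noise, params.noise_fraction))
    psma_mrac = _fill(
        pet_grid, _add_noise(scene.mrac(psma_to_anat(pts_pet)), rng_noise, params.noise_fraction)
    )
    # lesion segmentations: majority-inside rasterization (3^3 subsamples
    # per voxel) so the 2 mm grid tracks the true boundary sub-voxel
    offsets = (np.array(np.meshgrid(*[[-1, 0, 1]] * 3, indexing="ij")).reshape(3, -1).T
               * params.pet_voxel_mm / 3.0)

    def lesion_raster(to_anat, mirrored_lesion: bool) -> np.ndarray:
        frac = np.zeros(len(pts_pet))
        for off in offsets:
            frac += scene.lesion_inside(to_anat(pts_pet + off), mirrored_lesion)
        return (frac >= len(offsets) / 2.0).astype(np.uint8)

    rm2_lesion_mask = _fill(pet_grid, lesion_raster(lambda p: p, False))
    psma_lesion_mask = _fill(pet_grid, lesion_raster(psma_to_anat, mirrored))

    # -- histology sections ---------------------------------------------------
    # the scene is smooth at the 0.1 mm digitization scale, so each section
    # is evaluated on a 2x coarser lattice and bilinearly refined to 512x512
    nhist = HISTOLOGY_MATRIX
    hspacing = DEFAULT_HISTOLOGY_SPACING_MM
    center_h = np.array([nhist, nhist]) * hspacing / 2.0
    ncoarse = nhist // 2
    u = np.arange(ncoarse) * 2.0 * hspacing
    uu, vv = np.meshgrid(u, u, indexing="ij")
    histo_pts = np.stack([uu, vv], axis=-1).reshape(-1, 2)
    fine_idx = np.stack(
        np.meshgrid(np.arange(nhist) / 2.0, np.arange(nhist) / 2.0, indexing="ij"), axis=0
    )

    histology: list[HistologySlice] = []
    slices: list[SliceTruth] = []
    sigma_lm = params.landmark_noise_mm
    for i, (k, z) in enumerate(zip(k_sections, z_sections)):
        ang = rng_jit.uniform(-params.jitter_max_rotation_deg, params.jitter_max_rotation_deg)
        tr = rng_jit.uniform(-params.jitter_max_translation_mm, params.jitter_max_translation_mm, 2)
        rot2 = similarity_2d(ang, 1.0, (0.0, 0.0))
        # histology world -> ex vivo in-plane (moving -> fixed truth)
        jitter = AffineTransform(rot2.matrix, tr - rot2.matrix @ center_h, kind="rigid")
        jitter_inv = jitter.inverse()

        # fiducial landmark truth: strand crossings of this cutting plane
        fx, labels = [], []
        for j, st in enumerate(strands):
            for tag, xy in zip(("a", "b"), st.plane_crossings(z)):
                fx.append(xy)
                labels.append(f"s{j}{tag}")
        f_ex = np.asarray(fx)

        # render the section by sampling the ex vivo scene on the cut plane;
        # the strand holes are small disks at the crossing points
        plane_xy = jitter(histo_pts)
        plane3 = np.column_stack([plane_xy, np.full(len(plane_xy), z)])
        anat = gt_exvivo_to_invivo(plane3)
        img = scene.histology(anat)
        d_holes = np.min(
            np.linalg.norm(plane_xy[:, None, :] - f_ex[None, :, :], axis=2), axis=1
        )
        img = (img * (1.0 - 0.9 * _sigmoid((0.5 - d_holes) / 0.08))).reshape(ncoarse, ncoarse)
        img = ndimage.map_coordinates(img, fine_idx, order=1, mode="nearest")
        img = _add_noise(img.ravel(), rng_noise, params.noise_fraction).reshape(nhist, nhist)
        annot = scene.lesion_inside(anat).reshape(ncoarse, ncoarse)
        annot = ndimage.map_coordinates(
            annot.astype(float), fine_idx, order=1, mode="nearest"
        ) >= 0.5
        histology.append(HistologySlice(img, annot, hspacing, section_index_hint=int(k)))
        f_hist = jitter_inv(f_ex)
        f_ex3 = np.column_stack([f_ex, np.full(len(f_ex), z)])
        f_in = gt_exvivo_to_invivo(f_ex3)

        # eight well-spread validation targets inside the gland cross-section
        in_plane = gland_mask[:, :, k]
        if in_plane.sum() < params.n_tre_targets:
            raise ValueError(f"section {i} has fewer than {params.n_tre_targets} interior voxels")
        ix, iy = np.nonzero(in_plane)
        xy = exvivo.voxel_to_world(np.column_stack([ix, iy, np.full(ix.size, k)]))[:, :2]
        c2 = xy.mean(axis=0)
        semi2 = (xy.max(axis=0) - xy.min(axis=0)) / 2.0
        angles = np.linspace(0, 2 * np.pi, params.n_tre_targets, endpoint=False)
        angles = angles + rng_lm.uniform(0, 2 * np.pi / params.n_tre_targets)
        frac = 0.55
        while frac > 0.1:
            t_ex = c2 + frac * semi2 * np.column_stack([np.cos(angles), np.sin(angles)])
            t3 = np.column_stack([t_ex, np.full(len(t_ex), z)])
            if np.all(scene.gland_level(gt_exvivo_to_invivo(t3)) <= 0.95):
                break
            frac -= 0.05
        t_hist = jitter_inv(t_ex)
        t_in = gt_exvivo_to_invivo(t3)
        tlabels = [f"t{m}" for m in range(params.n_tre_targets)]

        def lset(pts, lab, space):
            return LandmarkSet(pts, lab, space)

        slices.append(
            SliceTruth(
                index=int(k),
                z_mm=float(z),
                jitter=jitter,
                fiducials_histology=lset(f_hist, labels, "histology"),
                fiducials_exvivo=lset(f_ex3, labels, "exvivo"),
                fiducials_invivo=lset(f_in, labels, "invivo"),
                fiducials_histology_noisy=lset(_noisy(f_hist, rng_lm, sigma_lm), labels, "histology"),
                fiducials_exvivo_noisy=lset(_noisy(f_ex3, rng_lm, sigma_lm), labels, "exvivo"),
                targets_histology=lset(t_hist, tlabels, "histology"),
                targets_exvivo=lset(t3, tlabels, "exvivo"),
                targets_invivo=lset(t_in, tlabels, "invivo"),
                targets_histology_noisy=lset(_noisy(t_hist, rng_lm, sigma_lm), tlabels, "histology"),
                targets_exvivo_noisy=lset(_noisy(t3, rng_lm, sigma_lm), tlabels, "exvivo"),
                targets_invivo_noisy=lset(_noisy(t_in, rng_lm, sigma_lm), tlabels, "invivo"),
            )
        )

    return PhantomStudy(
        params=params,
        invivo_t2w=invivo_t2w,
        exvivo_t1w=exvivo_t1w,
        exvivo_t2w=exvivo_t2w,
        rm2_mrac=rm2_mrac,
        psma_mrac=psma_mrac,
        rm2_pet=rm2_pet,
        psma_pet=psma_pet,
        rm2_lesion_mask=rm2_lesion_mask,
        psma_lesion_mask=psma_lesion_mask,
        exvivo_gland_mask=exvivo_gland_mask,
        histology=histology,
        slices=slices,
        gt_exvivo_to_invivo=gt_exvivo_to_invivo,
        gt_invivo_to_psma=gt_invivo_to_psma,
    )


def make_tre_targets(study: PhantomStudy, slice_index: int) -> tuple[LandmarkSet, LandmarkSet]:
    """The paired noisy validation targets of one section: (histology 2D,
    ex vivo 3D) annotations, eight points each, never used for fitting."""
    for st in study.slices:
        if st.index == slice_index:
            return st.targets_histology_noisy, st.targets_exvivo_noisy
    raise KeyError(f"no histology section at ex vivo index {slice_index}")
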