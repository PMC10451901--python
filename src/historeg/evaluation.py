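"""Validation metrics for the co-registration workflow.

Target registration error (TRE) is the Euclidean distance, in mm, between a
validation point mapped through the estimated transform, T(P1), and its true
counterpart P0, computed on points never used to fit the transform.  Slice
overlap is measured with the DICE score 2|A∩B|/(|A|+|B|).  TRE distributions
across the registration steps (histology↔ex vivo, ex vivo↔in vivo,
histology↔in vivo) are compared with a Kruskal–Wallis omnibus test followed
by pairwise Wilcoxon signed-rank tests with Benjamini–Hochberg false
discovery rate correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import LandmarkSet, Transform, Volume, apply_to_points

TRE_POINTS_PER_SLICE = 8  # validation targets annotated per section


def tre(transform: Transform, moved_points: LandmarkSet, target_points: LandmarkSet) -> np.ndarray:
    """Per-point target registration error ‖T(P1_i) − P0_i‖ in mm.

    ``moved_points`` are the P1 annotations in the space the transform maps
    from; ``target_points`` the P0 annotations in the space it maps into.
    Labels must match pairwise.
    """
    moved_points.check_paired(target_points)
    mapped = apply_to_points(transform, moved_points)
    return np.linalg.norm(mapped.points - target_points.points, axis=1)


def dice(a, b) -> float:
    """DICE overlap 2|A∩B|/(|A|+|B|) between two binary masks.

    Accepts arrays or Volumes on congruent grids; two empty masks give 0
    with a warning (no region to compare).
    """
    if isinstance(a, Volume) and isinstance(b, Volume):
        if not a.same_geometry(b):
            raise ValueError("DICE requires masks on the same grid geometry")
        a, b = a.voxels, b.voxels
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    a = a > 0
    b = b > 0
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        warnings.warn("DICE of two empty masks is undefined; returning 0", stacklevel=2)
        return 0.0
    return 2.0 * int(np.logical_and(a, b).sum()) / denom


def summarize_dice(per_slice: list[float] | np.ndarray) -> dict:
    """Median and min–max range of per-slice DICE scores, rounded to two
    decimals for reporting (midpoint median for even n)."""
    values = np.asarray(per_slice, dtype=float)
    if values.size == 0:
        raise ValueError("no per-slice DICE values to summarize")
    return {
        "median": round(float(np.median(values)), 2),
        "range": (round(float(values.min()), 2), round(float(values.max()), 2)),
        "n": int(values.size),
    }


@dataclass
class TREReport:
    """Per-step TRE distributions with summary statistics and the
    nonparametric step comparison."""

    distances: dict[str, np.ndarray]
    medians: dict[str, float] = field(default_factory=dict)
    iqrs: dict[str, tuple[float, float]] = field(default_factory=dict)
    kruskal_h: float = float("nan")
    kruskal_p: float = float("nan")
    pairwise_p_raw: dict[str, float] = field(default_factory=dict)
    pairwise_p_adjusted: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "medians": self.medians,
            "iqrs": {k: list(v) for k, v in self.iqrs.items()},
            "kruskal_h": self.kruskal_h,
            "kruskal_p": self.kruskal_p,
            "pairwise_p_raw": self.pairwise_p_raw,
            "pairwise_p_adjusted": self.pairwise_p_adjusted,
        }


def wilcoxon_signed_rank(x, y) -> float:
    """Paired Wilcoxon signed-rank p value (two-sided).

    Zero differences are dropped (Wilcoxon's original treatment); the exact
    null distribution is used for n ≤ 25 without ties, the tie-corrected
    normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0.0]
    if d.size == 0:
        return 1.0
    n = d.size
    has_ties = np.unique(np.abs(d)).size < n
    method = "approx" if (has_ties or n > 25) else "exact"
    return float(stats.wilcoxon(d, zero_method="wilcox", correction=False, method=method).pvalue)


def benjamini_hochberg(p_values) -> np.ndarray:
    """Step-up FDR adjustment of a family of raw p values."""
    p = np.asarray(p_values, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def compare_tre_groups(groups: dict[str, np.ndarray]) -> TREReport:
    """Compare TRE across the three registration pairs.

    ``groups`` maps a step name to its pooled per-point distances; the three
    samples must be matched one-to-one (same validation points) for the
    pairwise signed-rank tests.
    """
    if len(groups) != 3:
        raise ValueError("expected exactly three TRE groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    sizes = {len(v) for v in arrays.values()}
    if len(sizes) != 1:
        raise ValueError("TRE groups must contain matched points (equal lengths)")
    (n,) = sizes
    if n < 2:
        raise ValueError("need at least two points per group")

    report = TREReport(distances=arrays)
    for name, v in arrays.items():
        report.medians[name] = float(np.median(v))
        q1, q3 = np.percentile(v, [25, 75])
        report.iqrs[name] = (float(q1), float(q3))

    pooled = np.concatenate(list(arrays.values()))
    if np.ptp(pooled) == 0:
        report.kruskal_h, report.kruskal_p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*arrays.values())
        report.kruskal_h, report.kruskal_p = float(h), float(p)

    names = list(arrays)
    pairs = [(names[0], names[1]), (names[0], names[2]), (names[1], names[2])]
    raw = [wilcoxon_signed_rank(arrays[a], arrays[b]) for a, b in pairs]
    adjusted = benjamini_hochberg(raw)
    for (a, b), pr, pa in zip(pairs, raw, adjusted):
        key = f"{a} vs {b}"
        report.pairwise_p_raw[key] = float(pr)
        report.pairwise_p_adjusted[key] = float(max(pa, pr))
    return report


def per_slice_dice(
    histology_volume: Volume, pet_mask_volume: Volume, slice_indices: list[int]
) -> dict[int, float]:
    """2D DICE between the embedded histology annotation and a co-registered
    PET lesion mask, slice by slice on the common ex vivo grid."""
    if not histology_volume.same_geometry(pet_mask_volume):
        raise ValueError("volumes must share the ex vivo grid geometry")
    out = {}
    for k in slice_indices:
        a = histology_volume.voxels[:, :, k]
        b = pet_mask_volume.voxels[:, :, k]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out[k] = dice(a, b)
    return out
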