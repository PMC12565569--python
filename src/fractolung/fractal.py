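"""The three morphometric-complexity biomarkers: BoxFD, lacunarity, MSTFD.

Box-counting fractal dimension (BoxFD)
    Cover the occupied set with grid-aligned cubic boxes of edge ``s`` and
    count the boxes N(s) containing at least one occupied voxel.  The
    estimate is the least-squares slope of log N(s) vs log(1/s): a
    space-filling set scores 3, a plane 2, a line 1.  The counting grid is
    anchored at the corner of the mask's bounding box (single origin, no
    multi-offset averaging), which makes the count translation invariant.

Lacunarity
    Gliding-box statistic of mass-distribution heterogeneity.  For a box
    edge ``r``, every fully-interior r-cube window (stride 1) contributes
    its occupied-voxel mass M; the per-scale lacunarity is
    lambda(r) = Var(M) / Mean(M)^2 (squared coefficient of variation, so a
    homogeneous pattern scores 0).  The scalar estimate is the arithmetic
    mean of lambda(r) over the requested box sizes.  Higher values mean a
    gappier / clumpier texture.

MST fractal dimension (MSTFD)
    For subsets of n occupied-voxel coordinates, the total Euclidean edge
    length L(n) of a minimum spanning tree scales as L ~ n^((D-1)/D) for a
    D-dimensional support.  Fitting the slope m of log L vs log n over a
    schedule of subsample sizes gives D = 1 / (1 - m).  Full-volume MSTs
    (10^6+ voxels) are infeasible, so L(n) is averaged over seeded random
    subsamples.

Anisotropy: box counting and lacunarity run on an isotropically resampled
mask (cubic cells); the MST needs only pairwise distances and uses the
physical mm coordinates of the original voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from fractolung.errors import (
    ConfigurationError,
    DegenerateEstimateError,
    UndefinedMetricError,
)
from fractolung.io import BinaryMask3D, resample_isotropic


@dataclass
class ScaleCurve:
    """Per-scale measurements underlying a log-log dimension fit."""

    scales: np.ndarray  # strictly increasing box edges (voxels) or subset sizes
    values: np.ndarray  # box counts, lacunarities, or mean MST lengths
    fit_range: tuple[float, float]  # (min_scale, max_scale) used in regression

    def __post_init__(self) -> None:
        self.scales = np.asarray(self.scales, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.scales.shape != self.values.shape:
            raise ConfigurationError("scales and values must have equal length")
        if np.any(np.diff(self.scales) <= 0):
            raise ConfigurationError("scales must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise UndefinedMetricError("scale curve contains non-finite values")


@dataclass
class FractalProfile:
    """Per-scan biomarker triple with fit diagnostics."""

    boxfd: float
    lacunarity: float
    mstfd: float
    diagnostics: dict = field(default_factory=dict)

    def as_row(self, prefix: str = "") -> dict:
        """Flat dict for cohort-table assembly."""
        return {
            f"{prefix}boxfd": self.boxfd,
            f"{prefix}lacunarity": self.lacunarity,
            f"{prefix}mstfd": self.mstfd,
        }


@dataclass
class DeltaProfile:
    """Post-minus-pre differences of the three biomarkers."""

    d_boxfd: float
    d_lacunarity: float
    d_mstfd: float

    def as_row(self) -> dict:
        return {
            "d_boxfd": self.d_boxfd,
            "d_lacunarity": self.d_lacunarity,
            "d_mstfd": self.d_mstfd,
        }


# ---------------------------------------------------------------------------
# Box counting
# ---------------------------------------------------------------------------

def _crop_to_bbox(occ: np.ndarray) -> np.ndarray:
    idx = np.argwhere(occ)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    return occ[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]


def box_counts(occ: np.ndarray, scales: Sequence[int]) -> np.ndarray:
    """N(s): number of grid-aligned s-boxes containing >= 1 occupied voxel.

    The grid is anchored at the corner of ``occ`` (callers crop to the
    bounding box first); partial boxes at the far edges are counted.
    """
    occ = np.asarray(occ, dtype=bool)
    counts = []
    for s in scales:
        s = int(s)
        if s < 1:
            raise ConfigurationError(f"box scale must be >= 1, got {s}")
        pads = [(0, (-d) % s) for d in occ.shape]
        a = np.pad(occ, pads) if any(p[1] for p in pads) else occ
        nx, ny, nz = (d // s for d in a.shape)
        blocks = a.reshape(nx, s, ny, s, nz, s).any(axis=(1, 3, 5))
        counts.append(int(blocks.sum()))
    return np.asarray(counts, dtype=float)


def default_box_scales(shape: Sequence[int]) -> list[int]:
    """Powers of 2 from 1 up to a quarter of the smallest grid dimension."""
    limit = max(4, min(shape) // 4)
    scales, s = [], 1
    while s <= limit:
        scales.append(s)
        s *= 2
    return scales


def _loglog_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares slope of log y vs log x, with fit R^2."""
    lx, ly = np.log(x), np.log(y)
    slope, intercept = np.polyfit(lx, ly, 1)
    pred = slope * lx + intercept
    ss_res = float(np.sum((ly - pred) ** 2))
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(slope), r2


def box_counting_dimension(
    mask: BinaryMask3D | np.ndarray,
    scales: Sequence[int] | None = None,
    fit_range: tuple[float, float] | None = None,
) -> tuple[float, ScaleCurve]:
    """Box-counting fractal dimension of a binary mask.

    Parameters
    ----------
    mask : binary mask (assumed already isotropic; resample first if not).
    scales : box edge lengths in voxels; default powers of 2 from 1 to a
        quarter of the smallest bounding-box dimension.
    fit_range : (min_scale, max_scale) restricting the regression; at least
        three scales must fall inside.

    Returns
    -------
    (estimate, curve) : slope of log N vs log(1/s) over the fit range, and
        the full count curve with diagnostics in ``curve.fit_range``.
    """
    occ = mask.occupancy if isinstance(mask, BinaryMask3D) else np.asarray(mask, bool)
    if not occ.any():
        raise UndefinedMetricError("box-counting dimension is undefined on an empty mask")
    occ = _crop_to_bbox(occ)
    if scales is None:
        scales = default_box_scales(occ.shape)
    scales = sorted(int(s) for s in set(scales))
    counts = box_counts(occ, scales)
    scales_arr = np.asarray(scales, dtype=float)
    if fit_range is None:
        fit_range = (scales_arr[0], scales_arr[-1])
    in_fit = (scales_arr >= fit_range[0]) & (scales_arr <= fit_range[1])
    if in_fit.sum() < 3:
        raise ConfigurationError(
            f"need >= 3 scales inside fit_range {fit_range}, have {int(in_fit.sum())}"
        )
    # slope of log N vs log(1/s); equals -d log N / d log s
    slope, r2 = _loglog_fit(1.0 / scales_arr[in_fit], counts[in_fit])
    curve = ScaleCurve(scales_arr, counts, tuple(fit_range))
    curve.r_squared = r2
    return slope, curve


# ---------------------------------------------------------------------------
# Lacunarity
# ---------------------------------------------------------------------------

def _window_sums(arr: np.ndarray, r: int) -> np.ndarray:
    """Masses of all fully-interior r-cube windows (stride 1), via an
    integral volume."""
    p = np.zeros(tuple(s + 1 for s in arr.shape))
    p[1:, 1:, 1:] = arr.cumsum(0).cumsum(1).cumsum(2)
    return (
        p[r:, r:, r:] - p[:-r, r:, r:] - p[r:, :-r, r:] - p[r:, r:, :-r]
        + p[:-r, :-r, r:] + p[:-r, r:, :-r] + p[r:, :-r, :-r] - p[:-r, :-r, :-r]
    )


def lacunarity(
    mask: BinaryMask3D | np.ndarray,
    box_sizes: Sequence[int] = (2, 4, 8, 16),
) -> tuple[float, ScaleCurve]:
    """Gliding-box lacunarity, averaged over ``box_sizes``.

    The gliding window slides with stride 1 over the full array (windows
    entirely inside the grid); lambda(r) = Var(M)/Mean(M)^2 with population
    variance.  Values are >= 0, with 0 for translation-invariant patterns.
    Note the statistic is NOT symmetric under voxel-value complementation:
    the mask and its complement generally score differently.
    """
    occ = mask.occupancy if isinstance(mask, BinaryMask3D) else np.asarray(mask, bool)
    if not occ.any():
        raise UndefinedMetricError("lacunarity is undefined on an empty mask")
    box_sizes = sorted(int(r) for r in set(box_sizes))
    if box_sizes[0] < 1:
        raise ConfigurationError("box sizes must be >= 1")
    if box_sizes[-1] > min(occ.shape):
        raise ConfigurationError(
            f"largest box size {box_sizes[-1]} exceeds smallest grid "
            f"dimension {min(occ.shape)}"
        )
    a = occ.astype(np.float64)
    lams = []
    for r in box_sizes:
        masses = _window_sums(a, r)
        mean = masses.mean()
        if mean == 0:
            raise UndefinedMetricError(
                f"mean gliding-box mass is zero at box size {r}"
            )
        lams.append(float(masses.var() / mean**2))
    curve = ScaleCurve(np.asarray(box_sizes, float), np.asarray(lams),
                       (float(box_sizes[0]), float(box_sizes[-1])))
    return float(np.mean(lams)), curve


# ---------------------------------------------------------------------------
# Minimum spanning tree
# ---------------------------------------------------------------------------

def mst_total_length(points: np.ndarray) -> float:
    """Total Euclidean edge length of a minimum spanning tree.

    The MST itself need not be unique (tied edges), but its total length is.
    Implemented as Prim's algorithm with lazily computed distances, O(n^2)
    time and O(n) memory, so subsamples of several thousand voxels are cheap.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or len(pts) < 2:
        raise ConfigurationError("MST needs >= 2 points of equal dimension")
    n = len(pts)
    # distance from each out-of-tree point to its nearest in-tree point
    best = np.linalg.norm(pts - pts[0], axis=1)
    best[0] = np.inf  # never re-add the root
    in_tree = np.zeros(n, dtype=bool)
    in_tree[0] = True
    total = 0.0
    masked = best.copy()
    for _ in range(n - 1):
        j = int(np.argmin(masked))
        total += masked[j]
        in_tree[j] = True
        d = np.linalg.norm(pts - pts[j], axis=1)
        best = np.minimum(best, d)
        masked = np.where(in_tree, np.inf, best)
    return float(total)


def mst_dimension_from_points(
    points: np.ndarray,
    subsample_sizes: Sequence[int] = (256, 512, 1024, 2048, 4096),
    reps: int = 10,
    seed: int = 0,
) -> tuple[float, ScaleCurve]:
    """MST fractal dimension of a point set via subsample scaling.

    For each n in ``subsample_sizes``, ``reps`` random n-subsets are drawn
    (without replacement, seeded) and the mean MST length L(n) recorded; the
    slope m of log L vs log n gives D = 1/(1 - m).  A slope m >= 1 has no
    finite dimension and raises :class:`DegenerateEstimateError` carrying the
    raw slope.
    """
    pts = np.asarray(points, dtype=float)
    sizes = sorted(int(n) for n in set(subsample_sizes))
    if len(sizes) < 3:
        raise ConfigurationError("need >= 3 subsample sizes")
    if sizes[0] < 2:
        raise ConfigurationError("subsample sizes must be >= 2")
    if len(pts) < sizes[-1]:
        raise ConfigurationError(
            f"point count {len(pts)} is below the largest subsample size {sizes[-1]}"
        )
    rng = np.random.default_rng(seed)
    mean_lengths = []
    for n in sizes:
        lengths = []
        for _ in range(int(reps)):
            idx = rng.choice(len(pts), size=n, replace=False)
            lengths.append(mst_total_length(pts[idx]))
        mean_lengths.append(float(np.mean(lengths)))
    sizes_arr = np.asarray(sizes, dtype=float)
    slope, r2 = _loglog_fit(sizes_arr, np.asarray(mean_lengths))
    if slope >= 1.0:
        raise DegenerateEstimateError(
            f"log L vs log n slope {slope:.4f} >= 1 has no finite dimension",
            slope=slope,
        )
    estimate = 1.0 / (1.0 - slope)
    curve = ScaleCurve(sizes_arr, np.asarray(mean_lengths),
                       (sizes_arr[0], sizes_arr[-1]))
    curve.r_squared = r2
    curve.slope = slope
    return float(estimate), curve


def mst_fractal_dimension(
    mask: BinaryMask3D,
    subsample_sizes: Sequence[int] = (256, 512, 1024, 2048, 4096),
    reps: int = 10,
    seed: int = 0,
) -> tuple[float, ScaleCurve]:
    """MST fractal dimension of a mask's occupied voxels (physical mm
    coordinates of the original, possibly anisotropic, grid)."""
    if mask.n_occupied < max(int(n) for n in subsample_sizes):
        raise ConfigurationError(
            f"mask has {mask.n_occupied} occupied voxels, below the largest "
            f"subsample size {max(subsample_sizes)}"
        )
    return mst_dimension_from_points(
        mask.coordinates_mm(), subsample_sizes, reps=reps, seed=seed
    )


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------

@dataclass
class ProfileSettings:
    """All knobs for a per-scan biomarker profile; every field is recorded in
    the profile diagnostics."""

    resample_mm: float = 1.0
    box_scales: tuple[int, ...] | None = None  # None -> powers of 2
    box_fit_range: tuple[float, float] | None = None
    lac_box_sizes: tuple[int, ...] = (2, 4, 8, 16)
    mst_subsample_sizes: tuple[int, ...] = (256, 512, 1024, 2048, 4096)
    mst_reps: int = 10
    seed: int = 0

    def as_dict(self) -> dict:
        return {
            "resample_mm": self.resample_mm,
            "box_scales": list(self.box_scales) if self.box_scales else None,
            "box_fit_range": list(self.box_fit_range) if self.box_fit_range else None,
            "lac_box_sizes": list(self.lac_box_sizes),
            "mst_subsample_sizes": list(self.mst_subsample_sizes),
            "mst_reps": self.mst_reps,
            "seed": self.seed,
        }


def compute_single_profile(
    mask: BinaryMask3D, settings: ProfileSettings = ProfileSettings()
) -> FractalProfile:
    """BoxFD + lacunarity (on the isotropically resampled mask) and MSTFD
    (on physical voxel coordinates) for one scan."""
    iso = resample_isotropic(mask, settings.resample_mm)
    boxfd, box_curve = box_counting_dimension(
        iso, settings.box_scales, settings.box_fit_range
    )
    lac, lac_curve = lacunarity(iso, settings.lac_box_sizes)
    mstfd, mst_curve = mst_fractal_dimension(
        mask,
        settings.mst_subsample_sizes,
        reps=settings.mst_reps,
        seed=settings.seed,
    )
    flags = []
    if not 0.0 <= boxfd <= 3.0:
        flags.append(f"boxfd {boxfd:.4f} outside [0, 3]")
    if not 0.0 <= mstfd <= 3.0:
        flags.append(f"mstfd {mstfd:.4f} outside [0, 3]")
    diagnostics = {
        "settings": settings.as_dict(),
        "box_scales": box_curve.scales.tolist(),
        "box_counts": box_curve.values.tolist(),
        "box_r2": getattr(box_curve, "r_squared", None),
        "lac_box_sizes": lac_curve.scales.tolist(),
        "lac_per_scale": lac_curve.values.tolist(),
        "mst_subsample_sizes": mst_curve.scales.tolist(),
        "mst_mean_lengths": mst_curve.values.tolist(),
        "mst_r2": getattr(mst_curve, "r_squared", None),
        "seed": settings.seed,
        "flags": flags,
    }
    return FractalProfile(boxfd=boxfd, lacunarity=lac, mstfd=mstfd,
                          diagnostics=diagnostics)


def compute_profile(
    pre_mask: BinaryMask3D,
    post_mask: BinaryMask3D,
    settings: ProfileSettings = ProfileSettings(),
) -> tuple[FractalProfile, FractalProfile, DeltaProfile]:
    """Profiles for a pre/post scan pair plus their exact differences
    (post minus pre)."""
    pre = compute_single_profile(pre_mask, settings)
    post = compute_single_profile(post_mask, settings)
    delta = DeltaProfile(
        d_boxfd=post.boxfd - pre.boxfd,
        d_lacunarity=post.lacunarity - pre.lacunarity,
        d_mstfd=post.mstfd - pre.mstfd,
    )
    return pre, post, delta
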