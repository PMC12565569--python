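"""Synthetic phantoms, paired pre/post volumes, and cohorts.

This module stands in for patient CT data: it generates (a) binary phantom
volumes with analytically known complexity (filled cube -> BoxFD 3, plane ->
BoxFD 2, Menger sponge -> log20/log3, smoothed-noise textures resembling
normal-attenuation-area masks), (b) paired pre/post volumes with a planted
lacunarity change and stable box-counting dimension, emulating the
radiation-induced texture coarsening seen after radiotherapy, and (c)
per-patient feature tables whose pneumonitis labels follow a planted
shallow threshold tree, so feature-ranking and tree-recovery behaviour can
be tested against ground truth.

All generators are deterministic for a fixed seed (seeds are spawned from a
``numpy.random.SeedSequence`` so sub-streams never collide).
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from fractolung.errors import ConfigurationError, GenerationError
from fractolung.fractal import box_counting_dimension, lacunarity
from fractolung.io import BinaryMask3D

PHANTOM_KINDS = (
    "filled_cube",
    "plane",
    "menger_sponge",
    "random_dust",
    "thresholded_field",
    "line_points",
    "plane_points",
    "uniform_points",
)


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for a binary phantom volume of edge ``size`` voxels.

    ``level`` applies to menger_sponge (requires size = 3**level);
    ``occupancy`` to random_dust / thresholded_field / plane_points /
    uniform_points; ``correlation_length`` (voxels) to thresholded_field.
    """

    kind: str
    size: int
    level: int = 0
    occupancy: float = 0.5
    correlation_length: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in PHANTOM_KINDS:
            raise ConfigurationError(
                f"unknown phantom kind {self.kind!r}; choose from {PHANTOM_KINDS}"
            )
        if self.size < 1:
            raise ConfigurationError(f"size must be positive, got {self.size}")
        if self.kind == "menger_sponge":
            if self.level < 0:
                raise ConfigurationError("menger_sponge level must be >= 0")
            if self.size != 3**self.level:
                raise ConfigurationError(
                    f"menger_sponge requires size = 3**level; got size={self.size}, "
                    f"level={self.level} (3**level = {3**self.level})"
                )
        if not 0.0 < self.occupancy <= 1.0:
            raise ConfigurationError(
                f"occupancy must be in (0, 1], got {self.occupancy}"
            )
        if self.correlation_length <= 0:
            raise ConfigurationError("correlation_length must be > 0")


def _menger_occupied(size: int, level: int) -> np.ndarray:
    """Menger sponge by base-3 digit test: a voxel is removed iff at some
    recursion depth at least two of its three base-3 digits equal 1 (the
    standard subdivide-into-27, keep-the-20-off-center-children rule)."""
    idx = np.indices((size, size, size))
    keep = np.ones((size, size, size), dtype=bool)
    for d in range(level):
        p = 3**d
        digits = (idx // p) % 3
        center_hits = (digits == 1).sum(axis=0)
        keep &= center_hits < 2
    return keep


def generate_phantom(spec: PhantomSpec) -> BinaryMask3D:
    """Deterministic phantom volume of shape (size, size, size), unit spacing."""
    s = spec.size
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "filled_cube":
        occ = np.ones((s, s, s), dtype=bool)
    elif spec.kind == "plane":
        occ = np.zeros((s, s, s), dtype=bool)
        occ[:, :, s // 2] = True
    elif spec.kind == "menger_sponge":
        occ = _menger_occupied(s, spec.level)
    elif spec.kind in ("random_dust", "uniform_points"):
        n = max(1, int(round(spec.occupancy * s**3)))
        flat = rng.choice(s**3, size=n, replace=False)
        occ = np.zeros(s**3, dtype=bool)
        occ[flat] = True
        occ = occ.reshape(s, s, s)
    elif spec.kind == "thresholded_field":
        occ = _thresholded_field(s, spec.occupancy, spec.correlation_length, rng)
    elif spec.kind == "line_points":
        occ = np.zeros((s, s, s), dtype=bool)
        occ[:, s // 2, s // 2] = True
    elif spec.kind == "plane_points":
        n = max(1, int(round(spec.occupancy * s**2)))
        flat = rng.choice(s**2, size=n, replace=False)
        plane = np.zeros(s**2, dtype=bool)
        plane[flat] = True
        occ = np.zeros((s, s, s), dtype=bool)
        occ[:, :, s // 2] = plane.reshape(s, s)
    else:  # pragma: no cover - guarded by PhantomSpec
        raise ConfigurationError(spec.kind)
    if not occ.any():
        raise GenerationError(f"phantom {spec.kind!r} came out empty")
    return BinaryMask3D(occ, (1.0, 1.0, 1.0))


def _top_k_mask(score: np.ndarray, occupancy: float) -> np.ndarray:
    """Exact-count thresholding: the top round(occupancy * N) scores are
    occupied, so the occupied count is identical across realizations."""
    k = max(1, int(round(occupancy * score.size)))
    thresh = np.partition(score.ravel(), -k)[-k]
    return score >= thresh


def _thresholded_field(
    size: int, occupancy: float, correlation_length: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian-smoothed white noise thresholded at the exact-count quantile.
    Periodic smoothing keeps the texture stationary."""
    noise = rng.standard_normal((size, size, size))
    f = ndimage.gaussian_filter(noise, sigma=correlation_length, mode="wrap")
    return _top_k_mask(f, occupancy)


def generate_point_cloud(
    kind: str, n: int, seed: int = 0, extent: float = 100.0
) -> np.ndarray:
    """Continuous point sets of known dimension for MSTFD validation.

    kind 'line' -> uniform on a segment (D=1); 'plane' -> uniform in a square
    (D=2); 'volume' -> uniform in a cube (D=3).  Coordinates in mm, 3 columns.
    """
    rng = np.random.default_rng(seed)
    if n < 2:
        raise ConfigurationError("need n >= 2 points")
    if kind == "line":
        t = rng.uniform(0, extent, size=n)
        return np.column_stack([t, np.zeros(n), np.zeros(n)])
    if kind == "plane":
        xy = rng.uniform(0, extent, size=(n, 2))
        return np.column_stack([xy, np.zeros(n)])
    if kind == "volume":
        return rng.uniform(0, extent, size=(n, 3))
    raise ConfigurationError(f"unknown point-cloud kind {kind!r}")


# ---------------------------------------------------------------------------
# Paired pre/post volumes with a planted lacunarity effect
# ---------------------------------------------------------------------------

_PAIRABLE_KINDS = ("thresholded_field", "random_dust", "uniform_points")


@dataclass(frozen=True)
class PairedEffectSpec:
    """Paired pre/post phantoms with a planted lacunarity change.

    ``lacunarity_shift`` is the sign and minimum magnitude of the post-minus-
    pre lacunarity difference.  The mechanism adds a weak large-scale
    occupancy modulation to the score field of one member of the pair before
    exact-count thresholding, so the modulated volume has the same voxel
    count but a clumpier mass distribution (higher gliding-box lacunarity)
    while the box-counting scaling is untouched.  ``preserve_boxfd_tol``
    bounds |BoxFD(post) - BoxFD(pre)| as measured by this package's own
    estimator.  ``mod_sigma`` is the modulation's Gaussian correlation length
    in voxels; ``mod_amplitude`` is the starting amplitude relative to the
    base score's unit standard deviation, escalated across retries until the
    requested shift is reached.
    """

    base: PhantomSpec
    lacunarity_shift: float = 0.02
    preserve_boxfd_tol: float = 0.05
    seed: int = 0
    max_retries: int = 20
    mod_sigma: float = 10.0
    mod_amplitude: float = 0.08

    def __post_init__(self) -> None:
        if self.preserve_boxfd_tol < 0:
            raise ConfigurationError("preserve_boxfd_tol must be >= 0")
        if self.lacunarity_shift != 0 and self.base.kind not in _PAIRABLE_KINDS:
            raise ConfigurationError(
                "planted lacunarity shifts require a stochastic score-field "
                f"base (one of {_PAIRABLE_KINDS}); got {self.base.kind!r}"
            )
        if self.mod_sigma <= 0 or self.mod_amplitude <= 0:
            raise ConfigurationError("mod_sigma and mod_amplitude must be > 0")


def _standardized(arr: np.ndarray) -> np.ndarray:
    sd = arr.std()
    if sd == 0:
        raise GenerationError("degenerate (constant) score field")
    return (arr - arr.mean()) / sd


def _score_field(base: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance score field whose top-k set reproduces the base kind."""
    s = base.size
    noise = rng.standard_normal((s, s, s))
    if base.kind == "thresholded_field":
        noise = ndimage.gaussian_filter(
            noise, sigma=base.correlation_length, mode="wrap"
        )
    return _standardized(noise)


def _modulated_mask(
    base: PhantomSpec, rng: np.random.Generator, amplitude: float, mod_sigma: float
) -> BinaryMask3D:
    score = _score_field(base, rng)
    if amplitude > 0:
        s = base.size
        g = _standardized(
            ndimage.gaussian_filter(
                rng.standard_normal((s, s, s)), sigma=mod_sigma, mode="wrap"
            )
        )
        score = score + amplitude * g
    return BinaryMask3D(_top_k_mask(score, base.occupancy), (1.0, 1.0, 1.0))


def generate_paired_volumes(
    spec: PairedEffectSpec,
) -> tuple[BinaryMask3D, BinaryMask3D]:
    """Generate a (pre, post) mask pair realizing the planted effect.

    Both volumes are independent realizations of the base texture at exactly
    the same occupied-voxel count; the post volume (pre for a negative shift)
    additionally carries the large-scale occupancy modulation.  Candidates
    are re-drawn with escalating modulation amplitude (bounded retries,
    seeded) until the measured lacunarity difference has the requested sign
    and magnitude and the BoxFD change is within tolerance; failure raises
    :class:`GenerationError` naming the violated constraint.
    """
    base = spec.base
    ss = np.random.SeedSequence(spec.seed)
    plain_ss, *attempt_ss = ss.spawn(1 + spec.max_retries)
    plain = _modulated_mask(
        base, np.random.default_rng(plain_ss), 0.0, spec.mod_sigma
    )
    if spec.lacunarity_shift == 0:
        return plain, plain.copy()

    lac_plain, _ = lacunarity(plain)
    boxfd_plain, _ = box_counting_dimension(plain)
    direction = 1.0 if spec.lacunarity_shift > 0 else -1.0
    amplitude = spec.mod_amplitude
    last_violation = "no attempts made"
    for child in attempt_ss:
        mod = _modulated_mask(
            base, np.random.default_rng(child), amplitude, spec.mod_sigma
        )
        lac_mod, _ = lacunarity(mod)
        boxfd_mod, _ = box_counting_dimension(mod)
        # the modulated member always has the higher lacunarity; it becomes
        # post for a positive shift and pre for a negative one
        excess = lac_mod - lac_plain
        d_box = boxfd_mod - boxfd_plain
        if excess < abs(spec.lacunarity_shift):
            last_violation = (
                f"lacunarity shift {direction * excess:+.5f} did not reach "
                f"requested {spec.lacunarity_shift:+.5f}"
            )
            amplitude *= 1.4
            continue
        if abs(d_box) > spec.preserve_boxfd_tol:
            last_violation = (
                f"|BoxFD change| {abs(d_box):.4f} exceeded tolerance "
                f"{spec.preserve_boxfd_tol}"
            )
            continue
        return (plain, mod) if direction > 0 else (mod, plain)
    raise GenerationError(
        f"paired-volume effect not achievable in {spec.max_retries} retries: "
        f"{last_violation}"
    )


# ---------------------------------------------------------------------------
# Synthetic cohorts with planted decision-tree structure
# ---------------------------------------------------------------------------

#: Uniform marginal ranges bracketing realistic clinical values for an
#: RT-alone-like NSCLC cohort (ages in years, MLD in cGy, Vx in percent,
#: fractal biomarkers dimensionless).
DEFAULT_FEATURE_RANGES: dict[str, tuple[float, float]] = {
    "age": (38.0, 93.0),
    "sex": (0.0, 1.0),
    "smoking": (0.0, 1.0),
    "lung_disease": (0.0, 1.0),
    "mld_cgy": (88.0, 1239.0),
    "v5_pct": (5.3, 59.1),
    "v10_pct": (2.0, 40.0),
    "v20_pct": (0.4, 21.4),
    "boxfd_pre": (2.20, 2.45),
    "lacunarity_pre": (0.10, 0.20),
    "mstfd_pre": (2.69, 2.78),
    "d_boxfd": (-0.08, 0.03),
    "d_lacunarity": (-0.02, 0.06),
    "d_mstfd": (-0.05, 0.02),
}

_BINARY_FEATURES = {"sex", "smoking", "lung_disease"}


@dataclass(frozen=True)
class PlantedRule:
    """One node of a planted decision list: rows with feature > threshold get
    event probability ``p_above``; rows at or below fall to ``p_below`` when
    set, otherwise to the next rule.  The final rule must set ``p_below``."""

    feature: str
    threshold: float
    p_above: float
    p_below: float | None = None

    def __post_init__(self) -> None:
        for p in (self.p_above, self.p_below):
            if p is not None and not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"rule probability {p} outside [0, 1]")


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a synthetic patient table with planted label structure."""

    n_patients: int
    feature_names: tuple[str, ...]
    tree_rules: tuple[PlantedRule, ...]
    noise_features: int = 0
    label_noise: float = 0.0
    seed: int = 0
    feature_ranges: tuple[tuple[str, tuple[float, float]], ...] = ()

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ConfigurationError("n_patients must be >= 2")
        if not self.feature_names:
            raise ConfigurationError("feature_names must be non-empty")
        if not self.tree_rules:
            raise ConfigurationError("tree_rules must be non-empty")
        if self.tree_rules[-1].p_below is None:
            raise ConfigurationError("the final planted rule must set p_below")
        if not 0.0 <= self.label_noise < 0.5:
            raise ConfigurationError("label_noise must be in [0, 0.5)")
        ranges = self.ranges()
        for rule in self.tree_rules:
            if rule.feature not in self.feature_names:
                raise ConfigurationError(
                    f"rule feature {rule.feature!r} not in feature_names"
                )
            lo, hi = ranges[rule.feature]
            if not lo <= rule.threshold <= hi:
                raise ConfigurationError(
                    f"threshold {rule.threshold} for {rule.feature!r} outside "
                    f"its generated range ({lo}, {hi})"
                )

    def ranges(self) -> dict[str, tuple[float, float]]:
        out = dict(DEFAULT_FEATURE_RANGES)
        out.update(dict(self.feature_ranges))
        for name in self.feature_names:
            out.setdefault(name, (0.0, 1.0))
        return out


def apply_planted_rules(
    df: pd.DataFrame, rules: Sequence[PlantedRule]
) -> np.ndarray:
    """Replay a planted decision list; returns per-row event probabilities."""
    n = len(df)
    p = np.full(n, np.nan)
    undecided = np.ones(n, dtype=bool)
    for rule in rules:
        above = df[rule.feature].to_numpy() > rule.threshold
        take = undecided & above
        p[take] = rule.p_above
        undecided &= ~take
        if rule.p_below is not None:
            p[undecided] = rule.p_below
            undecided[:] = False
            break
    if undecided.any():  # defensive; CohortSpec enforces a terminal p_below
        raise ConfigurationError("planted rules leave rows undecided")
    return p


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Synthetic patient table.

    Columns: ``patient_id``, the requested features (uniform marginals over
    :data:`DEFAULT_FEATURE_RANGES`, binary for sex/smoking/lung_disease),
    ``noise_<i>`` label-independent features, ``rp_grade`` (0-5 CTCAE-like)
    and ``label`` (grade >= 2 pneumonitis).  With ``label_noise = 0`` and
    planted probabilities in {0, 1}, labels equal the planted tree's output
    on every row.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_feat, rng_label, rng_noiseflip, rng_grade = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    ranges = spec.ranges()
    data: dict[str, np.ndarray] = {
        "patient_id": np.array([f"P{i:04d}" for i in range(spec.n_patients)])
    }
    for name in spec.feature_names:
        lo, hi = ranges[name]
        if name in _BINARY_FEATURES:
            data[name] = rng_feat.integers(0, 2, size=spec.n_patients).astype(float)
        else:
            data[name] = rng_feat.uniform(lo, hi, size=spec.n_patients)
    for i in range(spec.noise_features):
        data[f"noise_{i}"] = rng_feat.uniform(0, 1, size=spec.n_patients)
    df = pd.DataFrame(data)

    p_event = apply_planted_rules(df, spec.tree_rules)
    label = np.where(
        p_event >= 1.0, True,
        np.where(p_event <= 0.0, False, rng_label.random(spec.n_patients) < p_event),
    ).astype(bool)
    if spec.label_noise > 0:
        flips = rng_noiseflip.random(spec.n_patients) < spec.label_noise
        label = label ^ flips
    # grades consistent with the binary endpoint: events are grade 2-3,
    # non-events grade 0-1
    grade = np.where(
        label,
        rng_grade.choice([2, 3], size=spec.n_patients, p=[0.75, 0.25]),
        rng_grade.choice([0, 1], size=spec.n_patients, p=[0.6, 0.4]),
    )
    df["rp_grade"] = grade.astype(int)
    df["label"] = label
    return df


def cohort_to_csv(df: pd.DataFrame) -> str:
    """Canonical CSV rendering (used for byte-identity determinism checks)."""
    buf = _io.StringIO()
    df.to_csv(buf, index=False)
    return buf.getvalue()
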