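"""Synthetic two-group voxel data with known standardized effects.

The generator emulates the canonical demonstration setup: one fMRI-like
slice, two groups of subjects, circular regions in which group B's mean is
shifted by ``d * noise_sd`` relative to group A, and spatially smooth
Gaussian noise whose per-voxel marginal SD is renormalized to ``noise_sd``
after smoothing — so the realized standardized mean difference at an effect
voxel equals the declared d in expectation regardless of smoothing or grid
size.

The default three-effect configuration places effects I, II, III with
d = 0.28, 0.50, 0.50 on the middle row of the slice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .design import DesignSpec
from .effect_size import ci_g
from .maps import StatMap, cluster_reference, es_map_from_tmap, threshold_tmap
from .inference import undecidability_map

__all__ = [
    "Effect",
    "SimulatedStudy",
    "canonical_effects",
    "simulation_experiment",
    "simulate_study",
    "two_sample_tmap",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class Effect:
    """A circular (spherical in 3-D) region of true standardized effect d."""

    center: tuple
    radius: float
    d: float


def _normalize_shape(shape) -> tuple[int, int, int]:
    shape = tuple(int(s) for s in shape)
    if len(shape) == 2:
        shape = shape + (1,)
    if len(shape) != 3 or any(s < 1 for s in shape):
        raise ValueError(f"shape must be 2-D or 3-D, got {shape}")
    return shape


def _normalize_center(center, shape) -> tuple[int, ...]:
    center = tuple(int(c) for c in center)
    if len(center) == 2:
        center = center + (0,)
    if len(center) != 3:
        raise ValueError(f"effect center must be 2-D or 3-D, got {center}")
    if not all(0 <= c < s for c, s in zip(center, shape)):
        raise ValueError(f"effect center {center} outside grid {shape}")
    return center


def _effect_region(center, radius: float, shape) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    dist2 = sum((gr - c) ** 2 for gr, c in zip(grids, center))
    return dist2 <= radius ** 2


def _smoothing_norm(shape, sigma: float) -> float:
    """SD inflation factor of circularly-smoothed unit white noise.

    For a linear filter the output variance is the sum of squared kernel
    weights; with 'wrap' boundaries the field is stationary, so the factor
    is exact at every voxel and separable across axes.
    """
    factor = 1.0
    for s in shape:
        if s == 1:
            continue
        impulse = np.zeros(s)
        impulse[s // 2] = 1.0
        kernel = ndimage.gaussian_filter1d(impulse, sigma, mode="wrap")
        factor *= float(np.sqrt(np.sum(kernel ** 2)))
    return factor


@dataclass
class SimulatedStudy:
    """Two-group synthetic data with known ground truth."""

    group_a: np.ndarray  # (n, x, y, z)
    group_b: np.ndarray
    truth_map: np.ndarray  # true standardized effect delta per voxel
    affine: np.ndarray
    n_per_group: int
    seed: int
    noise_sd: float
    smoothing_fwhm: float
    effects: tuple[Effect, ...]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.truth_map.shape


def default_fwhm(shape) -> float:
    """Default smoothing FWHM: 5% of the slice width.

    Keeping the smoothness a fixed fraction of the field of view (rather
    than a fixed voxel count) matches how fMRI smoothing behaves in
    physical units — an ~8-10 mm kernel on a ~200 mm slice — and makes the
    generator's spatial statistics invariant under grid re-scaling.
    """
    return 0.05 * _normalize_shape(shape)[0]


def simulate_study(shape, effects: Sequence, n_per_group: int,
                   noise_sd: float = 1.0, smoothing_fwhm: float | None = None,
                   seed: int = 0) -> SimulatedStudy:
    """Draw a two-group study with localized standardized effects.

    Parameters
    ----------
    shape : tuple
        Slice (2-D) or volume (3-D) grid shape in voxels.
    effects : sequence
        :class:`Effect` instances or ``(center, radius, d)`` tuples.
        Regions must not overlap (the ground truth would be ambiguous).
    n_per_group : int
        Subjects per group (>= 2).
    noise_sd : float
        Marginal SD of the per-voxel noise after smoothing.
    smoothing_fwhm : float, optional
        FWHM of the isotropic Gaussian smoothing kernel, in voxels
        (0 disables smoothing).  Default: 5% of the slice width (see
        :func:`default_fwhm`).
    seed : int
        Single integer governing the whole study; per-subject noise streams
        are spawned deterministically from it, so regeneration is
        bit-identical.
    """
    shape = _normalize_shape(shape)
    if smoothing_fwhm is None:
        smoothing_fwhm = default_fwhm(shape)
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    norm_effects = []
    for eff in effects:
        if not isinstance(eff, Effect):
            eff = Effect(*eff)
        norm_effects.append(
            Effect(_normalize_center(eff.center, shape), float(eff.radius),
                   float(eff.d))
        )
    truth = np.zeros(shape)
    coverage = np.zeros(shape, dtype=int)
    for eff in norm_effects:
        region = _effect_region(eff.center, eff.radius, shape)
        coverage += region
        truth[region] = eff.d
    if (coverage > 1).any():
        raise ValueError("effect regions overlap; ground truth is ambiguous")

    sigma = smoothing_fwhm * _FWHM_TO_SIGMA
    norm = _smoothing_norm(shape, sigma) if smoothing_fwhm > 0 else 1.0
    signal_b = truth * noise_sd

    n_total = 2 * n_per_group
    streams = np.random.SeedSequence(seed).spawn(n_total)

    def draw(stream) -> np.ndarray:
        rng = np.random.default_rng(stream)
        white = rng.standard_normal(shape)
        if smoothing_fwhm > 0:
            white = ndimage.gaussian_filter(white, sigma, mode="wrap") / norm
        return noise_sd * white

    group_a = np.empty((n_per_group,) + shape)
    group_b = np.empty((n_per_group,) + shape)
    for i in range(n_per_group):
        group_a[i] = draw(streams[i])
        group_b[i] = signal_b + draw(streams[n_per_group + i])

    return SimulatedStudy(
        group_a=group_a, group_b=group_b, truth_map=truth,
        affine=np.eye(4), n_per_group=n_per_group, seed=seed,
        noise_sd=noise_sd, smoothing_fwhm=smoothing_fwhm,
        effects=tuple(norm_effects),
    )


def two_sample_tmap(study: SimulatedStudy) -> StatMap:
    """Voxel-wise pooled-variance two-sample t-map (group B minus group A).

    dof = n1 + n2 - 2.  Voxels with zero pooled within-group variance are
    degenerate and carry NaN.
    """
    a, b = study.group_a, study.group_b
    n1, n2 = a.shape[0], b.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need >= 2 subjects")
    mean_diff = b.mean(axis=0) - a.mean(axis=0)
    var_a = a.var(axis=0, ddof=1)
    var_b = b.var(axis=0, ddof=1)
    pooled_var = ((n1 - 1) * var_a + (n2 - 1) * var_b) / (n1 + n2 - 2)
    denom = np.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, mean_diff / denom, np.nan)
    return StatMap(values=t, affine=study.affine.copy(),
                   mask=np.ones(study.shape, dtype=bool))


def canonical_effects(shape) -> tuple[Effect, Effect, Effect]:
    """The canonical three effects I, II, III (d = 0.28, 0.50, 0.50).

    Placed on the middle row of the slice at 1/4, 1/2 and 3/4 of its width,
    with radius 1/24 of the width — localized, well-separated circular
    bumps whose size, like the smoothing kernel, is a fixed fraction of the
    field of view.
    """
    shape = _normalize_shape(shape)
    nx, ny, _ = shape
    row = ny // 2
    radius = max(2, round(nx / 24))
    return (
        Effect((nx // 4, row, 0), radius, 0.28),
        Effect((nx // 2, row, 0), radius, 0.50),
        Effect((3 * nx // 4, row, 0), radius, 0.50),
    )


def _region_masks(study: SimulatedStudy):
    return [
        _effect_region(eff.center, eff.radius, study.shape)
        for eff in study.effects
    ]


def simulation_experiment(n_per_group: int = 500, seed: int = 0,
                          shape=(400, 400), noise_sd: float = 1.0,
                          smoothing_fwhm: float | None = None,
                          alpha: float = 0.001,
                          confidence: float = 0.90,
                          high_confidence: float = 0.999) -> dict:
    """Run the full three-effect slice demonstration and summarize it.

    Simulates the study, computes the two-sample t-map, converts it to g
    and CI maps at two confidence levels, calls voxel-wise significance at
    the uncorrected one-sided ``alpha``, and builds the undecidability map
    against the in-slice maximum effect size (excluding significant
    voxels).  Returns a JSON-serializable report with, per effect location:
    the estimated g and both CIs at the center voxel, the significance
    call, and whether the high-confidence CI lower bound is above zero;
    plus the maximum-ES reference and undecidability summaries (notably
    whether an undecidable-but-not-significant voxel exists at location
    III).
    """
    effects = canonical_effects(shape)
    study = simulate_study(shape, effects, n_per_group=n_per_group,
                           noise_sd=noise_sd, smoothing_fwhm=smoothing_fwhm,
                           seed=seed)
    tmap = two_sample_tmap(study)
    design = DesignSpec.two_sample(n_per_group, n_per_group)
    es = es_map_from_tmap(tmap, design, confidence=confidence)
    sig = threshold_tmap(tmap, design, alpha=alpha, sidedness="one-sided")
    sig_mask = sig.values == 1.0

    # reference = peak g in the detected (significant) voxels — the "red
    # line" of the demonstration; with nothing detected, the slice peak
    ref_region = sig_mask if sig_mask.any() else es.mask
    max_ref = cluster_reference(es, ref_region, kind="percentile",
                                percentile=1.0)
    undec = undecidability_map(es, max_ref, exclude_mask=sig_mask)

    regions = _region_masks(study)
    report: dict = {
        "n_per_group": n_per_group,
        "seed": seed,
        "shape": list(study.shape),
        "dof": design.dof,
        "scale": design.scale,
        "confidence": confidence,
        "high_confidence": high_confidence,
        "alpha": alpha,
        "locations": {},
    }
    for name, eff, region in zip(("I", "II", "III"), effects, regions):
        c = eff.center
        # high-confidence CI only at the center voxel (scalar route)
        est_high = ci_g(float(tmap.values[c]), design.dof, design.scale,
                        confidence=high_confidence)
        report["locations"][name] = {
            "center": list(c),
            "true_d": eff.d,
            "g": float(es.g_map[c]),
            "ci": [float(es.ci_lower_map[c]), float(es.ci_upper_map[c])],
            "ci_high": [est_high.ci_lower, est_high.ci_upper],
            "significant": bool(sig_mask[c]),
            "ci_high_lower_positive": bool(est_high.ci_lower > 0),
        }
    undec_not_sig_iii = bool((undec.values & regions[2]).any())
    report["max_es"] = {
        "value": max_ref.value,
        "voxel": list(max_ref.source_voxel),
    }
    report["undecidability"] = {
        "reference": max_ref.value,
        "n_undecidable": undec.count(),
        "n_significant": int(sig_mask.sum()),
        "undecidable_not_significant_at_III": undec_not_sig_iii,
    }
    return report
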