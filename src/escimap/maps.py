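"""Volume-level machinery: NIfTI I/O, masking, and voxel-wise effect-size maps.

Lifts the scalar computations of :mod:`escimap.effect_size` to whole
3-D statistic volumes.  Out-of-mask or degenerate voxels carry NaN and stay
NaN through every operation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import stats as sps

from .design import DesignSpec
from .effect_size import correction_factor_j, ncp_ci_array

__all__ = [
    "ClusterReference",
    "ESMapBundle",
    "EmptyClusterError",
    "GridMismatchError",
    "StatMap",
    "cluster_reference",
    "es_map_from_tmap",
    "read_stat_map",
    "threshold_tmap",
    "write_volume",
]


class GridMismatchError(ValueError):
    """Two volumes do not share shape and affine."""


class EmptyClusterError(ValueError):
    """A cluster mask selects no usable voxels."""


@dataclass
class StatMap:
    """A 3-D statistic volume with voxel-to-world affine and analysis mask.

    ``values`` is float64 with NaN at out-of-mask voxels (enforced at
    construction); ``mask`` marks the in-analysis voxels.
    """

    values: np.ndarray
    affine: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 3:
            raise ValueError(f"StatMap expects a 3-D array, got shape {values.shape}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be a 4x4 matrix")
        if self.mask is None:
            mask = np.isfinite(values) & (values != 0)
        else:
            mask = np.asarray(self.mask, dtype=bool)
            if mask.shape != values.shape:
                raise GridMismatchError(
                    f"mask shape {mask.shape} != data shape {values.shape}"
                )
        if not mask.any():
            raise EmptyClusterError("mask selects no voxels")
        values = values.copy()
        values[~mask] = np.nan
        self.values = values
        self.affine = affine
        self.mask = mask

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape


def _same_grid(shape_a, affine_a, shape_b, affine_b) -> bool:
    return tuple(shape_a) == tuple(shape_b) and np.allclose(
        affine_a, affine_b, atol=1e-4
    )


def _require_same_grid(shape_a, affine_a, shape_b, affine_b, what: str) -> None:
    if not _same_grid(shape_a, affine_a, shape_b, affine_b):
        raise GridMismatchError(
            f"{what}: grids differ (shapes {tuple(shape_a)} vs {tuple(shape_b)} "
            "or affines disagree)"
        )


def _load_3d(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(float)
    # SPM and friends often write x*y*z*1 volumes; squeeze trailing singletons
    while data.ndim > 3 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim == 2:
        data = data[..., np.newaxis]
    if data.ndim != 3:
        raise ValueError(
            f"{path}: expected a 3-D statistic volume, got shape {data.shape} "
            "(4-D series are not supported)"
        )
    return data, np.asarray(img.affine, dtype=float)


def read_stat_map(path, mask_path=None) -> StatMap:
    """Read a 3-D NIfTI statistic volume, optionally with an explicit mask.

    Without a mask, in-analysis voxels default to the finite, nonzero ones.
    A supplied mask must live on the same grid (shape + affine).
    """
    data, affine = _load_3d(path)
    mask = None
    if mask_path is not None:
        mask_data, mask_affine = _load_3d(mask_path)
        _require_same_grid(data.shape, affine, mask_data.shape, mask_affine,
                           f"mask {mask_path} vs map {path}")
        mask = np.isfinite(mask_data) & (mask_data != 0)
    return StatMap(values=data, affine=affine, mask=mask)


def write_volume(values: np.ndarray, affine: np.ndarray, path) -> Path:
    """Write a 3-D array as NIfTI (float64, NaN kept for missing voxels)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(values, dtype=np.float64), affine), str(path))
    return path


@dataclass
class ESMapBundle:
    """Co-registered g / CI-lower / CI-upper maps on one grid."""

    g_map: np.ndarray
    ci_lower_map: np.ndarray
    ci_upper_map: np.ndarray
    affine: np.ndarray
    mask: np.ndarray
    confidence: float
    dof: int
    scale: float

    def __post_init__(self) -> None:
        shapes = {self.g_map.shape, self.ci_lower_map.shape,
                  self.ci_upper_map.shape, self.mask.shape}
        if len(shapes) != 1:
            raise GridMismatchError("bundle maps do not share one grid")
        both = np.isfinite(self.ci_lower_map) & np.isfinite(self.ci_upper_map)
        if np.any(self.ci_lower_map[both] > self.ci_upper_map[both]):
            raise ValueError("ci_lower exceeds ci_upper at some voxel")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.g_map.shape


def es_map_from_tmap(tmap: StatMap, design: DesignSpec,
                     confidence: float = 0.90,
                     exact_j: bool = False) -> ESMapBundle:
    """Voxel-wise Hedges' g and exact CI maps from a group-level t-map.

    Applies ``g = t * scale * J(dof)`` and the noncentral-t CI inversion to
    every finite in-mask voxel; everything else propagates as NaN.  Results
    are deterministic and independent of voxel iteration order (the solver
    is element-wise).
    """
    usable = tmap.mask & np.isfinite(tmap.values)
    g = np.full(tmap.shape, np.nan)
    lo = np.full(tmap.shape, np.nan)
    hi = np.full(tmap.shape, np.nan)
    tv = tmap.values[usable]
    if tv.size:
        j = correction_factor_j(design.dof, exact=exact_j)
        g[usable] = tv * design.scale * j
        dl, du = ncp_ci_array(tv, design.dof, confidence)
        lo[usable] = dl * design.scale
        hi[usable] = du * design.scale
    return ESMapBundle(
        g_map=g, ci_lower_map=lo, ci_upper_map=hi,
        affine=tmap.affine.copy(), mask=usable,
        confidence=confidence, dof=design.dof, scale=design.scale,
    )


@dataclass(frozen=True)
class ClusterReference:
    """A reference effect size anchored at an actual voxel of a cluster."""

    statistic_kind: str  # "median" or "percentile"
    percentile: float
    value: float
    source_voxel: tuple[int, int, int]


def _as_mask(mask, shape, affine, what: str) -> np.ndarray:
    if isinstance(mask, StatMap):
        _require_same_grid(shape, affine, mask.shape, mask.affine, what)
        return mask.mask
    arr = np.asarray(mask, dtype=bool)
    if arr.shape != tuple(shape):
        raise GridMismatchError(f"{what}: mask shape {arr.shape} != {tuple(shape)}")
    return arr


def cluster_reference(es: ESMapBundle, cluster_mask, kind: str = "median",
                      percentile: float | None = None) -> ClusterReference:
    """Order-statistic reference g within a cluster, by nearest rank.

    ``kind='median'`` picks rank ``ceil(n/2)`` (the lower of the two middle
    ranks for even n); ``kind='percentile'`` picks rank ``ceil(p * n)``.
    Either way the reference is the g value of an actual voxel, whose index
    is returned.
    """
    cm = _as_mask(cluster_mask, es.shape, es.affine, "cluster mask")
    if kind == "median":
        q = 0.5
    elif kind == "percentile":
        if percentile is None or not 0.0 < percentile <= 1.0:
            raise ValueError("percentile must be given in (0, 1]")
        q = float(percentile)
    else:
        raise ValueError(f"unknown reference kind {kind!r}")
    usable = cm & es.mask & np.isfinite(es.g_map)
    n = int(usable.sum())
    if n == 0:
        raise EmptyClusterError("cluster contains no usable voxels")
    vals = es.g_map[usable]
    order = np.argsort(vals, kind="stable")
    rank = int(np.ceil(q * n))  # 1-based nearest rank
    pick = order[rank - 1]
    coords = np.argwhere(usable)  # same C-order as the boolean fancy index
    voxel = tuple(int(i) for i in coords[pick])
    return ClusterReference(statistic_kind=kind, percentile=q,
                            value=float(vals[pick]), source_voxel=voxel)


def threshold_tmap(tmap: StatMap, design: DesignSpec, alpha: float = 0.001,
                   sidedness: str = "one-sided") -> StatMap:
    """Binary significance map from central-t critical values (uncorrected).

    One-sided by default (the usual fMRI contrast convention): a voxel
    passes iff ``t > t_crit(1 - alpha, dof)`` (strict).  Two-sided uses
    ``|t| > t_crit(1 - alpha/2, dof)``.  FWE-corrected cluster masks are
    inputs elsewhere, never computed here.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    if sidedness not in ("one-sided", "two-sided"):
        raise ValueError("sidedness must be 'one-sided' or 'two-sided'")
    if sidedness == "one-sided":
        crit = sps.t.ppf(1.0 - alpha, design.dof)
        passed = tmap.values > crit
    else:
        crit = sps.t.ppf(1.0 - alpha / 2.0, design.dof)
        passed = np.abs(tmap.values) > crit
    passed &= tmap.mask
    return StatMap(values=passed.astype(float), affine=tmap.affine.copy(),
                   mask=tmap.mask.copy())
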