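"""CI-based inference procedures on effect-size maps.

Three applications built on :class:`escimap.maps.ESMapBundle`:

* **maps of undecidability** — voxels whose CI upper limit includes or
  exceeds a reference effect from a detected cluster, i.e. voxels that
  cannot be shown to carry a smaller effect than the detected one;
* **voxel-wise replication tests** — whether the reference sample's g falls
  into the replication sample's CI, evaluated where the reference g > 0;
* **lateralization tests** — inferiority of mirrored contralateral voxels
  against a percentile reference within a unilateral cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .maps import (
    ClusterReference,
    ESMapBundle,
    EmptyClusterError,
    GridMismatchError,
    StatMap,
    _as_mask,
    _require_same_grid,
    cluster_reference,
)

__all__ = [
    "BinaryResultMap",
    "infer_mirror_axis",
    "lateralization_test",
    "mirror_mask",
    "replication_map",
    "undecidability_map",
]


@dataclass
class BinaryResultMap:
    """Boolean outcome volume of one inference procedure.

    ``values`` is the positive call; ``evaluated`` marks where the test was
    actually applied (e.g. the replication test skips voxels with reference
    g <= 0).  ``ternary()`` encodes {1: positive, 0: negative, NaN: not
    evaluated} for writing to NIfTI.
    """

    values: np.ndarray
    affine: np.ndarray
    label: str
    evaluated: np.ndarray
    reference: ClusterReference | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        self.evaluated = np.asarray(self.evaluated, dtype=bool)
        if self.values.shape != self.evaluated.shape:
            raise GridMismatchError("values and evaluated masks differ in shape")
        if np.any(self.values & ~self.evaluated):
            raise ValueError("positive voxels outside the evaluated region")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    def ternary(self) -> np.ndarray:
        out = np.full(self.values.shape, np.nan)
        out[self.evaluated] = 0.0
        out[self.values] = 1.0
        return out

    def count(self) -> int:
        return int(self.values.sum())


def undecidability_map(es: ESMapBundle, reference: ClusterReference | float,
                       exclude_mask=None) -> BinaryResultMap:
    """Voxels statistically indistinguishable from a detected effect.

    A voxel is *undecidable* iff its CI upper limit includes or exceeds the
    reference value (``ci_upper >= reference``).  Voxels of ``exclude_mask``
    (by default the detected significant clusters that supplied the
    reference are passed here — they are already decided) are removed from
    both the result and the evaluated region.
    """
    ref_value = reference.value if isinstance(reference, ClusterReference) else float(reference)
    if not np.isfinite(ref_value):
        raise ValueError("reference value must be finite")
    evaluated = es.mask & np.isfinite(es.ci_upper_map)
    values = evaluated & (es.ci_upper_map >= ref_value)
    if exclude_mask is not None:
        excl = _as_mask(exclude_mask, es.shape, es.affine, "exclude mask")
        values &= ~excl
        evaluated &= ~excl
    return BinaryResultMap(
        values=values, affine=es.affine.copy(), label="undecidable",
        evaluated=evaluated,
        reference=reference if isinstance(reference, ClusterReference) else None,
    )


def _reference_g_array(reference, shape, affine) -> np.ndarray:
    if isinstance(reference, ESMapBundle):
        _require_same_grid(shape, affine, reference.shape, reference.affine,
                           "reference bundle vs replication bundle")
        return reference.g_map
    if isinstance(reference, StatMap):
        _require_same_grid(shape, affine, reference.shape, reference.affine,
                           "reference map vs replication bundle")
        return reference.values
    arr = np.asarray(reference, dtype=float)
    if arr.shape != tuple(shape):
        raise GridMismatchError(
            f"reference g array shape {arr.shape} != {tuple(shape)}"
        )
    return arr


def replication_map(reference, replication: ESMapBundle) -> BinaryResultMap:
    """Voxel-wise replication of reference effect sizes.

    A voxel counts as replicated iff the reference sample's g falls into the
    replication sample's CI, read as a closed interval
    (``ci_lower <= g_ref <= ci_upper``).  Only voxels with reference
    ``g > 0`` are evaluated (one contrast direction); the rest are encoded
    as not-evaluated in :meth:`BinaryResultMap.ternary`.
    """
    ref_g = _reference_g_array(reference, replication.shape, replication.affine)
    evaluated = (
        replication.mask
        & np.isfinite(replication.ci_lower_map)
        & np.isfinite(replication.ci_upper_map)
        & np.isfinite(ref_g)
        & (ref_g > 0)
    )
    values = evaluated & (replication.ci_lower_map <= ref_g) \
        & (ref_g <= replication.ci_upper_map)
    return BinaryResultMap(values=values, affine=replication.affine.copy(),
                           label="replicated", evaluated=evaluated)


def infer_mirror_axis(affine: np.ndarray) -> int:
    """Voxel axis most aligned with the world left-right (x) direction."""
    affine = np.asarray(affine, dtype=float)
    return int(np.argmax(np.abs(affine[0, :3])))


def mirror_mask(mask: np.ndarray, axis: int) -> np.ndarray:
    """Reflect a voxel mask across the grid midline along ``axis``.

    Assumes a midline-symmetric grid; applying it twice is the identity.
    """
    return np.flip(np.asarray(mask, dtype=bool), axis=axis)


def lateralization_test(es: ESMapBundle, cluster_mask,
                        percentile: float = 0.75,
                        mirror_axis: int | None = None) -> BinaryResultMap:
    """Test a unilateral cluster's effect against its mirror region.

    Computes the ``percentile`` (nearest-rank) reference g within the
    cluster, mirrors the cluster mask across the grid midline of the
    left-right axis, and marks mirrored voxels whose CI upper limit includes
    or exceeds the reference.  An empty result supports lateralization (all
    contralateral voxels are inferior to the reference); a non-empty result
    speaks against it.
    """
    cm = _as_mask(cluster_mask, es.shape, es.affine, "cluster mask")
    if not cm.any():
        raise EmptyClusterError("cluster mask is empty")
    axis = infer_mirror_axis(es.affine) if mirror_axis is None else int(mirror_axis)
    if not 0 <= axis <= 2:
        raise ValueError("mirror_axis must be 0, 1, or 2")
    idx = np.nonzero(cm)[axis]
    mid = (es.shape[axis] - 1) / 2.0
    if (idx < mid).any() and (idx > mid).any() or (idx == mid).any():
        raise ValueError(
            "cluster straddles (or touches) the midline of the mirror axis"
        )
    ref = cluster_reference(es, cm, kind="percentile", percentile=percentile)
    mirrored = mirror_mask(cm, axis)
    evaluated = mirrored & es.mask & np.isfinite(es.ci_upper_map)
    if not evaluated.any():
        raise ValueError(
            "mirrored cluster falls entirely outside the analysis mask"
        )
    values = evaluated & (es.ci_upper_map >= ref.value)
    return BinaryResultMap(values=values, affine=es.affine.copy(),
                           label="not_inferior", evaluated=evaluated,
                           reference=ref)
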