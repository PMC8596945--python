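"""Model/Results surface tying the package together.

:class:`TMapEffectSize` is the model: a group-level t-map plus the design
that produced it.  ``fit()`` performs the voxel-wise conversion to Hedges'
g with exact noncentral-t confidence intervals and returns
:class:`ESMapResults`, which carries the estimate maps, a ``summary()``
table, the three CI-based inference procedures, plotting, and writers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import __version__
from .design import DesignSpec, parse_contrast, read_design
from .effect_size import EffectSizeEstimate, TTestEffectSize  # noqa: F401
from .inference import (
    BinaryResultMap,
    lateralization_test,
    replication_map,
    undecidability_map,
)
from .maps import (
    ClusterReference,
    ESMapBundle,
    StatMap,
    cluster_reference,
    es_map_from_tmap,
    read_stat_map,
    threshold_tmap,
    write_volume,
)

__all__ = ["TMapEffectSize", "ESMapResults"]


class TMapEffectSize:
    """Effect-size model for a group-level t-statistic volume.

    Parameters
    ----------
    tmap : StatMap
        The group-level t-map (with analysis mask).
    design : DesignSpec
        The design matrix and contrast that produced the t-map; supplies
        the degrees of freedom and the contrast variance scale
        ``sqrt(c'(X'X)^- c)``.
    """

    def __init__(self, tmap: StatMap, design: DesignSpec) -> None:
        self.tmap = tmap
        self.design = design

    @classmethod
    def from_files(cls, tmap_path, design_path, contrast,
                   mask_path=None) -> "TMapEffectSize":
        """Build the model from a NIfTI t-map and a delimited-text design."""
        tmap = read_stat_map(tmap_path, mask_path)
        design = read_design(design_path, parse_contrast(contrast))
        return cls(tmap, design)

    def fit(self, confidence: float = 0.90,
            exact_j: bool = False) -> "ESMapResults":
        """Voxel-wise g and exact CI maps at the given two-sided confidence."""
        bundle = es_map_from_tmap(self.tmap, self.design,
                                  confidence=confidence, exact_j=exact_j)
        return ESMapResults(self, bundle)

    def threshold(self, alpha: float = 0.001,
                  sidedness: str = "one-sided") -> StatMap:
        """Uncorrected voxel-wise significance map of the underlying t-map."""
        return threshold_tmap(self.tmap, self.design, alpha=alpha,
                              sidedness=sidedness)


class ESMapResults:
    """Fitted effect-size maps with CI-based inference procedures."""

    def __init__(self, model: TMapEffectSize, bundle: ESMapBundle) -> None:
        self.model = model
        self.bundle = bundle

    # -- convenience views -------------------------------------------------
    @property
    def g_map(self) -> np.ndarray:
        return self.bundle.g_map

    @property
    def ci_lower_map(self) -> np.ndarray:
        return self.bundle.ci_lower_map

    @property
    def ci_upper_map(self) -> np.ndarray:
        return self.bundle.ci_upper_map

    @property
    def confidence(self) -> float:
        return self.bundle.confidence

    @property
    def dof(self) -> int:
        return self.bundle.dof

    @property
    def scale(self) -> float:
        return self.bundle.scale

    def estimate_at(self, voxel) -> EffectSizeEstimate:
        """Scalar estimate at one voxel (same numbers as the maps)."""
        voxel = tuple(int(i) for i in voxel)
        t = float(self.model.tmap.values[voxel])
        return TTestEffectSize(t, self.dof, scale=self.scale).fit(
            confidence=self.confidence
        )

    # -- inference procedures ---------------------------------------------
    def cluster_reference(self, cluster_mask, kind: str = "median",
                          percentile: float | None = None) -> ClusterReference:
        return cluster_reference(self.bundle, cluster_mask, kind=kind,
                                 percentile=percentile)

    def undecidability(self, reference, exclude_mask=None) -> BinaryResultMap:
        """Map of voxels not decidably smaller than ``reference``.

        ``reference`` may be a :class:`ClusterReference`, a plain value, or
        a cluster mask (then the median-voxel reference is computed and the
        cluster itself is excluded from the output unless an explicit
        ``exclude_mask`` is given).
        """
        if isinstance(reference, (ClusterReference, int, float)):
            return undecidability_map(self.bundle, reference, exclude_mask)
        ref = self.cluster_reference(reference)
        if exclude_mask is None:
            exclude_mask = reference
        return undecidability_map(self.bundle, ref, exclude_mask)

    def replication_of(self, reference) -> BinaryResultMap:
        """Treat *this* fit as the replication sample of ``reference``."""
        return replication_map(reference, self.bundle)

    def lateralization(self, cluster_mask, percentile: float = 0.75,
                       mirror_axis: int | None = None) -> BinaryResultMap:
        return lateralization_test(self.bundle, cluster_mask,
                                   percentile=percentile,
                                   mirror_axis=mirror_axis)

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        g = self.g_map[self.bundle.mask]
        width = (self.ci_upper_map - self.ci_lower_map)[self.bundle.mask]
        q = np.nanpercentile(g, [0, 25, 50, 75, 100])
        pct = 100.0 * self.confidence
        lines = [
            "Effect-size map results (Hedges' g, exact noncentral-t CI)",
            "=" * 60,
            f"in-mask voxels        {int(self.bundle.mask.sum())}",
            f"degrees of freedom    {self.dof}",
            f"contrast scale        {self.scale:.6f}",
            f"confidence            {pct:.1f}% (two-sided)",
            f"g min/q25/med/q75/max {q[0]: .4f} {q[1]: .4f} {q[2]: .4f} "
            f"{q[3]: .4f} {q[4]: .4f}",
            f"median CI width       {np.nanmedian(width): .4f}",
        ]
        return "\n".join(lines)

    def sidecar(self, extra: dict | None = None) -> dict:
        meta = {
            "software": "escimap",
            "version": __version__,
            "dof": self.dof,
            "scale": self.scale,
            "confidence": self.confidence,
            "n_voxels_in_mask": int(self.bundle.mask.sum()),
        }
        if extra:
            meta.update(extra)
        return meta

    def save(self, outdir, force: bool = False,
             extra_meta: dict | None = None) -> dict[str, Path]:
        """Write g/ci_lower/ci_upper NIfTIs plus a JSON sidecar."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "g": outdir / "g.nii.gz",
            "ci_lower": outdir / "ci_lower.nii.gz",
            "ci_upper": outdir / "ci_upper.nii.gz",
            "sidecar": outdir / "esmap.json",
        }
        clashes = [p for p in paths.values() if p.exists()]
        if clashes and not force:
            raise FileExistsError(
                f"refusing to overwrite {clashes[0]} (use force=True / --force)"
            )
        write_volume(self.g_map, self.bundle.affine, paths["g"])
        write_volume(self.ci_lower_map, self.bundle.affine, paths["ci_lower"])
        write_volume(self.ci_upper_map, self.bundle.affine, paths["ci_upper"])
        paths["sidecar"].write_text(
            json.dumps(self.sidecar(extra_meta), indent=2, sort_keys=True)
        )
        return paths

    def plot_profile(self, row: int | None = None, axis: int = 1, ax=None):
        """Plot g with its CI band along one grid line of the slice.

        Mirrors the classic demonstration figure: the profile of the
        effect-size estimate and its CI across the row holding the effects.
        Requires matplotlib.
        """
        import matplotlib.pyplot as plt

        if row is None:
            row = self.bundle.shape[1] // 2 if axis == 1 else \
                self.bundle.shape[0] // 2
        if axis == 1:
            sel = (slice(None), row, 0)
        else:
            sel = (row, slice(None), 0)
        x = np.arange(self.g_map[sel].shape[0])
        if ax is None:
            _, ax = plt.subplots()
        ax.fill_between(x, self.ci_lower_map[sel], self.ci_upper_map[sel],
                        alpha=0.3, label=f"{100 * self.confidence:.1f}% CI")
        ax.plot(x, self.g_map[sel], lw=1.0, label="Hedges' g")
        ax.axhline(0.0, color="k", lw=0.5)
        ax.set_xlabel("voxel")
        ax.set_ylabel("standardized effect (g)")
        ax.legend()
        return ax
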