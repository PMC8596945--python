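import numpy as np
import pytest

from escimap import DesignSpec, ESMapBundle


def bundle_from_arrays(g, lo, hi, mask=None, affine=None, confidence=0.90,
                       dof=98, scale=0.2) -> ESMapBundle:
    """Assemble an effect-size bundle directly from known arrays.

    Lets inference procedures be tested against hand-chosen CIs without
    running the CI solver.
    """
    g = np.asarray(g, dtype=float)
    if g.ndim == 2:
        g = g[..., np.newaxis]
        lo = np.asarray(lo, dtype=float)[..., np.newaxis]
        hi = np.asarray(hi, dtype=float)[..., np.newaxis]
    else:
        lo = np.asarray(lo, dtype=float)
        hi = np.asarray(hi, dtype=float)
    if mask is None:
        mask = np.isfinite(g)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.ndim == 2:
            mask = mask[..., np.newaxis]
    if affine is None:
        affine = np.eye(4)
    return ESMapBundle(g_map=g, ci_lower_map=lo, ci_upper_map=hi,
                       affine=affine, mask=mask, confidence=confidence,
                       dof=dof, scale=scale)


@pytest.fixture
def two_sample_design() -> DesignSpec:
    return DesignSpec.two_sample(50, 50)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
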