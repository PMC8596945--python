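"""Group-level GLM designs: degrees of freedom and contrast variance scale.

A group analysis tests a contrast ``c`` on a design matrix ``X`` (rows =
subjects).  Two derived quantities are all the effect-size machinery needs:

* ``dof = N - rank(X)`` — the error degrees of freedom of the GLM;
* ``scale = sqrt(c'(X'X)^- c)`` — the factor converting the contrast
  t-statistic into a standardized effect size.

For the canonical designs these reduce to the textbook values:
an all-ones column (one-sample t-test) gives ``dof = n - 1`` and
``scale = sqrt(1/n)``; two group-indicator columns give
``dof = n1 + n2 - 2`` and ``scale = sqrt(1/n1 + 1/n2)``.  Covariate columns
reduce the dof by their rank contribution and, if correlated with the
contrast columns, alter the scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DesignSpec",
    "InvalidContrastError",
    "InvalidDesignError",
    "contrast_variance_scale",
    "glm_dof",
    "parse_contrast",
    "read_design",
]


class InvalidDesignError(ValueError):
    """Design matrix unusable (rank-deficient to dof <= 0, ragged file, ...)."""


class InvalidContrastError(ValueError):
    """Contrast vector is zero or not estimable under the design."""


def glm_dof(X: np.ndarray) -> int:
    """Error degrees of freedom ``N - rank(X)`` of a group-level GLM."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    dof = X.shape[0] - np.linalg.matrix_rank(X)
    if dof <= 0:
        raise InvalidDesignError(
            f"design with {X.shape[0]} rows and rank {X.shape[0] - dof} "
            "leaves no error degrees of freedom"
        )
    return int(dof)


def contrast_variance_scale(X: np.ndarray, c: np.ndarray) -> float:
    """Contrast variance scale ``sqrt(c'(X'X)^- c)`` via pseudoinverse.

    The pseudoinverse uses tolerance-based rank determination, so
    rank-deficient designs (e.g. two group indicators plus an intercept) are
    handled.  A contrast outside the row space of X is not estimable and
    raises :class:`InvalidContrastError`.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    c = np.asarray(c, dtype=float).ravel()
    if c.shape[0] != X.shape[1]:
        raise InvalidContrastError(
            f"contrast length {c.shape[0]} != {X.shape[1]} design columns"
        )
    if not np.any(c):
        raise InvalidContrastError("contrast vector is all zero")
    xtx = X.T @ X
    xtx_pinv = np.linalg.pinv(xtx)
    # estimability: c must lie in the column space of X'X (= row space of X)
    proj = xtx @ (xtx_pinv @ c)
    if not np.allclose(proj, c, rtol=1e-8, atol=1e-8 * max(1.0, float(np.abs(c).max()))):
        raise InvalidContrastError(
            "contrast is not estimable (outside the row space of the design)"
        )
    value = float(c @ xtx_pinv @ c)
    if value <= 0:
        raise InvalidContrastError("contrast variance scale is not positive")
    return float(np.sqrt(value))


@dataclass(frozen=True)
class DesignSpec:
    """A group-level design matrix with contrast and derived quantities."""

    X: np.ndarray
    c: np.ndarray
    dof: int = field(init=False)
    scale: float = field(init=False)

    def __post_init__(self) -> None:
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        c = np.asarray(self.c, dtype=float).ravel()
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "c", c)
        object.__setattr__(self, "dof", glm_dof(X))
        object.__setattr__(self, "scale", contrast_variance_scale(X, c))

    @property
    def n(self) -> int:
        return int(self.X.shape[0])

    @classmethod
    def one_sample(cls, n: int) -> "DesignSpec":
        """All-ones design of a one-sample t-test (dof n-1, scale sqrt(1/n))."""
        return cls(np.ones((n, 1)), np.array([1.0]))

    @classmethod
    def two_sample(cls, n1: int, n2: int) -> "DesignSpec":
        """Two-indicator design of a two-sample t-test.

        The contrast is [-1, 1], i.e. group 2 minus group 1, so positive
        effects mean group 2 > group 1.
        """
        X = np.zeros((n1 + n2, 2))
        X[:n1, 0] = 1.0
        X[n1:, 1] = 1.0
        return cls(X, np.array([-1.0, 1.0]))


def parse_contrast(contrast) -> np.ndarray:
    """Accept a sequence of reals or a comma-separated string like '1,-1'."""
    if isinstance(contrast, str):
        tokens = [tok for tok in contrast.replace(";", ",").split(",") if tok.strip()]
        try:
            return np.array([float(tok) for tok in tokens])
        except ValueError as exc:
            raise InvalidContrastError(f"cannot parse contrast {contrast!r}") from exc
    return np.asarray(contrast, dtype=float).ravel()


def _load_matrix(path) -> np.ndarray:
    path = Path(path)
    attempts = (
        dict(sep=None, engine="python", header=None),
        dict(sep=r"\s+", header=None),
        dict(sep=",", header=None),
    )
    last_error: Exception | None = None
    for kwargs in attempts:
        try:
            df = pd.read_csv(path, comment="#", **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raised below
            last_error = exc
            continue
        arr = df.to_numpy()
        try:
            arr = arr.astype(float)
        except (TypeError, ValueError):
            # first row may be a header of column names
            try:
                arr = df.iloc[1:].to_numpy().astype(float)
            except (TypeError, ValueError) as exc:
                last_error = exc
                continue
        if arr.ndim != 2 or arr.size == 0 or np.isnan(arr).any():
            last_error = InvalidDesignError(
                f"design matrix file {path} is ragged or contains missing values"
            )
            continue
        return arr
    raise InvalidDesignError(f"could not parse design matrix {path}: {last_error}")


def read_design(matrix_path, contrast) -> DesignSpec:
    """Read a delimited-text design matrix (rows = subjects) plus contrast.

    Whitespace- or comma-delimited, optional single header row, '#' comments
    allowed.  Returns a :class:`DesignSpec` with derived dof and scale.
    """
    X = _load_matrix(matrix_path)
    c = parse_contrast(contrast)
    if c.shape[0] != X.shape[1]:
        raise InvalidContrastError(
            f"contrast length {c.shape[0]} does not match the "
            f"{X.shape[1]}-column design in {matrix_path}"
        )
    return DesignSpec(X, c)
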