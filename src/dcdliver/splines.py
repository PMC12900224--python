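"""Restricted cubic splines: knot placement, basis construction, joint Wald
tests, and effect curves relative to a reference value.

The basis is the restricted (natural) cubic truncated-power basis: a cubic
spline constrained to be linear below the first and above the last knot.
With k knots the basis has k - 1 columns — the identity (linear) term plus
k - 2 nonlinear terms.  Nonlinear terms are divided by ``(t_k - t_1)**2`` so
their coefficients live on the scale of the predictor itself, matching the
convention of the rms/Hmisc toolchain this mirrors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import linalg, stats

__all__ = [
    "SplineSpec",
    "WaldTest",
    "EffectCurve",
    "compute_knots",
    "rcs_basis",
    "wald_group_test",
    "effect_curve",
]

DEFAULT_PERCENTILES = (5.0, 35.0, 65.0, 95.0)


@dataclass(frozen=True)
class SplineSpec:
    """Knot locations and reference value for one continuous predictor.

    Parameters
    ----------
    variable
        Column name of the predictor.
    knots
        Strictly increasing knot locations, ``k >= 3``.
    x_ref
        Reference value for effect curves (ratio is 1 there).  Defaults to
        the first knot when unset.
    percentiles
        The sample percentiles the knots were (or will be) placed at.
    basis
        Identifier of the basis convention; only the normalized
        truncated-power basis is implemented.
    """

    variable: str
    knots: tuple[float, ...] = ()
    x_ref: float | None = None
    percentiles: tuple[float, ...] = DEFAULT_PERCENTILES
    basis: str = "rcs-truncated-power/(tk-t1)^2"

    def __post_init__(self) -> None:
        if self.knots:
            k = np.asarray(self.knots, dtype=float)
            if k.size < 3:
                raise ValueError(
                    f"{self.variable}: restricted cubic splines need >= 3 knots, got {k.size}"
                )
            if np.any(np.diff(k) <= 0):
                raise ValueError(f"{self.variable}: knots must be strictly increasing: {k}")

    @property
    def n_basis(self) -> int:
        """Number of basis columns (k - 1)."""
        return len(self.knots) - 1

    @property
    def reference(self) -> float:
        return float(self.knots[0]) if self.x_ref is None else float(self.x_ref)

    def with_knots_from(self, x: np.ndarray) -> "SplineSpec":
        """Return a copy with knots computed from observed values of ``x``."""
        return replace(self, knots=tuple(compute_knots(x, self.percentiles)))


def compute_knots(
    x: np.ndarray, percentiles: tuple[float, ...] = DEFAULT_PERCENTILES
) -> np.ndarray:
    """Place knots at sample percentiles of the observed (finite) values.

    Percentiles are computed with linear interpolation between order
    statistics (``numpy.percentile`` default).  Raises if ties collapse the
    knots, with a hint to use fewer knots.
    """
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    k = len(percentiles)
    n_distinct = np.unique(x).size
    if n_distinct < k:
        raise ValueError(
            f"need at least {k} distinct finite values to place {k} knots, "
            f"got {n_distinct}"
        )
    knots = np.percentile(x, percentiles)
    if np.any(np.diff(knots) <= 0):
        raise ValueError(
            f"knot percentiles {percentiles} fall on tied values {knots}; "
            "use fewer knots for this variable"
        )
    return knots


def rcs_basis(x: np.ndarray, spec: SplineSpec | np.ndarray) -> np.ndarray:
    """Evaluate the restricted cubic spline basis at ``x``.

    Returns an ``(n, k-1)`` array: column 0 is ``x`` itself, columns 1..k-2
    are normalized truncated-cubic terms.  The implied function space is
    linear for ``x <= t1`` and ``x >= tk`` with continuous value, first and
    second derivatives everywhere.  Missing values propagate as NaN.
    """
    t = np.asarray(spec.knots if isinstance(spec, SplineSpec) else spec, dtype=float)
    if t.size < 3:
        raise ValueError("restricted cubic splines need >= 3 knots")
    if np.any(np.diff(t) <= 0):
        raise ValueError("knots must be strictly increasing")
    x = np.asarray(x, dtype=float)
    norm = (t[-1] - t[0]) ** 2

    def cube(v: np.ndarray) -> np.ndarray:
        return np.where(v > 0, v, 0.0) ** 3

    cols = [x]
    for j in range(t.size - 2):
        term = (
            cube(x - t[j])
            - cube(x - t[-2]) * (t[-1] - t[j]) / (t[-1] - t[-2])
            + cube(x - t[-1]) * (t[-2] - t[j]) / (t[-1] - t[-2])
        )
        cols.append(term / norm)
    out = np.column_stack(cols)
    # np.where() above loses NaN; restore propagation explicitly
    out[~np.isfinite(x)] = np.nan
    return out


@dataclass(frozen=True)
class WaldTest:
    statistic: float
    df: int
    p: float


def wald_group_test(beta: np.ndarray, cov: np.ndarray) -> WaldTest:
    """Joint chi-square Wald test that a coefficient group is zero.

    ``statistic = beta' V^{-1} beta`` with ``df = len(beta)`` and the p-value
    from the chi-square upper tail.  For a single coefficient this is exactly
    the squared z-statistic.
    """
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    if cov.shape != (beta.size, beta.size):
        raise ValueError(f"covariance shape {cov.shape} does not match {beta.size} terms")
    if not np.allclose(cov, cov.T, rtol=1e-8, atol=1e-12):
        raise ValueError("covariance submatrix is not symmetric")
    try:
        cf = linalg.cho_factor(cov)
    except linalg.LinAlgError:
        eigvals = linalg.eigvalsh(cov)
        bad = np.flatnonzero(eigvals <= 1e-12 * max(eigvals.max(), 1.0))
        raise ValueError(
            "covariance submatrix is singular (aliased terms along eigen "
            f"directions {bad.tolist()}); drop or merge collinear terms"
        ) from None
    statistic = float(beta @ linalg.cho_solve(cf, beta))
    df = int(beta.size)
    return WaldTest(statistic=statistic, df=df, p=float(stats.chi2.sf(statistic, df)))


@dataclass
class EffectCurve:
    """A ratio-scale effect curve for one spline-coded predictor.

    ``ratio[i]`` is the hazard or odds ratio comparing ``x[i]`` with
    ``x_ref``; ``lo``/``hi`` are pointwise 95% bounds from the delta method.
    ``extrapolated`` flags grid points outside the 1st-99th percentile range
    of the training data (when that range is known).
    """

    variable: str
    x: np.ndarray
    ratio: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    scale: str  # "hazard" or "odds"
    x_ref: float
    extrapolated: np.ndarray = field(default=None)  # type: ignore[assignment]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"x": self.x, "ratio": self.ratio, "lo": self.lo, "hi": self.hi}
        )
        if self.extrapolated is not None:
            df["extrapolated"] = self.extrapolated
        return df


def effect_curve(
    beta: np.ndarray,
    cov: np.ndarray,
    block: np.ndarray,
    spec: SplineSpec,
    grid: np.ndarray,
    scale: str = "hazard",
    level: float = 0.95,
    training_range: tuple[float, float] | None = None,
) -> EffectCurve:
    """Effect curve of a spline block relative to the reference value.

    Parameters
    ----------
    beta, cov
        Full coefficient vector and covariance from a (pooled) fit.
    block
        Integer indices of the spline block's columns within ``beta``.
    spec
        The spline's knots and reference value.
    grid
        Predictor values to evaluate.
    training_range
        (1st, 99th) percentile of the training predictor; grid values
        outside are flagged, never withheld.

    The log-ratio at x is ``(basis(x) - basis(x_ref)) . beta_block`` and its
    variance follows from the delta method with that contrast vector.
    """
    beta = np.asarray(beta, dtype=float)
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    block = np.asarray(block, dtype=int)
    grid = np.asarray(grid, dtype=float)
    x_ref = spec.reference

    b_grid = rcs_basis(grid, spec)
    b_ref = rcs_basis(np.array([x_ref]), spec)
    contrast = b_grid - b_ref  # (n, k-1)

    beta_block = beta[block]
    cov_block = cov[np.ix_(block, block)]
    log_ratio = contrast @ beta_block
    var = np.einsum("ij,jk,ik->i", contrast, cov_block, contrast)
    se = np.sqrt(np.clip(var, 0.0, None))
    z = stats.norm.ppf(0.5 + level / 2.0)

    extrapolated = None
    if training_range is not None:
        lo_r, hi_r = training_range
        extrapolated = (grid < lo_r) | (grid > hi_r)

    return EffectCurve(
        variable=spec.variable,
        x=grid,
        ratio=np.exp(log_ratio),
        lo=np.exp(log_ratio - z * se),
        hi=np.exp(log_ratio + z * se),
        scale=scale,
        x_ref=x_ref,
        extrapolated=extrapolated,
    )
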