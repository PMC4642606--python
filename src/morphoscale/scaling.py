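"""Scaling-dimension estimation: log-log regression of warp variance on
bending energy, optional nugget term, and regime classification.

Under the self-similar null, partial warp variance falls as the inverse
of specific bending energy: the ordinary least-squares slope of
log(variance) on log(energy) is -1.  Slopes steeper than -1 indicate
*integration* (dominant large-scale covariation, e.g. growth
gradients); slopes shallower than -1 indicate *disintegration*, with
the isotropic Procrustes model (slope 0) as the extreme.  An additive
*nugget* variance -- scale-free digitizing noise -- can be estimated by
minimizing the regression's residual sum of squares over the nugget
subtracted from every variance before taking logs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "ScalingFit",
    "RegimeResult",
    "scaling_regression",
    "scaling_regression_nugget",
    "classify_regime",
    "uniform_point",
]


@dataclass
class ScalingFit:
    """Result of the log variance vs log energy regression."""

    slope: float
    intercept: float
    nugget: float | None  # additive variance term, None if not fitted
    subset: np.ndarray  # 0-based warp indices used
    sse: float  # residual sum of squares on the log scale
    n_warps: int
    variances: np.ndarray  # the full input vector (all warps)
    energies: np.ndarray
    nugget_at_boundary: bool = False
    bootstrap_ci: tuple[float, float] | None = None
    outliers: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def predicted_log_variance(self, log_energy: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(log_energy)


@dataclass
class RegimeResult:
    label: str  # integrated | self-similar | disintegrated | indeterminate
    ci: tuple[float, float] | None
    slopes: np.ndarray  # bootstrap slope distribution (possibly empty)


def _prepare(variances, energies, subset):
    variances = np.asarray(variances, dtype=float)
    energies = np.asarray(energies, dtype=float)
    if variances.shape != energies.shape or variances.ndim != 1:
        raise ValueError("variances and energies must be equal-length vectors")
    if subset is None:
        subset = np.arange(variances.size)
    else:
        subset = np.unique(np.asarray(subset, dtype=int))
    if np.any(subset < 0) or np.any(subset >= variances.size):
        raise IndexError("subset index out of range")
    return variances, energies, subset


def _ols(logv: np.ndarray, loge: np.ndarray) -> tuple[float, float, float]:
    slope, intercept = np.polyfit(loge, logv, 1)
    resid = logv - (intercept + slope * loge)
    return float(slope), float(intercept), float(resid @ resid)


def _studentized_outliers(logv, loge, slope, intercept) -> np.ndarray:
    resid = logv - (intercept + slope * loge)
    m = resid.size
    if m <= 3:
        return np.array([], dtype=int)
    x = loge - loge.mean()
    h = 1.0 / m + x ** 2 / (x @ x)
    s2 = (resid @ resid) / (m - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = resid / np.sqrt(s2 * (1.0 - h))
    return np.flatnonzero(np.abs(t) > 3.0)


def scaling_regression(
    variances,
    energies,
    subset=None,
) -> ScalingFit:
    """Unweighted OLS of log(variance) on log(energy) over a warp subset.

    Warp indices in ``subset`` are 0-based; the default uses all warps.
    Warps flagged as outliers (studentized residual above 3) are
    reported in the result but never dropped automatically -- excluding
    a warp is a scientific judgment, not an algorithmic one.
    """
    variances, energies, subset = _prepare(variances, energies, subset)
    if subset.size < 2:
        raise ValueError("need at least 2 warps for a regression")
    v, e = variances[subset], energies[subset]
    if np.any(v <= 0) or np.any(e <= 0):
        raise ValueError("variances and energies must be strictly positive")
    logv, loge = np.log(v), np.log(e)
    slope, intercept, sse = _ols(logv, loge)
    out = _studentized_outliers(logv, loge, slope, intercept)
    return ScalingFit(
        slope, intercept, None, subset, sse, variances.size,
        variances, energies, outliers=subset[out],
    )


def scaling_regression_nugget(
    variances,
    energies,
    subset=None,
) -> ScalingFit:
    """Scaling regression with an additive nugget variance.

    Finds nu in [0, 0.999 * min variance) minimizing the SSE of the OLS
    fit of log(variance - nu) on log(energy), by a 64-point grid scan
    refined with bounded golden-section/Brent search.  If the optimum
    sits at the upper boundary the fit is flagged.
    """
    variances, energies, subset = _prepare(variances, energies, subset)
    if subset.size < 3:
        raise ValueError("nugget fitting needs at least 3 warps")
    v, e = variances[subset], energies[subset]
    if np.any(v <= 0) or np.any(e <= 0):
        raise ValueError("variances and energies must be strictly positive")
    loge = np.log(e)
    hi = (1.0 - 1e-6) * v.min()

    def sse_of(nu: float) -> float:
        return _ols(np.log(v - nu), loge)[2]

    grid = np.linspace(0.0, hi * 0.999, 64)
    sses = np.array([sse_of(nu) for nu in grid])
    j = int(np.argmin(sses))
    lo_b = grid[max(j - 1, 0)]
    hi_b = grid[min(j + 1, grid.size - 1)]
    if hi_b > lo_b:
        res = minimize_scalar(sse_of, bounds=(lo_b, hi_b), method="bounded",
                              options={"xatol": 1e-14 * max(hi, 1e-300)})
        nu = float(res.x) if res.fun <= sses[j] else float(grid[j])
    else:
        nu = float(grid[j])
    if nu < 0:
        nu = 0.0
    slope, intercept, sse = _ols(np.log(v - nu), loge)
    at_boundary = nu >= grid[-1]
    out = _studentized_outliers(np.log(v - nu), loge, slope, intercept)
    return ScalingFit(
        slope, intercept, nu, subset, sse, variances.size,
        variances, energies, nugget_at_boundary=at_boundary,
        outliers=subset[out],
    )


def classify_regime(
    fit: ScalingFit,
    scores: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> RegimeResult:
    """Bootstrap-over-specimens classification of the scaling regime.

    ``scores`` is the (n, m, d) partial-warp score array the variances
    came from.  Specimens are resampled with replacement, warp variances
    recomputed, and the regression refitted (with a nugget if ``fit``
    has one); the percentile confidence interval of the slope yields the
    label: *self-similar* if it contains -1, *integrated* if entirely
    below -1, *disintegrated* if entirely above.  Fewer than 10
    specimens gives "indeterminate" with no interval.
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.shape[0]
    if n < 10:
        return RegimeResult("indeterminate", None, np.array([]))
    rng = np.random.default_rng(seed)
    refit = scaling_regression_nugget if fit.nugget is not None else scaling_regression
    slopes = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        var = scores[idx].var(axis=0, ddof=1).sum(axis=1)
        if np.any(var[fit.subset] <= 0):
            var = np.maximum(var, 1e-300)
        try:
            slopes[b] = refit(var, fit.energies, fit.subset).slope
        except ValueError:
            slopes[b] = np.nan
    slopes = slopes[np.isfinite(slopes)]
    tail = (1.0 - level) / 2.0
    lo, hi = np.quantile(slopes, [tail, 1.0 - tail])
    if hi < -1.0:
        label = "integrated"
    elif lo > -1.0:
        label = "disintegrated"
    else:
        label = "self-similar"
    fit.bootstrap_ci = (float(lo), float(hi))
    return RegimeResult(label, (float(lo), float(hi)), slopes)


def uniform_point(fit: ScalingFit, uniform_variance: float) -> tuple[float, float]:
    """Fictive log-log plot position of the uniform term ("partial warp 0").

    The uniform term has zero bending energy, so it has no abscissa of
    its own; this heuristic assigns it a fictive one by sliding along
    the fitted line: displaced from warp 1's log-energy by
    log(uniform_variance / variance_1) / slope.  With variance ratio
    1.74 and slope -2.2 that is log(1.74)/2.2 ~ 0.252 to the left of
    warp 1.  The abscissa is indeterminate in principle; treat the
    output as a plotting heuristic only.
    """
    if fit.slope == 0.0:
        raise ValueError("uniform point undefined for zero slope")
    if uniform_variance <= 0:
        raise ValueError("uniform variance must be positive")
    e1 = fit.energies[fit.subset[0]]
    v1 = fit.variances[fit.subset[0]]
    abscissa = np.log(e1) + np.log(uniform_variance / v1) / fit.slope
    return float(abscissa), float(np.log(uniform_variance))
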