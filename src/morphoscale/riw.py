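"""Relative intrinsic warps and the quadratic growth-gradient analysis.

The *relative intrinsic warps* (RIWs) are the principal components of
the bending-deflated shape coordinates.  Because deflation rescales the
warp basis by sqrt(E_1/E_l) (2D) or E_1/E_l (3D), this ordinary PCA is
equivalent to a relative eigenanalysis of the nonaffine shape
covariance with respect to the bending-energy quadratic form: the
components are orthogonal in the bending-energy metric and rank shape
features by how much variance they carry relative to their geometric
scale.  Each loading can also be re-expressed with the undeflated warps
("reinflated"), which restores the visual weight of small-scale
features such as single-landmark displacements.

The *quadratic growth gradient* is a cruder summary of large-scale
integration: principal components of the projections onto the
orthonormalized quadratic monomials (x^2, xy, y^2 per output axis,
after partialling out the linear terms).  A shape change whose affine
derivative varies linearly across the form lives entirely in this
6-dimensional space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Configuration
from .procrustes import ProcrustesFit
from .tps import SplineMap, tps_map
from .warps import DeflatedSample

__all__ = [
    "RIWResult",
    "QuadraticGradient",
    "relative_intrinsic_warps",
    "riw_grid",
    "quadratic_gradient",
]


@dataclass
class RIWResult:
    eigenvalues: np.ndarray  # descending, nonnegative
    loadings_deflated: np.ndarray  # (n_comp, k, d) unit-norm patterns
    loadings_reinflated: np.ndarray  # same patterns with undeflated warps
    warp_coefficients: np.ndarray  # (n_comp, m, d) in the deflated warp basis
    scores: np.ndarray  # (n, n_comp)
    var_explained: np.ndarray
    deflated: DeflatedSample

    @property
    def n_components(self) -> int:
        return self.eigenvalues.size


def relative_intrinsic_warps(
    deflated: DeflatedSample, rank_tol: float = 1e-10
) -> RIWResult:
    """Principal components of a deflated sample.

    Components with eigenvalue below ``rank_tol`` times the largest are
    dropped; no automatic retention rule beyond that is applied.
    Loadings are stored both in the deflated frame (unit-norm patterns
    of the deflated coordinates) and reinflated (each warp component
    multiplied back by (E_l/E_1)^p and renormalized).
    """
    n = deflated.n
    if n < 3:
        raise ValueError("need at least 3 specimens for a meaningful PCA")
    spec = deflated.spectrum
    k, d = spec.mean.coords.shape
    flat = (deflated.coords - spec.mean.coords[None]).reshape(n, k * d)
    flat = flat - flat.mean(axis=0)
    u, s, vt = np.linalg.svd(flat, full_matrices=False)
    eigvals = s ** 2 / (n - 1)
    keep = eigvals > rank_tol * max(eigvals.max(), 1e-300)
    eigvals = eigvals[keep]
    loadings = vt[keep]  # (n_comp, 2k)
    # deterministic sign: largest-magnitude entry positive
    idx = np.argmax(np.abs(loadings), axis=1)
    signs = np.sign(loadings[np.arange(loadings.shape[0]), idx])
    loadings = loadings * signs[:, None]
    scores = flat @ loadings.T

    patterns = loadings.reshape(-1, k, d)
    coeff = np.einsum("ckd,km->cmd", patterns, spec.warps)
    re_coeff = coeff / deflated.prefactors[None, :, None]
    re_patterns = np.einsum("cmd,km->ckd", re_coeff, spec.warps)
    norms = np.sqrt((re_patterns ** 2).sum(axis=(1, 2)))
    re_patterns = re_patterns / norms[:, None, None]

    total = flat.var(axis=0, ddof=1).sum()
    return RIWResult(
        eigvals, patterns, re_patterns, coeff, scores,
        eigvals / total, deflated,
    )


def riw_grid(
    result: RIWResult,
    index: int,
    amplitude: float,
    reinflated: bool = False,
) -> SplineMap:
    """Thin-plate map from the mean to mean + amplitude * loading.

    ``index`` is 0-based.  With ``reinflated`` the undeflated-warp
    version of the pattern is drawn instead, restoring small-scale
    detail.
    """
    if not 0 <= index < result.n_components:
        raise IndexError(f"component {index} out of range")
    pattern = (
        result.loadings_reinflated[index]
        if reinflated
        else result.loadings_deflated[index]
    )
    mean = result.deflated.spectrum.mean
    target = Configuration(mean.coords + amplitude * pattern)
    return tps_map(mean, target)


@dataclass
class QuadraticGradient:
    basis: np.ndarray  # (n_terms, k, d) orthonormal quadratic directions
    scores: np.ndarray  # (n, n_terms)
    pc_eigenvalues: np.ndarray
    pc_loadings: np.ndarray  # (n_comp, n_terms)
    pc_scores: np.ndarray  # (n, n_comp)
    var_explained: np.ndarray


def _quadratic_columns(mean: np.ndarray) -> np.ndarray:
    d = mean.shape[1]
    if d == 2:
        x, y = mean[:, 0], mean[:, 1]
        return np.column_stack([x * x, x * y, y * y])
    x, y, z = mean[:, 0], mean[:, 1], mean[:, 2]
    return np.column_stack([x * x, x * y, y * y, x * z, y * z, z * z])


def quadratic_gradient(fit: ProcrustesFit) -> QuadraticGradient:
    """PCA of the quadratic-trend subspace of a Procrustes sample.

    The quadratic monomials of the mean's coordinates are partialled
    against the affine span {1, x, y[, z]} and orthonormalized
    (Gram-Schmidt, fixed order), then replicated once per output axis
    to give 6 (2D) or 18 (3D) orthonormal directions in coordinate
    space.  Specimen deviations are projected onto these directions and
    the resulting scores decomposed by PCA.
    """
    mean = fit.mean
    k, d = mean.shape
    quad = _quadratic_columns(mean)
    if k < (d + 1) + quad.shape[1]:
        raise ValueError(
            f"k={k} landmarks cannot support a rank-{quad.shape[1]} "
            "quadratic basis beyond the affine terms"
        )
    lin = np.hstack([np.ones((k, 1)), mean])
    resid = quad - lin @ np.linalg.lstsq(lin, quad, rcond=None)[0]
    q, r = np.linalg.qr(resid)
    # deterministic orientation of the orthonormalized columns
    q = q * np.sign(np.diag(r))[None, :]
    n_q = q.shape[1]

    # one direction per (quadratic term, output axis); orthonormal in 2k space
    basis = np.zeros((n_q * d, k, d))
    t = 0
    for axis in range(d):
        for j in range(n_q):
            basis[t, :, axis] = q[:, j]
            t += 1

    dev = fit.deviations.reshape(fit.n, k * d)
    flat_basis = basis.reshape(t, k * d)
    scores = dev @ flat_basis.T

    centered = scores - scores.mean(axis=0)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    eig = s ** 2 / (fit.n - 1)
    idx = np.argmax(np.abs(vt), axis=1)
    signs = np.sign(vt[np.arange(vt.shape[0]), idx])
    vt = vt * signs[:, None]
    pc_scores = centered @ vt.T
    total = centered.var(axis=0, ddof=1).sum()
    total = total if total > 0 else 1.0
    return QuadraticGradient(basis, scores, eig, vt, pc_scores, eig / total)
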