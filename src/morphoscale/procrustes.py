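"""Generalized Procrustes superposition and the uniform (affine) subspace.

Every specimen is centered, scaled to unit centroid size, and rotated to
the evolving consensus until the consensus stabilizes; the consensus is
then *standardized* -- centered, unit centroid size, rotated to principal
axes -- and all specimens are carried into that frame.  For a
standardized 2D mean with moments alpha = sum x_i^2 and
gamma = 1 - alpha = sum y_i^2, the uniform (affine) subspace of the
Procrustes tangent space is spanned by the two row vectors

    ( alpha y_1,  gamma x_1,  alpha y_2,  gamma x_2, ... )
    (-gamma x_1,  alpha y_1, -gamma x_2,  alpha y_2, ... )

in the vectorized coordinate order (x1, y1, x2, y2, ...).  These rows
are orthogonal to every principal warp, so the nonaffine projection and
the partial-warp machinery commute.  No closed-form basis of this kind
exists in 3D; there the affine component is removed by per-specimen
least-squares regression on (1, x, y, z) of the mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Configuration, DegenerateConfigurationError, ShapeSample

__all__ = [
    "ProcrustesFit",
    "UniformBasis",
    "GPAConvergenceError",
    "gpa",
    "standardize_mean",
    "uniform_basis",
    "project_nonaffine",
]


class GPAConvergenceError(RuntimeError):
    def __init__(self, iterations: int, last_change: float):
        self.iterations = iterations
        self.last_change = last_change
        super().__init__(
            f"GPA did not converge in {iterations} iterations "
            f"(last mean change {last_change:.3e})"
        )


@dataclass
class ProcrustesFit:
    """Aligned sample, standardized mean, and the 2D mean moments."""

    aligned: np.ndarray  # (n, k, d) shape coordinates
    mean: np.ndarray  # (k, d) standardized mean
    centroid_sizes: np.ndarray  # (n,) original sizes
    alpha: float | None  # sum x_i^2 of the mean (2D only)
    gamma: float | None  # sum y_i^2 = 1 - alpha (2D only)
    iterations: int

    @property
    def n(self) -> int:
        return self.aligned.shape[0]

    @property
    def k(self) -> int:
        return self.aligned.shape[1]

    @property
    def dim(self) -> int:
        return self.aligned.shape[2]

    @property
    def deviations(self) -> np.ndarray:
        """(n, k, d) residuals of the aligned specimens from the mean."""
        return self.aligned - self.mean[None]

    def as_sample(self) -> ShapeSample:
        return ShapeSample.from_array(self.aligned)


@dataclass
class UniformBasis:
    """Two spanning row vectors of the 2D uniform subspace.

    ``vectors`` holds the raw rows in the (x1, y1, ..., xk, yk) order;
    ``orthonormal`` is the same span orthonormalized for projections.
    """

    vectors: np.ndarray  # (2, 2k)
    orthonormal: np.ndarray  # (2, 2k)


def _center_scale(coords: np.ndarray) -> tuple[np.ndarray, float]:
    c = coords - coords.mean(axis=0)
    size = float(np.sqrt((c ** 2).sum()))
    if size == 0.0:
        raise DegenerateConfigurationError("configuration has zero centroid size")
    return c / size, size


def _optimal_rotation(x: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Proper rotation R minimizing ||x R - target||_F (no reflection)."""
    u, _, vt = np.linalg.svd(x.T @ target)
    r = u @ vt
    if np.linalg.det(r) < 0:
        u[:, -1] *= -1
        r = u @ vt
    return r


def _rotate_all(arr: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Optimally rotate each centered specimen in (n, k, d) to the target."""
    n, k, d = arr.shape
    if d == 2:
        # closed form: rotation angle from the pooled dot and cross products
        a = np.einsum("nki,ki->n", arr, target)
        b = arr[:, :, 0] @ target[:, 1] - arr[:, :, 1] @ target[:, 0]
        theta = np.arctan2(b, a)
        c, s = np.cos(theta), np.sin(theta)
        rot = np.empty_like(arr)
        rot[:, :, 0] = c[:, None] * arr[:, :, 0] - s[:, None] * arr[:, :, 1]
        rot[:, :, 1] = s[:, None] * arr[:, :, 0] + c[:, None] * arr[:, :, 1]
        return rot
    out = np.empty_like(arr)
    for i in range(n):
        out[i] = arr[i] @ _optimal_rotation(arr[i], target)
    return out


def standardize_mean(config: Configuration) -> Configuration:
    """Center, scale to unit centroid size, and rotate to principal axes.

    In 2D the output satisfies sum x = sum y = sum xy = 0 and
    sum x^2 >= sum y^2; in 3D the coordinate second-moment matrix is
    diagonal with non-increasing entries.  The residual ambiguity (180
    degree rotations about the principal axes) is resolved by requiring
    the landmark farthest from the centroid to have coordinates as
    positive as possible, so the output is deterministic.  Only proper
    rotations are used; the shape is never reflected.
    """
    coords, _ = _center_scale(config.coords)
    d = config.dim
    m = coords.T @ coords
    evals, evecs = np.linalg.eigh(m)
    order = np.argsort(evals)[::-1]
    r = evecs[:, order]
    if np.linalg.det(r) < 0:
        r[:, -1] *= -1
    rotated = coords @ r
    ref = int(np.argmax((rotated ** 2).sum(axis=1)))
    # proper sign flips: any even number of axis negations
    best = None
    if d == 2:
        flips = [np.array([1.0, 1.0]), np.array([-1.0, -1.0])]
    else:
        flips = [
            np.array(f, dtype=float)
            for f in [(1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)]
        ]
    for f in flips:
        cand = rotated * f
        key = tuple(np.round(cand[ref], 12))
        if best is None or key > best[0]:
            best = (key, cand)
    out = best[1]
    return Configuration(out, config.labels, config.id)


def gpa(sample: ShapeSample, tol: float = 1e-10, max_iter: int = 200) -> ProcrustesFit:
    """Generalized Procrustes superposition onto a standardized consensus.

    Specimens are centered and scaled to unit centroid size (full
    Procrustes), then iteratively rotated to the evolving consensus
    until the consensus changes by less than ``tol`` in Frobenius norm.
    The converged consensus is standardized by :func:`standardize_mean`
    and all specimens are re-rotated into that frame.
    """
    raw = sample.coords
    n = raw.shape[0]
    sizes = np.empty(n)
    arr = np.empty_like(raw)
    for i in range(n):
        arr[i], sizes[i] = _center_scale(raw[i])

    mean, _ = _center_scale(arr[0])
    iterations = 0
    change = np.inf
    for iterations in range(1, max_iter + 1):
        arr = _rotate_all(arr, mean)
        new_mean, _ = _center_scale(arr.mean(axis=0))
        # the consensus orientation is itself arbitrary; compare in a
        # common frame so convergence is detected rotation-free
        new_mean = new_mean @ _optimal_rotation(new_mean, mean)
        change = float(np.sqrt(((new_mean - mean) ** 2).sum()))
        mean = new_mean
        if change < tol:
            break
    else:
        raise GPAConvergenceError(max_iter, change)

    smean = standardize_mean(Configuration(mean)).coords
    arr = _rotate_all(arr, smean)

    if sample.dim == 2:
        alpha = float((smean[:, 0] ** 2).sum())
        gamma = float((smean[:, 1] ** 2).sum())
    else:
        alpha = gamma = None
    return ProcrustesFit(arr, smean, sizes, alpha, gamma, iterations)


def uniform_basis(mean: Configuration | np.ndarray) -> UniformBasis:
    """The two uniform-subspace row vectors for a standardized 2D mean."""
    coords = mean.coords if isinstance(mean, Configuration) else np.asarray(mean)
    if coords.shape[1] != 2:
        raise ValueError(
            "no closed-form uniform basis exists in 3D; "
            "use project_nonaffine, which removes the affine term by regression"
        )
    x, y = coords[:, 0], coords[:, 1]
    alpha = float((x ** 2).sum())
    gamma = float((y ** 2).sum())
    k = coords.shape[0]
    u1 = np.empty(2 * k)
    u2 = np.empty(2 * k)
    u1[0::2] = alpha * y
    u1[1::2] = gamma * x
    u2[0::2] = -gamma * x
    u2[1::2] = alpha * y
    vectors = np.vstack([u1, u2])
    q, _ = np.linalg.qr(vectors.T)
    return UniformBasis(vectors, q.T)


def _affine_residual_3d(dev: np.ndarray, mean: np.ndarray) -> np.ndarray:
    """Residual of each specimen's deviation after regression on (1, mean)."""
    n, k, d = dev.shape
    design = np.hstack([np.ones((k, 1)), mean])  # (k, d+1)
    proj = design @ np.linalg.pinv(design)
    resid = dev - np.einsum("ij,njd->nid", proj, dev)
    return resid


def project_nonaffine(fit: ProcrustesFit) -> ShapeSample:
    """Remove the uniform (affine) component from every aligned specimen.

    2D: the deviation of each specimen from the mean is projected onto
    the orthogonal complement of the two-vector uniform basis and added
    back to the mean.  3D: the affine subspace is removed by
    per-specimen multivariate regression of the deviation on
    (1, x, y, z) of the mean.  Either way the result has zero uniform
    component, and the operation is idempotent.
    """
    dev = fit.deviations
    if fit.dim == 2:
        basis = uniform_basis(fit.mean).orthonormal
        flat = dev.reshape(fit.n, -1)
        flat = flat - (flat @ basis.T) @ basis
        out = fit.mean[None] + flat.reshape(dev.shape)
    else:
        out = fit.mean[None] + _affine_residual_3d(dev, fit.mean)
    return ShapeSample.from_array(out)
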