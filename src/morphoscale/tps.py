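"""Thin-plate spline systems, interpolation maps, and bending energy.

The spline interpolating heights ``h_i`` at landmarks ``P_i`` is

    f(P) = sum_i v_i U(P - P_i) + a_0 + a_x x + a_y y [+ a_z z]

with kernel U(r) = r^2 log r in 2D (U(0) = 0 by continuity) and
U(r) = |r| in 3D.  The coefficients solve the bordered linear system
L V = H where L stacks the kernel matrix K over the affine design
Q = (1, coordinates).  The *bending energy* of the interpolant -- the
integral of summed squared second derivatives over the whole plane --
equals (1/8 pi) V^t K V, and the k x k upper-left block of L^{-1} is the
*bending-energy matrix* whose quadratic form gives that energy for any
height vector directly.

In 3D the upper-left block of L^{-1} is negative semidefinite; this
module sign-normalizes it so that downstream code always sees a positive
semidefinite bending-energy matrix with positive eigenvalues.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import lu_factor, lu_solve

from .core import Configuration, DegenerateConfigurationError, _affine_rank

__all__ = [
    "SplineSystem",
    "SplineMap",
    "build_spline_system",
    "tps_map",
    "bending_energy_matrix",
    "bending_energy",
    "evaluate_grid",
    "ZERO_EIGENVALUE_RTOL",
]

#: eigenvalues below this fraction of the largest count as zero
ZERO_EIGENVALUE_RTOL = 1e-9


def _kernel(r: np.ndarray, dim: int) -> np.ndarray:
    if dim == 2:
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(r > 0.0, r * r * np.log(np.where(r > 0, r, 1.0)), 0.0)
        return out
    return r


def _check_nondegenerate(coords: np.ndarray) -> None:
    k, d = coords.shape
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff ** 2).sum(-1))
    if np.any(dist[np.triu_indices(k, 1)] == 0.0):
        raise DegenerateConfigurationError("coincident landmarks")
    if _affine_rank(coords) < d + 1:
        raise DegenerateConfigurationError(
            "collinear (2D) or coplanar (3D) landmarks: spline system singular"
        )


def _assemble(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (K, Q, L) for a source configuration."""
    k, d = coords.shape
    diff = coords[:, None, :] - coords[None, :, :]
    r = np.sqrt((diff ** 2).sum(-1))
    K = _kernel(r, d)
    Q = np.hstack([np.ones((k, 1)), coords])
    L = np.zeros((k + d + 1, k + d + 1))
    L[:k, :k] = K
    L[:k, k:] = Q
    L[k:, :k] = Q.T
    return K, Q, L


@dataclass
class SplineSystem:
    """One solved height problem over a source configuration."""

    source: Configuration
    K: np.ndarray
    Q: np.ndarray
    L: np.ndarray
    H: np.ndarray  # (h_1 ... h_k, 0, ..., 0)
    V: np.ndarray  # (v_1 ... v_k, a_0, a_x, a_y[, a_z])

    @property
    def k(self) -> int:
        return self.source.k

    @property
    def dim(self) -> int:
        return self.source.dim

    @property
    def spline_weights(self) -> np.ndarray:
        return self.V[: self.k]

    @property
    def affine_coefficients(self) -> np.ndarray:
        return self.V[self.k :]

    def evaluate(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        r = np.sqrt(
            ((pts[:, None, :] - self.source.coords[None, :, :]) ** 2).sum(-1)
        )
        U = _kernel(r, self.dim)
        a = self.affine_coefficients
        return U @ self.spline_weights + a[0] + pts @ a[1:]


def build_spline_system(source: Configuration, heights: np.ndarray) -> SplineSystem:
    """Assemble and solve the bordered spline system for one height vector."""
    coords = source.coords
    _check_nondegenerate(coords)
    heights = np.asarray(heights, dtype=float).ravel()
    if heights.size != source.k:
        raise ValueError("heights must have one entry per landmark")
    K, Q, L = _assemble(coords)
    H = np.concatenate([heights, np.zeros(source.dim + 1)])
    V = np.linalg.solve(L, H)
    return SplineSystem(source, K, Q, L, H, V)


def bending_energy(system: SplineSystem) -> float:
    """Bending energy (1/8 pi) V^t K V of a solved system, >= 0.

    In 3D the quadratic form is negative; the returned value is
    sign-normalized to be nonnegative, matching the sign convention of
    :func:`bending_energy_matrix`.
    """
    value = _energy_formulas(system)[0]
    return abs(value)


def _energy_formulas(system: SplineSystem) -> tuple[float, float, float]:
    """The three algebraically equivalent bending-energy expressions.

    Returns ((1/8pi) V^t K V, (1/8pi) V^t H, (1/8pi) H_k^t B_signed H_k)
    before sign normalization; used to cross-check the assembly.
    """
    k = system.k
    v = system.spline_weights
    h = system.H[:k]
    c = 1.0 / (8.0 * np.pi)
    f1 = c * float(v @ system.K @ v)
    f2 = c * float(system.V @ system.H)
    B = np.linalg.inv(system.L)[:k, :k]
    f3 = c * float(h @ B @ h)
    return f1, f2, f3


@dataclass
class SplineMap:
    """A landmark-to-landmark thin-plate deformation of the plane or space."""

    source: Configuration
    systems: list[SplineSystem]  # one height problem per target coordinate

    @property
    def dim(self) -> int:
        return self.source.dim

    def __call__(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return np.column_stack([s.evaluate(pts) for s in self.systems])

    def bending_energy(self) -> float:
        """Total energy: the scalar sum over target coordinate splines."""
        return sum(bending_energy(s) for s in self.systems)


def tps_map(source: Configuration, target: Configuration) -> SplineMap:
    """Thin-plate spline mapping ``source`` landmarks onto ``target``.

    One height problem is solved per target coordinate, all reusing a
    single LU factorization of the bordered matrix L.
    """
    if source.coords.shape != target.coords.shape:
        raise ValueError("source and target must share k and d")
    coords = source.coords
    _check_nondegenerate(coords)
    k, d = coords.shape
    K, Q, L = _assemble(coords)
    lu = lu_factor(L)
    systems = []
    for axis in range(d):
        H = np.concatenate([target.coords[:, axis], np.zeros(d + 1)])
        V = lu_solve(lu, H)
        systems.append(SplineSystem(source, K, Q, L, H, V))
    return SplineMap(source, systems)


def bending_energy_matrix(mean: Configuration) -> np.ndarray:
    """The k x k bending-energy matrix of a configuration.

    This is the upper-left block of the inverse bordered spline matrix.
    It is symmetric positive semidefinite of rank k-3 in 2D; in 3D the
    raw block is negative semidefinite of rank k-4 and is returned
    negated so that the nonzero eigenvalues are positive in either case.
    Its null space is spanned by the affine height patterns 1, x, y[, z].
    """
    coords = mean.coords
    _check_nondegenerate(coords)
    k = mean.k
    _, _, L = _assemble(coords)
    B = np.linalg.inv(L)[:k, :k]
    B = 0.5 * (B + B.T)
    if mean.dim == 3:
        B = -B
    return B


def evaluate_grid(
    spline_map: SplineMap,
    bounds: tuple[float, float, float, float] | None = None,
    resolution: int = 20,
) -> tuple[np.ndarray, np.ndarray]:
    """Map a regular source grid through a 2D spline for plotting.

    Parameters
    ----------
    spline_map
        The deformation to render.
    bounds
        (xmin, xmax, ymin, ymax); defaults to the source's bounding box
        padded by 10% of its span on each side.
    resolution
        Number of grid nodes per axis.

    Returns
    -------
    (source_points, mapped_points), each of shape (resolution, resolution, 2).
    """
    if spline_map.dim != 2:
        raise ValueError("grid rendering is 2D only")
    c = spline_map.source.coords
    if bounds is None:
        span = c.max(axis=0) - c.min(axis=0)
        pad = 0.1 * span
        bounds = (
            c[:, 0].min() - pad[0],
            c[:, 0].max() + pad[0],
            c[:, 1].min() - pad[1],
            c[:, 1].max() + pad[1],
        )
    xs = np.linspace(bounds[0], bounds[1], resolution)
    ys = np.linspace(bounds[2], bounds[3], resolution)
    gx, gy = np.meshgrid(xs, ys)
    src = np.column_stack([gx.ravel(), gy.ravel()])
    dst = spline_map(src)
    shape = (resolution, resolution, 2)
    return src.reshape(shape), dst.reshape(shape)
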