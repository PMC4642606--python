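"""Principal warps, partial warp scores, and bending-energy deflation.

The *principal warps* are the eigenvectors of the bending-energy matrix
of the mean configuration; their eigenvalues E_l (sorted ascending) are
the *specific bending energies*, an inverse index of geometric scale.
Projecting each specimen's Procrustes deviation onto warp l -- one dot
product per Cartesian axis -- gives its *partial warp scores*.

*Deflation* rescales the warp-l component of every specimen by
sqrt(E_1 / E_l) in 2D (by E_1 / E_l in 3D, where the kernel is |r|
instead of r^2 log r), leaving the largest-scale warp untouched.  Under
the isotropic offset Gaussian (Mardia-Dryden) model this turns the
scale-free Procrustes distribution into a spatially *self-similar* one:
feature variance becomes proportional to inverse squared feature scale
at every scale at once.  Deflation discards the uniform term and any
residual outside the warp span (both have zero bending energy or live
in the similarity directions), so deflate followed by reinflate equals
the nonaffine projection of the input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Configuration, ShapeSample
from .procrustes import ProcrustesFit
from .tps import ZERO_EIGENVALUE_RTOL, bending_energy_matrix

__all__ = [
    "BendingSpectrum",
    "PartialWarpScores",
    "DeflatedSample",
    "principal_warps",
    "partial_warp_scores",
    "deflate",
    "reinflate",
]


@dataclass
class BendingSpectrum:
    """Nonzero eigenpairs of a bending-energy matrix."""

    energies: np.ndarray  # (m,) ascending, strictly positive
    warps: np.ndarray  # (k, m) unit-norm eigenvector columns
    mean: Configuration
    zero_tol: float

    @property
    def m(self) -> int:
        return self.energies.size

    @property
    def k(self) -> int:
        return self.warps.shape[0]


@dataclass
class PartialWarpScores:
    """Per-specimen, per-warp projections of the Procrustes deviations."""

    scores: np.ndarray  # (n, m, d)
    variances: np.ndarray  # (m,) summed over the d components
    spectrum: BendingSpectrum

    @property
    def n(self) -> int:
        return self.scores.shape[0]


@dataclass
class DeflatedSample:
    """Shape coordinates after bending-energy deflation."""

    coords: np.ndarray  # (n, k, d)
    prefactors: np.ndarray  # (m,) sqrt(E_1/E_l) in 2D, E_1/E_l in 3D
    spectrum: BendingSpectrum
    power: float  # exponent p in (E_1/E_l)^p; 1/2 in 2D, 1 in 3D

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    def as_sample(self) -> ShapeSample:
        return ShapeSample.from_array(self.coords)


def _fix_signs(warps: np.ndarray) -> np.ndarray:
    """Make each column's largest-magnitude entry positive (reproducible)."""
    idx = np.argmax(np.abs(warps), axis=0)
    signs = np.sign(warps[idx, np.arange(warps.shape[1])])
    signs[signs == 0] = 1.0
    return warps * signs


def _canonical_eigenbasis(energies: np.ndarray, warps: np.ndarray) -> np.ndarray:
    """Deterministic basis within repeated eigenspaces.

    Symmetric means (squares, grids) force eigenvalue multiplicities,
    within which the eigenvector basis is arbitrary.  Here each repeated
    eigenspace is re-spanned by projecting the canonical unit vectors
    e_1, e_2, ... onto it in order and orthonormalizing, so identical
    inputs give identical warps on any platform.  All statistics that
    sum over an eigenspace are invariant to this choice.
    """
    out = warps.copy()
    m = energies.size
    start = 0
    while start < m:
        stop = start + 1
        while stop < m and np.isclose(
            energies[stop], energies[start], rtol=1e-8, atol=0.0
        ):
            stop += 1
        if stop - start > 1:
            sub = out[:, start:stop]
            proj = sub @ sub.T  # projector onto the eigenspace
            basis = []
            for j in range(out.shape[0]):
                cand = proj[:, j].copy()
                for b in basis:
                    cand -= (b @ cand) * b
                norm = np.linalg.norm(cand)
                if norm > 1e-8:
                    basis.append(cand / norm)
                if len(basis) == stop - start:
                    break
            out[:, start:stop] = np.column_stack(basis)
        start = stop
    return _fix_signs(out)


def principal_warps(
    B: np.ndarray | None = None,
    mean: Configuration | None = None,
    zero_tol: float = ZERO_EIGENVALUE_RTOL,
) -> BendingSpectrum:
    """Eigendecomposition of the bending-energy matrix.

    Either pass a precomputed matrix ``B`` together with the ``mean`` it
    came from, or just the ``mean`` (the matrix is then computed here).
    Returns the m = k-3 (2D) or k-4 (3D) nonzero eigenvalues in
    ascending order with unit-norm eigenvectors under a deterministic
    sign convention.
    """
    if mean is None:
        raise ValueError("the mean configuration is required")
    if B is None:
        B = bending_energy_matrix(mean)
    evals, evecs = np.linalg.eigh(B)
    tol = zero_tol * np.abs(evals).max()
    keep = evals > tol
    if not keep.any():
        raise ValueError("no nonzero bending eigenvalues: k too small")
    energies = evals[keep]
    warps = evecs[:, keep]
    order = np.argsort(energies)
    energies = energies[order]
    warps = _canonical_eigenbasis(energies, warps[:, order])
    return BendingSpectrum(energies, warps, mean, zero_tol)


def partial_warp_scores(
    fit: ProcrustesFit, spectrum: BendingSpectrum
) -> PartialWarpScores:
    """Project every specimen's deviation onto every principal warp.

    score(j, l) is a d-vector: the dot product of warp l with the j-th
    specimen's deviation from the mean, taken per Cartesian axis.  The
    variance of warp l is the sum of its component variances.  The
    uniform term need not be removed first: the warps are orthogonal to
    it.
    """
    if fit.k != spectrum.k or fit.dim != spectrum.mean.dim:
        raise ValueError("fit and spectrum do not share a landmark scheme")
    if not np.allclose(fit.mean, spectrum.mean.coords, atol=1e-8):
        raise ValueError("fit and spectrum must be computed from the same mean")
    scores = np.einsum("nkd,km->nmd", fit.deviations, spectrum.warps)
    variances = scores.var(axis=0, ddof=1).sum(axis=1)
    return PartialWarpScores(scores, variances, spectrum)


def _default_power(dim: int) -> float:
    return 0.5 if dim == 2 else 1.0


def deflate(
    fit: ProcrustesFit,
    spectrum: BendingSpectrum | None = None,
    power: float | None = None,
) -> DeflatedSample:
    """Bending-energy deflation of a Procrustes sample.

    Each specimen is rebuilt as mean + sum_l (E_1/E_l)^p s_jl W_l where
    s_jl are its partial warp scores.  The default exponent p is 1/2 in
    2D and 1 in 3D, which produces the self-similar null; other values
    generate distributions with log variance-vs-energy slope -2p, useful
    for simulating integrated (p > default) or disintegrated regimes.
    The warp-1 component is preserved exactly; the uniform component and
    anything outside the warp span are dropped.
    """
    if spectrum is None:
        spectrum = principal_warps(mean=Configuration(fit.mean))
    if power is None:
        power = _default_power(fit.dim)
    pws = partial_warp_scores(fit, spectrum)
    pref = (spectrum.energies[0] / spectrum.energies) ** power
    weighted = pws.scores * pref[None, :, None]
    dev = np.einsum("nmd,km->nkd", weighted, spectrum.warps)
    return DeflatedSample(fit.mean[None] + dev, pref, spectrum, power)


def reinflate(deflated: DeflatedSample) -> ShapeSample:
    """Undo deflation: returns the nonaffine part of the original sample."""
    spec = deflated.spectrum
    dev = deflated.coords - spec.mean.coords[None]
    scores = np.einsum("nkd,km->nmd", dev, spec.warps)
    scores = scores / deflated.prefactors[None, :, None]
    out = np.einsum("nmd,km->nkd", scores, spec.warps)
    return ShapeSample.from_array(spec.mean.coords[None] + out)
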