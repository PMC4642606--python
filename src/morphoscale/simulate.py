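"""Synthetic landmark data: toy means, the isotropic offset Gaussian
(Mardia-Dryden) model, its bending-deflated self-similar counterpart, a
hierarchical parcellation process, and sub-configuration variance tools.

These generators define the study conditions under which every claim in
this package is validated.  The isotropic model perturbs each landmark
of a mean form with independent circular (spherical) Gaussian noise --
the "totally disintegrated" reference distribution.  Its deflated
version is the self-similar null.  The parcellation process builds
nearly self-similar deformations constructively: a square of corners is
perturbed, then each successively smaller compartment contributes one
new landmark placed at the location imputed by the thin-plate map of
everything placed so far, plus circular noise whose variance shrinks
with compartment size.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .core import Configuration, ShapeSample
from .procrustes import gpa, project_nonaffine
from .tps import tps_map
from .warps import DeflatedSample, deflate

__all__ = [
    "SimulationSpec",
    "ParcellationSpec",
    "toy_configuration",
    "isotropic_sample",
    "self_similar_sample",
    "parcellation_sample",
    "enumerate_grid_squares",
    "subconfig_nonaffine_variance",
]


@dataclass
class SimulationSpec:
    """Parameters of one isotropic (or deflated-isotropic) simulation."""

    mean: Configuration
    sigma: float  # per-coordinate sd, in the units of the mean's coordinates
    n: int
    seed: int = 0
    deflate: bool = False
    power: float | None = None  # deflation exponent override (see warps.deflate)

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.n < 2:
            raise ValueError("need at least 2 specimens")


@dataclass
class ParcellationSpec:
    """Parameters of the hierarchical parcellation generator.

    ``levels`` counts refinement stages beyond the 4 outer corners:
    0 = corners only (4 landmarks), 1 = + center (5), 2 = + edge
    midpoints (9), 3 = + quarter-cell centers (13).  ``decay`` is the
    per-level variance ratio; the default 1/2 halves the noise variance
    at each stage, tracking compartment area.
    """

    levels: int = 3
    base_sd: float = 0.15
    decay: float = 0.5
    n: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.levels <= 3:
            raise ValueError("levels must be between 0 and 3")
        if not 0.0 < self.decay <= 1.0:
            raise ValueError("decay must be in (0, 1]")
        if self.base_sd < 0:
            raise ValueError("base_sd must be nonnegative")


_TOYS = {}


def toy_configuration(name: str) -> Configuration:
    """Canonical toy mean configurations used throughout the test suite.

    - ``quincunx``: the five-spot of a die -- unit-offset square corners
      (+-1, +-1) numbered consecutively around the outline, plus the
      center as landmark 5.
    - ``grid5``: a 5 x 5 square grid at integer positions 0..4 x 0..4.
    - ``prologue6``: a unit square (landmarks 1-4, with 2 and 3
      diagonally opposite) plus landmarks 5, 6 completing the
      sqrt(2)-scale square erected outward on the diagonal 2-3.  The
      layout's identifying signature is its bending-eigenvalue ratio
      sequence 1 : 1.07 : 2.15, asserted in the test suite.
    - ``giza``: two 3D square pyramids of the same shape pointing the
      same way, the larger base exactly 4 times the smaller's edge,
      bases coplanar and concentric, apex height half the base edge.
    """
    if name not in _TOYS:
        raise ValueError(f"unknown toy configuration {name!r}")
    coords, labels = _TOYS[name]
    return Configuration(np.array(coords, dtype=float), list(labels), id=name)


_TOYS["quincunx"] = (
    [(1.0, 1.0), (1.0, -1.0), (-1.0, -1.0), (-1.0, 1.0), (0.0, 0.0)],
    ["c1", "c2", "c3", "c4", "center"],
)
_TOYS["grid5"] = (
    [(float(i), float(j)) for j in range(5) for i in range(5)],
    [f"g{i}{j}" for j in range(5) for i in range(5)],
)
# landmarks 1..4 = unit square with 2-3 a diagonal; 5, 6 erect the
# sqrt(2)-scale square outward on that diagonal
_TOYS["prologue6"] = (
    [(0.0, 0.0), (1.0, 0.0), (0.0, 1.0), (1.0, 1.0), (0.0, -1.0), (-1.0, 0.0)],
    ["p1", "p2", "p3", "p4", "p5", "p6"],
)


def _pyramid(edge: float) -> list[tuple[float, float, float]]:
    h = edge / 2.0
    e = edge / 2.0
    return [(e, e, 0.0), (e, -e, 0.0), (-e, -e, 0.0), (-e, e, 0.0), (0.0, 0.0, h)]


_TOYS["giza"] = (
    _pyramid(1.0) + _pyramid(4.0),
    [f"s{i}" for i in range(1, 6)] + [f"l{i}" for i in range(1, 6)],
)


def isotropic_sample(spec: SimulationSpec) -> ShapeSample:
    """Draws from the isotropic offset Gaussian around the mean.

    Every landmark coordinate of every specimen is perturbed by
    independent Gaussian noise of standard deviation ``spec.sigma``,
    reproducibly seeded.
    """
    rng = np.random.default_rng(spec.seed)
    mean = spec.mean.coords
    draws = mean[None] + rng.normal(0.0, spec.sigma, (spec.n,) + mean.shape)
    return ShapeSample.from_array(
        draws,
        labels=spec.mean.labels,
        metadata={"model": "isotropic", "sigma": spec.sigma, "seed": spec.seed},
    )


def self_similar_sample(spec: SimulationSpec) -> DeflatedSample:
    """Isotropic simulation, Procrustes-fitted and bending-deflated."""
    sample = isotropic_sample(spec)
    fit = gpa(sample)
    return deflate(fit, power=spec.power)


def _parcellation_template() -> tuple[np.ndarray, list[int]]:
    """13-landmark template and the stage count of each refinement level."""
    corners = [(-1.0, -1.0), (1.0, -1.0), (1.0, 1.0), (-1.0, 1.0)]
    center = [(0.0, 0.0)]
    mids = [(0.0, -1.0), (1.0, 0.0), (0.0, 1.0), (-1.0, 0.0)]
    quarters = [(-0.5, -0.5), (0.5, -0.5), (0.5, 0.5), (-0.5, 0.5)]
    pts = np.array(corners + center + mids + quarters)
    return pts, [4, 5, 9, 13]


def parcellation_sample(spec: ParcellationSpec) -> ShapeSample:
    """Hierarchically parcellated deformations of a 13-landmark template.

    Per specimen: the 4 outer corners are perturbed with variance
    base_sd^2; each later landmark is placed at the location imputed by
    the thin-plate map of all previously placed landmarks, plus
    circular noise with variance reduced by a further factor of
    ``decay`` per refinement level (center: decay^1, edge midpoints:
    decay^2, quarter-cell centers: decay^3).  The output is nearly
    self-similar by construction when decay tracks compartment area.
    """
    template, counts = _parcellation_template()
    k_out = counts[spec.levels]
    rng = np.random.default_rng(spec.seed)
    out = np.empty((spec.n, k_out, 2))
    stage_sd = [
        spec.base_sd * spec.decay ** (lvl / 2.0) for lvl in range(4)
    ]  # sd per level; variance scales as decay**level
    for i in range(spec.n):
        placed = template[:4] + rng.normal(0.0, stage_sd[0], (4, 2))
        for lvl in range(1, spec.levels + 1):
            lo, hi = counts[lvl - 1], counts[lvl]
            fmap = tps_map(
                Configuration(template[:lo]), Configuration(placed)
            )
            imputed = fmap(template[lo:hi])
            noise = rng.normal(0.0, stage_sd[lvl], imputed.shape)
            placed = np.vstack([placed, imputed + noise])
        out[i] = placed
    return ShapeSample.from_array(
        out,
        metadata={
            "model": "parcellation",
            "levels": spec.levels,
            "base_sd": spec.base_sd,
            "decay": spec.decay,
            "seed": spec.seed,
        },
    )


def enumerate_grid_squares(grid: Configuration) -> list[tuple[int, int, int, int]]:
    """All 4-tuples of lattice landmarks forming a square, in cyclic order.

    The test is exact integer arithmetic on the six pairwise squared
    distances (four equal sides, two equal diagonals of twice that),
    so tilted "knight's-move" squares are found too.  Each square is
    listed once, vertices ordered counterclockwise from an arbitrary
    start.
    """
    coords = grid.coords
    if coords.shape[1] != 2:
        raise ValueError("square enumeration is 2D only")
    icoords = np.rint(coords).astype(np.int64)
    if not np.allclose(coords, icoords, atol=1e-9):
        raise ValueError("grid landmarks must sit on integer lattice positions")
    squares = []
    for combo in itertools.combinations(range(len(icoords)), 4):
        pts = icoords[list(combo)]
        d2 = []
        for a in range(4):
            for b in range(a + 1, 4):
                diff = pts[a] - pts[b]
                d2.append(int(diff @ diff))
        d2.sort()
        if d2[0] > 0 and d2[0] == d2[3] and d2[4] == d2[5] and d2[4] == 2 * d2[0]:
            center = pts.astype(float).mean(axis=0)
            ang = np.arctan2(*(pts - center).T[::-1])
            order = np.argsort(ang)
            squares.append(tuple(combo[j] for j in order))
    return squares


def subconfig_nonaffine_variance(
    coords: np.ndarray | ShapeSample | DeflatedSample,
    indices,
) -> float:
    """Per-coordinate nonaffine shape variance of a landmark subset.

    The subset is extracted from every specimen and given a *fresh*
    full Procrustes fit (re-centered, re-scaled, re-rotated in its own
    frame), its affine subspace is removed, and the trace of the
    coordinate variances divided by (d x subset size) is returned.
    This subset-level superposition is what makes the inverse-area law
    of the isotropic model (and its disappearance after deflation)
    visible.
    """
    if isinstance(coords, ShapeSample):
        arr = coords.coords
    elif isinstance(coords, DeflatedSample):
        arr = coords.coords
    else:
        arr = np.asarray(coords, dtype=float)
    indices = np.asarray(list(indices), dtype=int)
    d = arr.shape[2]
    if indices.size < d + 2:
        raise ValueError(f"need at least {d + 2} landmarks in the subset")
    sub = ShapeSample.from_array(arr[:, indices, :])
    fit = gpa(sub)
    nonaff = project_nonaffine(fit).coords
    var = nonaff.var(axis=0, ddof=1).sum()
    return float(var / (d * indices.size))
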