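"""Synthetic-data generators: toy means, isotropic and self-similar
samples, the parcellation process, square enumeration, and
sub-configuration variances."""

import itertools

import numpy as np
import pytest

import morphoscale as ms
from morphoscale.simulate import _parcellation_template


# ---------------------------------------------------------------------------
# toy configurations


def test_grid5_shape(grid5):
    assert (grid5.k, grid5.dim) == (25, 2)
    assert set(map(tuple, grid5.coords)) == {
        (float(i), float(j)) for i in range(5) for j in range(5)
    }


def _is_square(pts):
    d2 = sorted(
        ((pts[a] - pts[b]) ** 2).sum()
        for a, b in itertools.combinations(range(4), 2)
    )
    return d2[0] > 0 and np.allclose(d2[:4], d2[0]) and np.allclose(
        d2[4:], 2 * d2[0]
    )


def test_prologue6_two_squares_scale_root_two(prologue6):
    c = prologue6.coords
    small = c[[0, 1, 2, 3]]
    large = c[[1, 2, 4, 5]]
    assert _is_square(small) and _is_square(large)
    edge = lambda p: np.sqrt(min(
        ((p[a] - p[b]) ** 2).sum()
        for a, b in itertools.combinations(range(4), 2)
    ))
    assert edge(large) / edge(small) == pytest.approx(np.sqrt(2.0), abs=1e-12)


def test_giza_pentahedra_scale_four(giza):
    c = giza.coords
    small, large = c[:5], c[5:]
    for p in (small, large):
        assert _is_square(p[:4])
    def edge(p):
        return np.sqrt(min(
            ((p[a] - p[b]) ** 2).sum()
            for a, b in itertools.combinations(range(4), 2)
        ))
    assert edge(large[:4]) / edge(small[:4]) == pytest.approx(4.0, abs=1e-12)
    # same shape: centered-and-scaled copies coincide
    def norm(p):
        q = p - p.mean(axis=0)
        return q / np.sqrt((q ** 2).sum())
    np.testing.assert_allclose(norm(small), norm(large), atol=1e-12)


def test_unknown_toy_raises():
    with pytest.raises(ValueError):
        ms.toy_configuration("sphinx")


# ---------------------------------------------------------------------------
# isotropic generator


def test_generators_are_seed_deterministic(grid5):
    spec = ms.SimulationSpec(grid5, 0.1, 20, seed=42)
    a = ms.isotropic_sample(spec).coords
    b = ms.isotropic_sample(spec).coords
    np.testing.assert_array_equal(a, b)
    c = ms.isotropic_sample(ms.SimulationSpec(grid5, 0.1, 20, seed=43)).coords
    assert not np.array_equal(a, c)


def test_tiny_sigma_limit(quincunx):
    sample = ms.isotropic_sample(ms.SimulationSpec(quincunx, 1e-12, 5, seed=0))
    assert np.abs(sample.coords - quincunx.coords[None]).max() < 1e-10


def test_sample_mean_near_truth(grid5):
    spec = ms.SimulationSpec(grid5, 0.15, 1000, seed=1)
    sample = ms.isotropic_sample(spec)
    err = np.abs(sample.coords.mean(axis=0) - grid5.coords)
    assert err.max() < 3.0 * 0.15 / np.sqrt(1000) * 3.3  # ~3 sd + slack


def test_raw_scatter_is_circular(grid5):
    sample = ms.isotropic_sample(ms.SimulationSpec(grid5, 0.15, 1000, seed=8))
    dev = sample.coords - grid5.coords[None]
    for j in range(0, 25, 6):
        ev = np.linalg.eigvalsh(np.cov(dev[:, j, :], rowvar=False))
        assert ev[1] / ev[0] < 1.25


def test_undeflated_warp_variances_flat(grid5_scores):
    v = grid5_scores.variances
    assert (v.max() - v.min()) / v.mean() < 0.25
    assert v.std() / v.mean() < 0.10


# ---------------------------------------------------------------------------
# self-similar generator


def test_self_similar_sample_slope(grid5):
    deflated = ms.self_similar_sample(
        ms.SimulationSpec(grid5, 0.15, 1000, seed=1, deflate=True)
    )
    spec = deflated.spectrum
    dev = deflated.coords - spec.mean.coords[None]
    scores = np.einsum("nkd,km->nmd", dev, spec.warps)
    v = scores.var(axis=0, ddof=1).sum(axis=1)
    fit = ms.scaling_regression(v, spec.energies)
    assert fit.slope == pytest.approx(-1.0, abs=0.05)


def test_prologue_deflated_square_variances_equal(prologue6_deflated):
    v_small = ms.subconfig_nonaffine_variance(prologue6_deflated, [0, 1, 2, 3])
    v_large = ms.subconfig_nonaffine_variance(prologue6_deflated, [1, 2, 4, 5])
    assert v_large / v_small == pytest.approx(1.0, abs=0.10)


def test_giza_deflated_amplitudes_equal(giza_deflated):
    a_small = np.sqrt(ms.subconfig_nonaffine_variance(giza_deflated, range(5)))
    a_large = np.sqrt(ms.subconfig_nonaffine_variance(giza_deflated, range(5, 10)))
    assert a_small / a_large == pytest.approx(1.0, abs=0.15)


# ---------------------------------------------------------------------------
# parcellation generator


def test_parcellation_zero_noise_reproduces_template():
    sample = ms.parcellation_sample(
        ms.ParcellationSpec(levels=3, base_sd=0.0, n=3, seed=0)
    )
    template, _ = _parcellation_template()
    assert np.abs(sample.coords - template[None]).max() < 1e-9


@pytest.mark.parametrize("levels,k", [(0, 4), (1, 5), (2, 9), (3, 13)])
def test_parcellation_landmark_counts(levels, k):
    sample = ms.parcellation_sample(
        ms.ParcellationSpec(levels=levels, n=2, seed=0)
    )
    assert sample.k == k


def test_parcellation_center_to_corner_variance_ratio():
    """The center landmark's residual from its imputed location has
    variance ~ decay times the corner variance."""
    spec = ms.ParcellationSpec(levels=1, base_sd=0.15, decay=0.5, n=1000, seed=4)
    sample = ms.parcellation_sample(spec)
    template, _ = _parcellation_template()
    arr = sample.coords
    corner_var = arr[:, :4, :].var(axis=0, ddof=1).mean()
    residuals = np.empty((spec.n, 2))
    for i in range(spec.n):
        fmap = ms.tps_map(
            ms.Configuration(template[:4]), ms.Configuration(arr[i, :4])
        )
        residuals[i] = arr[i, 4] - fmap(template[4:5])[0]
    ratio = residuals.var(axis=0, ddof=1).mean() / corner_var
    assert ratio == pytest.approx(spec.decay, rel=0.15)


def test_parcellation_scaling_slope_near_minus_one():
    sample = ms.parcellation_sample(
        ms.ParcellationSpec(levels=3, base_sd=0.15, decay=0.5, n=1000, seed=4)
    )
    fit = ms.gpa(sample)
    spec = ms.principal_warps(mean=ms.Configuration(fit.mean))
    pws = ms.partial_warp_scores(fit, spec)
    sfit = ms.scaling_regression(pws.variances, spec.energies)
    assert sfit.slope == pytest.approx(-1.0, abs=0.15)


def test_parcellation_neighbors_positively_correlated():
    """Raw displacement vectors of adjacent landmarks correlate
    positively under the parcellation process but not under the
    isotropic model."""
    template, _ = _parcellation_template()
    dist = np.sqrt(((template[:, None] - template[None]) ** 2).sum(-1))
    pairs = [
        (a, b)
        for a in range(13)
        for b in range(a + 1, 13)
        if 0.0 < dist[a, b] <= 1.01
    ]

    def mean_cosine(dev):
        cs = []
        for a, b in pairs:
            u, v = dev[:, a, :], dev[:, b, :]
            num = (u * v).sum(axis=1)
            den = np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)
            cs.append((num / den).mean())
        return float(np.mean(cs))

    parc = ms.parcellation_sample(ms.ParcellationSpec(n=500, seed=7))
    cos_parc = mean_cosine(parc.coords - parc.coords.mean(axis=0))
    iso = ms.isotropic_sample(
        ms.SimulationSpec(ms.Configuration(template), 0.15, 500, seed=7)
    )
    cos_iso = mean_cosine(iso.coords - template[None])
    assert cos_parc > 0.05
    assert abs(cos_iso) < 0.05


# ---------------------------------------------------------------------------
# square enumeration


def _oracle_squares(coords):
    found = 0
    for combo in itertools.combinations(range(len(coords)), 4):
        if _is_square(coords[list(combo)]):
            found += 1
    return found


@pytest.mark.parametrize("n,expected", [(2, 1), (3, 6), (5, 50)])
def test_square_counts_on_lattices(n, expected):
    coords = np.array([(i, j) for i in range(n) for j in range(n)], dtype=float)
    cfg = ms.Configuration(coords)
    squares = ms.enumerate_grid_squares(cfg)
    assert len(squares) == expected
    assert len(set(frozenset(s) for s in squares)) == expected  # no repeats
    assert _oracle_squares(coords) == expected  # independent float oracle


def test_squares_are_in_cyclic_order(grid5):
    for sq in ms.enumerate_grid_squares(grid5):
        pts = grid5.coords[list(sq)]
        assert _is_square(pts)
        # consecutive vertices are adjacent (edge length, not diagonal)
        edges = [((pts[i] - pts[(i + 1) % 4]) ** 2).sum() for i in range(4)]
        assert np.allclose(edges, edges[0])


def test_non_lattice_input_rejected():
    cfg = ms.Configuration([[0.0, 0.0], [1.0, 0.0], [0.5, 0.7], [1.0, 1.0]])
    with pytest.raises(ValueError):
        ms.enumerate_grid_squares(cfg)


# ---------------------------------------------------------------------------
# sub-configuration variance


def test_identical_specimens_have_zero_variance(quincunx):
    arr = np.repeat(quincunx.coords[None], 5, axis=0)
    assert ms.subconfig_nonaffine_variance(arr, [0, 1, 2, 3]) == pytest.approx(
        0.0, abs=1e-20
    )


def test_prologue_inverse_area_law(prologue6_fit):
    """Before deflation the larger square carries half the nonaffine
    variance of the smaller: variance ~ 1/area."""
    v_small = ms.subconfig_nonaffine_variance(prologue6_fit.aligned, [0, 1, 2, 3])
    v_large = ms.subconfig_nonaffine_variance(prologue6_fit.aligned, [1, 2, 4, 5])
    assert v_large / v_small == pytest.approx(0.5, rel=0.10)


def test_grid5_inverse_area_law(grid5, grid5_fit):
    """Unit squares are 16x as variable as the 4x4-span square, and the
    log variance vs log area regression over all 50 squares is tight."""
    squares = ms.enumerate_grid_squares(grid5)
    areas, vs = [], []
    for sq in squares:
        pts = grid5.coords[list(sq)]
        areas.append(((pts[1] - pts[0]) ** 2).sum())
        vs.append(ms.subconfig_nonaffine_variance(grid5_fit.aligned, sq))
    areas, vs = np.array(areas), np.array(vs)
    ratio = vs[areas == 1].mean() / vs[areas == 16].mean()
    assert ratio == pytest.approx(16.0, rel=0.15)
    slope, intercept = np.polyfit(np.log(areas), np.log(vs), 1)
    pred = intercept + slope * np.log(areas)
    r2 = 1 - ((np.log(vs) - pred) ** 2).sum() / (
        (np.log(vs) - np.log(vs).mean()) ** 2
    ).sum()
    assert slope == pytest.approx(-1.0, abs=0.10)
    assert r2 > 0.95


def test_subset_too_small_rejected(grid5_fit):
    with pytest.raises(ValueError):
        ms.subconfig_nonaffine_variance(grid5_fit.aligned, [0, 1, 2])
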