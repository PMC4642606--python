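# Methods

This note records the models, conventions, numerical choices and known
limitations behind `morphoscale`, at the level of detail a maintainer
or a careful user needs.

## Shape coordinates and superposition

Specimens are superimposed by generalized Procrustes analysis in the
*full* (scaled) convention: each configuration is centered, scaled to
unit centroid size, and iteratively rotated to the evolving consensus
until the consensus changes by less than `tol` (default 1e−10) in
Frobenius norm. Only proper rotations are used; reflections are never
fitted. The converged consensus is then **standardized** — centered,
unit centroid size, rotated to principal axes so that Σxᵢyᵢ = 0 with
Σxᵢ² ≥ Σyᵢ² (in 3D, the coordinate second-moment matrix diagonal with
non-increasing entries) — and all specimens are carried into that
frame. The residual 180° ambiguities are resolved by requiring the
landmark farthest from the centroid to have coordinates as positive as
possible, using only proper (even) sign flips; every reported statistic
is invariant to this choice, which exists purely for reproducibility.

The 2D uniform (affine) subspace is spanned by the two rows

    ( αy₁,  γx₁,  αy₂,  γx₂, … )
    (−γx₁,  αy₁, −γx₂,  αy₂, … )

built from the standardized mean and its moments α = Σxᵢ², γ = 1 − α.
The second row follows the pattern "−γxᵢ, αyᵢ" at every landmark; this
is the only reading orthogonal to all principal warps, to the rotation
and scaling directions, and to translations, and the orthogonality is
asserted in the tests. Projections use the ordinary Euclidean inner product on
the vectorized (x₁,y₁,…,xₖ,yₖ) coordinates — the Procrustes tangent
metric. In 3D no such closed-form pair exists; the affine term is
removed by per-specimen least-squares regression of the deviation on
(1, x, y, z) of the mean, and the five-dimensional 3D uniform subspace
is never reported componentwise, only removed.

## Spline systems and bending energy

The kernel is U(r) = r² log r in 2D, with U(0) = 0 by continuous
extension, and U(r) = |r| in 3D. The bordered system L V = H is solved
with a single LU factorization reused across the d per-axis height
vectors. The bending-energy matrix is the k×k upper-left block of
L⁻¹, symmetrized; in 3D that block is negative semidefinite, and the
module stores its negation so that all downstream code (deflation,
scaling, RIWs) sees positive eigenvalues through one code path.
Eigenvalues below 1e−9 of the largest magnitude count as zero — a
scale-relative tolerance robust across the toy configurations used.

The scalar `bending_energy` carries the conventional 1/(8π)
normalization of the quadratic form VᵗKV. The raw integral of summed
squared second derivatives over the plane equals 8π·VᵗKV (U is 8π
times the biharmonic fundamental solution); the quadrature test
accounts for this (8π)² factor and tolerates 2% for the truncation of
the integral at a disc of 50× the configuration span.

Principal-warp eigenvectors get a deterministic sign (largest-magnitude
entry positive). Symmetric means force repeated eigenvalues, within
which the eigenbasis is arbitrary; such eigenspaces are re-spanned by
projecting the canonical unit vectors onto them in order, so identical
inputs give identical warps on any platform. Statistics that sum over
an eigenspace are invariant to this.

## Deflation

Deflation multiplies each specimen's warp-l component by
(E₁/Eₗ)ᵖ with p = 1/2 in 2D and p = 1 in 3D, centering on the sample
Procrustes mean (an override mean can be supplied for fixed-template
workflows). The uniform term and any residual outside the warp span —
the similarity directions, which carry only O(σ²) variance after
superposition — are dropped; `reinflate` therefore recovers exactly the
warp-span (nonaffine) part of the input, and the round trip is tested
to 1e−10. The exponent p is also exposed as a parameter: deflating an
isotropic sample with exponent p produces a distribution whose
log-variance/log-energy slope is −2p, which is how the simulators
generate integrated (p > default) and disintegrated (p = 0) synthetic
regimes for the recovery tests.

A note on spectra: the *deflated* isotropic sample has PCA eigenvalues
proportional to 1/E — that is the self-similar profile itself, not a
defect. "No meaningful components" means the score covariance matches
this null profile at every scale; the test asserts flatness of the
scores after standardizing by the null prefactors.

## Scaling regression and nugget

The scaling dimension is the unweighted OLS slope of log variance on
log energy, as the method's plots are drawn; no errors-in-variables
correction is applied. Warp subsets are always an explicit user
parameter (1-based in the CLI, matching the field's prose numbering);
warps with studentized residuals above 3 are flagged but never dropped
automatically — excluding a warp is a scientific judgment. Pooling of
warps that share an eigenvalue is available but off by default.

The nugget ν is an additive variance for scale-free digitizing noise,
fitted by minimizing the SSE of the OLS fit of log(variance − ν) on
log energy over ν ∈ [0, 0.999·min variance), via a 64-point grid scan
refined by bounded Brent search. The objective choice (log-scale SSE)
is the most direct reading of "the fit is optimized"; the original
source does not pin it down. A boundary solution is flagged. On the
synthetic families tested the objective is unimodal and the optimum
beats a 1024-point grid refinement.

Regime classification bootstraps specimens (default 1000 resamples,
seeded), refits the slope per resample, and takes the 95% percentile
interval: self-similar if it contains −1, integrated if entirely
below, disintegrated if entirely above; fewer than 10 specimens yields
"indeterminate". The resample count and level are declared choices —
the method itself prescribes no test.

The "partial warp 0" placement of the uniform term on the log-log plot
(abscissa displaced from warp 1 by log(var_uniform/var₁)/slope) is a
plotting heuristic with an admittedly indeterminate abscissa; the
function implements the worked rule verbatim and is labelled as such.

## Relative intrinsic warps

RIWs are computed as the ordinary PCA of the deflated coordinates; the
equivalence with the relative eigenanalysis of the nonaffine covariance
with respect to the bending-energy quadratic form is exercised as a
test oracle (generalized symmetric eigenproblem, agreement to 1e−8),
never used as the implementation. Reinflated loadings multiply each
warp component of a deflated loading by the inverse prefactor and
renormalize. All components above 1e−10 of the leading eigenvalue are
reported; no automatic retention rule is imposed. In 3D the deflated
coordinates of the cubic-kernel deflation are used directly for the
PCA; a squared-reference relative eigenanalysis is a conceivable
alternative formulation, but this package derives RIWs from the
deflated coordinates in both dimensions for one uniform code path.

The quadratic growth-gradient analysis orthonormalizes the quadratic
monomials of the mean (x², xy, y²; six terms in 3D) against {1, x, y[, z]}
per output axis (Gram–Schmidt in fixed order), projects specimen
deviations onto the resulting 6 (2D) or 18 (3D) orthonormal directions,
and takes PCA of the scores. The 3D version is a straightforward
extension beyond the worked 2D setting and should be treated as such.

## Simulators: what they emulate and what they do not

`isotropic_sample` is the offset isotropic Gaussian: independent
circular/spherical noise of standard deviation σ at every landmark, in
the units of the mean's coordinates. `self_similar_sample` is that
sample superimposed and deflated. Defaults used throughout the tests
are the study conditions of the claims being checked: σ = 0.15 of the
unit cell for the 5×5 grid at n = 1000, σ = 0.05 for the six-landmark
toy at n = 1000, and n = 500 in 3D. For the six-landmark toy only
variance *ratios* are asserted — the ratios, not the absolute levels,
are the scale-free content of the claims (larger square = ½ the smaller
before deflation, equal after; 75% trace after uniform removal).

Toy configurations: the quincunx (die five-spot; corners numbered
consecutively, center last); the 5×5 integer grid; the six-landmark
configuration reconstructed as a unit square (vertices 1–4, with 2–3 a
diagonal) plus the √2-scale square erected outward on that diagonal —
a layout whose identifying signature is its bending-eigenvalue ratio
1 : 1.07 : 2.15 (computed here as 1 : 1.0694 : 2.1451); and the
"giza" pair of 3D square pyramids of
identical shape at 4× scale, bases coplanar and concentric, apex height
half the base edge (the exact offsets are immaterial to the
amplitude-ratio properties, which depend only on the scale ratio). For
the 3D pair, the pre-deflation contrast follows the subset-Procrustes
convention: the *amplitude* (standard deviation) ratio is the scale
ratio 4, the variance ratio its square.

The parcellation generator perturbs the four corners of a square
template (variance base_sd², default 0.15²), then places each further
landmark at the location imputed by the thin-plate map of everything
placed so far plus circular noise whose variance shrinks by the factor
`decay` (default ½, tracking compartment area) per refinement level:
center, then the four edge midpoints, then the four quarter-cell
centers (13 landmarks in all). Its output is nearly self-similar by
construction (fitted slope ≈ −0.97 at n = 1000) and, unlike the
isotropic model, shows positive spatial autocorrelation of neighboring
displacements.

Sub-configuration variance uses a *fresh* full Procrustes fit of the
subset (re-center, re-scale, re-rotate) before removing its affine
subspace; only this convention exhibits the inverse-area law of the
isotropic model and its disappearance after deflation. Square
enumeration on integer lattices is exact integer arithmetic on the six
pairwise squared distances, so tilted ("knight's-move") squares are
found; a floating-point test would be fragile there.

None of the generators emulate directional or anisotropic landmark
noise, longitudinal (growth-trajectory) sampling, or measurement error
with spatial structure. Passing tests on them demonstrate the
machinery's internal consistency and the constructive properties of
the null — not that any particular real data set is self-similar.

## Problem sizes and determinism

All generators are seed-deterministic (NumPy `default_rng`). The test
suite and the acceptance script run the simulations at the sizes named
above; the acceptance script derives independent substreams from its
single `--seed` so that the two simulations it runs are uncorrelated.

## Known limitations

- The regression treats the estimated warp variances as error-free
  regressors and responses; no sampling-error weighting is applied.
- The nugget objective is only verified unimodal on the synthetic
  families tested.
- The 3D uniform term is removed but cannot be reported as a
  two-parameter decomposition the way the 2D term can.
- Real semilandmark data should be slid/flattened upstream; this
  package treats all supplied coordinates as fixed landmarks.
- The retention criterion for "interpretable" RIWs is left to the
  user; only a numerical rank cutoff is applied.
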