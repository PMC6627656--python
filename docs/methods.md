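# Methods

## Model

Unsharp masking forms `enhanced = original + α_usm · (original − smoothed)`.
Everything about the result is decided by the smoother.  `radusm` smooths
with reverse anisotropic diffusion: the minimizer of

    E(u) = ½ ‖u − I‖²  +  α ∫ Φ(‖∇u‖) dx dy,

whose gradient flow is `∂u/∂t = div(g(‖∇u‖) ∇u)` with the *increasing*
diffusivity `g(t) = t^β`.  Large gradients (edges, tube borders) get large
diffusivities and are flattened; small gradients (flat areas, the Gaussian
noise floor) get diffusivities near the floor `grad_eps^β` and pass through.
This is the mirror image of Perona–Malik diffusion, whose decreasing
diffusivity removes noise and keeps edges; both are provided so the contrast
between the two designs can be measured on the same inputs.

Assumptions worth stating explicitly:

- "Noise is preserved" is an amplitude-relative statement.  The diffusivity
  responds to gradient magnitude, so *any* high-gradient feature is smoothed,
  including impulse noise whose amplitude approaches edge contrast.  What
  holds, and what the tests measure, is the *ordering*: an isolated impulse
  has tiny support (it equilibrates with its four neighbours and stalls,
  retaining ≈1/5 of its amplitude regardless of how strong the coupling
  gets), while a step edge's across-boundary contrast shrinks like
  `1/(1 + 2α·h)` and keeps shrinking as `α` or the contrast `h` grows.  At
  the default `α = 0.02` and 12-bit contrasts this puts edge attenuation
  (~25×) far above impulse attenuation (~6×), with Gaussian smoothing showing
  the reverse ordering (~6× vs ~30×).
- The data term `½‖u − I‖²` anchors the solution to the input; the solve is a
  single implicit step of regularized diffusion, not a march to steady state.

## Discretization

The Euler–Lagrange equation is solved by lagged diffusivity: with the
coefficients frozen at the iterate `uᵐ` (iterate 0 = the input), each outer
iteration solves the linear system

    [D + α L(uᵐ)] uᵐ⁺¹ = I,

`D` the identity.  `L` is a five-point operator built from half-pixel
diffusivities: the diffusivity on the edge to the k-th neighbour is

    c_k = ( √G_k + grad_eps )^β,

where `G_k` is the squared gradient at the edge midpoint — the squared
difference along the edge plus a quarter of the squared central difference
across it, evaluated at the outer endpoint.  The row for pixel `(x, y)`
(x = column, y = row, origin top-left) reads

    u + α·( s·u − c1·u_west − c2·u_east − c3·u_south − c4·u_north ),
    s = c1 + c2 + c3 + c4.

Out-of-bounds neighbours are reflected (homogeneous Neumann), the standard
choice for diffusion filtering.  Three structural facts follow and are
enforced by tests:

- **Symmetry.** `c2` at `(x−1, y)` equals `c1` at `(x, y)` (and likewise
  north/south), so the assembled matrix is symmetric.
- **Unit row sums / mean conservation.** Reflection folds boundary
  coefficients into the diagonal, rows sum to 1, and the solve conserves the
  image mean to solver precision.
- **M-matrix / maximum principle.** The diagonal `1 + α·s` strictly dominates
  the off-diagonal mass, so the inverse is nonnegative and the output stays
  inside the input's intensity range.

The additive `grad_eps` (default 0.001) keeps every coefficient strictly
positive in flat regions; it simultaneously plays the role of the small
regularizer that makes the energy differentiable at zero gradient, so no
second constant is carried.

With the coefficient field frozen to a constant `c`, one implicit step is a
discrete resolvent of the heat equation and agrees with Gaussian convolution
of scale `σ = √(2αc)` to first order in the time step; the acceptance suite
checks 2% agreement on a smooth image.  This is the sense in which the
Gaussian-USM baseline is the linear limit of the method.

## Solver

Each outer iteration's system is solved matrix-free — the operator is a
handful of shifted-array operations — with the preconditioned bi-conjugate
gradient method and a Jacobi (diagonal) preconditioner `1 + α·s`.  Dense or
factorizing solvers are out of the question at radiograph sizes (5×10⁶
unknowns), and for `A = I + αL` with modest `α` the diagonal carries most of
the operator, so dividing it out clusters the spectrum near 1 (measured on
the 64×64 phantom at α = 0.2: 135 iterations with the preconditioner vs 212
without, identical fixed point).

Numerical choices:

- **Stopping rule.** Relative residual `‖b − Ax‖/‖b‖ ≤ solver_tol`
  (default 1e-8) with an absolute floor of 1e-30 on `‖b‖` so a zero
  right-hand side is handled.  The reported final residual is recomputed from
  scratch after the iteration, never trusted from the recurrence.
- **Initial guess** `x0 = b`: for `A ≈ I` this starts near the solution;
  overridable.
- **Breakdown.** A vanishing `r̄·z` or `p̄·Ap` raises a dedicated error
  carrying the iteration index; non-convergence within the budget returns
  diagnostics and lets the caller decide (the diffusion layer converts it to
  an error carrying the residual history).
- The implementation accepts a distinct transpose operator, although the
  diffusion operator is symmetric — in which case PBCG coincides with
  preconditioned CG iterate-for-iterate, a property the tests use as a strong
  internal consistency check.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `alpha_diff` | 0.02 | diffusion weight α; edge flattening strength.  Sweeping 0.001 / 0.02 / 0.2 trades noise pickup against contour thickness; 0.02 is the balanced setting for 12-bit radiographs |
| `beta` | 1 | diffusivity exponent; higher values make smoothing even more edge-selective |
| `grad_eps` | 0.001 | gradient floor (intensity units); far below the noise floor of 12-bit data, so it only matters in exactly-flat regions |
| `outer_iters` | 1 | lagged-diffusivity iterations; one already yields the edge-smoothed/noise-kept behaviour, more sharpen the nonlinear fixed point |
| `solver_tol` | 1e-8 | inner PBCG relative residual |
| `alpha_usm` | 1.0 | mask weight (the full mask is added back) |
| `range_policy` | clip | USM can leave the nominal range (dark halos); clipping is the minimal fix, `rescale`/`none` are available |
| EMEE `block_h×block_w`, `c` | 40×40, 30 | blockwise contrast protocol; `c` guards against the zero-intensity pixels common in radiographs |
| Gaussian `sigma` | `kernel_size/6` | so the conventional kernel sizes 15/19/23 alone fix the blur scale (±3σ support) |
| Perona–Malik `kappa, step, n_steps` | 40, 0.2, 20 | baseline only: κ sits above the σ=20 noise floor and far below 600-level edge contrast, so noise is flattened and edges kept; step ≤ 0.25 for explicit stability |

Note the two distinct α's: `alpha_usm` (mask weight) and `alpha_diff`
(diffusion weight).  They are deliberately separate parameters.

## EMEE and SNR

EMEE tiles the image into blocks, computes `r = I_max/(I_min + c)` per block
and averages `r·ln(r)`.  The log is natural; base changes only a global
scale, but absolute values depend on it, so cross-implementation comparisons
must fix the base.  Partial blocks at the right/bottom edges are included
as-is (image sides are rarely block multiples; this uses every pixel), and
`0·ln 0 := 0` by continuity for all-zero blocks.

SNR is mean intensity over a signal rectangle divided by the sample standard
deviation (n−1) over a noise rectangle.  It is one explicit protocol among
many, comparable only across identical region choices; note that because the
numerator is a *mean* rather than a contrast, enhancement that amplifies
retained noise can lower this SNR even while contrast improves.

## Synthetic phantoms

The generator emulates the features of portable chest radiographs that the
pipeline interacts with: a smooth intensity ramp (mediastinum-scale
background), raised-cosine horizontal bands (ribs), thin bright spline-shaped
tubes of known width and contrast, Gaussian read-out noise, and sparse
impulse pixels.  The standard preset is frozen (256×256, base 1500, ramp 400,
5 rib bands of amplitude 200, two curved width-3 tubes at +600, noise σ 20,
0.5% impulses at +400, seed 20190424) so every documented number is
reproducible.  Two constructions are deliberately exact so tests can assert
equalities: the impulse count is `round(density·N)` positions drawn without
replacement (not Bernoulli), and an impulse pixel *replaces* its noisy value
with (clean value + amplitude), so each differs from the noise-free render by
exactly the impulse amplitude.

What the phantom does **not** emulate: anatomy (lungs, clavicles, devices
other than tubes), X-ray physics (scatter, beam hardening, detector blur),
spatially varying noise, and realistic tube-to-background contrast
statistics.  In particular the preset's tubes are high-contrast relative to
its noise (600 vs σ = 20), which makes *any* USM mask — Gaussian included —
tube-dominated in energy: on this phantom the Gaussian mask concentrates
~73% of its energy near the tubes and the RAD mask ~76% (both computed by
`scripts/acceptance.py`).  The discriminating measurements are therefore the
attenuation-factor *orderings* and the EMEE trend, not the concentration gap;
on clinical images, where line-structure contrast sits much closer to the
noise floor, the noise content of a Gaussian mask matters far more than it
does here.  Passing tests on the phantom demonstrate the mechanism
(edge-selective masking), not clinical image quality.

## Known limitations

- Impulse noise with amplitude comparable to edge contrast is partially
  smoothed (see the amplitude-relative caveat above); the method's "noise
  preservation" is strictly a statement about low-gradient content.
- A single global `alpha_diff` cannot be optimal across exposure settings;
  adaptive, per-image selection is out of scope.
- `outer_iters > 1` changes the result only mildly at default settings but
  costs a full solve per iteration.
- No DICOM input; 16-bit PNG/TIFF and JSRT raw only.
- The CLI `phantom` command places the preset tubes only at the 256×256
  geometry (control points are absolute coordinates); other sizes render
  background, ribs and noise without tubes.
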