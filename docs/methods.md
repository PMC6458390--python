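# Methods

## The growth model

Early secondary-xylem development in the Arabidopsis root is treated as
the growth of an inverted cone: base area *a(t)* — the secondary-xylem
cross-section area at the root base — and height *h(t)* — the
longitudinal extension of secondary growth along the root, read off
serial sections as the last section (going from base to tip) in which
secondary vascular cells appear. Three modelling ingredients:

1. **Exponential kinetics.** Every measured quantity X ∈ {area, cell
   number, extension, cone volume} follows X(t) = X₀·e^(kt), the
   solution of dX/dt = kX — the linear, turgor-saturated special case of
   the Lockhart cell-expansion law. `forward_exponential` and the
   fitting routines use this single canonical form; each quantity
   carries its own rate constant (the package never hard-wires a factor
   of 2 between, say, a radius-based and an area-based rate — an area
   log-slope is exactly twice the corresponding radius log-slope, and
   which convention a reported constant uses must be decided by the
   analyst).
2. **Cone geometry.** V = a·h/3 (identically (1/3)πr²h with a = πr²).
   The radius is always derived, r = √(a/π), so the a = πr² constraint
   cannot be violated. Inverting the cone with a fitted volume
   trajectory gives the derived height law h = 3V₀e^(kt)/a.
3. **Allometry.** If a and h are both exactly exponential, then
   h = c·a^p with p = k_h/k_A: the allometric exponent is the ratio of
   log-slopes. The package fits p freely (LM in linear space), holds it
   at the 2/5 signature for comparison, and cross-checks with the
   log–log OLS slope.

Canonical internal units are mm, mm², mm³ and days; boundary IO converts
from the field-customary µm² (areas) and cm (extensions).

## Estimation

* `ols_log`: closed-form OLS of ln X on t. Deterministic, exact on
  noiseless data; standard errors by the delta method for X₀. Used to
  initialise the iterative routes.
* `lm`: Levenberg–Marquardt vertical least squares on the untransformed
  response (scipy `curve_fit`), optionally weighted by per-point value
  errors; parameter covariance scaled by residual variance.
* `odr`: orthogonal distance regression (ODRPACK via `scipy.odr`),
  per-axis scaling by the supplied time and value errors, unit weights
  when absent. When time errors are supplied as exactly zero the
  orthogonal objective degenerates to weighted vertical least squares,
  and the implementation switches ODRPACK to that mode (`fit_type=2`);
  this makes the ODR→LM zero-abscissa-error limit hold by construction
  rather than by a numerically delicate 1/σ²→∞ weight.

Numerical choices: LM starts from the `ols_log` (or log–log) closed
form, max 2000 function evaluations; ODR max 200 iterations, honest
`converged` flag from the solver's stop reason. R² for the nonlinear
routes is computed on the untransformed response (matching how the fits
are plotted); the closed-form log regressions report R² on their own
(log) axes. A constant series is a legal input: `ols_log` returns k = 0
exactly, and a perfect fit to zero-variance data reports R² = 1. Error
propagation is first-order quadrature on relative errors for products
and quotients; exact constants rescale the absolute error only. The
cone-volume series is derived per day from the area and extension means,
so its error is the quadrature sum of their relative SEMs.

## The synthetic study

`GenerativeParams` defaults define the emulated study: 4 sampling days
(7, 11, 15, 21 DAG), 10 replicate roots per day (the replicate-level
table of the original study is not machine-readable, so a typical
anatomical sample size was fixed once), and forward trajectories that
pass through the reported group means — initial values and log-slopes
obtained by closed-form log-OLS through those means (k_A = 0.3952 d⁻¹,
k_N = 0.3221 d⁻¹, k_h = 0.2276 d⁻¹, anchored at a(7 DAG) = 1519.56 µm²,
N(7 DAG) ≈ 3 cells, h(7 DAG) = 2.805 mm).

Noise: area and extension get multiplicative lognormal noise with unit
mean and a 10% coefficient of variation by default — measurements are
strictly positive and span four orders of magnitude, so additive
Gaussian noise would be unphysical — and cell counts are Poisson about
the forward value (switchable to a rounded lognormal). Setting all noise
parameters to zero reproduces the forward model bit-exactly, which the
round-trip tests rely on.

Section profiles tile successive 0.5 cm blocks with 5 µm sections from
the root base; a section is "present" when its midpoint lies within the
true extension, so profile round trips recover the extension to within
one section (±5 µm), the sectioning resolution of the emulated protocol.

Synthetic micrographs place cells as randomly perturbed ellipses
(radii 6–12 px, up to 25% eccentricity) with dark walls (intensity 50)
around light lumens (240) on a light background (200), plus σ = 5
Gaussian sensor noise — the Toluidine-Blue contrast polarity. A
configurable fraction of cells (10% by default) is placed as fused
pairs: both members near-circular, centres at 95% of the radius sum, so
their lumens merge into a dumbbell with a thin neck. The fusion depth
matters: much deeper fusion leaves the smaller lobe with almost no
distance-transform prominence once thresholding has widened the neck,
making the pair geometrically unsplittable, while shallower placement
would not merge the lumens at all. Non-fused cells keep two wall
thicknesses of lumen-to-lumen clearance so distinct cells never share a
bright region. Placement is rejection sampling; if a crowded canvas
cannot hold the requested count, the shortfall is warned about and the
ground truth reports the cells actually drawn.

What the images do **not** emulate: the ring-sector anatomy of real
sections (vessels vs fibres vs parenchyma, the primary-xylem core),
staining gradients, section folds and debris. Counter accuracy measured
here therefore shows that the algorithm resolves the generic
segmentation problem (contrast, touching objects, sensor noise, 3–250
objects per frame) at the reported accuracy level, not that it would
reach the same number on any particular real slide.

## The counter

`count_cells` follows the classic particle-counting recipe: Gaussian
smoothing (σ = 1 px) → Otsu threshold keeping the bright phase → area
window [25, 20000] px² and circularity ≥ 0.15 (this removes the
background, which is bright but far larger than any lumen, without
needing a border heuristic — border-touching cells are kept) → hole
filling → optional watershed split of fused lumens. Watershed markers
are the h-maxima of the distance transform with h = 1 px: a single
convex lumen contributes one marker, a dumbbell one per lobe whose core
stands at least 1 px above the connecting neck. Marker height is the
oversplit/undersplit trade-off: raising it misses fused pairs of
unequal size (the smaller lobe's prominence shrinks with the radius
ratio), lowering it below the boundary-raggedness scale would shatter
single cells. Accuracy is scored as relative count error,
1 − |N̂ − N|/N, because the original accuracy claim is a single scalar
against manual counts; `per_cell_matching` (greedy IoU ≥ 0.5) is the
stricter per-object diagnostic for users who need to rule out
compensating split/merge errors.

## Design notes and limitations

* Replicates are treated as exchangeable; experiment-level blocking
  (repetitions of the whole study) is not modelled.
* Fits operate on per-day means with SEM weights, not on replicate-level
  records; hierarchical/mixed-effects modelling is out of scope, as are
  bootstrap intervals.
* The default pipeline method is ODR for the exponential fits and LM for
  the power law, with `ols_log` always reported alongside as a
  transparent cross-check.
* Problem sizes in the test and acceptance runs — 100 images for the
  counting-accuracy suite, 200 trajectories for the noise-recovery
  check, 500+ replicates for Monte-Carlo convergence — were chosen as
  the smallest sets whose Monte-Carlo error is clearly below the margins
  being tested.
* `scipy.odr` is slated for removal from SciPy (≥1.19); the `odr`
  method will need repointing at the standalone `odrpack` distribution
  when that happens. The LM and closed-form routes are unaffected.
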