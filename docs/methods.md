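# Methods

## The physical picture

A single adherent cell, imaged top-down at high speed, is loaded by a
pressure ramp that rises from ambient `p0` to a peak `p_max` in under
0.1 ms. On that timescale biological remodelling is frozen, so the
cell's projected area `A` responds like a material property. Treating
the ramp as a sequence of equilibrium states, the relation `A(p)` is an
(incomplete) equation of state for the cell, and the headline
observable per experiment is the final-to-initial area ratio
`ζ = A_final / A_initial`.

The coupled compression–shear loading is decoupled kinematically: shear
produces local, area-preserving shape distortion, and compression alone
changes the projected area. The deformation gradient is split as
`F = s·I × S` with `S = [[1, γx], [γy, 1]] / sqrt(1 − γx·γy)`, which
has unit determinant by construction, so `area ratio = s²` exactly and
`s = sqrt(ζ)`. The shear magnitudes are deliberately not estimated
from images: local shape statistics (circularity, convexity,
compactness, solidity) are too irregular to support a quantitative
shear analysis, and the package only reports them descriptively.

## State-equation families

All pressures in kPa, areas in µm². The nondimensional overpressure is
`p̂ = (p − p0)/p_ref` with `p_ref = p0` by default (some pressure scale
is required for dimensional consistency of the exponent; the ambient
pressure is the only scale the problem supplies, and it makes the
initial-condition normalisation `B0 = 1` exact).

1. **Exponential family.** Define the area modulus
   `B(p̂) = (1/A)·dA/dp̂` and treat its pressure gradient as constant:
   `B = B0 + B′·p̂`. Integration gives
   `A = A0 · exp(B0·p̂ + ½·B′·p̂²)`, valid while `B ≥ 0`. Direct
   differentiation gives
   `d²A/dp̂² = A0·e^g·(B′ + (B0 + B′p̂)²)`: for `B′ < 0` the curvature
   changes sign exactly once, at `(B0 + B′p̂_k)² = −B′` — the point of
   maximum area-growth rate. (Note the additive `B′` term: a printed
   form of this second derivative that omits it is not consistent with
   the calculus; the implementation keeps the full expression and the
   tests verify it against central differences.) For `B′ ≥ 0` the
   curvature is strictly positive and no inflection exists.

2. **Tait-like family.** Assuming uniform area properties with one
   correction produces a power law, `p = α₃·p0·(A/A0)^κ + p0`, the 2D
   analogue of the Tait liquid equation of state. The exponent enters
   only as the composite `κ = α₂(1+γ)`; the two underlying factors are
   not separately identifiable and are never reported individually.
   The forward/inverse pair is algebraic and exact. A fixed-exponent
   power law has curvature of one sign, so this family has no interior
   inflection; note also its anchoring quirk, `p(A0) = p0(1 + α₃)`
   rather than `p0` (kept as derived — equivalently, the model predicts
   ζ < 1 below that pressure, consistent with the observation that some
   cells shrink).

3. **Logarithmic-integral family.** Letting the area properties vary
   continuously leads to `(p − p0)/p0 = exp(α₁·li(A/A0))` where
   `li(x) = ∫ du/ln u` diverges at `x = 1` and is regularised by a fixed
   offset ε (default 1e-6, always reported). `li` is evaluated as
   `Ei(ln x) − Ei(ln(1+ε))` via `scipy.special.expi`; an independent
   adaptive-quadrature route is kept for cross-checking. The inverse
   `A(p)` uses bracketed Brent root finding. Two structural
   consequences worth knowing: the model anchors at `p → 2·p0` as
   `A → A0⁺`, and because the regularised `li` grows like
   `ln((x−1)/ε)` near 1, the area barely moves until very large
   nondimensional pressures when ε is small — the inflection of this
   family sits at practical pressures only for loose ε (~1e-2).

### Inflection search

`find_inflection` uses the analytic curvature where available
(exponential family) and otherwise a central-difference second
derivative (relative step 1e-4) scanned on a 400-point grid, with the
sign change bracketed by Brent's method; ties are broken by the
smallest pressure. Reporting "no inflection" is a valid outcome
(Tait family, exponential with `B′ ≥ 0`).

### Discrete loading paths

With a constant loading rate, equal time steps are equal pressure
increments; `isobaric_trajectory` evaluates the family on that grid and
records step ratios `ζ_i = A_{i+1}/A_i` (which telescope to
`A_n/A_0`). `loading_rate_continuation` holds the end state fixed and
varies the step count: the step with the largest area increment
`ΔA_i` — the discrete `dA/dp`, whose maximum is the
maximum-deformation-rate point — converges to the analytic inflection
as steps refine, and migrates toward larger areas as steps coarsen
(faster loading). The step *ratio* `ζ_i` is not used to locate the
maximum: for a softening modulus the relative growth rate `B(p̂)`
decreases monotonically, so the max-ratio step is always the first one
and carries no inflection information. The coarse→larger-area ordering
holds for `n ≥ 4` steps; at `n = 1–2` the grid is too coarse for the
argmax to be meaningful.

### Two-compartment model

The cell area is split into a fluid-like cytoplasm (constant slope
`dA_cyto/dp`) and a stiffer porous core whose response must be concave
(`d²A_core/dp² < 0`, pore collapse): by default a concave quadratic
`A_core(p) = A_core0 + b·(p−p0) − c·(p−p0)²`, `c > 0`. The balance

    dA_cell/dp = ((A_cell − A_core)/A_cell)·dA_cyto/dp
               + C·(A_core/A_cell)·(dA_core/dp + p·d²A_core/dp²)

is integrated with fixed-step RK4. The two right-hand terms are
accumulated as separate states in the same integration, so the
conservation identity `ΔA_cell = ΔA_cyto + ΔA_core` holds to roundoff
by construction and is asserted on return; accuracy is checked against
a step-halving Richardson oracle in the tests.

## The synthetic study

The generator emulates the statistical structure of a 198-experiment
impact study. Defaults (one value per line, chosen once):

- **Population** (`PopulationSpec`): n = 198 cells; initial area
  Gaussian 450 ± 120 µm², perimeter Gaussian 90 ± 18 µm (both truncated
  at zero by resampling — areas must be positive), inclination angle
  uniform on [0°, 180°). The area/perimeter scales are typical of
  well-spread adherent macrophages on the 120 × 36 µm field of view;
  the dispersions are wide enough that Shapiro–Wilk tests have
  realistic power without the truncation biting.
- **Loading** (`generate_waveform`): constant-rate ramp, 0.1 ms at
  2×10⁵ fps (20 ramp intervals), after a 5-frame baseline; baseline
  pressure `p0 = 101.325` kPa (ambient).
- **Peak pressures**: fifteen levels at centres 478 … 3178 kPa with the
  study's printed dispersions, group sizes (14×7, 13×6, 13, 9) summing
  to 198 with the two highest levels at 13 and 9; sensor span
  156.48–3603.85 kPa enforced on the centres. By default the level
  dispersions are capped at 0.75% of the centre (`cv_compliant=True`)
  so the generated study satisfies the 5% within-group-variation rule
  it is meant to exhibit; the verbatim dispersions (the top level's is
  6.1% of its centre) are available with `cv_compliant=False`.
  Draws are truncated at ±3 sd and clipped to the span.
- **Response model**: Tait family, κ = 1.5, α₃ = 0.8.
- **Size coupling** (`SizeCouplingSpec`): the observed surface has
  `∂ζ/∂A_initial < 0` with `∂²ζ/∂A_initial² > 0`, but nothing ties the
  model parameters to `A_initial` quantitatively. The generator uses a
  one-parameter power law `θ(A0) = θ_ref·(A_ref/A0)^η`, `A_ref = 450`
  µm², η = 0.5, applied to each family's gain parameter with the sign
  that makes larger cells effectively stiffer (exponential: `B0` scaled
  by the factor; Tait: `α₃` by its reciprocal; li: `α₁` by its
  reciprocal). With the Tait defaults this makes all four sign
  constraints (`∂ζ/∂A < 0`, `∂²ζ/∂A² > 0`, `∂ζ/∂p > 0`, product < 0)
  hold analytically, and the surface audit confirms 100% of interior
  grid cells.
- **Noise** (`NoiseSpec`): multiplicative fluctuation of the final
  area from transmembrane water exchange — uniform on ±a under
  stationary fluid, Normal(0, a) under directed flow (the study's
  geometry has directed flow, so that is the default); amplitude
  a = 0.05. Only the distribution shapes are given by the theory; the
  scale is a free parameter.
- **Detachment**: Bernoulli with probability
  `detach_prob · logistic((p_max − 1500)/500)` (default base 0.05) —
  detachment is an observation rule, not a calibrated model; the
  pressure dependence simply makes harder impacts likelier to strip the
  cell. A detached record re-reads its peak pressure at the
  pre-detachment frame, which censors it between levels; detached
  records are therefore excluded from pressure grouping and (by
  default) from fits.

### Rendering

Frames are 160 × 48 px, 0.75 µm/px, 12-bit values in 16-bit containers
(no 12-bit file dialect exists). The cell is a star-convex polygon with
random radial harmonics (modes 2–6) that break the perimeter–area link
of a circle, rescaled to the exact target area, rotated to the cell's
angle and placed at the canvas centre with a subpixel jitter (a real
cell never sits exactly on the pixel grid, and exact alignment is a
degenerate rasterisation case). Pixel values are **fractional
coverage** (4× supersampled rasterisation): a physical pixel integrates
light over its aperture, so edge pixels carry intermediate
intensities. A small Gaussian PSF (σ = 0.3 px) and additive sensor
noise (σ = 40 counts on a 600/2800 background/foreground) follow.
Ground-truth masks are `coverage ≥ ½`; ground-truth polygons are also
returned so tests can bypass rasterisation entirely.

Frame areas between the anchored initial and final states interpolate
linearly in pressure; the analysis only ever uses the two anchored
states, so the intermediate shape path is cosmetic.

### What the generator does *not* emulate

Real bright-field texture (internal organelle contrast, halos,
illumination gradients), segmentation-confusing debris or neighbouring
cells, focus drift, motion blur within a frame, shear-induced local
distortion of the outline during loading, and any mechanistic link
between noise amplitude and pressure. Passing tests therefore show the
*pipeline* is correct and well-calibrated under the assumed data model,
not that the segmentation would meet the same tolerances on real
microscopy.

## Imaging measurements

Segmentation: Otsu threshold → morphological open/close (disk radius
1) → largest connected component (with a 20 px² floor) → marching
squares. A degenerate-scene guard rejects frames where the two Otsu
classes are separated by less than 4× their spread (on a blank noisy
frame Otsu happily splits the noise in half). The final contour is
traced on the intensity image at the midpoint of the interior and
background levels, clamped to the component's neighbourhood: because
edge pixels carry fractional coverage, interpolating through them
recovers the boundary to well below a pixel (observed area errors
~0.2–0.8% versus ~2–3% for contours of the binarised mask, which are
quantisation-limited). If the refinement finds no closed contour the
0.5-level mask contour is the fallback.

Shape descriptors from the polygon contour: area by the shoelace
formula; perimeter by edge-length sum; orientation and
elongation (= 1 − λmin/λmax) from the exact polygon second moments;
circularity `4πA/P²`; compactness defined here as its inverse `P²/4πA`
(the descriptor is named in the field without a canonical formula;
this choice is documented and tested for self-consistency);
convexity `P_hull/P`; solidity `A/A_hull`. Contours are validated as
simple polygons (shapely); self-intersection is an error.

Frame selection mirrors the experimental rule: the initial state is the
last frame before the detected wave arrival (first frame above
baseline + 3·baseline-noise-sd), the final state is the frame at the
pressure peak — unless segmentation detects detachment first (mask IoU
with the previous frame below 0.3, or no cell), in which case the last
adhered frame is used and its pressure is read off the waveform.

## Statistical analysis

**Distribution checks.** Shapiro–Wilk on area and perimeter (and
elongation when present), Kolmogorov–Smirnov against the uniform law on
the angle, all at α = 0.01. The three tests are descriptive
validation, run without multiple-testing correction (deliberately —
they gate nothing downstream). Constant-valued features yield a
degenerate-input entry rather than a bogus p-value.

**Pressure grouping.** Records are sorted by `p_max` and accreted
greedily: a candidate joins the open group while (i) the group's
coefficient of variation including the candidate stays ≤ 0.05 — the
"variation below 5%" rule read as a CV, since the per-level ± entries
are dispersion-like — and (ii) the candidate lies within 0.8·cv_max of
the previous sorted member. Condition (ii) applies the within-group
rule to the newcomer: consecutive pressures inside a tight level are
far closer than the ~10–22% spacing between levels, whereas one stray
point from the next level barely moves the CV of a 13-point group, so
a pure CV rule would chain-merge the levels. Groups need more than
three members (`min_size = 4`, the strict reading of the rule); smaller
clusters go to an ungrouped residue. The procedure is deterministic
and permutation-invariant.

**Per-group lines.** Ordinary least squares of ζ on `A_initial` within
each group; degenerate spreads produce per-group error entries.

**State-equation fits.** Nonlinear least squares
(`scipy.optimize.least_squares`, Levenberg–Marquardt) of observed ζ
against the family prediction with the size coupling applied per cell.
Residuals are *relative*, `(ζ_obs − ζ_pred)/ζ_pred`: the water-exchange
noise is multiplicative, so this is the correctly-specified error
model — it keeps the variance constant across the 30-fold ζ range and
makes the Gauss–Newton Wald intervals calibrated (observed 95%
coverage ≈ 0.95; absolute residuals under-cover at ≈ 0.87). Multi-start
initialisation (default 16 seeded starts, lowest residual sum wins);
standard errors from the Gauss–Newton covariance; non-convergence is
reported, never raised. Inside the fit loop the exponential prediction
evaluates its quadratic exponent everywhere rather than erroring at the
`B ≤ 0` boundary — outside the physical domain the model predicts
shrinkage the data contradict, which gives the optimiser a smooth
restoring gradient instead of a cliff.

**Recovery harness.** Replicated generate→(optionally image)→fit with
per-replicate seeds; reports bias, RMSE, median relative error and
coverage of nominal 95% intervals per parameter.

## Problem sizes

The shipped analyses use the study size everywhere it matters:
n = 198 records, 15 pressure levels, 200 recovery replicates, 100-seed
distribution studies, 1000-draw identity checks. The imaging round
trip uses 42 small cells (140 ± 12 µm²) at the three lowest pressure
levels with the coupling disabled: with the default Tait parameters a
mean-sized cell's final area at high pressure simply does not fit the
48-row canvas, so the imaged sub-study is scoped to geometries the
printed sensor format can hold.

## Known limitations

- The Tait and li families' anchoring quirks (`p(A0) = p0(1+α₃)`,
  `p → 2p0`) are kept as derived; no offset re-anchoring is attempted.
- `α₂` and `γ` are reported only as the composite κ.
- Shear is never quantified; only the isotropic compression factor is.
- The li family's practical behaviour depends strongly on the
  regularisation ε; results always carry the ε used.
- Wald intervals rely on the Gauss–Newton approximation; no bootstrap.
- The detachment model is an observation rule with an ad-hoc logistic
  pressure dependence, not a physical adhesion model.
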