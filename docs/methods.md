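# Methods

## The model

`rosphere` quantifies whether individual marine plankton cells can alter each
other's hydrogen-peroxide microenvironments by diffusion alone. Each cell is a
static sphere of radius *R* (µm) maintaining a homeostatic intracellular
concentration C_cell (mol L⁻¹) against a seawater background C_sea. No
advection, boundary-layer refreshment, motility, or spatially resolved
reaction–diffusion PDE is attempted: the model is a deliberately simple
volumetric-dilution heuristic whose virtue is that every quantity has a closed
form.

### Source cells (phytoplankton)

Over a time grid starting at exactly 0 µs, the diffusion front sits at

    r(t) = R + √(D·t)

with D the H₂O₂ diffusion coefficient (default 1500 µm² µs⁻¹). The
concentration carried at the front follows volumetric dilution of the
intracellular sphere plus optional pseudo-first-order decay:

    C(t) = C_cell · (R / r(t))³ · e^(−µ·t)

floored at C_sea — beyond the threshold the cell has no local influence and is
just one input into the bulk seawater pool. The decay constant is the
e-folding convention µ = 1/lifetime; at seawater H₂O₂ lifetimes (hours–days)
and simulated times ≤ 100 µs, µ·t ≤ 3×10⁻⁸, so decay changes concentrations
by < 10⁻⁶ relative. The term is retained because the same machinery applies to
shorter-lived reactive oxygen species, where decay matters. Note the half-life
convention µ = ln2/lifetime would be equally defensible; at these timescales
the two differ by < 10⁻⁷ relative, and the constant is user-settable.

### Sink cells (heterotrophic bacterioplankton)

A sink cell maintains C_cell < C_sea (literature estimate: one tenth of the
external concentration). Its local concentration rises from the surface as

    C(r) = C_cell · (r / R)³,   capped at C_sea

with no decay term — the cell acts on top of any bulk decay to deepen the
local depression. This is a mirrored dilution heuristic, not a steady-state
diffusion solution; it is implemented as such deliberately, to stay within
the model the closed forms derive from.

### Threshold radii

Setting C(t) = C_sea defines the cell-specific sphere of influence. Without
decay the source threshold is radius-only,

    r* = R · (C_cell / C_sea)^(1/3),

independent of D (D only sets the arrival time t* = (r*−R)²/D). With decay,
substituting Y = 2µt/3 gives a Lambert-W closed form on the principal branch:

    t* ≈ W₀( (k^(−1/3) − R)² · (2µ/3) / D ) / (2µ/3),  k = C_sea/(C_cell·R³)

The substitution treats the R offset as decay-free, so this expression is
exact only in the small-decay limit. We therefore use it as the seed for a
Newton iteration on ln C(t) − ln C_sea, which converges in a couple of steps
and guarantees that the profile evaluated at (t*, r*) recovers C_sea to
machine precision; for any H₂O₂-like lifetime the refinement moves the answer
by less than one part in 10⁶. When µ·t* < 10⁻¹² the solver branches to the
zero-decay closed form outright, avoiding the W₀(x)/x cancellation as x → 0.
The W₀ argument is provably ≥ 0 for valid inputs, so the non-principal branch
never arises. An independent bracketed-bisection oracle on the raw profile
function (no algebraic shortcuts, 10⁻¹³ relative in t) cross-checks all closed
forms in the test suite.

The sink threshold is algebraic: r* = R·(C_sea/C_cell)^(1/3). Sink results
report the front arrival time (r*−R)²/D for symmetry, though the radius itself
is time-independent.

Two radius conventions circulate for these spheres — distance from the cell
centre and distance from the surface — and published figures mix them.
`ThresholdResult` reports both; classification functions take a
`convention` flag (default `centre`).

### Grid-scan thresholds

`source_threshold_grid` reports the first time-grid point at which the decayed
concentration is at or below background. It deliberately overshoots the
continuous solution (converging from above as the grid refines) and exists
because the commonly quoted ~3.1 µm radius for a 0.3 µm cell is a log-grid
crossing: the continuous solution is 3.0 µm from centre, while the default
grid (below) lands at 3.04 µm, inside the [3.0, 3.2] bracket.

The default time grid is t = 0 followed by a log₁₀-spaced series from 10⁻³ µs
to 100 µs at 20 points per decade (102 points). Only the endpoints are
constrained by the model; the resolution is a package choice, exposed in
`TimeGrid.log10`.

## Cell spacing

For a homogeneous suspension at number density ρ, treating cell positions as
a spatial Poisson process gives the mean nearest-neighbour distance

    ⟨d⟩ = c · ρ^(−1/3),  c = Γ(4/3)·(4π/3)^(−1/3) = 0.553960…

The two-digit rounding 0.55 is commonly quoted; the package defaults to the
exact constant because the inverse problem — the critical density at which a
400 µm sphere of influence spans the mean spacing — reproduces the reference
2.7×10⁹ cells m⁻³ (as 2.656×10⁹) under the exact constant but not under 0.55
(2.60×10⁹). The rounded value is available as `ROUNDED_NN_CONSTANT`.
Densities are carried in cells m⁻³ everywhere (the unit of the shipped
reference table); conversion to cells mm⁻³ happens only inside the spacing
formulas.

## Interaction classification

A taxon's cells are classified as directly interacting when the sphere of
influence reaches at least the mean centre-to-centre spacing at the taxon's
density (`full_spacing` criterion, default). The alternative `half_spacing`
criterion — two neighbouring spheres meeting midway — is configurable; the
full-spacing centre-convention default is the combination that reproduces the
most precisely quoted reference number (2.7×10⁹ cells m⁻³ for 40 µm cells).
The small-cell end of the threshold lines is convention-sensitive: at 0.5 µm
and ratio 1000 the centre convention gives 1.36×10¹⁵ cells m⁻³ and the surface
convention 1.9×10¹⁵; both are computed, neither is privileged beyond the
default flag. Inverting the spacing law per cell radius and concentration
ratio yields the threshold lines of the density × radius plane; the default
ratio sets are {10, 100, 1000, 10000} for sources and {0.1, 0.05, 0.01, 0.001}
for sinks, bracketing the physiologically discussed range.

## Synthetic layouts

The synthetic-data generator emulates randomized 3-D cell positions at the
reference suspension densities, in two modes:

* `uniform_random` — complete spatial randomness: a Poisson-distributed count
  with mean ρ·V and i.i.d. uniform coordinates. This is the model under which
  the constant c is exact, and Monte-Carlo nearest-neighbour statistics on
  such layouts (periodic minimum-image boundaries) recover c ≈ 0.554 —
  the package's own validation of the spacing formula.
* `jittered_lattice` — the visualization convention: a cubic lattice at pitch
  equal to the mean spacing, each coordinate perturbed by uniform noise of
  half-width `jitter_fraction × pitch` (default 0.4, i.e. the conventional
  jitter amount of factor×d/5 with factor 2) and clipped to the box. Because
  the lattice pitch is the *corrected* mean spacing, this mode overstates the
  realized number density by 1/c³ ≈ 5.9× relative to the nominal density; it
  is the right picture for spacing-true figures, not for count statistics.

All randomness flows from the single `seed` in `LayoutConfig`; there is no
hidden global RNG state. Expected point counts above a configurable cap
(default 10⁶) are refused, which guards against colony-level densities in
large boxes. What the generators do *not* emulate: non-random clustering
(marine snow, bacterial colonization of colonies), mixed-community joint
spacing distributions, motility and advection. Passing tests on these layouts
therefore validate the spacing statistics and the classification machinery
under the model's own assumptions, not the spatial ecology of real seawater.

## Numerical choices and degenerate inputs

* Cube roots use `cbrt`, which keeps perfect cubes exact (ratio 1000 → factor
  10 exactly, so the 10 µm cell's threshold is 90 µm from surface to the last
  bit).
* Density↔spacing inversion is exact algebra; round-trip error < 10⁻¹².
* Ratio exactly 1 (no concentration contrast) raises a no-sphere-of-influence
  error in either direction; as ratio → 1 the threshold radius tends to R and
  the threshold time to 0.
* Nearest-neighbour statistics require ≥ 2 points; KD-tree results are tested
  against an all-pairs brute-force oracle (exact agreement for n ≤ 500).
* Grid scans that end before the crossing raise a grid-too-short error rather
  than extrapolating.

## Problem sizes

Default analyses are desk-scale: threshold computations are closed-form; the
Monte-Carlo constant uses 20,000 points (sampling error ≈ 0.0015, an order of
magnitude below the ±0.01 acceptance band); layout tests use boxes of 10³–10⁶
µm³. The figure pipeline renders up to a few 10⁵ cells via a single
matplotlib `EllipseCollection` with data-space radii, so cell symbols are
never exaggerated relative to the spatial axes.

## Known limitations

The dilution-front model attaches one concentration to one moving radius; it
is not a solution of the diffusion equation and says nothing about the
quasi-steady concentration *field* around a cell. The sink law rises as
(r/R)³, which is the mirrored heuristic, not Fick's-law uptake. The reference
table's densities are representative literature values spanning orders of
magnitude, not a survey; duplicate taxon×habitat rows from different sources
are kept as distinct records. The diffusion coefficient default follows the
reference parameterization (1500 µm² µs⁻¹); zero-decay threshold radii are
independent of D, so no headline number depends on its unit interpretation.
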