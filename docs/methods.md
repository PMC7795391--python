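# Methods

## The physical problem

A soft rectangular cantilever (PDMS, Young's modulus `Es ≈ 750 kPa` at a
10:1 base:curing-agent ratio, Poisson ratio `νs = 0.49`) carries a
confluent layer of cardiomyocytes on its top face. When the cells
contract they act like a residually stressed thin film and bend the
cantilever; the tip deflection is the sensor read-out for contractility
and, ultimately, for cardiotoxicity screening. Perforating the
cantilever with a regular grid of through-holes lowers its stiffness
and amplifies the read-out. This package predicts the deflection of
both the plain and the perforated sensor, and cross-checks the closed
forms with an independent finite-element plate model.

Units are a single consistent micromechanics system — µm, kPa, nN —
throughout. Note `1 nN/µm² = 1 kPa`, so contractile stresses (2–5
nN/µm² for beating monolayers) are kPa numerically. Deflections come
out in µm.

## Closed-form model (`core`)

The cell layer is a thin film of thickness `tf` (default 10 µm, one
cell thick) with in-plane stress `σf` on a substrate of thickness `ts`.
Stoney's relation links the stress to the curvature change; following
the plate-modulus correction for a coated cantilever we use
`Es/(1−νs²)` rather than the biaxial `Es/(1−νs)`:

    σf = Es·ts² / (6(1−νs²)·tf) · (1/r − 1/r0)

With the shallow-arc identity `r ≈ L²/(2δ)` and a flat initial state
(`1/r0 = 0` — the default; no initial curvature is modelled) this
inverts to the tip deflection

    δ = 3(1−νs²)·L²·tf·σf / (Es·ts²)

Properties the tests pin down: linearity in `σf`; scaling `δ ∝ L²`,
`∝ tf`, `∝ 1/ts²`, `∝ 1/Es`; independence of the width `b`; and exact
algebraic inversion through the stress–curvature pair. The biaxial
convention is retained behind a flag; for the same curvature it reports
a stress `(1+νs)` times larger.

The model is geometrically linear (the regime of interest reaches
`δ/L ≈ 0.19` at most) and ignores gravity sag. A warning (not an
error) fires when `tf/ts > 0.2`, where the thin-film assumption
degrades.

## Perforation and the effective modulus (`perforation`)

Holes of aperture `d` sit on a grid with pitch `q1` along the length
and `q2` across the width. The layout convention is an interior grid of

    n1 = ⌊L/q1⌋ − 1   by   n2 = ⌊b/q2⌋ − 1

centres, centred on the plate so no hole touches the boundary. On the
3000×1000 µm plate with `q1=300, q2=100` this gives 81 holes, and the
area-fraction porosity `p = n·πd²/4/(L·b)` evaluates to 0.053 / 0.076 /
0.104 / 0.136 for `d` = 50/60/70/80 µm. Through-thickness holes make
area and volume fraction identical. Not every porosity quoted for other
layouts follows this counting rule (the spacing-sweep values 0.147 and
0.041 in particular do not); every entry point therefore also accepts a
direct porosity value, and the bundled sweep campaigns use the quoted
values as direct inputs where the layout is underspecified.

The perforated plate is homogenized with the porosity power law

    E = Es·(1 − a·p)^b ,   defaults a = 0.49, b = 5.86

valid while `a·p < 1` (a domain error otherwise). Substituting `E` for
`Es` in the deflection formula gives the perforated deflection; the
gain over the plain sensor is exactly `(1−a·p)^(−b)`, independent of
geometry, load and modulus — about 22 % at `p = 0.068`.

`fit_porosity_law` recovers `(a, b)` from (porosity, modulus-ratio)
data by nonlinear least squares, with a fixed starting point
`(0.5, 5.0)` and bounds `a ∈ (0,1], b ∈ (0,50]` so results are
deterministic for a given dataset; Jacobian-based 95 % confidence
intervals are reported. Identifiability caveat: over a narrow porosity
range (say `p ≤ 0.15`) the curve is nearly linear and the data mainly
constrain the product `a·b`; individual constants are only pinned down
by wider ranges or by averaging over many noisy datasets (the test
suite checks exact recovery on noiseless data and 5 % median recovery
over 100 noisy seeds at noise sd 0.005, n = 10, p ∈ [0.02, 0.15]).

`generate_fit_fixture` produces synthetic fitting datasets from a known
law with optional Gaussian noise on the ratios (clipped back to
(0, 1]). It emulates the *statistics* of finite-element stiffness-ratio
data — smooth decay plus measurement-scale scatter — not any particular
solver's discretization bias, so passing recovery tests demonstrates
the estimator works, not that any specific simulation pipeline is
unbiased.

## Finite-element oracle (`fem`)

An independent numerical route used to verify the closed forms: a
Kirchhoff plate clamped along `x = 0`, free on the other three edges,
discretized with the 12-DOF ACM rectangle (nodal `w, w_x, w_y`;
non-conforming, passes the constant-moment patch test, second-order
convergent). Assembly is sparse; systems up to ~6·10⁴ DOFs solve in
seconds with SuperLU.

**Load reduction.** The film's membrane resultant `σf·tf` becomes a
distributed eigenstress moment per unit width `m = σf·tf·z̄` about the
composite neutral plane, with the film included in the layered bending
stiffness (default). With `include_film_stiffness=False` the film is a
thin stressed skin on a bare substrate plate and `m = σf·tf·ts/2`; in
that limit the cylindrical-mode solution is the Stoney parabola
exactly.

**Stress state.** The cells contract chiefly along the long axis, and
at these widths and deflections the plate bends cylindrically — the
anticlastic (saddle) counter-curvature a geometrically linear theory
predicts for a free strip is physically suppressed. The default
`cylindrical` mode therefore applies the eigenmoment pair `(m, νm)`,
whose exact solution is the modified-Stoney deflection.
`anticlastic_uniaxial` applies `(m, 0)` (the linear free-Poisson
response, ~25 % higher at ν = 0.49, kept to probe that limit) and
`equibiaxial` applies `(m, m)` (the classical biaxial Stoney regime,
lower by `(1−ν)/(1−ν²)`).

Measured at the two reference sizes (substrate 100 µm, film 10 µm at
188 kPa, `σf = 2`): layered default 485.2 µm (L = 9000) and 53.9 µm
(L = 3000); thin-skin limit 492.4 and 54.7 µm, equal to the closed form
to solver precision. Both lie within 5 % of the published simulation
values (500 and 54 µm) used as cross-check targets.

**Perforations.** Meshes are structured grids; elements fully inside a
hole are removed, and elements cut by a hole boundary stay with their
stiffness scaled by the solid-area fraction (8×8 midpoint subsampling).
This resolves the aperture to sub-element accuracy — pure element
removal quantizes so coarsely that different apertures can produce
identical meshes — and the summed fractions reproduce the analytic
porosity to ~2·10⁻³. The eigenmoment load is *not* scaled: apertures
are smaller than the cells, the layer spans the holes, and its
contraction acts over the full area.

`effective_modulus_from_fem` measures the stiffness knock-down
directly: plain and perforated plates under the same transverse
free-edge line load, ratio of tip deflections = `E/Es`. At mesh size
15 µm these ratios track the default power law within 5 % over
`p ∈ [0.05, 0.14]`; fitting them recovers the law's curve (and the
product `a·b ≈ 2.5`, against 2.87 for the defaults) subject to the
identifiability caveat above.

Known limitation: under the *eigenmoment* load the bending-only plate
shows just a 4–7 % perforation gain, far below the homogenized law's
22–50 %. A bending model has no membrane DOFs; most of the gain seen in
full 3-D simulations comes from the perforated substrate's in-plane
compliance letting the film contract further. The oracle is therefore
used quantitatively for the plain plate and for stiffness ratios, and
only qualitatively (perforated > plain) for the perforated prestress
case.

**Convergence.** `convergence_study` runs a refinement sequence and
Richardson-extrapolates the last two levels at order 2. It defaults to
the anticlastic mode because the cylindrical-mode plain solution is a
parabola inside the element space — exact at any mesh density, leaving
nothing but roundoff to study. Tip read-out is the free-end centre node
(the physical sensing point); the free-edge mean is also reported.

## Transient response (`transient`)

Beating is modelled as `σ(t) = A·sin(2πt/T)` (defaults A = 5 nN/µm²,
T = 1 s). The first bending resonance of these plates is orders of
magnitude above 1 Hz, so inertia and damping are neglected and the
response is quasi-static: `δ(t)` is the static deflection at `|σ(t)|`.
The magnitude is what matters — contraction in either phase bends the
plate toward the stiffer read-out — giving two equal peaks per period,
at 0.25 s and 0.75 s for the defaults, each equal to the static
deflection at the amplitude. The default grid is 1 ms over one period.
Peak extraction takes grid points strictly above the left neighbour and
not below the right one, so plateaus report their earliest time and a
constant series has no peaks.

## Sweeps and campaigns (`sweeps`, `cli`)

`run_sweep` varies one parameter (`size` couples L and b at a 3:1
aspect) with everything else fixed, one row per value, aborting with
the offending value named on any failure; provenance (spec hash,
package version) is logged per row. The bundled campaigns regenerate
the study's figure-level sweeps: plain size×force (fig2), plain
modulus/thickness (fig3), perforated size×force (fig4), perforated
modulus/thickness at p = 0.068 (fig5), aperture and spacing sweeps on
the 3000×1000 plate (fig6), and the transient comparison (fig7). CSVs
are written with a fixed float format and are byte-identical across
re-runs; plots are optional and headless-safe (Agg).

## Numerical choices

- Flat state sentinel: `math.inf` curvature radius; zero deflection ⇔
  infinite radius, enforced by the result type.
- Fit optimizer: trust-region reflective least squares, tolerances
  1e-12, evaluation cap 5000; non-convergence raises with the residual
  history attached.
- Layout counting uses `⌊x + 1e-9⌋` to protect exact-multiple pitches
  from floating-point flooring.
- Mesh determinism: node/element ordering is row-major from the clamped
  edge; identical inputs give identical meshes and matrices.
- Singular systems (e.g. a mesh with no clamped nodes) raise with the
  unconstrained DOFs named rather than returning garbage.

## Problem sizes

The default test and verification runs use meshes between 30×10 and
240×80 elements (up to ~58 000 DOFs) and four-point aperture sweeps at
15 µm element size; the whole suite, including all finite-element
cross-checks, runs in well under a minute on one CPU. These densities
were chosen as the coarsest at which the plain-plate checks sit
comfortably inside their 5 % bands and the stiffness-ratio curve is
smooth in the aperture.
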