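# Methods

`leafmorph` simulates the growth of a leaf primordium as a continuous,
deforming tissue sheet (the *canvas*) coupled to a population of polygonal
virtual cells (*v-cells*) that divide stochastically. Growth and division
are controlled by separate regulatory inputs, which is what lets the model
express compensation: changing the division machinery re-partitions the
leaf into different numbers of cells without changing organ size, unless a
feedback from cell size to growth is switched on.

## Tissue growth

The canvas is a 2D triangulated mesh (3000 linear elements by default,
never remeshed). Each element carries a specified growth tensor: rates
`K_par` and `K_per` (h⁻¹) parallel and perpendicular to a local polarity
axis. Over a step `dt` the element's target deformation is a pure stretch
`diag(1 + K_par·dt, 1 + K_per·dt)` in its polarity frame. Because
neighbouring targets are generally incompatible, realized node positions
minimise the area-weighted Frobenius misfit between realized and target
per-element deformation gradients (a least-squares elastic-mismatch
relaxation, solved as two sparse SPD systems per step, with the rigid
translation fixed at the base edge). Two properties follow by
construction and are enforced by tests:

* spatially uniform specified growth is compatible, so resultant growth
  equals specified growth to solver precision (no mechanical residual);
* incompatible fields are reconciled by tissue connectivity, producing
  the emergent organ shape.

The underlying mechanical formulation is deliberately the simplest one
satisfying the uniform-growth contract; no elastic moduli enter (only the
relative area weighting), and any scheme with the same contract would be
admissible. Steps that would invert an element are retried with internal
sub-stepping.

Resultant growth between two states is measured per element from the
deformation gradient `F`: areal rate `ln(det F)/dt`, and directional rates
as projections of the log right-stretch tensor `log(FᵀF)/2/dt` onto the
midline axis, so parallel + perpendicular = areal exactly.

## Regulatory factors

Tissue-fixed factors ride on mesh nodes and deform with the canvas:

* `PGRAD` declines linearly from 1 at the base to 0.195 at the tip of the
  initial canvas; promotes `K_par` (coefficient 0.041 h⁻¹).
* `LAM` rises sigmoidally from petiole to lamina (length scale 15 μm at
  the petiole-lamina boundary); promotes `K_per` (0.0235 h⁻¹).
* `MID` is a smooth midline stripe (half-width 14 μm initially); inhibits
  `K_per` (coefficient 1).
* `PROXORG` marks the base edge and organises polarity.

`POL` is clamped to 0.1 over `PROXORG` and diffuses with decay
(0.1 h⁻¹) for 20 setup steps before growth begins; each element's
polarity is the direction of `−∇POL` (distally down the gradient),
computed from an area-weighted nodal gradient recovery (raw P1 gradients
alternate with the mesh's diagonal parity), with elements whose gradient
magnitude is below 8 % of the field maximum inheriting the axis of the
nearest resolved neighbour (the gradient direction there is
discretization noise, e.g. at the no-flux distal edge). Polarity vectors
are subsequently pushed forward by each step's deformation gradient.

`PMF` is held at 1 on the material node band straddling the
petiole-lamina boundary and undergoes diffusion-decay (implicit Euler on
the current mesh; pure decay of an interior value over one step is
`v/(1+μ·dt)`). Its published decay rate is 0.3 h⁻¹ and diffusion constant
0.01 (units unstated); we read 0.01 as mm²·h⁻¹ and calibrate a single
dimensionless length factor (`pmf_length_calibration`, default 2.6,
giving λ = √(D/μ) ≈ 294 μm) so the 0.295 / 0.184 thresholds sit at about
300 / 400 μm from the boundary in the early presets — the published
correspondence between thresholds and corridor distances. Because the
quasi-steady profile is exponential, the ratio of the two corridor
distances is pinned at `ln 0.184 / ln 0.295 ≈ 1.39`; both cannot be
exactly 300 and 400. By default PMF is treated as a concentration diluted
by tissue expansion (node amounts conserved through the lumped mass
matrix); a non-diluting mode is available behind the same switch.

Temporal factors: `LATE` is 0 before 148 h and rises at 0.0048 h⁻¹; in
the mature-stage variants it continues exponentially after 189 h with
branch constants chosen for continuity (`A = g·41·e^{−189/41}`,
`B = 1/41`). `EARLYGROWTH` is 1 until 189 h and then falls at 0.0417 h⁻¹
to 0. LATE-shift mutants displace every breakpoint by `t'`.

Each model variant evaluates its own product-of-factors formulas for
`K_par`/`K_per` (early, mature, limit-free with distally increasing
inhibitors, and the cell-size-feedback variant with
`ω = clamp((a₂−ca)/(a₂−a₁), 0, 1)`, lamina thresholds 4000/8000 μm²,
midline 18000/20000 μm²). Growth-rate mutants scale both rates by `k'`.
Slow-physiology variants (plate `0.55`, chamber-tuned `0.75`) evaluate
all temporal factors at physiological time
`τ = 87 + ratio·(t−87)` and realise `ratio`-scaled rates per actual hour,
while diffusion runs in actual time; the plate preset additionally has
`k' = 0.6`, for a net linear-rate scale of 0.33.

## Cell division

V-cells tile the canvas exactly: their vertices are anchored to elements
by barycentric coordinates and move with the tissue; wall endpoints
created by a division are inserted into the neighbour sharing that wall,
so the tessellation stays conforming (edge-sharing adjacency is always
well defined, and cells + intercellular spaces account for the leaf area
to within a fraction of a percent throughout a run).

Competence (`CDIV`) requires PMF ≥ 0.184 (subepidermis) or ≥ 0.295 plus
PGRAD ≥ 0.628 (epidermis), and LATE below 0.1680 (0.0768 in the
epidermal midline). Factor values at a cell are the mean over its
vertices (a smooth-field approximation to the centroid value).

Each cell carries a target area drawn once at birth from
`normal(Ā, 0.2·Ā)`, truncated below at `0.3·Ā` (a 3.5 σ event; the
stated mean and SD are preserved to < 0.1 %). `Ā` is 150 μm² before
114 h; afterwards the lamina value interpolates from 150 μm² (PMF ≥ 0.51)
to 300 μm² (PMF at the competence threshold), the epidermal midline uses
a constant 500 μm², and the subepidermal midline uses `1.5·500·PGRAD`,
re-evaluated at check time with the cell's frozen noise factor (the
gradient advects under the cell). Threshold mutants add `a'` to the
lamina value.

A competent cell whose area has reached its target divides once per
1-hour step: the nominal wall is the global shortest chord through the
area centroid (0.5° direction scan with golden-section refinement;
near-ties broken towards the local polarity axis); the actual wall is
parallel to it through a point displaced uniformly at random in a disc of
radius 0.25 × the nominal length (resampled if it exits the polygon or
cuts a sliver below 2 % of the mother, falling back to the nominal wall),
and each endpoint is slid 5 % of the wall length along its host edge
towards the opposite endpoint — the slight shortening that gives
realistic wall angles. Daughters inherit region and layer and draw fresh
targets from the local `Ā`.

In the subepidermal model, 30 intercellular spaces appear at 120 h and
further vertices are replaced at 11 h⁻¹: a randomly chosen three-way
interior vertex (not touching an existing space) is replaced by a
triangle of area 2 μm² whose corners lie on the three walls; every space
then expands radially, each vertex's distance from the space centre
growing at 1.25 % h⁻¹ — an areal growth rate of 2.5 % h⁻¹ exactly (the
radial-distance reading is the only one consistent with both printed
numbers). Space vertices are re-anchored to the canvas after each
expansion, so the surrounding cells yield the area.

## Presets and calibrations

All presets start at 87 h. Early presets end at 178 h, mature-stage
presets at 412 h physiological time (stretched into actual time for the
slow-physiology variants). The initial primordium is a rounded
half-ellipse lamina on a petiole stub — width 100 μm, lamina length
150 μm, petiole 40 × 65 μm — a calibration input matching the first
tracked stage: with it, the early epidermal preset passes 0.2 mm width
near 115 h, divisions cease as the leaf nears 0.9 mm, and the mature
preset arrests near 3 mm at 412 h. The initial v-cell pattern is a
Voronoi packing of a hexagonal lattice jittered by half its spacing
(mean cell area 70 μm²): a near-Poisson packing whose neighbour-number
spread matches natural epidermis; a regular lattice would start the
tissue with ~96 % hexagons, unlike any observed packing.

A single seeded generator drives every stochastic choice, so runs are
bit-reproducible given (config, seed); mutant comparisons reuse the base
seed so Monte-Carlo variance largely cancels in the deltas.

## Tracking metrics

A `TrackingDataset` (CSV trio: vertices, cells, lineage, plus the
boundary-position table and metadata) is the common format for synthetic
and externally tracked data. Areal growth rates are clone-aware relative
rates `ln(A₂/A₁)/Δt`, summing all descendants at the later time.
Directional rates come from a least-squares affine fit to a cell's
shared vertices; projecting the log right-stretch tensor on the midline
axis makes parallel + perpendicular equal the areal rate and renders all
rates rigid-motion invariant. Division statistics stratify execution
areas and cycle durations into lamina bands `[0, 150)` / `[150, ∞)` μm
from the petiole-lamina boundary (half-open; distances measured along
the midline axis) and the midline, with 1.96 × SEM ranges. Topology
distributions count edge-sharing neighbours of interior, non-space cells.

### Estimator biases, quantified

In any threshold-division model checked on a discrete grid, the raw mean
of observed execution areas sits a few percent away from `Ā`: crossing is
detected late (+`(e^g−1)/g − 1` ≈ +2 % at 4 %/h areal growth and hourly
checks), the last frame *before* division underestimates the mother
(−g·Δt_sample), small-target lineages cycle faster and contribute more
events, and a daughter drawn a target below its birth area divides
immediately at an uninformative area. The parameter-recovery tests
therefore use founders' first divisions (equal weight per lineage, age
above one check interval) divided by the analytic overshoot factor, which
is unbiased to well within its confidence interval; pipeline-level tests
that use the raw stratified means carry a documented 10 % allowance, and
the cross-strata ratio (which cancels the multiplicative biases) is held
to 10 %.

## Synthetic data

The generator has two sources. `from_trajectory` exports simulator runs
at a chosen sampling interval (12 h or 2 h regimes), with isotropic
Gaussian vertex noise (default 0.5 μm — a sub-pixel placeholder for
hand-clicked vertex error, config-exposed) and occlusion-style dropout
that removes contiguous patches together with their lineage subtrees, so
retained lineages are complete. `parametric_generate` builds a packing
on a rectangle, advects vertices with prescribed per-axis elongation
rates (exact exponential update; folding fields are rejected on negative
cell areas), and divides cells with the same noisy shortest-wall engine
at a prescribed `Ā(x, y)` — emitting exact ground truth for every metric.

What synthetic data do not emulate: curvature and projection artifacts of
real imaging, segmentation errors, temporally correlated click errors,
stomatal-lineage divisions, and out-of-plane tissue motion. Passing the
recovery tests therefore validates the estimators and the pipeline, not
the imaging chain.

## Problem sizes used in the test suite

Corridor, topology, division-statistics and final-width checks run the
full presets at the default 3000-element mesh (the early presets take
~1 min each, the mature preset ~1–2 min). The twelve-way mutant sign
matrix and structural preset tests run on a 700-element mesh with larger
starting cells (140 μm²), which preserves every qualitative outcome while
keeping the whole suite within a routine CI budget.

## Known limitations

* Mechanics is a quasi-static least-squares relaxation; there is no
  viscoelasticity, no out-of-plane buckling, and no residual-stress
  bookkeeping between steps.
* The two corridor distances cannot be calibrated to 300 and 400 μm
  simultaneously (exponential profile; ratio fixed at 1.39) — the
  calibration splits the misfit between them.
* The competence zone is growth-limited before ~142 h with the calibrated
  initial geometry: its distal limit extends with the leaf first and only
  then becomes stationary, so stationarity statements apply to the
  threshold-limited phase.
* Division is checked hourly; sub-hour cell-cycle structure (and any
  minimum cycle duration) is not modelled.
* Serrations, stomatal lineages and 3D leaf curvature are out of scope.
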