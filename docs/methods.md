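# Methods

This note documents the models, numerical choices and limitations of the
`pullpush` pipeline: pressure fields from time-resolved planar
velocimetry, body-surface kinematics, the four-component pull/push
decomposition of surface pressure forces, and Froude-type hydrodynamic
efficiencies.

## Pressure from velocimetry

For incompressible planar flow the momentum balance gives the pressure
gradient at every node of the measurement grid,

    ∇p = −ρ (∂u/∂t + (u·∇)u) + μ ∇²u ,

with the unsteady term from a three-frame central difference in time,
the convective term and Laplacian from second-order central differences
in space (one-sided second-order stencils at the field-of-view edges;
the Laplacian edge rows replicate the adjacent interior value, a
negligible correction at the viscosities involved). A node's gradient is
valid only where its whole space–time stencil touches valid nodes;
non-finite results are invalidated as well.

The gauge pressure is then obtained by **median-of-eight-path
integration**: from every node, eight straight rays (E, NE, N, NW, W,
SW, S, SE along grid lines and diagonals) run to the edge of the field
of view, `−∫ ∇p·dl` is accumulated from the edge inward by the
trapezoidal rule (diagonal steps use the full vector increment
`g·(±dx, ±dy)`), and the node takes the **median** of the surviving ray
results (mean of the two central values for an even count). Rays that
cross a masked or invalid node are discarded — no detours around the
body. Nodes with fewer than `min_valid_paths` (default 3) survivors are
marked invalid and filled by nearest-valid interpolation, flagged
separately so downstream stages and QC can see them.

The median is a robustness device against *impulsive* errors: with at
least five agreeing rays, an arbitrarily large error on a single ray has
exactly zero effect on the output (an asserted, exact property).
Broadband measurement noise is a different matter — the median reduces
it only by roughly √8 — so the pipeline offers mask-aware Gaussian
pre-smoothing of the velocity fields (`smooth_sigma`, in cells, default
0 = off; 1–1.5 cells is the usual choice for noisy velocimetry, and at
the validation scales it attenuates the resolved signal by ≲0.1%).

**Edge treatment.** The rays need pressure values where they terminate.
Two policies are provided. The default (`edge_pressure="integrated"`)
first integrates the computed gradient around the field-of-view
perimeter (trapezoidal, closure error distributed linearly along the
loop, mean anchored at ambient 0) and anchors every ray at those values;
this keeps the method second-order accurate even when the true boundary
pressure varies along the edges, as it does for a vortex lattice that
fills the domain. `edge_pressure="ambient"` imposes a literal p = 0 at
every edge node, appropriate when the edges are genuinely far-field. The
gauge constant is unobservable from a finite field of view; comparisons
against analytic fields are therefore made after mean removal.

**Validation.** On the decaying vortex-lattice case (Taylor–Green,
u = sin x cos y·F(t), v = −cos x sin y·F(t), p = (ρ/4)(cos 2x + cos 2y)F²)
the recovered mid-frame pressure is accurate to 0.12% relative L2 at
128², converging at order ≈ 2.0 over 32²→64²→128². An independent
route — a finite-volume Poisson solve of ∇·(∇p) = ∇·g with
gradient-flux Neumann conditions (or Dirichlet edges for
compact-support fields), used only in tests — agrees with the path
integrator to ~0.05% of the field range. On potential flow past a
masked cylinder the surface pressure coefficient matches
C_p = 1 − 4 sin²θ to |ΔC_p| ≤ 0.06 and the net pressure force vanishes
to machine precision (d'Alembert). Reconstruction from a
central-difference gradient carries an intrinsic O(dx²) information
limit (~1.6×10⁻³ of the peak for a Gaussian pressure bump at 128²,
identical for both solution routes).

Problem sizes used throughout the validation suite — 128² for the
vortex lattice, 320² for the cylinder, a ~190×63 grid for the swimmer —
were chosen as the coarsest grids on which the asymptotic convergence
behaviour is already clean.

## Body-surface kinematics

The body outline is traced from the binary mask as the 0.5 iso-contour
of the 0/1 raster (sub-cell precision, counterclockwise), and resampled
to `n_control_points` = 60 points equally spaced in arc length,
anchored at the most-anterior point along the swimming direction
(max-x before the swimming direction is known). Correspondence across
frames is by arc-length index, not feature tracking — stable for
undulating bodies.

* **u_body**: central difference of control-point positions over a
  (prev, curr, next) contour triple.
* **BSR** (body surface rotation): the lab-frame angle of each segment
  joining adjacent control points via `atan2`, differenced centrally in
  time with minimal-change unwrapping (jumps beyond π folded by 2π).
  BSR lives on segments; the point value used for subsetting is the
  mean of the two adjacent segments.
* **BSV** (body surface vorticity): fluid vorticity
  ω = ∂v/∂x − ∂u/∂y (second-order central differences; exact for
  affine fields and equal to 2Ω under solid-body rotation) at the valid
  node nearest each control point, Euclidean search capped at 4 cells
  so masked shadows cannot source dynamically irrelevant far-field
  fluid. Per-frame normalisation divides by the maximum magnitude on
  the body.
* **Swim frame**: the least-squares line through the per-frame contour
  centroids gives the swimming direction ŝ (oriented along the net
  displacement); U is the net displacement projected on ŝ over the
  elapsed time; ĵ is ŝ rotated +90°; body length is the mean contour
  extent along ŝ.

Under the no-slip condition the fluid at the surface rotates with the
surface, so the sign of BSV should track the sign of BSR; on generated
traveling-wave data the per-point sign agreement is 95–100% per frame
on ground-truth contours, and ~75% on mask-extracted contours where
rasterisation jitter (1.5 mm cells on a 12 mm-wide body) adds angle
noise — the latter is reported as a QC metric, not asserted.

## Force decomposition

Each contour element carries the pressure force f_i = −p_i n̂_i dA_i,
with dA_i = ds_i per unit depth in planar mode (units N/m) or
dA_i = 2π r_i ds_i in axisymmetric mode (units N; the contour is then a
meridional half-profile and r_i the distance to the supplied symmetry
axis, which the profile must not cross). Surface pressure is sampled by
bilinear interpolation `surface_sample_offset` = 2 cells outward along
the normal — mask-adjacent nodes inherit stencil damage — stepping
outward in half-cell increments (up to 2 extra cells) when the stencil
is invalid; elements still unresolved are excluded, and more than 20%
of them is a hard failure. An optional two-point linear extrapolation to
the wall (`extrapolate=True`) recovers the true surface value when the
wall-normal pressure gradient is steep; it doubles noise sensitivity,
so the plain offset sample remains the default for force integration.

Elements are classified by the sign pair (sign p, sign f·ŝ): low
pressure is *pull*, high pressure is *push*, each either forward or
rearward along ŝ. The classification threshold is exactly p = 0
(gauge); a configurable dead band exists for noise studies and defaults
to 0. Gross thrust = forward pull + forward push, gross drag = rearward
pull + rearward push, net thrust their difference — the bookkeeping
identity Σ f·ŝ = F_fpull + F_fpush − F_rpull − F_rpush holds to machine
precision by construction and is asserted on every frame. Cycle
summaries are trapezoidal time averages over a window that should span
whole cycles; the pull fractions are ratios of those averages.

Viscous (shear) surface forces are not computed: pressure forces
dominate the thrust of the undulatory swimmers this pipeline targets,
and the omission is recorded in every report's provenance block.

## Efficiency

The Froude-type hydrodynamic efficiency compares useful power with the
power lost to lateral motions:

    η = T·U / (T·U + P_lat) ,
    P_lat = Σ_i p_i (n̂_i·ĵ)(u_body,i·ĵ) dA_i  (summed per frame,
            trapezoid-averaged over the window) ,

where T is the time-averaged gross forward thrust. Restricting both the
thrust and the lateral power to the low-pressure elements gives the
efficiency of the suction mechanism alone,
η_pull = T_pull·U / (T_pull·U + P_lat,pull), and η_push analogously;
subset membership is evaluated per element per frame, and the subsets
are exactly additive (pull + push + neutral = all). Useful limits:
η = 1 with no lateral loss, 0.5 at equal split, 0 at zero thrust; η is
invariant under rescaling all pressures; undefined subsets (no
hydrodynamic work) are reported as null rather than 0.

P_lat uses the *signed* integral: negative local terms represent
genuine energy recovery from the fluid, and no rectification is applied
(a config option exists for sensitivity studies). A negative
cycle-averaged P_lat pushes η above 1; the value is reported as-is with
an explicit flag rather than clamped.

## Synthetic data

Three analytic flows with known pressure validate the pressure stage
quantitatively: the Taylor–Green lattice (unsteady term, periodic-like
boundary pressure), potential flow past a masked cylinder (masking,
surface sampling, d'Alembert) and a Gaussian-core (Lamb–Oseen) vortex
whose pressure comes from radial-momentum quadrature anchored at the
analytic far-field tail (a suction core: minimum at the center,
negative everywhere).

The swimmer generator emulates the geometry and kinematics of a
larval-lamprey-scale animal: body length L = 0.12 m, elliptic
half-width profile (max 6 mm), lateral midline displacement
y(ξ,t) = A(ξ)·sin(2π(ξ/λ − t/T_p)) (traveling) or
A(ξ)·sin(2πξ/λ)·cos(2πt/T_p) (standing), amplitude envelope
A(ξ) = a₀ + a₁ξ + a₂ξ² growing from ~2 mm at the nose to ~10 mm (8% L)
at the tail, wavelength λ = L, period T_p = 0.4 s, and a prescribed
swimming speed of 2 body lengths/s (traveling) or 1.2 (standing) —
an efficient, coordinated swimmer versus the slower uncoordinated one.
The near-body flow is a superposition of Gaussian-core vortex blobs at
the contour segment midpoints, circulation Γ_i = Γ₀·BSR_i·ds_i
(Γ₀ = 0.35, clipped at 3Γ₀, sign following the rotation sense) with
cores placed one core radius (r_c = 8 mm) into the fluid along the
local normal — a core centered on the contour would be half-buried in
the masked interior. Because the BSR pattern itself travels at the wave
phase speed (traveling) or pulses in place (standing), the induced
suction cores advect or stay station-bound accordingly. Blob fields are
curl-of-streamfunction constructions, hence exactly solenoidal
analytically; the discrete divergence shrinks at second order.

**What this generator is not.** The flow is kinematically prescribed,
not a Navier–Stokes solution: it carries no momentum balance, no wake,
no boundary layer and no acceleration-reaction (added-mass) pressure
component. Consequences observed on the default datasets and accepted
as documented behaviour: gross drag exceeds gross thrust (the swimmer
would not actually hold its prescribed speed), and the cycle-averaged
lateral power of the traveling case is slightly *negative* — the
prescribed suction pattern, phase-locked to BSR with a tail-growing
envelope, returns some lateral energy to the body — so η exceeds 1 and
the report flags it. Quantitative pressure accuracy is therefore
validated only on the analytic cases; the swimmer fixtures validate the
*directional* biology-shaped contrasts, which are robust across every
generator variant explored: the traveling-wave swimmer derives a
strictly larger share of its gross thrust from forward pull (~90% vs
~64%), shows a strictly higher η, and its suction mechanism outperforms
its push mechanism (η_pull > η_push).

Measurement noise is modelled as i.i.d. zero-mean Gaussian perturbation
of both velocity components at valid nodes, reproducible under a fixed
seed. A single integer seed governs all stochastic elements; the
generators themselves are deterministic.

## Degenerate inputs, tie-breaks, tolerances

* Lattice regularity: coordinates must be uniform to 10⁻⁶·dx; a
  sequence must be uniformly sampled to 10⁻⁹ s; pressure needs ≥ 3
  frames (endpoint frames are not emitted — no one-sided time
  stencils).
* Even-count medians use the mean of the two central values.
* A stationary body has no defined swimming direction (error, unless a
  fixed axis is supplied); the threshold is a net centroid displacement
  of 0.1 cells.
* Angle unwrapping is minimal-change; a segment rotating more than π
  between the two outer frames of the stencil would alias (no swimmer
  in this regime approaches that).
* Γ = 0 yields a quiescent vortex case, not an error.
* The anterior anchor is the vertex of maximal projection on ŝ
  (first-of-ties); resampling an already-equally-spaced contour is
  idempotent to 10⁻⁹ relative.
* Contours assume a single connected body of ≥ 20 cells not touching
  the field-of-view edge; 60 unique points, with segment 60 closing the
  polygon.

## Known limitations

* The planar momentum balance ignores out-of-plane transport; on real
  mid-body slices of 3-D swimmers this biases the pressure field in
  ways the planar validation cannot quantify.
* Discarding blocked rays (rather than detouring around the body)
  starves nodes in mask shadows, which are filled by nearest-valid
  interpolation and flagged; enclosed pockets are never computed
  directly.
* The whole closed outline is integrated for planar forces; if only
  the lateral surfaces were intended, nose/tail caps contribute their
  (small) share.
* U is the cycle-mean centroid speed, not a fitted steady speed;
  windows that do not span whole cycles bias every time average.
* Efficiencies computed on the synthetic swimmer are internally
  consistent ratios, not physical efficiencies (see above).
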