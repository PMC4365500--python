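# Methods

## Scope and model structure

The package simulates intramembranous ossification of the mouse cranial
vault in two one-way-coupled stages on a fixed triangulated surface:

1. **Patterning (E0 → E15.4).** An activator–inhibitor reaction–diffusion
   system positions concentration peaks; a gated differentiation law
   converts peaks into osteoblast condensations (primary ossification
   centers).
2. **Growth (E15.4 → E22.9).** Condensations are labeled as bones; per-bone
   osteoblast and morphogen fields evolve with cross-bone inhibition,
   producing outward growth and persistent inter-bone gaps (sutures).

Activator/inhibitor fields are frozen at the stage handoff, and the
stage-1 differentiation law is switched off; stage 2 is a separate
initial-value problem seeded with the stage-1 osteoblast field. The
osteoblast field never feeds back on the activator/inhibitor system.

## Domain representation

The embryonic vault is a ~0.3 mm-thick shell of ~7 mm extent. Because the
thickness is ~4% of the lateral scale and the fields of interest have no
through-thickness structure, the domain is a 2-manifold: each triangle is a
finite-volume cell with measure = triangle area. The built-in dome is an
upper-half ellipsoid cap with semi-axes (3.5, 2.6, 2.49) mm: length 7 mm
(rostral = +x), height 2.49 mm, and a width of 5.2 mm chosen from the
length:width proportions of the E17.5 mouse vault (configurable). The
triangulation is built from latitude rings stitched into bands with an apex
fan; the two rim-adjacent rows are refined so cell centroids reach within
2% of both the rim and the apex. The default edge length is 0.15 mm
(~5,100 cells): a resolution scan (0.25 → 0.12 mm edges) shows the
headline region counts are converged from ~5,000 cells, while meshes below
~3,000 cells under-resolve the 1.8 mm-spaced frontal peak pair.

Diffusion uses the cell-centered two-point flux approximation (TPFA):
transmissibility = shared-edge length / centroid distance, zero flux across
boundary faces. TPFA is exactly conservative and exact on orthogonal
meshes (verified on the 1D chain); on triangle meshes it carries an O(1)
pointwise consistency error for non-aligned gradients, which acts as a
small mesh-dependent perturbation of the diffusivity. The 1D dispersion
test bounds the resulting rate error at <2% at the operating resolution.

The per-cell height coordinate `x_rel` is the centroid's distance above the
lowest centroid along the vertical (+z) axis; the differentiation gate
compares it with `x_ref`.

## Parameters

Reaction–diffusion (stage 1): sigma_a = sigma_h = 1e-5 ng/(mm³ s),
mu_a = 5e-5 /s, mu_h = 1e-4 /s, rho_a = 5e-5 /s, rho_h = 1e-4 mm³/(ng s),
D_a = 2.5e-6, D_h = 2.5e-4 mm²/s. These satisfy the pattern-formation
condition (0.667 ≤ 2.0 < 8.468) with a fastest-growing wavelength of
3.52 mm, giving ~6 spots on the dome.

Differentiation: eta = 1e-5 ng/(mm³ s), C_aT = 6.0 ng/mm³, T_a = 400 h
(stored as 1.44e6 s; all rates are per second), Hill exponent n = 8,
x_ref = 1.85 mm, x_top = 2.49 mm (domain metadata only; it enters no
equation).

Growth: alpha = 5e-5 /s, C_mS = 2.0, D_m = 1.2e-7 mm²/s, lambda = 0.1
ng/(mm³ s), C_oS = 1.0, C_mT = 2.0, C_ml = 1e-3 ng/mm³. The growth-stage
Hill exponent is not tabulated separately; the same n = 8 is used, matching
the symbol reuse across the rate laws.

Ossification threshold: a cell belongs to a bony region when C_o > 1.0
ng/mm³ (strict inequality, so an exactly-threshold field yields no region).

## Steady state and initial conditions

The closed-form homogeneous state C_a0 = mu_h rho_a/(mu_a rho_h) +
sigma_a/mu_a = 1.20, C_h0 = (rho_h/mu_h) C_a0² = 1.44 ng/mm³ zeroes the
activator equation exactly but leaves a residual dC_h/dt = sigma_h in the
inhibitor equation: the closed form is the exact fixed point only when
basal inhibitor production vanishes. The convention here follows the
model's standard formulation — simulations start from (1.20, 1.44), whose
small drift toward the true fixed point (~(1.13, 1.38)) is harmless to
patterning. Tests that need an exact fixed point (persistence, measured
mode growth) set sigma_h = 0, which leaves the steady state and the
Jacobian numerically unchanged.

The default perturbation raises the activator by 0.5% of C_a0 at the two
cells nearest the supra-orbital points: on the rostral half of the dome at
±35% of the half-width laterally and 0.6 mm above the rim, mirroring where
the frontal-bone condensations initiate. The perturbation sites, fraction,
and target field are configurable.

## Linear stability

The dispersion relation ω(k) is the largest real part of the eigenvalues of
J − k² diag(D_a, D_h), with J the analytic Jacobian of the reaction terms
at the steady state (closed form, not finite differences). `k` is the
*angular* wavenumber (perturbation ∝ cos(k x)); a cosine with m periods on
a length-L interval has k = 2πm/L. This convention matches the discrete
Laplacian eigenvalues directly. The fastest-growing mode is located by a
2001-point scan of [0, 50] /mm refined by bounded scalar minimization.
`turing_unstable` requires both the closed-form window condition and
ω_max > 0.

## Time integration

Internal time is seconds; outputs report embryonic days (t/86400, clock
starting at E0).

* **Stage 1.** Default scheme is IMEX: backward-Euler diffusion via a
  pre-factorized sparse LU of (I − dt·D·L) per species, explicit reaction,
  dt = safety × 0.05/max(mu_a, mu_h) (≈250 s at defaults) — the inhibitor
  diffusivity makes explicit stepping ~50× more expensive on the default
  dome. Explicit Euler with dt = safety·h_min²/(2·d_eff·D_max) (d_eff = 2
  on surfaces, 1 on intervals) is available and used for verification;
  both schemes agree within 1% on the 1D dispersion test, and measured mode
  growth matches ω(k) within 2%.
* **Stage 2.** Explicit Euler with dt = min(diffusion limit for D_m,
  safety × C_oS/lambda) ≈ 5 s: the morphogen diffusivity is small, so the
  osteoblast reaction timescale governs. Osteoblast and morphogen updates
  share a time level (one-way ordering effects are O(dt)).
* Differentiation/reaction updates use the state at the current time level;
  the osteoblast integral is first-order in time like the rest.
* **Non-negativity.** Transient undershoot is clipped to zero and counted;
  the Ca²/C_h quotient floors C_h at 1e-12 ng/mm³. Default runs floor 0
  cell-steps; the run manifest records the fraction.
* Snapshots are emitted at t = 0, every `output_every` seconds, and at the
  stage end; integration lands on output times exactly by shortening the
  final step of each interval (IMEX refactorizes for the odd step sizes,
  cached by dt).

## Region analysis

Bones and activator regions are connected components (edge adjacency) of
the strict supra-threshold mask, ordered by area-weighted centroid —
descending x (rostral first), then ascending y — so indices are stable
across runs and resolutions. Suture gaps between bone pairs are shortest
graph paths from one bone's cells to the other's, where an edge contributes
its centroid distance weighted by the fraction of its endpoints that are
sub-threshold (so touching regions measure exactly 0 and a one-cell band of
width w measures ≈ w); ossified cells of third bones block the path. The
per-pair gap is reported in mm and, because bone masks only grow, is
non-increasing in time by construction of the dynamics (verified on every
trajectory, not assumed).

## What the synthetic domain does and does not show

The dome emulates the size, proportions, and curvature of the E17.5 vault
surface, not its anatomy: there is no micro-CT geometry, no shell
thickness, no dura or brain, and the domain neither grows nor deforms. Spot
*count* and *placement* in Turing systems depend on domain size and shape,
so the six-peak/five-center result on the dome demonstrates that the model
with these parameters produces the observed pattern topology on a
vault-sized surface — not that it would do so on any individual animal's
geometry. Quantities tied to absolute anatomy (bone outlines, suture
positions relative to landmarks) are outside what the synthetic domain can
validate; pattern counts, gating behavior, disjointness, and gap monotony
are robust to the substitution and are what the tests assert.

## Known limitations

* No osteocyte entrapment/mineralization; "bone" means supra-threshold
  osteoblast concentration.
* No mechanics (brain growth, pressure, stress) and no moving domain; the
  growth stage therefore under-predicts late bone area compared with real
  P0 skulls, as expected for a fixed domain.
* Per-bone morphogen fields are tracked separately (5 diffusing fields);
  bones are never merged or relabeled after the handoff.
* TPFA on triangle meshes is not pointwise-consistent for general
  gradients (see above); results at the default resolution are verified
  against analytic rates in 1D and by mesh-refinement scans in 2D.
* First-order time stepping; halving dt changes stage-1 fields by <1% at
  the default steps.
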