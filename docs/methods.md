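# Methods

`cellflow` simulates a eukaryotic cell as three coupled mechanical
components immersed in a dissipative-particle-dynamics (DPD) fluid: an
outer membrane, a nucleus membrane, and a Kelvin–Voigt (KV) bond network
standing in for the cytoskeleton. This note records the model equations as
implemented, the defaults and why they hold, the numerical choices, what
the scaled instruments emulate, and the known limitations.

## Fluid: dissipative particle dynamics

Particles of equal mass m = 1 interact pairwise inside a cutoff r_c with

- a soft conservative repulsion `f_C = a_ij (1 − r/r_c) r̂`,
- a dissipative drag `f_D = −γ^D w_D(r) (r̂·v_ij) r̂`,
- a random kick `f_R = σ w_R(r) θ_ij Δt^(−1/2) r̂`,

with the generalized weight `w_R = (1 − r/r_c)^s`, `w_D = w_R²`, `s = 0.75`,
and the fluctuation–dissipation constraint `σ² = 2 γ^D kBT` enforced at
parameter construction (the pair shares one normal deviate θ_ij per step,
so the random force is exactly antisymmetric and momentum-conserving).
Equations of motion are integrated with the modified velocity-Verlet
scheme: positions advance with the current force, the new force is
evaluated at a velocity prediction `v + λ Δt f` (λ = 0.5, configurable),
and the velocity update averages old and new forces. A quiescent fluid of
3000 particles equilibrates to the imposed kBT within well under 5%.

Defaults: r_c = 1, γ^D = 4.5, kBT = 0.1, Δt = 0.005, number density 3,
`a_ij = 25 kBT/r_c` for all type pairs. The conservative coefficients are
deliberately plain config: the calibrated model's mechanics are carried by
the membrane and network forces, not by the fluid equation of state.
Pairs of particles belonging to the *same* membrane are excluded from DPD
interactions (the membrane model owns those); pairs from *different*
membranes keep the conservative term as an excluded-volume guard, without
fluid thermostatting.

## Membranes

Each membrane is a closed, outward-oriented, genus-0 triangulation whose
vertices are particles. Closed-surface bookkeeping is exact:
`N_e = 3(N_v − 2)`, `N_t = 2(N_v − 2)`, one bending (dihedral) element per
edge. Spheres are generated as Class-I geodesic icosahedra of frequency f
(`N_v = 10 f² + 2`); any integer f is allowed, so the realized mean edge
length lands within 15% of the requested bond length (0.5 by default) at
every radius used here. Rest lengths are the constructed per-edge lengths.

Elastic energy is the sum of four terms:

1. **Worm-like-chain bonds** — per bond,
   `U = (kBT l_max / 4p)(3x² − 2x³)/(1 − x)`, `x = l/l_max`; diverges as
   `l → l_max` (over-extension is a hard runtime error naming the bond).
2. **Triangle expansion** — per triangle, `C_q / A_α` with
   `C_q = 3√3 kBT l_max³ x₀⁴ (4x₀² − 9x₀ + 6) / (64 p (1 − x₀²))`,
   `x₀ = l₀/l_max`. Its gradient includes the full 1/A_α dependence.
3. **Bending** — per adjacent triangle pair, `k_b [1 − cos(θ − θ₀)]`. θ is
   the signed angle between outward normals, convex-outward positive;
   θ₀ = 0 by default (a per-surface scalar is configurable). Forces use the
   analytic four-site torsion gradient.
4. **Area and volume constraints** — global quadratic penalties
   `k_A kBT (A − A₀)²/(2 l₀² A₀)` and `k_V kBT (V − V₀)²/(2 l₀³ V₀)`, with
   A₀, V₀ taken from the built mesh.

All forces are exact negative gradients of these energies; the test suite
verifies them against central finite differences to better than 1e-5
relative error, and a free thermalized cell holds A and V within 1% of
reference over 1e5 steps at the default constraint constants.

Membrane viscosity is a pair force on every bond,
`f_D = −γ^T v_ij − γ^C (v_ij·r̂) r̂` with γ^T = γ^C = γ, plus the matched
random force built from one 3×3 Wiener-increment matrix per bond per step
(traceless-symmetric part with amplitude √(2kBT)·√(2γ^T), trace part with
amplitude √(2kBT)·√(3γ^C − γ^T)). The random term is projected onto the
**unit** bond vector: that is the convention under which the pair satisfies
fluctuation–dissipation — an isolated membrane thermostated only by this
pair force equilibrates to kBT within a fraction of a percent. Projecting
onto the full bond vector instead would make the equilibrium temperature
scale with bond length (≈ 0.25 kBT at l₀ = 0.5), which we verified and
rejected.

Calibrated membrane constants (simulation units): persistence length
p = 0.00141, γ = 4; cell surface k_A = 10,000, k_V = 15,000, l_max = 3,
l₀ = 0.5, bending 65; nucleus surface k_A = 5,000, k_V = 15,000,
l_max = 1.2, l₀ = 0.5, bending 250.

## Cytoskeleton and nucleus interior

A KV bond is a spring (k_s) and damper (k_v) in parallel; since both see
the same strain, the tension is `T = k_s ε + k_v dε/dt` with
`ε = (l − l₀b)/l₀b` and `dε/dt = (v_ij·r̂)/l₀b`. The strain-based form
makes bond mechanics independent of rest length, hence of cell size; an
extension-based variant (`T = k_s(l − l₀b) + k_v dl/dt`) can be toggled.
A single bond under constant tension reproduces the closed-form creep
`ε(t) = (σ/k_s)(1 − e^{−t k_s/k_v})` within 1% over five time constants.

Wiring: k-means clustering of vertex coordinates restricts each membrane
to an eligible subset (per cluster, the vertex nearest the centroid; ties
to the lowest index; deterministic given the seed). Model M1 joins each
eligible outer vertex to its single nearest eligible nucleus vertex; model
M2 (default, w = 5) to its w nearest. Bond density ρ = bonds per outer
vertex fixes the count `round(ρ N_outer)` independent of resolution; the
eligible-set size is derived from it (`ceil(ρN/w)` for M2). M1 admits
geometrically straight bond chains crossing the whole cell through the
nucleus network — stress applied at one pole teleports to the other; the
graph test measures a maximum chain straightness of exactly 1 for M1 and
< 0.999 for M2, which is why M2/w = 5 is the default.

The nucleus interior reuses the machinery with *most-distant* partners
(chords through the nucleus volume), consumed round-robin through each
vertex's farthest-first ranking until `round(ρ_nucl N_nucl)` distinct
bonds exist. The nucleus springs are built five times stiffer than the
cytoskeleton (k_s^nuc = 5 k_s^cyt = 600 at the calibrated k_s = 120); the
damper viscosity is shared (k_v = 10).

KV bonds carry no thermal noise term (only the membranes do); the
resulting mild temperature depression of a free cell (≈ 10–20% below kBT
with the default networks) is visible in diagnostics and does not affect
the deterministic instruments.

## Cell assembly

`build_cell(diameter, nc_ratio)` meshes two concentric spheres at the same
target bond length. The nuclear–cytoplasmic ratio 0.29 is interpreted as
a volume ratio (nucleus radius = 0.29^(1/3) × cell radius); after
meshing, the nucleus is rescaled so the realized mesh-volume ratio is
exact. Cells whose membranes would come within half a bond length are
rejected. The builder guarantees size invariance by construction: cells
of any diameter built at the same ρ have identical bonds-per-vertex.

Unit mapping (μm, Pa, s per simulation unit) is explicit configuration
with nominal identity defaults — 1 sim length ≈ 1 μm is consistent with a
20 μm cell discretizing to roughly 5,000 outer vertices at l₀ = 0.5, but
pressure and time scales require a full-resolution calibration that is
out of desk scope, so scaled-mode moduli are reported in simulation units.

## Virtual micropipette

The pipette is an analytic plate at x = 0 with a circular mouth of radius
R_p opening into a cylindrical tube, both enforced by bounce-back
(position mirrored across the violated surface, velocity negated). The
suction ΔP acts as a direct axial traction `ΔP · (A₀/N_outer)` on outer
membrane particles inside the mouth cylinder. We chose this over driving
a fluid column in the tube because at desk scale a DPD fluid can only
sustain pressure differences of order n·kBT ≈ 0.3 across the cell —
orders of magnitude below the ~50–150 sim-unit suctions the calibrated
membrane requires — and because the traction instrument is deterministic
(kBT enters the elastic coefficients but no noise is injected), which
makes parameter sweeps strict orderings rather than statistical ones.

Protocols: *ramp* raises ΔP in quasi-static steps (default six levels,
hold 15 time units each, Δt = 0.005) after a strongly damped settle; the
first (smallest) level defines the reference length L₀, and
`L_n = (L_p − L₀)/R_p` with L_p the maximal axial extent past the mouth
plane. *Creep* holds ΔP constant after a damped minute-pressure hold and
records L_n(t) densely (every step) — the measured transient lasts a few
tenths of a time unit, set jointly by the KV dampers, membrane viscosity
and a weak ambient drag (0.2) standing in for the missing solvent.

Rheology: the half-space (Theret) punch model gives
`E = (3Φ/2π) · dΔP/dL_n` from a least-squares ramp slope (wall function
Φ = 2.1 by default, configurable in [2.0, 2.2]); creep is fit to the
standard-linear-solid form `L_n(t) = L_∞(1 − a e^{−t/τ})`, from which
`k₁ = 3ΦΔP/(2π L_∞)`, `k₂ = a k₁/(1 − a)` and the apparent viscosity
`μ = τ k₁ k₂/(k₁ + k₂) = a τ k₁`. Estimators recover generating
parameters exactly on noise-free synthetic traces and within their
standard errors under noise; E is invariant to time rescaling while μ
scales linearly with it, as dimensional analysis demands.

The standard sweep cell is 6.6 μm across (642 outer vertices, R_p = 1.3).
At the coarsest resolution (162 outer vertices) the ρ-sweep is not
monotone — re-clustering the small eligible set rewires the network
discretely — while at 642 vertices all five sweeps are strictly monotone:
E rises with k_s and with ρ and falls with p; μ rises with k_v and with
γ. The ρ response at this resolution is monotone over 0.4–1.2 but rolls
over in the dense-network regime (ρ ≈ 1.6), a known scaled-resolution
limitation.

## Obstacle channel

The device is a slab bounded by no-slip walls (frozen DPD particles at
fluid density plus bounce-back planes) with rows of triangular prism
obstacles, apex upstream, one prism per spanwise period; the free span
between prism bases is the gap, and x-periodicity makes the rows repeat.
A body force on fluid particles drives the flow; its magnitude is set by
secant iteration against a target cell-free mean velocity (the frozen
wall realization belongs to the device, not the run seed, so calibration
transfers across runs). The full-geometry constructor reproduces the
experiment scale (28 μm height, 10 rows, 60 μm spacing, gaps 10/12/15 μm)
and is intended for cluster runs; the scaled default is two rows at gap
2.6 with a 3.3 μm cell.

At desk scale the fluid cannot deform the full-stiffness cell (it clogs
rigidly), so scaled channel studies use a *compliant instrument
configuration* (`scaled_channel_cell`): every elastic coefficient divided
by 10 and the viscous ones reduced in proportion, preserving the
elastic/viscous balance. The transit measurement records the outer
membrane centroid and gyration-tensor asphericity; the relaxation time
after each row is the delay from the post-gap deformation peak until
asphericity falls within 5% of the peak excess over the undeformed
baseline, and the reported ratio is mean relaxation time over total
transit time. In the scaled runs the cell deforms at every row and
recovers between rows. Post-constriction recovery at this scale is
dominated by fluid-membrane coupling: changing the KV damper viscosity
eight-fold moves the measured relaxation time by under 2%, so the damper
dependence of the viscous response is characterized with the aspiration
creep instrument (where it is strictly monotone), and the quantitative
relaxation/transit ratios of the full-resolution study are neither
reproducible nor asserted at desk scale.

## Numerical choices

- Δt = 0.005 for every system containing a membrane (the nucleus mesh's
  bending modes ring at Δt = 0.01); pure-fluid runs also default to 0.005.
- Neighbor search: linked cells with a Verlet skin of 0.3 r_c, rebuilt
  when any particle has moved half the skin; exact O(N²) minimum-image
  search is the oracle and the small-box fallback. A periodic dimension
  thinner than r_c is rejected.
- A displacement larger than r_c in one step aborts with a time-step
  diagnostic. Overlapping soft particles get zero conservative force and
  a warning.
- Ties (nearest/farthest partners, k-means representatives) break to the
  lowest vertex index; all randomness derives from explicit seeds, and
  equal seed + config reproduces trajectories bit-for-bit.
- Degenerate triangles and coincident bonded particles are hard errors.

## Limitations

- The supplementary three-parameter (standard-linear-solid) bond model is
  an extension point, not implemented; KV bonds are the shipped model.
- No cytoskeleton remodeling, bond rupture, or adhesion; walls are
  non-adhesive by construction.
- Desk-scale instruments are deterministic and coarse: absolute moduli in
  simulation units are not mapped to Pa/s without a full-resolution
  calibration of the unit block; qualitative orderings and closed-form
  recoveries are the validated content.
- The DPD fluid at scaled parameters shows measurable wall-slip
  variability across frozen-wall realizations and mild viscous heating at
  Mach ≳ 0.2; the Stokes-linearity check therefore uses the plain
  bounce-back slab.
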