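# Methods

This note documents the models implemented in `vasgrow`, their assumptions,
the numerical choices that were genuinely open, and what the synthetic
benchmarks do and do not demonstrate.

## Units

Lengths are cm, volumes ml (= cm³), flows ml/s, pressures mmHg, metabolic
demand ml/min/g, tissue density g/cm³, blood viscosity poise (dyn s/cm²).
The 1D solver assembles in CGS internally and converts at the interface
(1 mmHg = 1333.22 dyn/cm²).  Metabolic demand is converted min → s wherever
it enters a flow: Q = Σ m·ρ·V/60.

## Tissue domain

The perfused tissue Ω is a tetrahedral mesh; demand and density are
piecewise constant, sampled at element centroids (demand accounting is a
sum over tissue partitions, so element-wise constants are the natural
discretization).  The built-in sphere tessellation places a body-centred
cubic lattice of spacing `edge_length` inside the ball plus a golden-spiral
surface point set, and takes the Delaunay tetrahedralization (valid because
the ball is convex).  The point set, including the symmetry-breaking jitter
(relative magnitude 1e-4, fixed seed), is constructed mirror-symmetric
about z = 0 so the two-source polar benchmark is geometrically symmetric;
the triangulation near the midplane is not forced to be symmetric, which
leaves a residual O(1%) asymmetry between the hemispheres.  Mesh volume
converges to (4/3)πr³ from below (inscribed polyhedron); absolute tissue
volumes are therefore mesh-dependent, and all volume comparisons in the
tests are ratios or convergence statements, never absolute matches.

## Vascular forests

Trees are strictly binary; segments are straight lines with radius r,
length l and flow q.  Radii follow the power law q ∝ r^k anchored at
(r_min, q_min):

    r(q) = r_min (q/q_min)^(1/k),      default k = 3 (Murray's law).

Because flow is conserved at junctions, r₀^k = r₁^k + r₂^k holds exactly at
every bifurcation by construction.  The work rate of a network is

    L = Σ_p [ 8 μ l_p q_p² / (π r_p⁴) + β π r_p² l_p ],

viscous dissipation plus a metabolic cost proportional to blood volume.
The default β is the self-consistent choice that makes the single-segment
optimum radius of a q_min terminal equal r_min, i.e.
β = 16 μ q_min²/(π² r_min⁶); with it, r* = (16 μ q²/(π² β))^(1/6)
reproduces the anchor point.  μ defaults to 0.04 poise.

## Growth-based generation (GBO)

Growth state: a claim map (element → owning terminal) and the current
forest.  Each eligible source outlet starts at r_min supplying q_min and
claims elements nearest-first until the claimed demand reaches that flow.
Per iteration:

1. **Tissue growth.** Every unclaimed element within scaled distance
   ‖c ∘ (x − x_p)‖ < 1 of a live terminal p, and closer (in the scaled
   metric) to p than to any other terminal, is claimed by p.  Ties go to
   the lowest terminal id, which makes claiming order-independent.  The
   default c is isotropic, 1/h with h = 2·(mean element volume)^{1/3}, the
   same for all sources ("uniform growth rate").  If an iteration claims
   nothing while unclaimed tissue and incomplete sources remain, the reach
   is doubled for the next iteration and reset after the next successful
   claim; this removes the bootstrap stall of very coarse trees, where the
   demand of one growth ring rounds to zero new terminals and the front
   would otherwise freeze.  The escalation is a growth-rate schedule — the
   growth-rate vector is per-iteration by definition.
2. **Terminal budget.** Per source, the number of new terminals is the
   half-up-rounded increment of claimed flow over the flow already covered
   by its terminals: round((Q_claimed − n·q_min)/q_min).  This accumulates
   increments without losing rounding residues and reduces to the plain
   increment rule when every increment is large.  The budget is apportioned
   over the partitions that grew, proportional to their claimed-flow
   increment (largest-remainder method; deterministic tie-breaks).
3. **Placement & connection.** New terminal positions are centroids of
   newly claimed elements, chosen by farthest-point sampling inside each
   grown partition; the partition's new elements are then reassigned to
   their nearest new terminal.  Each new terminal connects to its source's
   tree at the attachment segment (candidates: segments within the search
   length l_min; nearest-segment fallback, logged, if none) and junction
   point minimizing the work-loss increase: golden-section search of the
   split point along the candidate segment followed by a shrinking
   pattern-search refinement of the junction position in 3D.  The loss
   delta of a candidate is local (the three affected segments) plus the
   rootward path term from the flow increase, with radii implied by the
   power law — radii are never free variables.
4. **Update.** Terminal flows are reset to the demand of their partitions,
   internal flows by rootward summation, radii by the power law.  The
   source radius grows as r_min (Q_source/q_min)^{1/k}; a source whose
   radius reaches its segmented radius is complete and its terminals stop
   claiming.  The loop ends when all sources are complete or the tissue is
   exhausted; no-growth with unreachable tissue stops with a warning.

**Parallel execution.** Within an iteration, candidate evaluation for all
new terminals is a pure function of the iteration-start snapshot and runs
on a thread pool; connections are applied at a barrier in canonical
terminal order (with deterministic re-resolution when an earlier connection
split the chosen segment).  The result is bit-identical for any worker
count — that invariance, not wall-clock scaling, is the contract.

There is no randomness anywhere in GBO.

The allometric exponent p (flow ∝ volume^p for initial volumes) is kept as
a configurable parameter with default 1, under which the linear demand
accounting and the allometric statement coincide; values ≠ 1 only affect
documentation of the initial claim, whose implementation inverts the
demand sum directly.

## CCO baseline

Classical single-source constrained constructive optimization sharing the
radius law and loss with GBO: terminal sites are drawn uniformly (seeded)
from unused element centroids, accepted if farther from the existing tree
than an adaptive criterion d = f·(V_domain/n)^{1/3} (f = 0.9, shrunk ×0.9
after 50 consecutive rejections), and connected via the same
loss-minimizing bifurcation search over the nearest 8 segments.  Each
terminal carries Q_domain/n_terminals.  Identical seeds yield identical
forests.  The two-source sphere comparison runs CCO once per hemisphere
(the baseline is single-source by construction) with half the terminal
count each and sums the volumes.

## 1D network blood flow

Vessel walls are rigid, so mass balance makes flow uniform along a segment
and the steady momentum balance reduces to a Poiseuille drop
Δp = (8 μ l/(π r⁴))·Q.  Junctions impose mass conservation and pressure
continuity.  Steady mode (the default for perfusion coupling) assembles
the sparse linear network system for either prescribed terminal flows plus
a root pressure datum, or prescribed inflow plus resistance/RCR terminal
boundary models.  The transient solver integrates the lumped per-segment
momentum equation (ρl/S)·dQ/dt + RQ = Δp together with the junction
constraints and Windkessel state equations using the generalized-α method
for first-order systems, parameterized by a single spectral radius ρ∞
(default 0.5): α_m = ½(3−ρ∞)/(1+ρ∞), α_f = 1/(1+ρ∞), γ = ½+α_m−α_f.  Each
step iterates until the relative flow change between passes is below 1e-6
(configurable); for this linear system one pass suffices.  With rigid
walls the advective momentum-flux difference (1+δ)Q²/S vanishes within a
segment and pressure continuity carries no Bernoulli recovery, so the
advective term does not enter the assembled system; δ (parabolic profile:
1/3) and the friction parameter N = 8πν remain in the parameter set.
Discontinuous inflow steps excite a geometrically decaying start-up
oscillation (the initial rate is consistent with the pre-step state);
smooth waveforms do not.

## Darcy perfusion

Single-compartment porous model of the capillary bed: v = −K∇p (gravity
term available, off by default), with distributed sources and sinks

    ∇·v = β_source (p_source − p) − β_sink (p − p_sink),    v·n = 0 on Γ.

K is taken directly as the printed "permeability coefficient" scalar
(default 1.07e-4 /mmHg/s, i.e. combined mobility, cm/s per mmHg/cm).  The
coupling coefficients (1/(mmHg·s): volumetric flow per tissue volume per
pressure difference) are initialized from averages,
β_source = m̄/(p̄_source − p̄) and β_sink = m̄/(p̄ − p̄_sink), with m̄ the mean
volumetric demand rate in 1/s.  The discretization is an equal-order
(P1/P1) stabilized mixed Galerkin method: the velocity equation is tested
directly, the mass equation is integrated by parts (making the zero-flux
boundary natural), and a consistent least-squares term on the Darcy-law
residual with τ = K/2 supplies the pressure-Laplacian stabilization of
equal-order pairs.  Summing the pressure rows gives the constant test
function, so Σ q_source = Σ q_sink holds to solver precision for any
coefficient fields.  The matrix depends only on mesh, K and the β fields;
source/sink pressures enter the right-hand side, so the coupling loop
factorizes once (SuperLU, plus one iterative-refinement sweep to push the
residual to ~1e-14).  A primal P1 discretization of the equivalent
pressure-Poisson problem is kept as an independent test oracle only.
At the physiological parameters the diffusion length √(K/β) ≈ 0.3 cm is
below the mesh size, so the pressure field is close to the local reaction
equilibrium — tissue flow is nearly uniform, dipping slightly far from the
sources where terminal pressures are lower.

## Explicit 1D–Darcy coupling

Fixed-point sweep: (a) 1D solve with current terminal flows → terminal
pressures; (b) each terminal's pressure becomes p_source on its tissue
partition (piecewise constant); (c) Darcy solve → per-element source
flows, summed per partition; (d) partition flows become the new 1D
terminal flows, under-relaxed (default factor 0.5).  Convergence requires
the max terminal-pressure change below 1e-6 mmHg and max relative flow
change below 1e-8 (defaults; the coupled system is linear so the fixed
point is initialization-independent to tolerance).  When a prescribed
total flow is given, β_sink is rescaled by a secant iteration on
log β_sink vs log Q, clamped to ±2% of its initial value; an unreachable
target pins the adjustment at the bound with a warning.  At convergence
the same numbers cross the interface in both directions, so total 1D
inflow equals total Darcy sink outflow by construction.

## The sphere benchmark

`vasgrow.fixtures.sphere_benchmark` builds the idealized study: ball of
radius 10 cm, two sources of segmented radius 0.4 cm at (0,0,±10), uniform
demand 1.0 ml/min/g at density 1.05 g/cm³ (radial profiles 3.0→0.3 and
0.1→1.5 available, renormalized to the same total flow).  Tree resolution
is set by the target terminal count n: q_min = Q_total/n, and r_min
follows from requiring the source-radius law to reach 0.4 cm when a source
supplies half the total flow.  The default mesh edge length targets ~2.5
elements per terminal (floored at ~1500 elements, capped at 2.2 cm) so
terminal positions — which are element centroids — stay resolvable; these
problem sizes keep a full 5000-terminal growth under a minute while
exhibiting the same structure as finer meshes.  Because μ, β, k, r_min and
q_min of the original experiments are not published, absolute tree volumes
are comparable only in magnitude; ratios (left/right symmetry, GBO vs CCO,
worker invariance) are the quantitative checks.

What the synthetic benchmark does **not** show: anatomical realism of
patient-specific geometries (irregular boundaries, heterogeneous demand,
many outlets of unequal radii), image-derived source radii, or transient
cardiac-cycle perfusion.  Those enter only through the general interfaces
(arbitrary tet meshes, per-element fields, per-source radii).

## Degenerate inputs and tie-breaks

Zero-demand tissue is rejected at initialization; zero-flow terminals get
r = r_min for bookkeeping and a vanishing-flow guard keeps loss
evaluations finite; junction placements that collapse onto a segment
endpoint fall back to an interior projection; equidistant claims go to the
lowest terminal id, then lowest element id; apportionment ties go to the
lowest terminal id.  All tie-breaks are deterministic by design.

## Known limitations

- Terminal sites are mesh-centroid-bound, so tree density follows mesh
  density (finer near the surface); source flows and territories are
  insensitive to this, terminal radii are not.
- Single-compartment Darcy: no scale separation between arterioles,
  capillaries and venules.
- Thread-based workers give determinism but no CPython speedup.
- The CCO baseline implements one standard volume/work-minimizing variant;
  it is a comparison point, not a reproduction of any specific historical
  code.
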