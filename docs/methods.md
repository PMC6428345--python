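# Methods

## The model class

`efmcost` studies growth-rate maximization in kinetic metabolic models with
constraints on enzyme concentrations. A model consists of three layers:

1. **Stoichiometry.** An irreversible-reaction network with stoichiometric
   matrix `N` (rows = metabolites, columns = reactions) and a designated
   objective reaction (typically biomass synthesis). Metabolites are
   partitioned into external ones, `x^E` — environment parameters that are
   never balanced — and internal ones, `x^I`, which must satisfy
   `N_I v = 0` at steady state. Together with irreversibility (`v >= 0`)
   this defines the flux cone. Reversible reactions are handled by splitting
   into forward/backward column pairs, after which the Elementary Flux Modes
   (EFMs) — the support-minimal steady-state flux distributions — coincide
   with the extreme rays of the cone.
2. **Kinetics.** Every reaction obeys `v_i = e_i * kcat_i * f_i(x)`:
   proportional to the enzyme concentration `e_i`, with a saturation
   function `f_i(x) in [0, 1]`. The catalog covers a `constant` kind
   (f = 1), multi-substrate Michaelis–Menten
   (`f = prod_s x_s / (Km_s + x_s)`), and Michaelis–Menten with one
   non-competitive product-inhibition factor (`* 1 / (1 + x_inh / Ki)`).
   A registry hook allows custom kinds; unregistered kinds are rejected at
   validation. Bounding `f` by 1 is a package convention: `kcat` is the
   maximal turnover.
3. **Enzyme pools.** K constraints `sum_j w_j^(k) e_j <= C^(k)` with
   nonnegative weights and positive capacities, modelling limited solvent
   capacities (cytosol, membrane, …) or synthesis capacity. Pool bounds are
   stored explicitly; all internal computations rescale the weights by the
   bounds so capacities become 1. This makes perturbation experiments
   (shrinking a pool) a pure change of `bounds`.

## Cost vectors and the inner linear program

Scaling each objective-carrying EFM to unit objective flux, the enzyme the
EFM needs is `e_j = V_j / (kcat_j f_j(x))`, and its **cost vector** collects
the pool fractions those enzymes occupy:

    d_k^i(x) = sum_j w_j^(k) V_j^i / (kcat_j f_j(x)).

Writing any steady-state flux as a nonnegative EFM combination with weights
`lambda`, the objective flux is `sum_i lambda_i` and every enzyme constraint
becomes linear in `lambda`. At fixed concentrations the problem is the LP

    max { sum(lambda) : lambda >= 0, D(x) lambda <= 1 },

whose optimum lies at a vertex of the feasible polytope. A vertex satisfies
at least M of the M + K constraints with equality, so at most K entries of
`lambda` are nonzero: **at most K non-equivalent EFMs carry flux at any
optimum** (EFMs with identical cost vectors — "equivalent" — can substitute
for one another and are counted once). The contrapositive is used as a
diagnostic: observing n non-equivalent active EFMs implies at least n
active constraints.

`solve_inner_lp` solves the LP with HiGHS, resolves ties deterministically
by sequential lexicographic maximization of `lambda_1, lambda_2, ...` over
the optimal face, and snaps the winner onto its exact active basis
(re-solving `D[T, S] lambda_S = 1` over the tight rows T and support S). If
the snap cannot be certified, the vertex is recovered by exhaustive basis
enumeration — which is also exposed separately (`enumerate_lp_vertices`) as
an independent oracle for tests. During the outer search only the LP
*value* is needed, and closed forms are used for K = 1 (best single cost)
and K = 2 (best of pure strategies and opposite-side two-EFM mixtures).

With K = 2 the geometry is plotted on the unit square: a pure EFM's cost
per unit flux is `max(d_1, d_2)` (projection of its cost vector onto the
diagonal), a mixture of an above-diagonal and a below-diagonal EFM is ranked
by the intersection of the diagonal with the segment between the two cost
vectors, and the strategy with the dot closest to the origin wins, with
objective value 1/dot. Vectors exactly on the diagonal are classified as
pure strategies that can exhaust both pools. `rank_on_diagonal_2d` and
`best_strategy_2d` implement this construction and are cross-validated
against the LP.

## The outer problem

Internal concentrations enter only through the saturation functions, so the
outer problem is `max_x_I` of the inner LP value. This map is
piecewise-smooth and, with two or more constraints, generally non-convex;
no closed-form solution exists. The package uses multistart Nelder–Mead in
log10 concentration space:

- decision variables: internal metabolites referenced by at least one
  saturation function (others cannot affect the optimum and are reported at
  concentration 1);
- bounds `[1e-3, 1e3]` model units (log10 in [-3, 3]); default 16 starts —
  the origin (all concentrations 1) plus seeded uniform draws; sweeps add
  the previous grid point's optimum as a warm start;
- termination on simplex size only (`xatol = 1e-7` in log10 units, function
  tolerance effectively infinite). Nelder–Mead steps depend on objective
  *comparisons* only, so this makes the search trajectory invariant under
  uniform positive rescaling of the objective. A uniform pool shrink by
  `gamma` rescales the LP value by exactly `gamma` at every x, hence the
  search returns the same optimal concentrations and the optimum scales
  exactly — the proportional-decrease prediction holds to rounding error.

Multistart is a heuristic: a run that misses the global optimum is possible
and is reported as found (per-start logs are kept in the result
diagnostics), not silently corrected. Active sets are read off at relative
tolerance 1e-6 for both `lambda` and pool usage; the extremum-principle
check collapses active EFMs whose cost-matrix columns at the optimum agree
within 1e-8 (relative) before comparing against the active-constraint
count.

EFMs that carry no objective flux and no cost would make the decomposition
degenerate; the framework assumes they do not exist. A zero cost *column*
(cost-free objective EFM) is a hard error; a costless non-objective EFM
triggers a warning at optimization time rather than a load-time rejection,
since it does not change the optimal value.

## Independent oracles

Two routes independent of the cost-vector machinery validate the results:

- **Brute-force EFM enumeration** tests every support subset: a subset is
  an EFM support iff the kernel of the corresponding stoichiometric
  submatrix is one-dimensional with a strictly positive vector. This is
  exponential (guarded at r <= 12) and is compared against the
  double-description enumeration on generated networks.
- **Dynamic brute force.** `steady_state_for_enzymes` integrates
  `dx_I/dt = N_I v(e, x)` with LSODA in geometrically growing chunks
  (capped at 2e4 time units per chunk, evaluation budget 100k) until
  `||dx/dt||_inf < tol (1 + ||x||_inf)` (default tol 1e-9, time budget 1e6),
  a concentration exceeds 1e9, or a trajectory is flagged as escaping
  (> 1e5 and still increasing). `brute_force_optimize` samples enzyme
  allocations on the pool polytope boundary (one-hot, pairwise, triple and
  Dirichlet-random directions, scaled outward — uniform scaling of `e`
  scales all fluxes at an unchanged steady state, so optima lie on the
  boundary). Enzymes outside every pool are costless but still shape the
  dynamics — a costless uptake step must match downstream capacity while a
  costless drain is best switched off — so each is searched on a log10
  level (grid −4 / 0 / 3, refined continuously). Converged steady states
  are scored by their objective flux (looser scoring tolerance 1e-7, time
  budget 2e4) and the best allocation is refined by Nelder–Mead with ODE
  warm starts. It is a lower-bound oracle with no
  optimality guarantee; agreement within a few percent of — and never
  above — the LP-based optimum is the consistency check.

## Packaged case studies

Both case-study models are coarse-grained reconstructions whose kinetic
constants are package constants (stored in the fixture JSON files and in
`casestudies.py`); all claims asserted about them are qualitative — switch
existence and direction, constraint activity, near-constant enzyme
profiles — not numeric curve fits.

**Overflow metabolism** (`build_overflow_model`): glucose →(membrane
transporter, kcat 10, Km 1)→ intermediate, consumed either by respiration
(1 intermediate → 1 precursor, kcat 1) or by overflow (2 intermediate →
1 precursor + acetate, kcat 3), with the precursor feeding the biomass
objective (kcat 10, Km 1; pool-free enzyme). Pools: cytosol {respiration,
overflow} with bound 1, membrane {transporter} with bound 0.3. At low
glucose the transporter is unsaturated, every cost vector is
membrane-heavy (above diagonal) and pure respiration under a sole membrane
constraint wins; as glucose rises the membrane cost shrinks until the
respiration vector drops below the diagonal, a respiration+overflow mixture
exhausts both pools, and respiratory flux declines — the
respirofermentative switch. With saturated catabolic enzymes the both-tight
vertex gives `lambda_ovf = (3/5)(3 f_T - 1)` (f_T = transporter
saturation), so the switch sits near glucose = Km/2; the default sweep grid
(15 log-spaced points, 0.05–20) brackets it.

**L. lactis switch** (`build_lactis_model`): glucose is fermented to ATP by
a mixed-acid pathway (yield 2 ATP, kcat 2, Km 0.04, strong ATP product
inhibition Ki 0.15) or a homolactic pathway (yield 1 ATP, kcat 8, Km 1,
weak inhibition Ki 10); ATP drives the biomass objective (kcat 14, Km 0.5).
Pools: total enzyme (all three enzymes, bound 1) and glucose-uptake
machinery (weights 0.4 / 2.8 on mixed-acid / homolactic, bound 0.4). The
uptake weights encode how much transport machinery each pathway engages per
enzyme complex: the homolactic branch ferments twice the glucose per unit
objective flux. Along the default sweep grid (10 log-spaced points,
1.25–50 — the crossover window) the optimal flux fraction shifts from
mixed-acid to homolactic while each optimal enzyme concentration changes by
less than 20%: the reallocation is carried by enzyme saturation (homolactic
saturating with glucose, mixed-acid increasingly ATP-inhibited), not by
expression changes.

**Perturbations.** `perturb_pool_bounds` multiplies pool capacities
elementwise (emulating expression of non-functional protein);
`perturb_catalytic_rates` multiplies per-reaction kcats (emulating enzyme
inhibition, which lengthens cost vectors). Two predictions are exercised:
uniform shrink of all pools rescales flux and growth proportionally
(exactly, by LP linearity), and shrinking only the pool predominantly used
by one EFM of a mixture (operationalized: that EFM's usage share of the
pool exceeds 2/3 at the unperturbed optimum) first raises and then lowers
the other EFM's flux.

**Proportionality diagnostic.** A single active EFM fixes all flux ratios,
so uptake rates are proportional to growth rate; departure from
proportionality marks the activation of a second EFM.
`fit_proportional_breakpoint` compares a through-origin line against
two-segment fits (proportional up to a candidate breakpoint, then a
free-slope segment continuous there), with candidates at interior data
points and consecutive midpoints, and reports a breakpoint only when the
two-segment fit improves the squared error by more than 5% (and the
through-origin fit is above rounding noise). This suits the small-n
chemostat tables it is meant for.

## Synthetic instances

`generate_instance` builds seeded random models for property tests: a
guaranteed backbone (uptake → internal chain → objective) plus sparse side
reactions with coefficients in {−2, −1, 1, 2}, kcat and Km log-uniform in
[0.1, 10], and pools joined with probability 0.7 (weights uniform in
[0.2, 2], bounds in [0.5, 2]). Saturation kinds are drawn roughly 70%
Michaelis–Menten, 20% constant, 10% with product inhibition, with one
amendment: a reaction consuming internal metabolites is never `constant`,
because concentration-independent consumption leaves the internal ODE
without feedback and the dynamic oracle's steady state becomes generically
unreachable. Candidates are rejection-sampled (bounded attempts, loud
failure) until the instance has an objective EFM, non-empty pools, and no
cost-free EFM — the theory's standing assumptions. The generator emulates
the assumed model class, not real metabolic topologies; passing property
tests demonstrates correctness of the mathematics on that class, not
biological realism of any particular network.

## Problem sizes and numerical choices

Enumeration is floating-point throughout (rank decisions at 1e-8, support
membership at 1e-10 after normalization) — adequate for the desk-scale
networks (r ≤ ~25) this package targets; genome-scale enumeration is out
of scope. Acceptance-style checks run at the sizes the properties demand:
hundreds of seeded instances for the extremum-principle and
single-constraint sweeps, 500 random cost matrices for the vertex property,
and ~20 instances for the dynamic-oracle comparison, chosen so the whole
suite completes in minutes on one CPU. EFM-decomposition weights are
computed by nonnegative least squares and are not unique when more EFMs
than reactions exist; the reported residual certifies membership of the
flux cone.

## Known limitations

- Outer-search optimality is heuristic (multistart local search); the
  extremum principle itself holds at any inner-LP vertex, but sweep curves
  could in principle report a local optimum.
- The saturation catalog is deliberately small; thermodynamic rate laws and
  multi-effector allostery are not modelled.
- The case-study models are qualitative reconstructions; their parameters
  are not fitted to published chemostat data.
- No SBML/SBtab import; the JSON model document is the only exchange
  format.
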