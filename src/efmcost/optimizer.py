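"""Growth-rate maximization under enzyme-pool constraints.

The full problem — maximize the objective flux over internal metabolite
concentrations and enzyme concentrations subject to steady state and K
weighted enzyme pools — separates into

* an **inner linear program** over EFM usage weights at fixed concentrations:
  ``max { sum(lambda) : lambda >= 0, D(x) @ lambda <= 1 }``, whose optimum is
  attained at a vertex, so at most K non-equivalent EFMs carry flux
  (the extremum principle); and
* an **outer search** over internal metabolite concentrations, performed by
  multistart Nelder-Mead in log-concentration space (the map
  ``x -> inner optimum`` is piecewise-smooth and may be non-convex with two
  or more constraints, so a derivative-free local method with restarts is
  used and global optimality is not certified).

An independent brute-force oracle samples enzyme allocations on the
constraint polytope and evaluates their ODE steady states; it provides a
lower bound on the achievable objective for cross-checking.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares, linprog, minimize

from .costspace import CostMatrix, compute_cost_matrix
from .efm import EFM, enumerate_efms
from .errors import InfeasibleStateError, NumericalError, ValidationError
from .kinetics import (
    KineticModel,
    MetaboliteState,
    constraint_usage,
    enzyme_demand,
)

logger = logging.getLogger(__name__)

__all__ = [
    "InnerLPResult",
    "OptimizationResult",
    "OptimizeOptions",
    "solve_inner_lp",
    "enumerate_lp_vertices",
    "optimize_growth",
    "steady_state_for_enzymes",
    "brute_force_optimize",
    "analyze_active_sets",
    "verify_extremum_principle",
]

LP_TOL = 1e-9
#: relative threshold below which a whole cost column counts as cost-free
COSTFREE_TOL = 1e-12


@dataclass(frozen=True)
class InnerLPResult:
    """A vertex optimum of ``max { sum(lambda) : lambda >= 0, D lambda <= 1 }``."""

    lambdas: np.ndarray
    objective: float
    basis_support: frozenset[int]
    lp_matrix: tuple[np.ndarray, np.ndarray]  # (A, z) of the stacked LP form

    def __post_init__(self) -> None:
        object.__setattr__(self, "lambdas", np.asarray(self.lambdas, dtype=float))


@dataclass
class OptimizeOptions:
    """Tunables of the outer concentration search.

    ``n_starts`` seeded Nelder-Mead runs in log10 concentration space within
    ``log10_bounds``; termination is on simplex size (``xatol``) only, which
    makes the search trajectory invariant under uniform rescaling of the
    objective (pool-shrink experiments then rescale exactly).
    """

    n_starts: int = 16
    seed: int = 0
    maxiter: int = 200
    xatol: float = 1e-7
    log10_bounds: tuple[float, float] = (-3.0, 3.0)
    extra_starts: tuple = ()  # sequence of {met: conc} warm starts
    efms: Sequence[EFM] | None = None  # precomputed objective EFMs
    tol_lambda: float = 1e-6
    tol_constraint: float = 1e-6


@dataclass(frozen=True)
class OptimizationResult:
    """Optimal state, EFM weights, enzyme profile and active sets."""

    x_internal: MetaboliteState
    inner: InnerLPResult | None
    enzyme_profile: np.ndarray
    active_efms: tuple[str, ...]
    active_constraints: tuple[str, ...]
    objective: float
    efms: tuple[EFM, ...] = ()
    cost_matrix: CostMatrix | None = None
    model: KineticModel | None = None
    diagnostics: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# inner LP
# ---------------------------------------------------------------------------


def _cost_array(D: CostMatrix | np.ndarray) -> np.ndarray:
    arr = D.D if isinstance(D, CostMatrix) else np.atleast_2d(np.asarray(D, float))
    if np.any(arr < 0):
        raise ValidationError("cost matrix entries must be nonnegative")
    return arr


def _check_costfree(arr: np.ndarray) -> None:
    scale = max(1.0, float(np.max(arr, initial=0.0)))
    free = [int(i) for i in range(arr.shape[1]) if np.all(arr[:, i] <= COSTFREE_TOL * scale)]
    if free:
        raise ValidationError(
            f"cost-free EFM column(s) {free}: the objective is unbounded. The "
            "framework assumes every EFM uses some limited enzyme pool."
        )


def _inner_value_fast(arr: np.ndarray) -> float:
    """Objective of the inner LP, closed-form for K = 1 and K = 2."""
    K, M = arr.shape
    if K == 1:
        return float(1.0 / np.min(arr[0]))
    if K == 2:
        best = float(1.0 / np.min(np.max(arr, axis=0)))
        g = arr[0] - arr[1]
        above = np.nonzero(g < 0)[0]
        below = np.nonzero(g > 0)[0]
        for i in above:
            for j in below:
                t = g[i] / (g[i] - g[j])
                dot = arr[0, i] + t * (arr[0, j] - arr[0, i])
                if dot > 0:
                    best = max(best, 1.0 / dot)
        return best
    res = linprog(
        -np.ones(M), A_ub=arr, b_ub=np.ones(K), bounds=(0, None), method="highs"
    )
    if not res.success:
        raise NumericalError(f"inner LP failed: {res.message}")
    return float(-res.fun)


def inner_objective(D: CostMatrix | np.ndarray) -> float:
    """Optimal value of the inner LP (no vertex bookkeeping; fast path)."""
    arr = _cost_array(D)
    _check_costfree(arr)
    return _inner_value_fast(arr)


def _n_candidate_bases(K: int, M: int) -> int:
    from math import comb

    return sum(comb(M, s) * comb(K, s) for s in range(1, min(K, M) + 1))


def _polish_vertex(arr: np.ndarray, lam: np.ndarray, v_star: float) -> np.ndarray | None:
    """Snap a near-vertex LP solution onto its exact basis.

    Thresholds the support, identifies the tight pool rows, and re-solves the
    active square/overdetermined system ``D[T, S] lam_S = 1`` exactly. Returns
    None when the candidate does not verify as an optimal vertex.
    """
    K, M = arr.shape
    scale = max(1.0, v_star)
    S = [int(i) for i in np.nonzero(lam > 1e-7 * scale)[0]]
    if len(S) > K or not S:
        return None
    usage = arr @ lam
    T = [k for k in range(K) if usage[k] >= 1.0 - 1e-6]
    if len(T) < len(S):
        return None
    sub = arr[np.ix_(T, S)]
    sol, *_ = np.linalg.lstsq(sub, np.ones(len(T)), rcond=None)
    if np.any(sol < -LP_TOL):
        return None
    out = np.zeros(M)
    out[S] = np.clip(sol, 0.0, None)
    if np.any(arr @ out > 1.0 + 1e-9):
        return None
    if abs(float(np.sum(out)) - v_star) > 1e-9 * scale:
        return None
    return out


def solve_inner_lp(D: CostMatrix | np.ndarray) -> InnerLPResult:
    """Vertex optimum of ``max sum(lambda)`` s.t. ``lambda >= 0, D lambda <= 1``.

    The polytope's vertices are basic feasible solutions, so the optimum lies
    at a vertex and its support has at most K elements. The LP is solved with
    HiGHS; ties between optimal vertices are resolved deterministically by
    sequential lexicographic maximization of ``lambda_1, lambda_2, ...`` over
    the optimal face (this prefers the lexicographically smallest support),
    and the winner is snapped onto its exact active basis. If the snap fails
    numerically, the vertex is recovered by exhaustive basis enumeration.
    """
    arr = _cost_array(D)
    _check_costfree(arr)
    K, M = arr.shape
    b = np.ones(K)
    A = np.vstack([-np.eye(M), arr])
    z = np.concatenate([np.zeros(M), b])
    res = linprog(-np.ones(M), A_ub=arr, b_ub=b, bounds=(0, None), method="highs")
    if not res.success:
        raise NumericalError(f"inner LP failed: {res.message}")
    v_star = float(-res.fun)
    lam = np.asarray(res.x, dtype=float)

    fixed: list[tuple[int, float]] = []
    for j in range(M):
        cj = np.zeros(M)
        cj[j] = -1.0
        A_eq = np.vstack(
            [np.ones(M)] + [np.eye(M)[i] for i, _ in fixed]
        )
        b_eq = np.array([v_star] + [val for _, val in fixed])
        ref = linprog(
            cj, A_ub=arr, b_ub=b, A_eq=A_eq, b_eq=b_eq, bounds=(0, None),
            method="highs",
        )
        if not ref.success:
            break
        fixed.append((j, float(ref.x[j])))
        lam = np.asarray(ref.x, dtype=float)

    polished = _polish_vertex(arr, lam, v_star)
    if polished is None and _n_candidate_bases(K, M) <= 200000:
        _, optimal = enumerate_lp_vertices(arr)
        if optimal:
            polished = min(
                optimal,
                key=lambda v: (
                    tuple(int(i) for i in np.nonzero(v > LP_TOL)[0]),
                ),
            )
    if polished is None:
        raise NumericalError("inner LP solution could not be certified as a vertex")
    lam = np.where(polished > LP_TOL * max(1.0, v_star), polished, 0.0)
    support = frozenset(int(i) for i in np.nonzero(lam)[0])
    return InnerLPResult(
        lambdas=lam,
        objective=float(np.sum(lam)),
        basis_support=support,
        lp_matrix=(A, z),
    )


def enumerate_lp_vertices(D: CostMatrix | np.ndarray) -> tuple[float, list[np.ndarray]]:
    """Exhaustive vertex enumeration of the inner-LP polytope (oracle).

    Enumerates every candidate basis (support S, tight pool set T with
    |T| = |S|), solves the square system, keeps feasible solutions, and
    returns the best objective together with all optimal vertices. Intended
    for small instances (M <= ~10).
    """
    arr = _cost_array(D)
    K, M = arr.shape
    best = 0.0
    vertices: list[np.ndarray] = [np.zeros(M)]
    optimal: list[np.ndarray] = []
    for s in range(1, min(K, M) + 1):
        for S in itertools.combinations(range(M), s):
            for T in itertools.combinations(range(K), s):
                sub = arr[np.ix_(T, S)]
                if abs(np.linalg.det(sub)) < 1e-12:
                    continue
                lam_s = np.linalg.solve(sub, np.ones(s))
                if np.any(lam_s < -LP_TOL):
                    continue
                lam = np.zeros(M)
                lam[list(S)] = np.clip(lam_s, 0.0, None)
                if np.any(arr @ lam > 1.0 + 1e-9):
                    continue
                vertices.append(lam)
                best = max(best, float(np.sum(lam)))
    for lam in vertices:
        if np.sum(lam) >= best - 1e-9 * (1.0 + best):
            optimal.append(lam)
    return best, optimal


# ---------------------------------------------------------------------------
# outer problem
# ---------------------------------------------------------------------------


def _objective_efms(model: KineticModel, efms: Sequence[EFM] | None) -> list[EFM]:
    all_efms = list(efms) if efms is not None else enumerate_efms(model.network)
    obj = [e for e in all_efms if e.has_objective]
    if not obj:
        raise ValidationError("model has no EFM carrying objective flux")
    # warn on the pathological cost-free, objective-free EFM the theory excludes
    Ws = model.constraints.scaled_weights
    kcat = model.kcat_vector
    for e in all_efms:
        if e.has_objective:
            continue
        # cost lower bound with fully saturated enzymes (f = 1)
        if float(np.max(Ws @ (np.abs(e.values) / kcat))) <= COSTFREE_TOL:
            warnings.warn(
                f"EFM with support {sorted(e.support)} produces no objective "
                "flux and has no enzyme cost; the optimum is degenerate",
                stacklevel=3,
            )
    return obj


def _safe_cost_matrix(
    efms: Sequence[EFM], x: MetaboliteState, model: KineticModel
) -> tuple[CostMatrix | None, list[int]]:
    """Cost matrix over the EFMs feasible at ``x`` plus their indices."""
    cols, keep = [], []
    Ws = model.constraints.scaled_weights
    for i, e in enumerate(efms):
        try:
            cols.append(Ws @ enzyme_demand(e, x, model))
            keep.append(i)
        except InfeasibleStateError:
            continue
    if not keep:
        return None, []
    cm = CostMatrix(
        D=np.column_stack(cols),
        efm_ids=tuple(f"efm_{'+'.join(str(j) for j in sorted(efms[i].support))}" for i in keep),
        state=x,
        pool_ids=model.constraints.pool_ids,
    )
    return cm, keep


def optimize_growth(
    model: KineticModel,
    x_external: Mapping[str, float] | MetaboliteState,
    options: OptimizeOptions | None = None,
) -> OptimizationResult:
    """Maximize objective flux over internal metabolite concentrations.

    For each candidate internal state the cost matrix of the objective EFMs
    is assembled and the inner LP solved; a multistart Nelder-Mead search in
    log10 concentration space picks the best internal state. Internal
    metabolites not referenced by any saturation function do not affect the
    optimum and are reported at concentration 1.
    """
    opts = options or OptimizeOptions()
    xe = dict(
        x_external.concentrations
        if isinstance(x_external, MetaboliteState)
        else x_external
    )
    missing = [m for m in model.network.external_metabolite_ids if m not in xe]
    if missing:
        raise ValidationError(f"external concentrations missing: {missing}")
    efms = _objective_efms(model, opts.efms)
    variables = model.kinetic_internal_metabolites
    base_internal = {m: 1.0 for m in model.network.internal_metabolite_ids}

    def build_state(logs: np.ndarray) -> MetaboliteState:
        conc = dict(base_internal)
        conc.update({m: float(10.0 ** v) for m, v in zip(variables, logs)})
        conc.update(xe)
        return MetaboliteState(conc)

    def value(logs: np.ndarray) -> float:
        cm, keep = _safe_cost_matrix(efms, build_state(logs), model)
        if cm is None:
            return 0.0
        try:
            return inner_objective(cm)
        except (ValidationError, NumericalError):
            return 0.0

    lo, hi = opts.log10_bounds
    start_log: list[dict] = []
    if len(variables) == 0:
        best_logs = np.zeros(0)
        best_val = value(best_logs)
    else:
        rng = np.random.default_rng(opts.seed)
        starts = [np.zeros(len(variables))]
        starts += [rng.uniform(lo, hi, len(variables)) for _ in range(max(0, opts.n_starts - 1))]
        for extra in opts.extra_starts:
            starts.append(
                np.array([np.log10(max(extra[m], 10.0 ** lo)) for m in variables])
            )
        best_val, best_logs = -np.inf, starts[0]
        bounds = [(lo, hi)] * len(variables)
        for s0 in starts:
            res = minimize(
                lambda g: -value(g),
                np.clip(s0, lo, hi),
                method="Nelder-Mead",
                bounds=bounds,
                options={
                    "maxiter": opts.maxiter * max(1, len(variables)),
                    "xatol": opts.xatol,
                    "fatol": 1e30,  # terminate on simplex size only (scale-free)
                },
            )
            start_log.append(
                {"x0": [float(v) for v in s0], "objective": float(-res.fun),
                 "iterations": int(res.nit)}
            )
            if -res.fun > best_val:
                best_val, best_logs = float(-res.fun), np.asarray(res.x)
        if not np.isfinite(best_val):
            raise NumericalError("all outer-search starts failed")

    x_star = build_state(best_logs)
    cm, keep = _safe_cost_matrix(efms, x_star, model)
    if cm is None:
        raise NumericalError("no EFM is feasible at the optimal state")
    inner = solve_inner_lp(cm)
    kept_efms = [efms[i] for i in keep]
    e_profile = np.zeros(model.network.n_reactions)
    for lam, efm in zip(inner.lambdas, kept_efms):
        if lam > 0:
            e_profile += lam * enzyme_demand(efm, x_star, model)
    usage = constraint_usage(e_profile, model.constraints)
    rel_usage = usage / model.constraints.bounds
    active_constraints = tuple(
        pid
        for k, pid in enumerate(model.constraints.pool_ids)
        if rel_usage[k] >= 1.0 - opts.tol_constraint
    )
    lam_max = float(np.max(inner.lambdas, initial=0.0))
    active_efms = tuple(
        cm.efm_ids[i]
        for i in range(len(kept_efms))
        if inner.lambdas[i] > opts.tol_lambda * lam_max
    )
    x_internal = MetaboliteState(
        {
            m: x_star[m]
            for m in model.network.internal_metabolite_ids
        }
    )
    return OptimizationResult(
        x_internal=x_internal,
        inner=inner,
        enzyme_profile=e_profile,
        active_efms=active_efms,
        active_constraints=active_constraints,
        objective=inner.objective,
        efms=tuple(kept_efms),
        cost_matrix=cm,
        model=model,
        diagnostics={"starts": start_log, "usage": rel_usage.tolist()},
    )


# ---------------------------------------------------------------------------
# ODE oracle
# ---------------------------------------------------------------------------


def steady_state_for_enzymes(
    model: KineticModel,
    e: np.ndarray,
    x_external: Mapping[str, float] | MetaboliteState,
    x0: Mapping[str, float] | None = None,
    t_budget: float = 1e6,
    tol: float = 1e-9,
    divergence_cap: float = 1e9,
) -> tuple[MetaboliteState, str]:
    """Integrate ``dx_I/dt = N_I v(e, x)`` towards steady state.

    Returns the final state and a flag: ``"converged"`` when
    ``||dx/dt||_inf < tol * (1 + ||x||_inf)``, ``"diverged"`` when any
    internal concentration exceeds ``divergence_cap``, else
    ``"not_converged"`` after the time budget.
    """
    e = np.asarray(e, dtype=float)
    if np.any(e < 0):
        raise ValidationError("enzyme concentrations must be nonnegative")
    xe = dict(
        x_external.concentrations
        if isinstance(x_external, MetaboliteState)
        else x_external
    )
    internal = model.network.internal_metabolite_ids
    NI = model.network.internal_stoichiometry
    kcat = model.kcat_vector
    sat = [model.kinetics[r].saturation for r in model.network.reaction_ids]

    nfev = [0]
    nfev_budget = 100_000

    class _EvalBudgetExceeded(Exception):
        pass

    def fluxes(xi: np.ndarray) -> np.ndarray:
        conc = dict(xe)
        conc.update({m: max(float(v), 0.0) for m, v in zip(internal, xi)})
        f = np.array([s.evaluate(conc) for s in sat])
        return e * kcat * f

    def rhs(_t: float, xi: np.ndarray) -> np.ndarray:
        nfev[0] += 1
        if nfev[0] > nfev_budget:
            raise _EvalBudgetExceeded
        return NI @ fluxes(xi)

    xi = np.array([float((x0 or {}).get(m, 1.0)) for m in internal])
    if xi.size == 0:
        return MetaboliteState(xe), "converged"
    t_done = 0.0
    span = 1.0
    flag = "not_converged"
    while t_done < t_budget:
        span = min(span, t_budget - t_done)
        try:
            sol = solve_ivp(
                rhs, (0.0, span), xi, method="LSODA", rtol=1e-8, atol=1e-11
            )
        except _EvalBudgetExceeded:
            logger.debug("steady-state integration hit the evaluation budget")
            break
        if not sol.success:
            flag = "not_converged"
            break
        xi = np.clip(sol.y[:, -1], 0.0, None)
        t_done += span
        span = min(span * 10.0, 2e4)  # bounded chunks keep the solver honest
        rate = NI @ fluxes(xi)
        if float(np.max(xi)) > divergence_cap:
            flag = "diverged"
            break
        # escaping trajectory: very large concentration still increasing
        if np.any((xi > 1e5) & (rate > 0)):
            flag = "diverged"
            break
        if float(np.max(np.abs(rate))) < tol * (1.0 + float(np.max(xi))):
            flag = "converged"
            break
    state = MetaboliteState({**xe, **dict(zip(internal, (float(v) for v in xi)))})
    return state, flag


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------


def _compile_saturations(model: KineticModel, xe: Mapping[str, float]):
    """Build a fast evaluator x_internal -> f-vector for the builtin
    saturation kinds, folding external concentrations into constants.
    Returns None when a custom kind is present (callers fall back to the
    generic per-reaction evaluation)."""
    internal = {m: i for i, m in enumerate(model.network.internal_metabolite_ids)}
    plans = []
    for rid in model.network.reaction_ids:
        s = model.kinetics[rid].saturation
        if s.kind == "constant":
            plans.append((1.0, (), (), None, None))
            continue
        if s.kind not in ("michaelis_menten", "mm_product_inhibition"):
            return None
        const = 1.0
        idx: list[int] = []
        km: list[float] = []
        for sub in s.substrate_ids:
            if sub in internal:
                idx.append(internal[sub])
                km.append(s.Km[sub])
            else:
                x = float(xe[sub])
                const *= x / (s.Km[sub] + x)
        inh_idx = None
        ki = None
        if s.kind == "mm_product_inhibition":
            if s.inhibitor_id in internal:
                inh_idx, ki = internal[s.inhibitor_id], float(s.Ki)
            else:
                const *= 1.0 / (1.0 + float(xe[s.inhibitor_id]) / float(s.Ki))
        plans.append((const, tuple(idx), tuple(km), inh_idx, ki))

    def evaluate(x_int: np.ndarray) -> np.ndarray:
        f = np.empty(len(plans))
        for j, (const, idx, km, inh_idx, ki) in enumerate(plans):
            val = const
            for i, k in zip(idx, km):
                xi = x_int[i]
                val *= xi / (k + xi)
            if inh_idx is not None:
                val *= 1.0 / (1.0 + x_int[inh_idx] / ki)
            f[j] = val
        return f

    return evaluate


def _best_root_steady_state(
    model: KineticModel,
    e: np.ndarray,
    xe: dict,
    y0_list: list[np.ndarray],
    log_bounds: tuple[float, float] = (np.log(1e-3), np.log(1e3)),
) -> tuple[MetaboliteState | None, float]:
    """Steady states as roots of N_I v(e, x) = 0 in log-concentration space.

    Damped Newton (least-squares fallback) from several starts; among
    accepted roots (residual at rounding level relative to the flux scale)
    the one with the largest objective flux is returned together with that
    flux. The concentration domain matches the box the outer concentration
    search uses, so oracle and optimizer compare like with like. Faster than
    time integration, and also reaches dynamically unstable steady states.
    """
    internal = model.network.internal_metabolite_ids
    NI = model.network.internal_stoichiometry
    kcat = model.kcat_vector
    j_obj = model.network.objective_index
    fast_sat = _compile_saturations(model, xe)

    if fast_sat is not None:
        ekcat = e * kcat

        def fluxes(y: np.ndarray) -> np.ndarray:
            return ekcat * fast_sat(np.exp(y))

    else:  # custom saturation kinds: generic (slower) path
        sat = [model.kinetics[r].saturation for r in model.network.reaction_ids]

        def fluxes(y: np.ndarray) -> np.ndarray:
            conc = dict(xe)
            conc.update({m: float(v) for m, v in zip(internal, np.exp(y))})
            f = np.array([s.evaluate(conc) for s in sat])
            return e * kcat * f

    if len(internal) == 0:
        v = fluxes(np.zeros(0))
        return MetaboliteState(xe), float(v[j_obj])

    def resid(y: np.ndarray) -> np.ndarray:
        return NI @ fluxes(y)

    lo, hi = log_bounds
    ni_dim = len(internal)

    def _accepted(y: np.ndarray) -> bool:
        v = fluxes(y)
        scale = 1.0 + float(np.max(np.abs(v), initial=0.0))
        return float(np.max(np.abs(NI @ v), initial=0.0)) <= 1e-7 * scale

    def _newton(y0: np.ndarray) -> np.ndarray | None:
        y = np.clip(y0, lo, hi)
        r0 = resid(y)
        for _ in range(40):
            norm0 = float(np.max(np.abs(r0), initial=0.0))
            scale = 1.0 + float(np.max(np.abs(fluxes(y)), initial=0.0))
            if norm0 <= 1e-9 * scale:
                return y
            J = np.empty((r0.size, ni_dim))
            h = 1e-7
            for i in range(ni_dim):
                yp = y.copy()
                yp[i] += h
                J[:, i] = (resid(yp) - r0) / h
            try:
                step, *_ = np.linalg.lstsq(J, -r0, rcond=None)
            except np.linalg.LinAlgError:
                return None
            alpha = 1.0
            for _bt in range(12):
                y_new = np.clip(y + alpha * step, lo, hi)
                r_new = resid(y_new)
                if float(np.max(np.abs(r_new), initial=0.0)) < norm0 * (1 - 1e-4 * alpha):
                    break
                alpha *= 0.5
            else:
                return None
            y, r0 = y_new, r_new
        return y if _accepted(y) else None

    best_state, best_obj = None, 0.0
    ls_used = False
    for y0 in y0_list:
        y = _newton(np.asarray(y0, dtype=float))
        if y is None and best_state is None and y0 is y0_list[-1] and not ls_used:
            # last resort once per call: bounded trust-region least squares
            ls_used = True
            try:
                y = least_squares(
                    resid,
                    np.clip(y0, lo + 1e-9, hi - 1e-9),
                    bounds=(lo, hi),
                    xtol=3e-12,
                    ftol=3e-12,
                    gtol=3e-12,
                    max_nfev=120,
                ).x
            except Exception:  # singular Jacobians on degenerate allocations
                y = None
        if y is None or not _accepted(y):
            continue
        v = fluxes(y)
        if v[j_obj] > best_obj:
            conc = dict(xe)
            conc.update({m: float(val) for m, val in zip(internal, np.exp(y))})
            best_state, best_obj = MetaboliteState(conc), float(v[j_obj])
    return best_state, best_obj


def _scale_to_polytope(u: np.ndarray, model: KineticModel) -> np.ndarray:
    """Scale a nonnegative direction onto the boundary of {W e <= b}."""
    W, b = model.constraints.weights, model.constraints.bounds
    usage = W @ u
    with np.errstate(divide="ignore"):
        t = float(np.min(np.where(usage > 0, b / np.where(usage > 0, usage, 1.0), np.inf)))
    if not np.isfinite(t):
        return u
    return u * t


def brute_force_optimize(
    model: KineticModel,
    x_external: Mapping[str, float] | MetaboliteState,
    n_random: int = 120,
    seed: int = 0,
    refine: bool = True,
    refine_maxiter: int = 80,
) -> OptimizationResult:
    """Lower-bound oracle: sample enzyme allocations, evaluate their steady states.

    Constrained enzymes are sampled on the boundary of the pool polytope
    (one-hot, pairwise and Dirichlet-random directions, scaled outward).
    Enzymes belonging to no pool are costless but still shape the dynamics —
    a costless uptake step must match downstream capacity, a costless drain
    is best switched off entirely — so each one is searched on a log10
    scale (grid levels spanning off / unit / large, then refined). Each
    allocation is scored by the objective flux of its best steady state,
    located by bounded root-finding in log-concentration space from several
    starts; the best allocation is refined by Nelder-Mead and finally
    re-verified with the ODE integrator (:func:`steady_state_for_enzymes`)
    when the root is dynamically stable. No optimality guarantee.
    """
    r = model.network.n_reactions
    if r > 6:
        raise ValidationError("brute_force_optimize is limited to r <= 6 models")
    rng = np.random.default_rng(seed)
    W = model.constraints.weights
    constrained = np.nonzero(np.any(W > 0, axis=0))[0]
    free = [j for j in range(r) if j not in constrained]
    xe = dict(
        x_external.concentrations
        if isinstance(x_external, MetaboliteState)
        else x_external
    )
    internal = model.network.internal_metabolite_ids
    ni = len(internal)
    base_y0 = [np.zeros(ni), np.full(ni, np.log(1e2))]
    extra_y0 = [rng.uniform(np.log(1e-3), np.log(1e3), ni)]

    def assemble(u: np.ndarray) -> np.ndarray:
        """u = [pool direction (n_constrained), log10 levels of free enzymes]."""
        e = np.zeros(r)
        e[constrained] = np.abs(u[: len(constrained)])
        e = _scale_to_polytope(e, model)
        for idx, j in enumerate(free):
            e[j] = 10.0 ** float(np.clip(u[len(constrained) + idx], -5.0, 6.0))
        return e

    def score(
        u: np.ndarray, warm: np.ndarray | None = None
    ) -> tuple[float, MetaboliteState | None]:
        e = assemble(u)
        y0s = list(base_y0) + extra_y0
        if warm is not None:
            y0s = [warm] + y0s
        state, v_obj = _best_root_steady_state(model, e, xe, y0s)
        if state is None:
            return 0.0, None
        return v_obj, state

    def warm_of(state: MetaboliteState | None) -> np.ndarray | None:
        if state is None:
            return None
        return np.log(
            np.clip([state[m] for m in internal], 1e-300, None)
        )

    nc = len(constrained)
    nf = len(free)
    structured: list[np.ndarray] = []
    eye = np.eye(nc)
    structured.extend(eye)  # pure allocations
    for i, j in itertools.combinations(range(nc), 2):
        for a in (0.5, 0.9, 0.99):  # balanced and strongly skewed pairs
            structured.append(a * eye[i] + (1 - a) * eye[j])
            if a != 0.5:
                structured.append((1 - a) * eye[i] + a * eye[j])
    for i, j, k in itertools.combinations(range(nc), 3):
        structured.append((eye[i] + eye[j] + eye[k]) / 3.0)
    level_grid = (-4.0, -1.0, 0.0, 2.0, 5.0)
    if nf == 0:
        level_combos = [np.zeros(0)]
    else:
        level_combos = [np.array(c) for c in itertools.product(level_grid, repeat=nf)]
        if len(level_combos) > 25:
            keep = rng.choice(len(level_combos), size=25, replace=False)
            level_combos = [level_combos[int(i)] for i in keep]
    candidates = [
        np.concatenate([d, levels]) for d in structured for levels in level_combos
    ]
    # joint random samples cover direction x free-level space continuously;
    # flat and spiky Dirichlet plus log-magnitude draws reach both balanced
    # allocations and the extreme ratios sparse optima need
    n_each = max(n_random // 3, 1)
    dirs = list(rng.dirichlet(np.ones(nc), size=n_each))
    dirs += list(rng.dirichlet(np.full(nc, 0.3), size=n_each))
    for _ in range(n_each):
        mag = 10.0 ** rng.uniform(-3.0, 0.0, size=nc)
        mag[rng.random(nc) < 0.25] = 0.0
        if not np.any(mag > 0):
            mag[int(rng.integers(0, nc))] = 1.0
        dirs.append(mag / np.sum(mag))
    for d in dirs:
        w = rng.uniform(-4.0, 5.0, size=nf)
        candidates.append(np.concatenate([d, w]))

    scored: list[tuple[float, np.ndarray, MetaboliteState | None]] = []
    best_u, best_val, best_state = None, 0.0, None
    for u in candidates:
        val, state = score(u)
        if val > 0.0:
            scored.append((val, u, state))
        if val > best_val:
            best_u, best_val, best_state = u, val, state
    # refinement works on log10 allocation ratios so extreme (sparse)
    # allocations stay reachable by multiplicative moves
    def to_z(u: np.ndarray) -> np.ndarray:
        z = np.log10(np.clip(np.abs(u[:nc]), 1e-5, None))
        return np.concatenate([z, u[nc:]])

    def from_z(z: np.ndarray) -> np.ndarray:
        return np.concatenate([10.0 ** np.clip(z[:nc], -5.0, 2.0), z[nc:]])

    if refine and scored:
        # polish the best few basins; the steady-state landscape is rugged,
        # so a single local search is unreliable. Basins are picked greedily
        # by score but skipping near-duplicates of already-picked allocations
        # so the refinement budget spreads over distinct regions.
        scored.sort(key=lambda t: -t[0])
        picked: list[tuple[float, np.ndarray, MetaboliteState | None]] = []
        for cand in scored:
            if len(picked) >= 10:
                break
            if all(
                float(np.sum(np.abs(cand[1][:nc] - p[1][:nc]))) > 0.15
                for p in picked
            ) or not picked:
                picked.append(cand)
        for _, u0, state0 in picked:
            warm0 = warm_of(state0)

            def refine_objective(z: np.ndarray) -> float:
                return -score(from_z(z), warm=warm0)[0]

            res = minimize(
                refine_objective,
                to_z(u0),
                method="Nelder-Mead",
                options={"maxiter": refine_maxiter, "xatol": 1e-6, "fatol": 1e-12},
            )
            val, state = score(from_z(np.asarray(res.x)), warm=warm0)
            if val > best_val:
                best_u, best_val, best_state = from_z(np.asarray(res.x)), val, state
        # one restart from the overall winner
        warm1 = warm_of(best_state)
        res = minimize(
            lambda z: -score(from_z(z), warm=warm1)[0],
            to_z(best_u),
            method="Nelder-Mead",
            options={"maxiter": refine_maxiter, "xatol": 1e-7, "fatol": 1e-12},
        )
        val, state = score(from_z(np.asarray(res.x)), warm=warm1)
        if val > best_val:
            best_u, best_val, best_state = from_z(np.asarray(res.x)), val, state
    e_best = assemble(best_u) if best_u is not None else np.zeros(r)
    stable = False
    if best_u is not None and best_state is not None:
        ode_state, flag = steady_state_for_enzymes(
            model,
            e_best,
            xe,
            x0=dict(best_state.concentrations),
            t_budget=1e4,
            tol=1e-7,
        )
        stable = flag == "converged"
        if stable:
            best_state = ode_state
    x_internal = MetaboliteState(
        {m: (best_state[m] if best_state is not None else 0.0) for m in internal}
    )
    return OptimizationResult(
        x_internal=x_internal,
        inner=None,
        enzyme_profile=e_best,
        active_efms=(),
        active_constraints=(),
        objective=best_val,
        model=model,
        diagnostics={"n_candidates": len(candidates), "ode_verified": stable},
    )


# ---------------------------------------------------------------------------
# active-set analysis / extremum principle
# ---------------------------------------------------------------------------


def analyze_active_sets(
    result: OptimizationResult,
    tol_lambda: float = 1e-6,
    tol_constraint: float = 1e-6,
) -> tuple[int, int, int]:
    """Counts of active EFMs, active constraints, and equivalence-collapsed
    active EFMs (EFMs with identical cost columns at the optimal state merge).
    """
    if result.inner is None or result.cost_matrix is None:
        raise ValidationError("result lacks inner-LP diagnostics")
    lam = result.inner.lambdas
    lam_max = float(np.max(lam, initial=0.0))
    active_idx = [i for i in range(lam.size) if lam[i] > tol_lambda * lam_max]
    model = result.model
    usage = constraint_usage(result.enzyme_profile, model.constraints)
    rel = usage / model.constraints.bounds
    n_constraints = int(np.sum(rel >= 1.0 - tol_constraint))
    # collapse equivalent EFMs: identical cost columns at the optimal state
    D = result.cost_matrix.D
    groups: list[np.ndarray] = []
    for i in active_idx:
        col = D[:, i]
        scale = 1.0 + float(np.max(np.abs(col)))
        if not any(np.max(np.abs(col - g)) <= 1e-8 * scale for g in groups):
            groups.append(col)
    return len(active_idx), n_constraints, len(groups)


def verify_extremum_principle(
    result: OptimizationResult,
    tol_lambda: float = 1e-6,
    tol_constraint: float = 1e-6,
) -> tuple[bool, dict]:
    """Check that non-equivalent flux-carrying EFMs never outnumber the
    active enzyme constraints at the optimum."""
    n_active, n_constraints, n_collapsed = analyze_active_sets(
        result, tol_lambda, tol_constraint
    )
    ok = n_collapsed <= n_constraints
    report = {
        "active_efms": n_active,
        "non_equivalent_active_efms": n_collapsed,
        "active_constraints": n_constraints,
        "holds": ok,
    }
    return ok, report
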