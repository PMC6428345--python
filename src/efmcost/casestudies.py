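"""Packaged case-study models, substrate sweeps and perturbation experiments.

Two coarse-grained models are shipped:

* an **overflow-metabolism core model**: glucose enters through a membrane
  transporter and is converted to biomass either by an efficient respiration
  pathway (1 intermediate per biomass) or by a faster but wasteful overflow
  pathway (2 intermediates per biomass, excreting acetate), under a cytosolic
  enzyme pool (bound 1) and a membrane pool holding the transporter
  (bound 0.3). Sweeping external glucose reproduces the respirofermentative
  switch: below a critical substrate concentration only respiration runs and
  only the membrane pool is limiting; above it both pathways and both pools
  are active and the respiratory flux declines.
* an **L. lactis switch model**: glucose is fermented to ATP either by a
  high-yield mixed-acid pathway under strong ATP product inhibition or by a
  faster, low-yield homolactic pathway with weak inhibition; ATP drives the
  biomass reaction. Along a substrate sweep the flux fraction crosses from
  mixed-acid to homolactic while the optimal enzyme concentrations barely
  move — the reallocation happens through enzyme saturation, not expression.

All kinetic parameters are package constants chosen to realize these
qualitative regimes; see the kinetic parameter tables in the fixture JSON
files and docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .efm import enumerate_efms
from .errors import ValidationError
from .kinetics import (
    ConstraintSet,
    KineticModel,
    MetaboliteState,
    ReactionKinetics,
    SaturationSpec,
)
from .network import MetabolicNetwork
from .optimizer import OptimizationResult, OptimizeOptions, optimize_growth

__all__ = [
    "SweepTable",
    "BreakpointFit",
    "build_overflow_model",
    "build_lactis_model",
    "sweep_external_substrate",
    "detect_critical_point",
    "perturb_pool_bounds",
    "perturb_catalytic_rates",
    "fit_proportional_breakpoint",
]


@dataclass(frozen=True)
class SweepTable:
    """Result of a substrate sweep: one row per grid point with the optimal
    growth objective, per-EFM usage weights and substrate-uptake fluxes, and
    the active constraint ids."""

    substrate_id: str
    efm_ids: tuple[str, ...]
    frame: pd.DataFrame
    results: tuple[OptimizationResult, ...] = ()

    def lambda_columns(self) -> list[str]:
        return [f"lambda_{eid}" for eid in self.efm_ids]

    def uptake_columns(self) -> list[str]:
        return [f"uptake_{eid}" for eid in self.efm_ids]


@dataclass(frozen=True)
class BreakpointFit:
    """Two-segment fit of uptake rate against growth rate: a through-origin
    proportional segment up to the critical rate, then a free-slope segment.
    ``critical_rate`` is None when one proportional line explains the data."""

    slope: float
    critical_rate: float | None
    sse: float
    second_slope: float | None = None

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValidationError("fitted slope must be positive")


# ---------------------------------------------------------------------------
# packaged models
# ---------------------------------------------------------------------------

#: kinetic constants of the overflow core model (model units)
OVERFLOW_PARAMS = {
    "kcat_transport": 10.0,
    "Km_glucose": 1.0,
    "kcat_respiration": 1.0,
    "kcat_overflow": 3.0,
    "Km_intermediate": 1.0,
    "kcat_biomass": 10.0,
    "Km_precursor": 1.0,
    "membrane_bound": 0.3,
    "cytosol_bound": 1.0,
}


def build_overflow_model() -> KineticModel:
    """Overflow-metabolism core model (see module docstring).

    Reactions: membrane ``transport`` (glucose -> intermediate), cytosolic
    ``respiration`` (1 intermediate -> 1 precursor), cytosolic ``overflow``
    (2 intermediate -> 1 precursor + acetate, higher kcat), and the
    ``biomass`` objective consuming the precursor. Pools: cytosol holds the
    two catabolic enzymes (bound 1); the membrane holds the transporter
    (bound 0.3). The biomass enzyme belongs to no pool.
    """
    p = OVERFLOW_PARAMS
    metabolites = ("glucose_ext", "intermediate", "precursor", "acetate_ext")
    is_external = {
        "glucose_ext": True,
        "intermediate": False,
        "precursor": False,
        "acetate_ext": True,
    }
    #                 transport  respiration  overflow  biomass
    N = np.array(
        [
            [-1.0, 0.0, 0.0, 0.0],   # glucose_ext
            [1.0, -1.0, -2.0, 0.0],  # intermediate
            [0.0, 1.0, 1.0, -1.0],   # precursor
            [0.0, 0.0, 1.0, 0.0],    # acetate_ext
        ]
    )
    network = MetabolicNetwork(
        metabolite_ids=metabolites,
        is_external=is_external,
        stoichiometry=N,
        reaction_ids=("transport", "respiration", "overflow", "biomass"),
        objective_index=3,
    )
    kinetics = {
        "transport": ReactionKinetics(
            kcat=p["kcat_transport"],
            saturation=SaturationSpec(
                kind="michaelis_menten",
                substrate_ids=("glucose_ext",),
                Km={"glucose_ext": p["Km_glucose"]},
            ),
        ),
        "respiration": ReactionKinetics(
            kcat=p["kcat_respiration"],
            saturation=SaturationSpec(
                kind="michaelis_menten",
                substrate_ids=("intermediate",),
                Km={"intermediate": p["Km_intermediate"]},
            ),
        ),
        "overflow": ReactionKinetics(
            kcat=p["kcat_overflow"],
            saturation=SaturationSpec(
                kind="michaelis_menten",
                substrate_ids=("intermediate",),
                Km={"intermediate": p["Km_intermediate"]},
            ),
        ),
        "biomass": ReactionKinetics(
            kcat=p["kcat_biomass"],
            saturation=SaturationSpec(
                kind="michaelis_menten",
                substrate_ids=("precursor",),
                Km={"precursor": p["Km_precursor"]},
            ),
        ),
    }
    constraints = ConstraintSet(
        weights=np.array(
            [
                [0.0, 1.0, 1.0, 0.0],  # cytosolic enzymes
                [1.0, 0.0, 0.0, 0.0],  # membrane transporter
            ]
        ),
        bounds=np.array([p["cytosol_bound"], p["membrane_bound"]]),
        pool_ids=("cytosol", "membrane"),
    )
    return KineticModel(network=network, kinetics=kinetics, constraints=constraints)


#: kinetic constants of the L. lactis switch model (model units)
LACTIS_PARAMS = {
    "kcat_mixed_acid": 2.0,
    "Km_ma_glucose": 0.04,
    "Ki_ma_atp": 0.15,
    "yield_mixed_acid": 2.0,
    "kcat_homolactic": 8.0,
    "Km_hl_glucose": 1.0,
    "Ki_hl_atp": 10.0,
    "yield_homolactic": 1.0,
    "kcat_biomass": 14.0,
    "Km_bm_atp": 0.5,
    "enzyme_bound": 1.0,
    "uptake_weight_mixed_acid": 0.4,
    "uptake_weight_homolactic": 2.8,
    "uptake_bound": 0.4,
}

#: default glucose grid for the overflow sweep (brackets the switch)
OVERFLOW_SWEEP_GRID = tuple(np.geomspace(0.05, 20.0, 15))
#: default glucose grid for the L. lactis sweep (the crossover window)
LACTIS_SWEEP_GRID = tuple(np.geomspace(1.25, 50.0, 10))


def build_lactis_model() -> KineticModel:
    """L. lactis mixed-acid/homolactic switch model (see module docstring).

    The mixed-acid pathway has high ATP yield (2 per glucose), high glucose
    affinity and strong ATP product inhibition; the homolactic pathway is
    faster but low-yield (1 ATP per glucose), has low glucose affinity and
    weak inhibition. Besides the total-enzyme pool there is a glucose-uptake
    pool whose per-enzyme weights reflect how much transport machinery each
    pathway engages per enzyme complex: the homolactic branch moves far more
    glucose per unit objective flux, so it weighs heavier in this pool.
    """
    p = LACTIS_PARAMS
    metabolites = ("glucose_ext", "atp")
    is_external = {"glucose_ext": True, "atp": False}
    N = np.array(
        [
            [-1.0, -1.0, 0.0],  # glucose_ext
            [p["yield_mixed_acid"], p["yield_homolactic"], -1.0],  # atp
        ]
    )
    network = MetabolicNetwork(
        metabolite_ids=metabolites,
        is_external=is_external,
        stoichiometry=N,
        reaction_ids=("mixed_acid", "homolactic", "biomass"),
        objective_index=2,
    )
    kinetics = {
        "mixed_acid": ReactionKinetics(
            kcat=p["kcat_mixed_acid"],
            saturation=SaturationSpec(
                kind="mm_product_inhibition",
                substrate_ids=("glucose_ext",),
                Km={"glucose_ext": p["Km_ma_glucose"]},
                inhibitor_id="atp",
                Ki=p["Ki_ma_atp"],
            ),
        ),
        "homolactic": ReactionKinetics(
            kcat=p["kcat_homolactic"],
            saturation=SaturationSpec(
                kind="mm_product_inhibition",
                substrate_ids=("glucose_ext",),
                Km={"glucose_ext": p["Km_hl_glucose"]},
                inhibitor_id="atp",
                Ki=p["Ki_hl_atp"],
            ),
        ),
        "biomass": ReactionKinetics(
            kcat=p["kcat_biomass"],
            saturation=SaturationSpec(
                kind="michaelis_menten",
                substrate_ids=("atp",),
                Km={"atp": p["Km_bm_atp"]},
            ),
        ),
    }
    constraints = ConstraintSet(
        weights=np.array(
            [
                [1.0, 1.0, 1.0],  # total enzyme
                [
                    p["uptake_weight_mixed_acid"],
                    p["uptake_weight_homolactic"],
                    0.0,
                ],  # glucose-uptake machinery
            ]
        ),
        bounds=np.array([p["enzyme_bound"], p["uptake_bound"]]),
        pool_ids=("total_enzyme", "uptake"),
    )
    return KineticModel(network=network, kinetics=kinetics, constraints=constraints)


# ---------------------------------------------------------------------------
# sweeps
# ---------------------------------------------------------------------------


def _uptake_per_efm(model: KineticModel, efms, substrate_id: str) -> np.ndarray:
    """Substrate consumption per unit objective flux for each EFM."""
    row = model.network.metabolite_index(substrate_id)
    N = model.network.stoichiometry
    return np.array(
        [float(np.sum(np.clip(-N[row], 0.0, None) * e.values)) for e in efms]
    )


def sweep_external_substrate(
    model: KineticModel,
    substrate_grid: Sequence[float],
    substrate_id: str | None = None,
    other_external: Mapping[str, float] | None = None,
    options: OptimizeOptions | None = None,
) -> SweepTable:
    """Optimize growth at each external substrate concentration.

    The grid must be sorted ascending and positive. Consecutive points are
    warm-started from the previous optimum. ``substrate_id`` defaults to the
    first external metabolite; other external metabolites default to 1.
    """
    grid = [float(g) for g in substrate_grid]
    if any(g <= 0 for g in grid) or grid != sorted(grid):
        raise ValidationError("substrate grid must be positive and ascending")
    if substrate_id is None:
        substrate_id = model.network.external_metabolite_ids[0]
    base = {m: 1.0 for m in model.network.external_metabolite_ids}
    if other_external:
        base.update(other_external)
    opts = replace(options) if options is not None else OptimizeOptions()
    efms = list(opts.efms) if opts.efms is not None else [
        e for e in enumerate_efms(model.network) if e.has_objective
    ]
    opts.efms = efms
    efm_ids = tuple(f"efm_{'+'.join(str(j) for j in sorted(e.support))}" for e in efms)
    uptake_unit = _uptake_per_efm(model, efms, substrate_id)

    rows = []
    results = []
    warm: tuple = ()
    for s in grid:
        xe = dict(base)
        xe[substrate_id] = s
        opts.extra_starts = warm
        res = optimize_growth(model, xe, opts)
        results.append(res)
        warm = (dict(res.x_internal.concentrations),)
        lam = {eid: 0.0 for eid in efm_ids}
        if res.cost_matrix is not None and res.inner is not None:
            for eid, l in zip(res.cost_matrix.efm_ids, res.inner.lambdas):
                lam[eid] = float(l)
        row = {"substrate": s, "mu": res.objective}
        for eid, unit in zip(efm_ids, uptake_unit):
            row[f"lambda_{eid}"] = lam[eid]
            row[f"uptake_{eid}"] = lam[eid] * unit
        row["active_constraints"] = "+".join(res.active_constraints)
        rows.append(row)
    frame = pd.DataFrame(rows)
    return SweepTable(
        substrate_id=substrate_id,
        efm_ids=efm_ids,
        frame=frame,
        results=tuple(results),
    )


def detect_critical_point(sweep: SweepTable, tol: float = 1e-6) -> float | None:
    """Smallest substrate value at which a second EFM carries weight.

    The primary EFM is the one active at the lowest grid point; the critical
    point is the first grid value where any other EFM's weight exceeds
    ``tol * max(lambda)`` in that row. None when no second EFM ever runs.
    """
    lam_cols = sweep.lambda_columns()
    if len(lam_cols) < 2:
        return None
    frame = sweep.frame
    first_row = frame.iloc[0]
    primary = max(lam_cols, key=lambda c: first_row[c])
    for _, row in frame.iterrows():
        lam_max = max(row[c] for c in lam_cols)
        if lam_max <= 0:
            continue
        for c in lam_cols:
            if c != primary and row[c] > tol * lam_max:
                return float(row["substrate"])
    return None


# ---------------------------------------------------------------------------
# perturbations
# ---------------------------------------------------------------------------


def perturb_pool_bounds(model: KineticModel, factors: Sequence[float]) -> KineticModel:
    """Multiply the pool bounds elementwise by positive factors — emulating
    e.g. the expression of non-functional protein filling part of a pool."""
    factors = np.asarray(list(factors), dtype=float)
    if factors.shape != (model.constraints.n_constraints,):
        raise ValidationError("one factor per constrained pool required")
    if np.any(factors <= 0):
        raise ValidationError("pool-bound factors must be positive")
    cs = model.constraints
    return KineticModel(
        network=model.network,
        kinetics=dict(model.kinetics),
        constraints=ConstraintSet(
            weights=cs.weights.copy(),
            bounds=cs.bounds * factors,
            pool_ids=cs.pool_ids,
        ),
    )


def perturb_catalytic_rates(
    model: KineticModel, reaction_factors: Mapping[str, float]
) -> KineticModel:
    """Multiply per-reaction kcat values by positive factors — emulating
    enzyme inhibition, which lengthens every cost vector using the enzyme."""
    kinetics = dict(model.kinetics)
    for rid, factor in reaction_factors.items():
        if rid not in kinetics:
            raise ValidationError(f"unknown reaction id {rid!r}")
        if factor <= 0:
            raise ValidationError(f"kcat factor for {rid!r} must be positive")
        rk = kinetics[rid]
        kinetics[rid] = ReactionKinetics(
            kcat=rk.kcat * float(factor), saturation=rk.saturation
        )
    return KineticModel(
        network=model.network, kinetics=kinetics, constraints=model.constraints
    )


# ---------------------------------------------------------------------------
# proportionality diagnostic
# ---------------------------------------------------------------------------


def fit_proportional_breakpoint(
    growth_rates: Sequence[float],
    uptake_rates: Sequence[float],
    improvement_tol: float = 0.05,
) -> BreakpointFit:
    """Fit uptake-vs-growth chemostat data with a proportional line plus an
    optional breakpoint.

    A strictly proportional relation (through-origin line) over the whole
    range indicates the use of a single EFM. The fit therefore compares a
    single through-origin line against two-segment fits — proportional up to
    a candidate breakpoint ``b`` (placed at data midpoints), then a free-slope
    segment continuous at ``b`` — and reports the breakpoint only when the
    two-segment fit reduces the squared error by more than
    ``improvement_tol`` (relative).
    """
    mu = np.asarray(list(growth_rates), dtype=float)
    q = np.asarray(list(uptake_rates), dtype=float)
    if mu.size != q.size:
        raise ValidationError("growth and uptake vectors must have equal length")
    if mu.size < 4:
        raise ValidationError("at least 4 data points required")
    if np.any(mu < 0) or np.any(q < 0):
        raise ValidationError("rates must be nonnegative")
    order = np.argsort(mu)
    mu, q = mu[order], q[order]

    def through_origin(m, y) -> tuple[float, float]:
        denom = float(m @ m)
        slope = float(m @ y) / denom if denom > 0 else 0.0
        return slope, float(np.sum((y - slope * m) ** 2))

    slope0, sse0 = through_origin(mu, q)

    # candidate breakpoints: interior data points and consecutive midpoints
    candidates = sorted(
        set(float(m) for m in mu[1:-1])
        | set(0.5 * (float(mu[i]) + float(mu[i + 1])) for i in range(1, mu.size - 1))
    )
    best = (None, slope0, None, sse0)  # (breakpoint, slope1, slope2, sse)
    for b in candidates:
        left = mu <= b
        if left.sum() < 2 or (~left).sum() < 1:
            continue
        # joint least squares: q = s1*mu on the left;
        # q = s1*b + s2*(mu-b) on the right (continuity at b)
        a1 = np.where(left, mu, b)
        a2 = np.where(left, 0.0, mu - b)
        A = np.column_stack([a1, a2])
        coef, *_ = np.linalg.lstsq(A, q, rcond=None)
        s1, s2 = float(coef[0]), float(coef[1])
        if s1 <= 0:
            continue
        sse = float(np.sum((A @ coef - q) ** 2))
        if sse < best[3]:
            best = (float(b), s1, s2, sse)

    b, s1, s2, sse = best
    # a through-origin fit already at rounding-noise level is proportional
    noise_floor = 1e-12 * float(q @ q)
    if b is None or sse0 <= noise_floor or (sse0 - sse) / sse0 < improvement_tol:
        return BreakpointFit(slope=slope0, critical_rate=None, sse=sse0)
    return BreakpointFit(slope=s1, critical_rate=b, sse=sse, second_slope=s2)
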