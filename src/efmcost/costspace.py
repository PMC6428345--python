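"""Cost vectors, EFM equivalence and the two-pool diagonal-ranking geometry.

The cost vector of an objective-normalized EFM at metabolite state ``x`` has
one entry per constrained enzyme pool:

    d_k^i(x) = sum_j w_j^(k) V_j^i / (kcat_j f_j(x)),

the fraction of pool k consumed to produce one unit of objective flux through
EFM i (weights are pre-scaled by the pool bounds, so feasibility of a usage
vector ``lambda`` reads ``D @ lambda <= 1``). Two EFMs are *equivalent* when
their cost vectors coincide — they are then interchangeable in an optimum.

With K = 2 pools the constraint region is the unit square and every strategy
(a pure EFM, or a mixture of one above-diagonal and one below-diagonal EFM)
can be ranked by a single dot on the diagonal: the average cost per unit
objective flux. Pure above-diagonal vectors project horizontally onto the
diagonal, below-diagonal ones vertically, and a mixture's dot is the
intersection of the diagonal with the segment between the two cost vectors.
The strategy whose dot is closest to the origin yields the highest objective
flux, equal to 1/dot.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .efm import EFM
from .errors import ValidationError
from .kinetics import KineticModel, MetaboliteState, enzyme_demand

__all__ = [
    "CostMatrix",
    "DiagonalRanking",
    "compute_cost_matrix",
    "are_equivalent",
    "rank_on_diagonal_2d",
    "best_strategy_2d",
    "sample_equivalence_states",
]

#: classification band for "exactly on the diagonal"
DIAGONAL_TOL = 1e-12


@dataclass(frozen=True)
class CostMatrix:
    """K x M matrix of per-pool, per-EFM costs (pool fraction per unit
    objective flux), with the metabolite state it was evaluated at."""

    D: np.ndarray
    efm_ids: tuple[str, ...]
    state: MetaboliteState
    pool_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        D = np.atleast_2d(np.asarray(self.D, dtype=float))
        object.__setattr__(self, "D", D)
        object.__setattr__(self, "efm_ids", tuple(self.efm_ids))
        if D.shape[1] != len(self.efm_ids):
            raise ValidationError("one efm id per cost-matrix column required")
        if np.any(D < 0):
            raise ValidationError("cost-matrix entries must be nonnegative")
        if not self.pool_ids:
            object.__setattr__(
                self, "pool_ids", tuple(f"pool_{k}" for k in range(D.shape[0]))
            )
        else:
            object.__setattr__(self, "pool_ids", tuple(self.pool_ids))

    @property
    def n_pools(self) -> int:
        return self.D.shape[0]

    @property
    def n_efms(self) -> int:
        return self.D.shape[1]


@dataclass(frozen=True)
class DiagonalRanking:
    """Strategies (pure EFMs, opposite-side 2-EFM mixtures) ranked by their
    dot on the diagonal of the unit constraint square; smaller is better and
    the achievable objective flux of a strategy equals 1/dot."""

    dots: Mapping[str, float]
    best: str
    strategies: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "dots", dict(self.dots))
        object.__setattr__(self, "strategies", dict(self.strategies))
        if any(v <= 0 for v in self.dots.values()):
            raise ValidationError("diagonal dots must be positive")
        if self.best not in self.dots:
            raise ValidationError("best strategy missing from dots")

    def objective(self, strategy: str) -> float:
        return 1.0 / self.dots[strategy]


def compute_cost_matrix(
    efms: Sequence[EFM],
    x: MetaboliteState | Mapping[str, float],
    model: KineticModel,
) -> CostMatrix:
    """Cost vectors of objective-normalized EFMs at state ``x`` as columns.

    Column i equals ``(W / bounds) @ enzyme_demand(efm_i, x)``; pool bounds
    are folded in so the feasibility region is the unit box.
    """
    if not efms:
        raise ValidationError("no EFMs supplied")
    state = x if isinstance(x, MetaboliteState) else MetaboliteState(dict(x))
    Ws = model.constraints.scaled_weights
    cols = [Ws @ enzyme_demand(efm, state, model) for efm in efms]
    ids = tuple(f"efm_{'+'.join(str(j) for j in sorted(e.support))}" for e in efms)
    return CostMatrix(
        D=np.column_stack(cols),
        efm_ids=ids,
        state=state,
        pool_ids=model.constraints.pool_ids,
    )


def sample_equivalence_states(
    model: KineticModel,
    n_samples: int = 20,
    seed: int = 0,
    log_range: tuple[float, float] = (1e-3, 1e3),
) -> list[MetaboliteState]:
    """Seeded log-uniform concentration samples used to probe equivalence
    across states (a decidable surrogate for 'equal cost vectors at all x')."""
    rng = np.random.default_rng(seed)
    lo, hi = np.log10(log_range[0]), np.log10(log_range[1])
    mets = model.network.metabolite_ids
    states = []
    for _ in range(n_samples):
        conc = 10.0 ** rng.uniform(lo, hi, size=len(mets))
        states.append(MetaboliteState(dict(zip(mets, conc))))
    return states


def are_equivalent(
    efm_a: EFM,
    efm_b: EFM,
    model: KineticModel,
    x_samples: Sequence[MetaboliteState],
    tol: float = 1e-8,
) -> bool:
    """True iff the two EFMs' cost vectors agree (sup-norm <= tol) at every
    sampled metabolite state."""
    if not (efm_a.has_objective and efm_b.has_objective):
        raise ValidationError("equivalence is defined for objective EFMs")
    if len(x_samples) == 0:
        raise ValidationError("at least one metabolite state sample required")
    for x in x_samples:
        cm = compute_cost_matrix([efm_a, efm_b], x, model)
        if float(np.max(np.abs(cm.D[:, 0] - cm.D[:, 1]))) > tol:
            return False
    return True


def _mixture_dot(a: np.ndarray, b: np.ndarray) -> float | None:
    """Diagonal coordinate of the segment between cost vectors a and b, or
    None when they lie on the same side of the diagonal (no valid mixture)."""
    ga, gb = a[0] - a[1], b[0] - b[1]
    if ga * gb >= 0:  # same side (or one on the diagonal): not a mixture
        return None
    t = ga / (ga - gb)
    return float(a[0] + t * (b[0] - a[0]))


def rank_on_diagonal_2d(cost: CostMatrix) -> DiagonalRanking:
    """Rank all pure and opposite-side mixture strategies of a K=2 cost
    matrix by their dot on the diagonal (see module docstring)."""
    if cost.n_pools != 2:
        raise ValidationError(
            f"diagonal ranking is defined for exactly 2 pools (got {cost.n_pools})"
        )
    if np.any(cost.D <= 0):
        raise ValidationError("diagonal ranking requires strictly positive costs")
    dots: dict[str, float] = {}
    strategies: dict[str, tuple[str, ...]] = {}
    for i, eid in enumerate(cost.efm_ids):
        dots[eid] = float(np.max(cost.D[:, i]))
        strategies[eid] = (eid,)
    for i in range(cost.n_efms):
        for j in range(i + 1, cost.n_efms):
            dot = _mixture_dot(cost.D[:, i], cost.D[:, j])
            if dot is None:
                continue
            key = f"{cost.efm_ids[i]}|{cost.efm_ids[j]}"
            dots[key] = dot
            strategies[key] = (cost.efm_ids[i], cost.efm_ids[j])
    best = min(sorted(dots), key=lambda k: dots[k])
    return DiagonalRanking(dots=dots, best=best, strategies=strategies)


def best_strategy_2d(cost: CostMatrix) -> tuple[tuple[int, ...], np.ndarray]:
    """Optimal support and lambda for a K=2 cost matrix by exact enumeration.

    Returns the column indices used and the full-length lambda vector
    maximizing ``sum(lambda)`` subject to ``D @ lambda <= 1``; at most two
    EFMs appear. Agrees with the inner LP (cross-checked in the test suite).
    """
    ranking = rank_on_diagonal_2d(cost)
    members = ranking.strategies[ranking.best]
    idx = tuple(cost.efm_ids.index(m) for m in members)
    lambdas = np.zeros(cost.n_efms)
    if len(idx) == 1:
        lambdas[idx[0]] = 1.0 / float(np.max(cost.D[:, idx[0]]))
    else:
        sub = cost.D[:, list(idx)]
        sol = np.linalg.solve(sub, np.ones(2))
        lambdas[list(idx)] = sol
    return idx, lambdas
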