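"""Rate laws, enzyme demand and weighted enzyme-concentration constraints.

Each reaction rate follows ``v_i = e_i * kcat_i * f_i(x)``: proportional to
the enzyme concentration ``e_i``, with a saturation function
``f_i(x) in [0, 1]`` describing how metabolite concentrations scale the rate
below the kcat maximum. Enzyme-expression limits are modelled as K weighted
sums ``sum_j w_j^(k) e_j <= C^(k)`` — limited enzyme pools such as cytosolic
solvent capacity or membrane area. An enzyme may belong to none, one or
several pools.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

from .efm import EFM
from .errors import InfeasibleStateError, ValidationError
from .network import MetabolicNetwork

__all__ = [
    "SaturationSpec",
    "ReactionKinetics",
    "ConstraintSet",
    "MetaboliteState",
    "KineticModel",
    "reaction_rate",
    "enzyme_demand",
    "constraint_usage",
    "register_saturation_kind",
]

#: registry for custom saturation kinds (extension hook); maps the kind name
#: to a callable (spec, concentrations) -> float in [0, 1]
_CUSTOM_KINDS: dict[str, Callable[["SaturationSpec", Mapping[str, float]], float]] = {}

_BUILTIN_KINDS = ("constant", "michaelis_menten", "mm_product_inhibition")


def register_saturation_kind(
    name: str, fn: Callable[["SaturationSpec", Mapping[str, float]], float]
) -> None:
    """Register a custom saturation kind. The callable must map nonnegative
    concentrations into [0, 1]; this is the caller's responsibility."""
    if name in _BUILTIN_KINDS:
        raise ValidationError(f"cannot override builtin saturation kind {name!r}")
    _CUSTOM_KINDS[name] = fn


@dataclass(frozen=True)
class SaturationSpec:
    """Saturation function f(x) of an enzyme, bounded in [0, 1].

    Kinds:

    - ``constant``: f = 1 (fully saturated / concentration-independent).
    - ``michaelis_menten``: product over substrates of ``x_s / (Km_s + x_s)``.
    - ``mm_product_inhibition``: Michaelis-Menten multiplied by the
      non-competitive inhibition factor ``1 / (1 + x_inh / Ki)``.
    """

    kind: str = "constant"
    substrate_ids: tuple[str, ...] = ()
    Km: Mapping[str, float] = field(default_factory=dict)
    inhibitor_id: str | None = None
    Ki: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "substrate_ids", tuple(self.substrate_ids))
        object.__setattr__(self, "Km", dict(self.Km))
        if self.kind not in _BUILTIN_KINDS and self.kind not in _CUSTOM_KINDS:
            raise ValidationError(
                f"unknown saturation kind {self.kind!r}; builtin kinds are "
                f"{_BUILTIN_KINDS} (custom kinds must be registered first)"
            )
        if self.kind in ("michaelis_menten", "mm_product_inhibition"):
            if not self.substrate_ids:
                raise ValidationError(f"{self.kind} requires at least one substrate")
            for s in self.substrate_ids:
                km = self.Km.get(s)
                if km is None or km <= 0:
                    raise ValidationError(
                        f"substrate {s!r} needs a positive Km (got {km!r})"
                    )
        if self.kind == "mm_product_inhibition":
            if self.inhibitor_id is None or self.Ki is None or self.Ki <= 0:
                raise ValidationError(
                    "mm_product_inhibition requires inhibitor_id and positive Ki"
                )

    @property
    def referenced_metabolites(self) -> tuple[str, ...]:
        mets = list(self.substrate_ids)
        if self.kind == "mm_product_inhibition" and self.inhibitor_id is not None:
            mets.append(self.inhibitor_id)
        return tuple(mets)

    def evaluate(self, x: Mapping[str, float]) -> float:
        """f(x) for a mapping of metabolite concentrations (>= 0)."""
        for mid in self.referenced_metabolites:
            if mid not in x:
                raise ValidationError(
                    f"metabolite {mid!r} required by saturation function "
                    "missing from the state"
                )
        if self.kind == "constant":
            return 1.0
        if self.kind in ("michaelis_menten", "mm_product_inhibition"):
            f = 1.0
            for s in self.substrate_ids:
                xs = float(x[s])
                f *= xs / (self.Km[s] + xs)
            if self.kind == "mm_product_inhibition":
                f *= 1.0 / (1.0 + float(x[self.inhibitor_id]) / self.Ki)
            return f
        return float(_CUSTOM_KINDS[self.kind](self, x))


@dataclass(frozen=True)
class ReactionKinetics:
    """kcat (maximal per-enzyme turnover, flux per enzyme concentration)
    plus the saturation function."""

    kcat: float
    saturation: SaturationSpec = field(default_factory=SaturationSpec)

    def __post_init__(self) -> None:
        if self.kcat <= 0:
            raise ValidationError(f"kcat must be positive (got {self.kcat})")


@dataclass(frozen=True)
class ConstraintSet:
    """K weighted enzyme pools: weights W (K x r, >= 0) and positive bounds.

    ``weights[k, j]`` is the fraction of pool k consumed per concentration
    unit of enzyme j. Internally all cost computations rescale weights by the
    bounds so that feasibility reads ``D @ lambda <= 1``.
    """

    weights: np.ndarray
    bounds: np.ndarray
    pool_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        W = np.atleast_2d(np.asarray(self.weights, dtype=float))
        b = np.atleast_1d(np.asarray(self.bounds, dtype=float))
        object.__setattr__(self, "weights", W)
        object.__setattr__(self, "bounds", b)
        if W.shape[0] != b.shape[0]:
            raise ValidationError("one bound per constraint row required")
        if np.any(W < 0):
            raise ValidationError("constraint weights must be nonnegative")
        if np.any(b <= 0):
            raise ValidationError("pool bounds must be positive")
        empty = [k for k in range(W.shape[0]) if not np.any(W[k] > 0)]
        if empty:
            raise ValidationError(f"all-zero constraint rows: {empty}")
        if not self.pool_ids:
            object.__setattr__(
                self, "pool_ids", tuple(f"pool_{k}" for k in range(W.shape[0]))
            )
        else:
            object.__setattr__(self, "pool_ids", tuple(self.pool_ids))
            if len(self.pool_ids) != W.shape[0]:
                raise ValidationError("one pool id per constraint row required")

    @property
    def n_constraints(self) -> int:
        return self.weights.shape[0]

    @property
    def scaled_weights(self) -> np.ndarray:
        """Weights divided by bounds, so every pool capacity becomes 1."""
        return self.weights / self.bounds[:, None]


@dataclass(frozen=True)
class MetaboliteState:
    """Nonnegative metabolite concentrations (model concentration units)."""

    concentrations: Mapping[str, float]

    def __post_init__(self) -> None:
        conc = {str(k): float(v) for k, v in dict(self.concentrations).items()}
        object.__setattr__(self, "concentrations", conc)
        neg = {k: v for k, v in conc.items() if v < 0}
        if neg:
            raise ValidationError(f"negative concentrations: {neg}")

    def __getitem__(self, mid: str) -> float:
        return self.concentrations[mid]

    def __contains__(self, mid: str) -> bool:
        return mid in self.concentrations

    def keys(self):
        return self.concentrations.keys()

    def updated(self, **changes: float) -> "MetaboliteState":
        merged = dict(self.concentrations)
        merged.update(changes)
        return MetaboliteState(merged)


def _as_mapping(x: MetaboliteState | Mapping[str, float]) -> Mapping[str, float]:
    return x.concentrations if isinstance(x, MetaboliteState) else x


@dataclass(frozen=True)
class KineticModel:
    """A stoichiometric network with per-reaction kinetics and enzyme pools."""

    network: MetabolicNetwork
    kinetics: Mapping[str, ReactionKinetics]
    constraints: ConstraintSet

    def __post_init__(self) -> None:
        object.__setattr__(self, "kinetics", dict(self.kinetics))
        missing = [rid for rid in self.network.reaction_ids if rid not in self.kinetics]
        if missing:
            raise ValidationError(f"reactions without kinetics: {missing}")
        extra = [rid for rid in self.kinetics if rid not in self.network.reaction_ids]
        if extra:
            raise ValidationError(f"kinetics for unknown reactions: {extra}")
        if self.constraints.weights.shape[1] != self.network.n_reactions:
            raise ValidationError(
                "constraint weight columns must align with the reaction order "
                f"({self.constraints.weights.shape[1]} != {self.network.n_reactions})"
            )
        unknown = [
            mid
            for rk in self.kinetics.values()
            for mid in rk.saturation.referenced_metabolites
            if mid not in self.network.metabolite_ids
        ]
        if unknown:
            raise ValidationError(
                f"saturation functions reference unknown metabolites: {unknown}"
            )

    @property
    def kcat_vector(self) -> np.ndarray:
        return np.array(
            [self.kinetics[rid].kcat for rid in self.network.reaction_ids]
        )

    def saturation_vector(self, x: MetaboliteState | Mapping[str, float]) -> np.ndarray:
        xm = _as_mapping(x)
        return np.array(
            [self.kinetics[rid].saturation.evaluate(xm) for rid in self.network.reaction_ids]
        )

    @property
    def kinetic_internal_metabolites(self) -> tuple[str, ...]:
        """Internal metabolites appearing in at least one saturation function
        (the decision variables of the outer concentration search)."""
        referenced = {
            mid
            for rk in self.kinetics.values()
            for mid in rk.saturation.referenced_metabolites
        }
        return tuple(
            mid for mid in self.network.internal_metabolite_ids if mid in referenced
        )


def reaction_rate(
    rk: ReactionKinetics, e: float, x: MetaboliteState | Mapping[str, float]
) -> float:
    """v = e * kcat * f(x)."""
    if e < 0:
        raise ValidationError("enzyme concentration must be nonnegative")
    return float(e) * rk.kcat * rk.saturation.evaluate(_as_mapping(x))


def enzyme_demand(
    efm: EFM, x: MetaboliteState | Mapping[str, float], model: KineticModel
) -> np.ndarray:
    """Enzyme concentrations needed for one unit of objective flux via an EFM.

    ``e_j = V_j / (kcat_j * f_j(x))`` on the EFM support, 0 elsewhere. The EFM
    must be normalized to unit objective flux. A vanishing saturation on the
    support makes the EFM infeasible at this state.
    """
    if not efm.has_objective:
        raise ValidationError("enzyme_demand requires an objective-carrying EFM")
    if efm.values[model.network.objective_index] != 1.0:
        raise ValidationError("EFM must be normalized to unit objective flux")
    xm = _as_mapping(x)
    e = np.zeros(model.network.n_reactions)
    for j in sorted(efm.support):
        rid = model.network.reaction_ids[j]
        rk = model.kinetics[rid]
        f = rk.saturation.evaluate(xm)
        if f <= 0.0:
            raise InfeasibleStateError(
                f"EFM infeasible at this state: saturation of {rid!r} is zero"
            )
        e[j] = efm.values[j] / (rk.kcat * f)
    return e


def constraint_usage(e: np.ndarray, cs: ConstraintSet) -> np.ndarray:
    """Pool usage W @ e (unscaled; compare against ``cs.bounds``)."""
    e = np.asarray(e, dtype=float)
    if e.shape != (cs.weights.shape[1],):
        raise ValidationError(
            f"enzyme vector length {e.shape} does not match "
            f"{cs.weights.shape[1]} weight columns"
        )
    if np.any(e < 0):
        raise ValidationError("enzyme concentrations must be nonnegative")
    return cs.weights @ e
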