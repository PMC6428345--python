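"""Stoichiometric networks with irreversible reactions and the flux cone.

The steady-state flux cone of a network with stoichiometric matrix ``N``
(rows = metabolites, columns = reactions) is ``{v : N_I v = 0, v >= 0}``,
where ``N_I`` is the restriction of ``N`` to *internal* metabolite rows.
External metabolites are environment parameters — unbalanced sources and
sinks — and carry no steady-state condition.

All reactions are irreversible by convention; reversible reactions are
represented by a forward/backward column pair (:func:`split_reversible`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ValidationError

__all__ = [
    "MetabolicNetwork",
    "FluxVector",
    "split_reversible",
    "check_steady_state",
    "merge_split_fluxes",
]


@dataclass(frozen=True)
class MetabolicNetwork:
    """An irreversible-reaction stoichiometric network.

    Parameters
    ----------
    metabolite_ids :
        Ordered metabolite identifiers (rows of ``stoichiometry``).
    is_external :
        Map metabolite id -> bool. External metabolites are environment
        parameters; internal metabolites must balance at steady state.
    stoichiometry :
        Real matrix of shape ``(m, r)``; negative entries consume, positive
        entries produce.
    reaction_ids :
        Ordered reaction identifiers (columns).
    objective_index :
        Column index of the objective reaction (e.g. biomass synthesis).
    """

    metabolite_ids: tuple[str, ...]
    is_external: dict[str, bool]
    stoichiometry: np.ndarray
    reaction_ids: tuple[str, ...]
    objective_index: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "metabolite_ids", tuple(self.metabolite_ids))
        object.__setattr__(self, "reaction_ids", tuple(self.reaction_ids))
        N = np.asarray(self.stoichiometry, dtype=float)
        object.__setattr__(self, "stoichiometry", N)
        m, r = N.shape if N.ndim == 2 else (-1, -1)
        if N.ndim != 2:
            raise ValidationError("stoichiometry must be a 2-D matrix")
        if m != len(self.metabolite_ids):
            raise ValidationError(
                f"stoichiometry has {m} rows but {len(self.metabolite_ids)} metabolite ids"
            )
        if r != len(self.reaction_ids):
            raise ValidationError(
                f"stoichiometry has {r} columns but {len(self.reaction_ids)} reaction ids"
            )
        if len(set(self.metabolite_ids)) != m:
            raise ValidationError("duplicate metabolite ids")
        if len(set(self.reaction_ids)) != r:
            raise ValidationError("duplicate reaction ids")
        missing = [mid for mid in self.metabolite_ids if mid not in self.is_external]
        if missing:
            raise ValidationError(f"is_external missing metabolites: {missing}")
        if not (0 <= self.objective_index < r):
            raise ValidationError(
                f"objective_index {self.objective_index} out of range for {r} reactions"
            )
        zero_cols = [
            self.reaction_ids[j] for j in range(r) if not np.any(N[:, j] != 0.0)
        ]
        if zero_cols:
            raise ValidationError(
                f"reactions with all-zero stoichiometry column: {zero_cols}"
            )
        if r > 1 and len(self.internal_indices) == 0:
            raise ValidationError(
                "network with more than one reaction must have at least one "
                "internal metabolite"
            )

    # -- derived views -------------------------------------------------

    @property
    def n_metabolites(self) -> int:
        return self.stoichiometry.shape[0]

    @property
    def n_reactions(self) -> int:
        return self.stoichiometry.shape[1]

    @property
    def internal_indices(self) -> tuple[int, ...]:
        return tuple(
            i for i, mid in enumerate(self.metabolite_ids) if not self.is_external[mid]
        )

    @property
    def external_indices(self) -> tuple[int, ...]:
        return tuple(
            i for i, mid in enumerate(self.metabolite_ids) if self.is_external[mid]
        )

    @property
    def internal_metabolite_ids(self) -> tuple[str, ...]:
        return tuple(self.metabolite_ids[i] for i in self.internal_indices)

    @property
    def external_metabolite_ids(self) -> tuple[str, ...]:
        return tuple(self.metabolite_ids[i] for i in self.external_indices)

    @property
    def internal_stoichiometry(self) -> np.ndarray:
        """Rows of ``N`` for internal metabolites only (the balanced part)."""
        return self.stoichiometry[list(self.internal_indices), :]

    @property
    def objective_id(self) -> str:
        return self.reaction_ids[self.objective_index]

    def reaction_index(self, rid: str) -> int:
        try:
            return self.reaction_ids.index(rid)
        except ValueError:
            raise ValidationError(f"unknown reaction id {rid!r}") from None

    def metabolite_index(self, mid: str) -> int:
        try:
            return self.metabolite_ids.index(mid)
        except ValueError:
            raise ValidationError(f"unknown metabolite id {mid!r}") from None


@dataclass(frozen=True)
class FluxVector:
    """A vector of reaction rates, one entry per reaction (flux units)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "values", np.atleast_1d(np.asarray(self.values, dtype=float))
        )


def _as_flux_array(network: MetabolicNetwork, v) -> np.ndarray:
    arr = v.values if isinstance(v, FluxVector) else np.asarray(v, dtype=float)
    arr = np.atleast_1d(arr)
    if arr.shape != (network.n_reactions,):
        raise ValidationError(
            f"flux vector length {arr.shape} does not match "
            f"{network.n_reactions} reactions"
        )
    return arr


def default_tolerance(v: np.ndarray) -> float:
    """Scale-free steady-state tolerance: ``1e-9 * (1 + max|v|)``."""
    return 1e-9 * (1.0 + float(np.max(np.abs(v))) if v.size else 1.0)


def check_steady_state(network: MetabolicNetwork, v, tol: float | None = None) -> bool:
    """True iff ``v`` lies in the flux cone within ``tol``.

    Balance is enforced on internal metabolite rows only; all entries must be
    nonnegative (within ``-tol``). ``tol`` defaults to the scale-free
    ``1e-9 * (1 + max|v|)``.
    """
    arr = _as_flux_array(network, v)
    if tol is None:
        tol = default_tolerance(arr)
    if tol <= 0:
        raise ValidationError("tol must be positive")
    NI = network.internal_stoichiometry
    imbalance = 0.0 if NI.shape[0] == 0 else float(np.max(np.abs(NI @ arr)))
    return imbalance <= tol and float(np.min(arr, initial=0.0)) >= -tol


def split_reversible(
    network: MetabolicNetwork, reversible: Sequence[bool]
) -> MetabolicNetwork:
    """Replace each reversible column by a forward/backward irreversible pair.

    The forward column keeps the original stoichiometry (id suffixed
    ``_fwd``); the backward column is its negation (``_bwd``). Irreversible
    columns are unchanged. The objective reaction must be irreversible.
    """
    reversible = list(reversible)
    if len(reversible) != network.n_reactions:
        raise ValidationError("one reversibility flag per reaction required")
    if reversible[network.objective_index]:
        raise ValidationError(
            "objective reaction must be a single irreversible flux; "
            "cannot split a reversible objective"
        )
    if not any(reversible):
        return network
    cols: list[np.ndarray] = []
    ids: list[str] = []
    objective_id = network.objective_id
    for j, rid in enumerate(network.reaction_ids):
        col = network.stoichiometry[:, j]
        if reversible[j]:
            cols.append(col)
            ids.append(f"{rid}_fwd")
            cols.append(-col)
            ids.append(f"{rid}_bwd")
        else:
            cols.append(col)
            ids.append(rid)
    return MetabolicNetwork(
        metabolite_ids=network.metabolite_ids,
        is_external=dict(network.is_external),
        stoichiometry=np.column_stack(cols),
        reaction_ids=tuple(ids),
        objective_index=ids.index(objective_id),
    )


def merge_split_fluxes(
    split: MetabolicNetwork, original: MetabolicNetwork, v_split
) -> np.ndarray:
    """Map a flux of the split network back to the original (fwd - bwd)."""
    arr = _as_flux_array(split, v_split)
    out = np.zeros(original.n_reactions)
    for j, rid in enumerate(original.reaction_ids):
        if rid in split.reaction_ids:
            out[j] = arr[split.reaction_ids.index(rid)]
        else:
            out[j] = arr[split.reaction_ids.index(f"{rid}_fwd")] - arr[
                split.reaction_ids.index(f"{rid}_bwd")
            ]
    return out
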