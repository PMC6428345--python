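"""Elementary Flux Mode enumeration, normalization and flux decomposition.

An EFM is a support-minimal element of the flux cone
``{v : N_I v = 0, v >= 0}``: no other cone element has a strictly contained
support. In a network whose reversible reactions have been split, the EFMs
coincide with the extreme rays of this pointed polyhedral cone, so they can
be enumerated by the nullspace/double-description algorithm implemented in
:func:`enumerate_efms`. :func:`enumerate_efms_bruteforce` is an independent
exponential-time oracle over support subsets, used for cross-validation.

EFMs whose objective entry is nonzero are normalized to unit objective flux
(``V_obj = 1``); any steady-state flux then decomposes as
``v = sum_i lambda_i EFM^i`` with ``lambda_i >= 0``, the lambda of an
objective EFM being the objective flux it contributes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.linalg import null_space
from scipy.linalg import qr as scipy_qr
from scipy.optimize import nnls

from .errors import NumericalError, ValidationError
from .network import FluxVector, MetabolicNetwork, _as_flux_array, check_steady_state

__all__ = [
    "EFM",
    "DecompositionResult",
    "enumerate_efms",
    "enumerate_efms_bruteforce",
    "normalize_to_objective",
    "decompose_flux",
]

#: entries below this magnitude (after normalization) are treated as zero
SUPPORT_TOL = 1e-10
#: rank decisions in the double-description pipeline
RANK_TOL = 1e-8
#: hard size limit for enumerate_efms
MAX_REACTIONS = 25


@dataclass(frozen=True)
class EFM:
    """A normalized Elementary Flux Mode.

    ``values`` has one entry per reaction; ``support`` is the set of reaction
    indices with nonzero flux; ``has_objective`` marks EFMs that carry
    objective flux (for those, the objective entry equals 1 exactly).
    """

    values: np.ndarray
    support: frozenset[int]
    has_objective: bool

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "support", frozenset(self.support))


@dataclass(frozen=True)
class DecompositionResult:
    """Nonnegative EFM weights reproducing a flux vector, plus the residual."""

    lambdas: np.ndarray
    residual: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "lambdas", np.asarray(self.lambdas, dtype=float))
        if np.any(self.lambdas < 0):
            raise ValidationError("lambdas must be nonnegative")
        if self.residual < 0:
            raise ValidationError("residual must be nonnegative")


def _make_efm(network: MetabolicNetwork, ray: np.ndarray) -> EFM:
    """Normalize a raw ray to an EFM (objective entry 1, or max entry 1)."""
    ray = np.array(ray, dtype=float)
    peak = float(np.max(np.abs(ray)))
    if peak <= 0:
        raise ValidationError("zero ray is not an EFM")
    ray = ray / peak
    ray[np.abs(ray) < SUPPORT_TOL] = 0.0
    obj = ray[network.objective_index]
    has_objective = obj != 0.0
    if has_objective:
        ray = ray / obj
        ray[network.objective_index] = 1.0
    support = frozenset(int(j) for j in np.nonzero(ray)[0])
    return EFM(values=ray, support=support, has_objective=has_objective)


def _kernel_ray_on_support(
    NI: np.ndarray, support: tuple[int, ...], r: int
) -> np.ndarray | None:
    """The unique (up to scale) nonnegative full-support kernel vector on a
    candidate support, or None if the support does not carry exactly one ray."""
    sub = NI[:, list(support)] if NI.shape[0] else np.zeros((0, len(support)))
    kern = null_space(sub, rcond=RANK_TOL) if sub.size else np.eye(len(support))
    if kern.shape[1] != 1:
        return None
    vec = kern[:, 0]
    vec = vec / np.max(np.abs(vec))
    if np.min(vec) < -SUPPORT_TOL:
        vec = -vec
    if np.min(vec) < SUPPORT_TOL:  # sign-mixed or not full support
        return None
    out = np.zeros(r)
    out[list(support)] = vec
    return out


def _sorted_efms(network: MetabolicNetwork, rays: list[np.ndarray]) -> list[EFM]:
    """Polish rays through their exact kernel, dedupe by support, sort."""
    NI = network.internal_stoichiometry
    r = network.n_reactions
    by_support: dict[tuple[int, ...], EFM] = {}
    for ray in rays:
        efm = _make_efm(network, ray)
        support = tuple(sorted(efm.support))
        polished = _kernel_ray_on_support(NI, support, r)
        if polished is None:
            continue  # numerically non-minimal or sign-mixed: not an EFM
        by_support[support] = _make_efm(network, polished)
    return [by_support[s] for s in sorted(by_support)]


def enumerate_efms(network: MetabolicNetwork) -> list[EFM]:
    """All EFMs of an irreversible network (double-description algorithm).

    Starts from a nullspace basis of the internal stoichiometry, processes the
    nonnegativity constraints one reaction at a time, combining adjacent rays
    (algebraic rank-based adjacency test), and finally discards any ray whose
    support does not carry a unique full-support kernel vector. Intended for
    desk-scale networks (``r`` up to ~25).
    """
    r = network.n_reactions
    if r > MAX_REACTIONS:
        raise ValidationError(
            f"network has {r} reactions; enumerate_efms supports at most "
            f"{MAX_REACTIONS} (genome-scale enumeration is out of scope)"
        )
    NI = network.internal_stoichiometry
    Z = null_space(NI, rcond=RANK_TOL) if NI.shape[0] else np.eye(r)
    d = Z.shape[1]
    if d == 0:
        return []
    # constraints rows: Z[j, :] @ a >= 0  (i.e. v_j >= 0), a in R^d
    # initial simplicial cone from d independent rows (QR column pivoting)
    _, _, piv = scipy_qr(Z.T, pivoting=True)
    init_rows = sorted(int(p) for p in piv[:d])
    B0 = Z[init_rows, :]
    if np.linalg.matrix_rank(B0, tol=RANK_TOL) < d:
        raise NumericalError("could not find an independent starting basis")
    rays = [np.ascontiguousarray(col) for col in np.linalg.inv(B0).T]
    processed = list(init_rows)
    remaining = [j for j in range(r) if j not in init_rows]

    def _adjacent(a1: np.ndarray, a2: np.ndarray) -> bool:
        rows = [j for j in processed
                if abs(Z[j] @ a1) < RANK_TOL and abs(Z[j] @ a2) < RANK_TOL]
        if len(rows) < d - 2:
            return False
        if d - 2 <= 0:
            return True
        return np.linalg.matrix_rank(Z[rows, :], tol=RANK_TOL) >= d - 2

    for j in remaining:
        vals = np.array([Z[j] @ a for a in rays])
        scale = max(1.0, float(np.max(np.abs(vals))) if vals.size else 1.0)
        pos = [i for i, s in enumerate(vals) if s > RANK_TOL * scale]
        neg = [i for i, s in enumerate(vals) if s < -RANK_TOL * scale]
        zero = [i for i in range(len(rays)) if i not in pos and i not in neg]
        new_rays = [rays[i] for i in pos + zero]
        for p, n in itertools.product(pos, neg):
            if not _adjacent(rays[p], rays[n]):
                continue
            combo = vals[p] * rays[n] - vals[n] * rays[p]
            norm = np.linalg.norm(combo)
            if norm > 0:
                new_rays.append(combo / norm)
        rays = new_rays
        processed.append(j)

    v_rays = []
    for a in rays:
        v = Z @ a
        if np.max(np.abs(v)) < SUPPORT_TOL:
            continue
        v[np.abs(v) < RANK_TOL * np.max(np.abs(v))] = 0.0
        if np.min(v) < 0:
            continue  # violates some processed constraint beyond tolerance
        v_rays.append(v)
    return _sorted_efms(network, v_rays)


def enumerate_efms_bruteforce(network: MetabolicNetwork) -> list[EFM]:
    """Independent EFM oracle: exhaustive search over support subsets.

    A support carries an EFM iff the kernel of the corresponding stoichiometry
    submatrix is one-dimensional with a strictly positive (after sign choice)
    full-support vector; such vectors are automatically support-minimal.
    Exponential in ``r`` — restricted to networks with at most 12 reactions.
    """
    r = network.n_reactions
    if r > 12:
        raise ValidationError(
            f"enumerate_efms_bruteforce is exponential; r = {r} exceeds 12"
        )
    NI = network.internal_stoichiometry
    rays = []
    indices = range(r)
    for size in range(1, r + 1):
        for support in itertools.combinations(indices, size):
            vec = _kernel_ray_on_support(NI, support, r)
            if vec is not None:
                rays.append(vec)
    return _sorted_efms(network, rays)


def normalize_to_objective(efm: EFM, network: MetabolicNetwork) -> EFM:
    """Rescale an EFM so its objective entry equals 1 exactly."""
    obj = efm.values[network.objective_index]
    if obj == 0.0:
        raise ValidationError(
            f"EFM with support {sorted(efm.support)} carries no objective flux; "
            "cannot normalize to unit objective"
        )
    values = efm.values / obj
    values[network.objective_index] = 1.0
    return EFM(values=values, support=efm.support, has_objective=True)


def decompose_flux(
    network: MetabolicNetwork,
    v: FluxVector | np.ndarray,
    efms: list[EFM],
    tol: float = 1e-8,
) -> DecompositionResult:
    """Nonnegative least-squares decomposition of a steady-state flux into EFMs.

    Returns the ``lambda >= 0`` minimizing ``||sum_i lambda_i EFM^i - v||_2``.
    When several decompositions reproduce ``v`` exactly (more EFMs than
    reactions), the returned one is the NNLS solution and is not unique in
    general. A residual above ``tol * (1 + ||v||)`` flags failure of the
    in-cone certificate.
    """
    arr = _as_flux_array(network, v)
    if not check_steady_state(network, arr):
        raise ValidationError("flux vector is not a steady state of the network")
    if not efms:
        raise ValidationError("no EFMs supplied")
    E = np.column_stack([e.values for e in efms])
    lambdas, residual = nnls(E, arr)
    flagged = residual > tol * (1.0 + float(np.linalg.norm(arr)))
    result = DecompositionResult(lambdas=lambdas, residual=float(residual))
    if flagged:
        raise NumericalError(
            f"flux could not be decomposed into the supplied EFMs "
            f"(residual {residual:.3e}); in-cone certificate failed"
        )
    return result
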