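"""Seeded generator of random small kinetic models.

Instances have the structure the theory assumes: an irreversible network
with at least one external substrate and a designated objective reaction,
Michaelis-Menten-type kinetics, and K weighted enzyme pools. Networks are
built around a guaranteed backbone (uptake -> internal chain -> objective)
plus random sparse side reactions, then rejection-sampled until the model
validates: at least one objective EFM, every pool non-empty, and no
cost-free objective EFM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .efm import EFM, enumerate_efms
from .errors import ValidationError
from .kinetics import (
    ConstraintSet,
    KineticModel,
    ReactionKinetics,
    SaturationSpec,
)
from .network import MetabolicNetwork

__all__ = ["GeneratorConfig", "generate_instance"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Ranges and probabilities of the random-instance generator.

    Stoichiometric coefficients are drawn from ``stoich_values``; kcat and Km
    are log-uniform in ``kcat_range`` / ``km_range`` (model units); each
    reaction joins each pool with probability ``weight_sparsity``.
    """

    seed: int = 0
    n_internal: int = 3
    n_reactions: int = 6
    n_constraints: int = 2
    stoich_values: tuple[float, ...] = (-2.0, -1.0, 1.0, 2.0)
    kcat_range: tuple[float, float] = (0.1, 10.0)
    km_range: tuple[float, float] = (0.1, 10.0)
    weight_sparsity: float = 0.7
    max_attempts: int = 100
    max_efms: int = 40

    def __post_init__(self) -> None:
        if not (2 <= self.n_internal <= 6):
            raise ValidationError("n_internal must be in 2..6")
        if not (4 <= self.n_reactions <= 10):
            raise ValidationError("n_reactions must be in 4..10")
        if not (1 <= self.n_constraints <= 3):
            raise ValidationError("n_constraints must be in 1..3")
        if self.kcat_range[0] <= 0 or self.km_range[0] <= 0:
            raise ValidationError("kinetic ranges must be positive")
        if not (0.0 < self.weight_sparsity <= 1.0):
            raise ValidationError("weight_sparsity must be in (0, 1]")


def _log_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def _random_network(
    rng: np.random.Generator, cfg: GeneratorConfig
) -> MetabolicNetwork | None:
    ni = cfg.n_internal
    r = cfg.n_reactions
    met_ids = ["substrate_ext"] + [f"m{i}" for i in range(ni)] + ["product_ext"]
    is_external = {m: m.endswith("_ext") for m in met_ids}
    m_total = len(met_ids)
    N = np.zeros((m_total, r))
    # backbone: uptake substrate_ext -> m0; chain m_i -> m_{i+1}; objective m_last ->
    N[0, 0] = -1.0
    N[1, 0] = 1.0
    chain_len = min(ni - 1, r - 2)
    for j in range(chain_len):
        N[1 + j, 1 + j] = -1.0
        N[2 + j, 1 + j] = 1.0
    obj = r - 1
    N[1 + chain_len, obj] = -1.0
    N[m_total - 1, obj] = 1.0
    # random sparse side reactions in the remaining columns
    for j in range(1 + chain_len, r - 1):
        k_mets = int(rng.integers(2, 4))
        rows = rng.choice(m_total, size=k_mets, replace=False)
        for row in rows:
            N[row, j] = rng.choice(cfg.stoich_values)
        # ensure each side reaction both consumes and produces something
        if np.all(N[rows, j] > 0):
            N[rows[0], j] = -abs(N[rows[0], j])
        if np.all(N[rows, j] < 0):
            N[rows[-1], j] = abs(N[rows[-1], j])
    reaction_ids = (
        ["uptake"]
        + [f"chain_{j}" for j in range(chain_len)]
        + [f"side_{j}" for j in range(r - 2 - chain_len)]
        + ["objective"]
    )
    try:
        return MetabolicNetwork(
            metabolite_ids=tuple(met_ids),
            is_external=is_external,
            stoichiometry=N,
            reaction_ids=tuple(reaction_ids),
            objective_index=obj,
        )
    except ValidationError:
        return None


def _random_kinetics(
    rng: np.random.Generator, cfg: GeneratorConfig, network: MetabolicNetwork
) -> dict[str, ReactionKinetics]:
    """Saturation kinds drawn roughly 70/20/10 (MM / constant / MM+inhibition).

    A reaction consuming internal metabolites is never given ``constant``
    kinetics: without concentration feedback on its substrates the ODE
    steady state used by the brute-force oracle is generically unreachable.
    Such draws fall back to Michaelis-Menten over the reaction's substrates.
    """
    kinetics = {}
    for j, rid in enumerate(network.reaction_ids):
        col = network.stoichiometry[:, j]
        substrates = [
            network.metabolite_ids[i] for i in np.nonzero(col < 0)[0]
        ]
        internal_subs = [
            s for s in substrates if not network.is_external[s]
        ]
        products = [
            network.metabolite_ids[i]
            for i in np.nonzero(col > 0)[0]
            if not network.is_external[network.metabolite_ids[i]]
        ]
        kcat = _log_uniform(rng, *cfg.kcat_range)
        u = rng.random()
        if u < 0.2 and not internal_subs:
            spec = SaturationSpec(kind="constant")
        else:
            km = {s: _log_uniform(rng, *cfg.km_range) for s in substrates}
            if u >= 0.9 and products:
                spec = SaturationSpec(
                    kind="mm_product_inhibition",
                    substrate_ids=tuple(substrates),
                    Km=km,
                    inhibitor_id=str(rng.choice(products)),
                    Ki=_log_uniform(rng, *cfg.km_range),
                )
            else:
                spec = SaturationSpec(
                    kind="michaelis_menten", substrate_ids=tuple(substrates), Km=km
                )
        kinetics[rid] = ReactionKinetics(kcat=kcat, saturation=spec)
    return kinetics


def _random_constraints(
    rng: np.random.Generator, cfg: GeneratorConfig, efms: list[EFM]
) -> ConstraintSet | None:
    r = len(efms[0].values)
    K = cfg.n_constraints
    W = np.zeros((K, r))
    for k in range(K):
        mask = rng.random(r) < cfg.weight_sparsity
        if not mask.any():
            mask[rng.integers(0, r)] = True
        W[k, mask] = rng.uniform(0.2, 2.0, size=int(mask.sum()))
    # every EFM must use at least one pooled enzyme (no cost-free EFMs)
    for efm in efms:
        support = sorted(efm.support)
        if not np.any(W[:, support] > 0):
            W[rng.integers(0, K), support[int(rng.integers(0, len(support)))]] = (
                rng.uniform(0.2, 2.0)
            )
    bounds = rng.uniform(0.5, 2.0, size=K)
    try:
        return ConstraintSet(weights=W, bounds=bounds)
    except ValidationError:
        return None


def generate_instance(config: GeneratorConfig) -> KineticModel:
    """Generate a random valid kinetic model (deterministic per seed).

    Rejection-samples up to ``config.max_attempts`` candidate networks,
    advancing a sub-seed each attempt, until one validates with at least one
    objective-carrying EFM, a bounded EFM count, non-empty pools, and no
    cost-free objective EFM.
    """
    for attempt in range(config.max_attempts):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed).spawn(attempt + 1)[0]
        )
        network = _random_network(rng, config)
        if network is None:
            continue
        try:
            efms = enumerate_efms(network)
        except Exception:
            continue
        objective_efms = [e for e in efms if e.has_objective]
        if not objective_efms or len(efms) > config.max_efms:
            continue
        kinetics = _random_kinetics(rng, config, network)
        constraints = _random_constraints(rng, config, efms)
        if constraints is None:
            continue
        try:
            model = KineticModel(
                network=network, kinetics=kinetics, constraints=constraints
            )
        except ValidationError:
            continue
        return model
    raise ValidationError(
        f"no valid instance found in {config.max_attempts} attempts for {config}"
    )
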