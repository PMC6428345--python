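"""JSON model documents and tabular writers.

A model document is a JSON object with ``format_version``, ``metabolites``
(id + external flag), ``reactions`` (id, stoichiometry map, kcat, saturation
spec, objective flag — exactly one true) and ``constraints`` (id, weight map,
bound). Documents are written canonically (sorted keys, fixed indentation)
so equal models serialize byte-identically.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .costspace import CostMatrix
from .efm import EFM
from .errors import ValidationError
from .kinetics import (
    ConstraintSet,
    KineticModel,
    ReactionKinetics,
    SaturationSpec,
)
from .network import MetabolicNetwork

__all__ = [
    "FORMAT_VERSION",
    "read_model",
    "write_model",
    "model_to_document",
    "document_to_model",
    "write_efm_table",
    "write_cost_table",
    "write_sweep_table",
    "write_tables",
]

FORMAT_VERSION = "1.0"


# ---------------------------------------------------------------------------
# document <-> model
# ---------------------------------------------------------------------------


def model_to_document(model: KineticModel) -> dict:
    net = model.network
    metabolites = [
        {"id": mid, "external": bool(net.is_external[mid])}
        for mid in net.metabolite_ids
    ]
    reactions = []
    for j, rid in enumerate(net.reaction_ids):
        col = net.stoichiometry[:, j]
        stoich = {
            net.metabolite_ids[i]: float(col[i]) for i in np.nonzero(col)[0]
        }
        rk = model.kinetics[rid]
        sat: dict = {"kind": rk.saturation.kind}
        if rk.saturation.substrate_ids:
            sat["Km"] = {s: float(rk.saturation.Km[s]) for s in rk.saturation.substrate_ids}
        if rk.saturation.inhibitor_id is not None:
            sat["inhibitor_id"] = rk.saturation.inhibitor_id
            sat["Ki"] = float(rk.saturation.Ki)
        reactions.append(
            {
                "id": rid,
                "stoichiometry": stoich,
                "kcat": float(rk.kcat),
                "saturation": sat,
                "objective": j == net.objective_index,
            }
        )
    constraints = [
        {
            "id": pid,
            "weights": {
                net.reaction_ids[j]: float(model.constraints.weights[k, j])
                for j in np.nonzero(model.constraints.weights[k])[0]
            },
            "bound": float(model.constraints.bounds[k]),
        }
        for k, pid in enumerate(model.constraints.pool_ids)
    ]
    return {
        "format_version": FORMAT_VERSION,
        "metabolites": metabolites,
        "reactions": reactions,
        "constraints": constraints,
    }


def _require(cond: bool, message: str) -> None:
    if not cond:
        raise ValidationError(message)


def document_to_model(doc: dict) -> KineticModel:
    _require(isinstance(doc, dict), "model document must be a JSON object")
    for key in ("format_version", "metabolites", "reactions", "constraints"):
        _require(key in doc, f"model document missing field {key!r}")
    metabolites = doc["metabolites"]
    _require(
        isinstance(metabolites, list) and len(metabolites) > 0,
        "metabolites must be a non-empty list",
    )
    met_ids = []
    is_external = {}
    for entry in metabolites:
        _require(
            isinstance(entry, dict) and "id" in entry and "external" in entry,
            f"malformed metabolite entry: {entry!r}",
        )
        met_ids.append(str(entry["id"]))
        is_external[str(entry["id"])] = bool(entry["external"])

    reactions = doc["reactions"]
    _require(
        isinstance(reactions, list) and len(reactions) > 0,
        "reactions must be a non-empty list",
    )
    rxn_ids = []
    cols = []
    kinetics = {}
    objective_ids = []
    for entry in reactions:
        _require(
            isinstance(entry, dict) and "id" in entry and "stoichiometry" in entry,
            f"malformed reaction entry: {entry!r}",
        )
        rid = str(entry["id"])
        rxn_ids.append(rid)
        col = np.zeros(len(met_ids))
        for mid, coeff in dict(entry["stoichiometry"]).items():
            _require(
                mid in is_external,
                f"reaction {rid!r} references unknown metabolite {mid!r}",
            )
            col[met_ids.index(mid)] = float(coeff)
        cols.append(col)
        kcat = float(entry.get("kcat", 0.0))
        _require(kcat > 0, f"reaction {rid!r} needs a positive kcat (got {kcat})")
        sat_doc = entry.get("saturation", {"kind": "constant"})
        kind = str(sat_doc.get("kind", "constant"))
        km = {str(k): float(v) for k, v in dict(sat_doc.get("Km", {})).items()}
        for s, v in km.items():
            _require(v > 0, f"reaction {rid!r}: Km for {s!r} must be positive")
        ki = sat_doc.get("Ki")
        _require(
            ki is None or float(ki) > 0, f"reaction {rid!r}: Ki must be positive"
        )
        try:
            sat = SaturationSpec(
                kind=kind,
                substrate_ids=tuple(km.keys()),
                Km=km,
                inhibitor_id=sat_doc.get("inhibitor_id"),
                Ki=None if ki is None else float(ki),
            )
        except ValidationError as exc:
            raise ValidationError(f"reaction {rid!r}: {exc}") from None
        kinetics[rid] = ReactionKinetics(kcat=kcat, saturation=sat)
        if entry.get("objective", False):
            objective_ids.append(rid)
    _require(
        len(objective_ids) == 1,
        f"exactly one objective reaction required (got {objective_ids or 'none'})",
    )

    constraints_doc = doc["constraints"]
    _require(
        isinstance(constraints_doc, list) and len(constraints_doc) > 0,
        "constraints must be a non-empty list",
    )
    K = len(constraints_doc)
    W = np.zeros((K, len(rxn_ids)))
    bounds = np.zeros(K)
    pool_ids = []
    for k, entry in enumerate(constraints_doc):
        _require(
            isinstance(entry, dict) and "weights" in entry and "bound" in entry,
            f"malformed constraint entry: {entry!r}",
        )
        pool_ids.append(str(entry.get("id", f"pool_{k}")))
        bound = float(entry["bound"])
        _require(bound > 0, f"constraint {pool_ids[-1]!r}: bound must be positive")
        bounds[k] = bound
        for rid, w in dict(entry["weights"]).items():
            _require(
                rid in rxn_ids,
                f"constraint {pool_ids[-1]!r} references unknown reaction {rid!r}",
            )
            _require(
                float(w) >= 0,
                f"constraint {pool_ids[-1]!r}: weight for {rid!r} must be >= 0",
            )
            W[k, rxn_ids.index(rid)] = float(w)

    network = MetabolicNetwork(
        metabolite_ids=tuple(met_ids),
        is_external=is_external,
        stoichiometry=np.column_stack(cols),
        reaction_ids=tuple(rxn_ids),
        objective_index=rxn_ids.index(objective_ids[0]),
    )
    constraint_set = ConstraintSet(weights=W, bounds=bounds, pool_ids=tuple(pool_ids))
    return KineticModel(network=network, kinetics=kinetics, constraints=constraint_set)


def read_model(path: str | Path) -> KineticModel:
    """Load and validate a JSON model document."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"model file not found: {path}")
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValidationError(f"{path}: not valid JSON ({exc})") from None
    return document_to_model(doc)


def write_model(model: KineticModel, path: str | Path) -> None:
    """Write a model canonically (sorted keys; equal models -> equal bytes)."""
    doc = model_to_document(model)
    Path(path).write_text(json.dumps(doc, sort_keys=True, indent=2) + "\n")


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------


def write_efm_table(
    efms: Sequence[EFM], network: MetabolicNetwork, path: str | Path
) -> None:
    """EFM matrix as TSV: reactions as rows, EFMs as columns."""
    ids = [f"efm_{'+'.join(str(j) for j in sorted(e.support))}" for e in efms]
    frame = pd.DataFrame(
        {eid: e.values for eid, e in zip(ids, efms)},
        index=list(network.reaction_ids),
    )
    frame.index.name = "reaction"
    frame.to_csv(path, sep="\t")


def write_cost_table(cost: CostMatrix, path: str | Path) -> None:
    """Cost matrix as TSV: pools as rows, EFMs as columns."""
    frame = pd.DataFrame(cost.D, index=list(cost.pool_ids), columns=list(cost.efm_ids))
    frame.index.name = "pool"
    frame.to_csv(path, sep="\t")


def write_sweep_table(sweep, path: str | Path) -> None:
    """Sweep table as CSV with the documented column order."""
    sweep.frame.to_csv(path, index=False)


def write_tables(obj, path: str | Path, network: MetabolicNetwork | None = None) -> None:
    """Dispatch on object type: EFM list, cost matrix or sweep table."""
    from .casestudies import SweepTable

    if isinstance(obj, CostMatrix):
        write_cost_table(obj, path)
    elif isinstance(obj, SweepTable):
        write_sweep_table(obj, path)
    elif isinstance(obj, (list, tuple)) and obj and isinstance(obj[0], EFM):
        if network is None:
            raise ValidationError("writing an EFM table requires the network")
        write_efm_table(obj, network, path)
    else:
        raise ValidationError(f"cannot write object of type {type(obj).__name__}")
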