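"""JSON-friendly (de)serialization of protocell types and networks.

Used by configuration files, run exports (types.json) and engine checkpoints.
"""

from __future__ import annotations

import numpy as np

from .core import MetabolicNetwork, ProtocellType
from .regulation import RegulatoryNetwork

__all__ = ["network_to_dict", "network_from_dict", "type_to_dict",
           "type_from_dict"]


def network_to_dict(net: RegulatoryNetwork | None) -> dict | None:
    if net is None:
        return None
    return {
        "w_in": net.w_in.tolist(),
        "b_hidden": net.b_hidden.tolist(),
        "w_out": net.w_out.tolist(),
        "b_out": net.b_out.tolist(),
        "decay": net.decay.tolist(),
        "k_tau": net.k_tau,
    }


def network_from_dict(data: dict | None) -> RegulatoryNetwork | None:
    if data is None:
        return None
    return RegulatoryNetwork(
        w_in=np.asarray(data["w_in"], float),
        b_hidden=np.asarray(data["b_hidden"], float),
        w_out=np.asarray(data["w_out"], float),
        b_out=np.asarray(data["b_out"], float),
        decay=np.asarray(data["decay"], float),
        k_tau=float(data.get("k_tau", 0.01)),
    )


def type_to_dict(t: ProtocellType) -> dict:
    return {
        "type_id": t.type_id,
        "parent_id": t.parent_id,
        "birth_time": t.birth_time,
        "diet": list(t.metabolism.nutrient_set),
        "byproducts": list(t.metabolism.byproduct_set),
        "weights": t.metabolism.weights.tolist(),
        "enzymes": t.enzymes.tolist(),
        "enzyme_costs": t.enzyme_costs.tolist(),
        "maintenance": t.maintenance,
        "e_budget": t.e_budget,
        "budget_weights": t.budget_weights.tolist(),
        "reg_enabled": t.reg_enabled,
        "regulation": network_to_dict(t.regulation),
    }


def type_from_dict(data: dict) -> ProtocellType:
    return ProtocellType(
        type_id=int(data["type_id"]),
        parent_id=None if data.get("parent_id") is None else int(data["parent_id"]),
        birth_time=float(data.get("birth_time", 0.0)),
        metabolism=MetabolicNetwork(
            tuple(data["diet"]), tuple(data["byproducts"]),
            np.asarray(data["weights"], float),
        ),
        enzymes=np.asarray(data["enzymes"], float),
        enzyme_costs=np.asarray(data["enzyme_costs"], float),
        maintenance=float(data["maintenance"]),
        e_budget=float(data["e_budget"]),
        budget_weights=np.asarray(data["budget_weights"], float),
        regulation=network_from_dict(data.get("regulation")),
        reg_enabled=bool(data.get("reg_enabled", False)),
    )
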