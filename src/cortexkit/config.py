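"""YAML configuration for the surrogate network and experiments."""

from __future__ import annotations

from pathlib import Path

import yaml

from .background import OUInjectionTable, OUParams
from .network import (LAYER_DEPTHS, POPULATIONS, NeuronParams, PopulationSpec,
                      build_surrogate, default_populations)
from .synapses import DEFAULT_PATHWAYS, TMSynapseParams


def default_config() -> dict:
    """A complete configuration for the default 9 x 200 surrogate."""
    return {
        "populations": {"n_per_pop": 200},
        "connectivity": {"p_conn": 0.05, "nsyn_mean": 1.0,
                         "delay_range_ms": [1.0, 3.0]},
        "synapses": {lab: _tm_to_dict(p) for lab, p in DEFAULT_PATHWAYS.items()},
        "meta": {"calcium_Cao": 1.05, "R_OU": 0.4, "P_FR": 0.3},
        "ou": {},   # population -> {OU_mu, OU_sigma}
        "simulation": {"dt": 0.1, "duration": 1000.0},
    }


def _tm_to_dict(p: TMSynapseParams) -> dict:
    return {"ghat_nS": p.peak_conductance, "U_SE": p.release_prob,
            "D_ms": p.depression_tau, "F_ms": p.facilitation_tau,
            "tau_decay_ms": p.decay_tau, "N_RRP": int(p.vesicle_pool),
            "U_Hill": p.hill_coefficient, "ghat_ratio": p.conductance_ratio,
            "spontaneous_rate_Hz": p.spontaneous_rate}


def _tm_from_dict(d: dict) -> TMSynapseParams:
    return TMSynapseParams(
        peak_conductance=d["ghat_nS"], release_prob=d["U_SE"],
        depression_tau=d["D_ms"], facilitation_tau=d["F_ms"],
        decay_tau=d["tau_decay_ms"], vesicle_pool=int(d.get("N_RRP", 1)),
        hill_coefficient=d.get("U_Hill", 2.0),
        conductance_ratio=d.get("ghat_ratio", 0.0),
        spontaneous_rate=d.get("spontaneous_rate_Hz", 0.0))


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    base = default_config()
    for key, val in cfg.items():
        if isinstance(val, dict) and key in base and isinstance(base[key], dict):
            base[key].update(val)
        else:
            base[key] = val
    return base


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def network_from_config(cfg: dict, seed: int = 0):
    pops = default_populations(n_per_pop=int(cfg["populations"]["n_per_pop"]))
    rule = dict(cfg["connectivity"])
    if "delay_range_ms" in rule:
        rule["delay_range_ms"] = tuple(rule["delay_range_ms"])
    rule["pathway_params"] = {lab: _tm_from_dict(d)
                              for lab, d in cfg["synapses"].items()}
    return build_surrogate(pops, rule, seed=seed)


def ou_table_from_config(cfg: dict) -> OUInjectionTable | None:
    ou = cfg.get("ou") or {}
    if not ou:
        return None
    r_ou = cfg.get("meta", {}).get("R_OU", 0.4)
    params = {pop: OUParams(OU_mu=d["OU_mu"], OU_sigma=d["OU_sigma"])
              for pop, d in ou.items()}
    return OUInjectionTable(params=params, R_OU=r_ou)


def ou_table_to_config(table: OUInjectionTable) -> dict:
    return {pop: {"OU_mu": float(p.OU_mu), "OU_sigma": float(p.OU_sigma)}
            for pop, p in table.params.items()}
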