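"""Stochastic multivesicular Tsodyks-Markram synapse model.

Each connection holds a pool of release-ready vesicles. A presynaptic action
potential lets every available vesicle release independently with probability
``u``, which facilitates on each spike and relaxes back between spikes;
released vesicles recover independently with the depression time constant.
The utilization parameter is scaled by extracellular calcium through a
Hill-type relation, normalised so that the in-vitro reference condition
(2.0 mM) reproduces the nominal release probability ``U_SE``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

#: In-vitro reference calcium concentration (mM) at which U_SE was measured.
CA_REFERENCE_MM = 2.0

#: Default half-saturation constant of the Hill scaling (mM). Not a measured
#: quantity; exposed as configuration (see docs/methods.md).
CA_HILL_K_DEFAULT = 2.5


@dataclass(frozen=True)
class TMSynapseParams:
    """Parameters of one synaptic pathway.

    Conductances in nS, time constants in ms, rates in Hz.
    ``conductance_ratio`` is the NMDA/AMPA peak-conductance ratio for
    excitatory pathways (GABA_B/GABA_A for inhibitory ones, unused unless the
    slow GABA_B component is enabled).
    """

    peak_conductance: float  # ghat, nS per released vesicle
    release_prob: float      # U_SE in (0, 1]
    depression_tau: float    # D, ms (vesicle recovery)
    facilitation_tau: float  # F, ms (decay of facilitation)
    decay_tau: float         # PSC decay time constant, ms
    vesicle_pool: int = 1    # N_RRP, vesicles per synapse
    hill_coefficient: float = 2.0   # U_Hill
    conductance_ratio: float = 0.0  # ghat_ratio
    spontaneous_rate: float = 0.0   # Hz per synapse

    def __post_init__(self) -> None:
        if not (0.0 < self.release_prob <= 1.0):
            raise ValueError(f"release_prob must be in (0, 1], got {self.release_prob}")
        for name in ("depression_tau", "facilitation_tau", "decay_tau"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if int(self.vesicle_pool) < 1 or self.vesicle_pool != int(self.vesicle_pool):
            raise ValueError("vesicle_pool must be an integer >= 1")
        if self.peak_conductance < 0 or self.spontaneous_rate < 0:
            raise ValueError("conductance and spontaneous rate must be >= 0")


def hill_scaled_use(params: TMSynapseParams, calcium_mM: float,
                    k_half: float = CA_HILL_K_DEFAULT) -> float:
    """Calcium-scaled utilization U_eff.

    Hill-type, monotone increasing in calcium, normalised so that
    ``U_eff(2.0 mM) == release_prob``. Clipped at 1.
    """
    if calcium_mM <= 0:
        raise ValueError("calcium must be > 0")
    h = params.hill_coefficient

    def _hill(ca: float) -> float:
        return ca ** h / (ca ** h + k_half ** h)

    u = params.release_prob * _hill(calcium_mM) / _hill(CA_REFERENCE_MM)
    return min(u, 1.0)


@dataclass
class TMState:
    """Per-connection release state (event-driven; updated at spikes)."""

    unavailable: int = 0        # vesicles currently recovering
    u: float = 0.0              # facilitation variable after the last spike
    last_time: float = -1e12    # time of last update, ms

    def available(self, pool_size: int) -> int:
        return pool_size - self.unavailable


def tm_release_step(state: TMState, spike_time: float, params: TMSynapseParams,
                    calcium_mM: float, rng: np.random.Generator,
                    pool_size: int | None = None,
                    k_half: float = CA_HILL_K_DEFAULT) -> tuple[int, TMState]:
    """Process one presynaptic spike; return (released vesicles, new state).

    ``pool_size`` defaults to ``params.vesicle_pool``; passing a larger value
    models several synapses of one connection sharing a spike train.

    The facilitation recursion is ``u_+ = U_eff + u (1 - U_eff) exp(-dt/F)``,
    so the first spike releases with probability exactly U_eff and, after long
    intervals, u relaxes back to U_eff. Each released vesicle recovers
    independently with probability ``1 - exp(-dt/D)`` per inter-spike interval.
    """
    pool = int(params.vesicle_pool if pool_size is None else pool_size)
    if state.unavailable < 0 or state.unavailable > pool:
        raise ValueError(f"corrupt state: unavailable={state.unavailable}, pool={pool}")
    u_eff = hill_scaled_use(params, calcium_mM, k_half=k_half)
    dt = spike_time - state.last_time

    recovered = rng.binomial(state.unavailable, 1.0 - math.exp(-dt / params.depression_tau)) \
        if state.unavailable > 0 else 0
    unavailable = state.unavailable - int(recovered)
    u = u_eff + state.u * (1.0 - u_eff) * math.exp(-dt / params.facilitation_tau)
    available = pool - unavailable
    released = int(rng.binomial(available, u)) if available > 0 else 0
    new_state = TMState(unavailable=unavailable + released, u=u, last_time=spike_time)
    return released, new_state


def biexp_normalization(tau_rise: float, tau_decay: float) -> float:
    """Amplitude factor so a difference-of-exponentials transient peaks at 1.

    g(t) = f * (exp(-t/tau_decay) - exp(-t/tau_rise)) with
    f = 1 / (exp(-tp/tau_decay) - exp(-tp/tau_rise)) at the analytic peak time.
    """
    if not (0 < tau_rise < tau_decay):
        raise ValueError("need 0 < tau_rise < tau_decay")
    tp = (tau_rise * tau_decay) / (tau_decay - tau_rise) * math.log(tau_decay / tau_rise)
    return 1.0 / (math.exp(-tp / tau_decay) - math.exp(-tp / tau_rise))


# Pathway-class defaults for the surrogate network. Values are typical cortical
# short-term-plasticity phenotypes: depressing E->E and E->I (PV-like),
# depressing I->E / I->I GABA_A. Conductances are chosen for a stable,
# asynchronous surrogate at p_conn = 0.05 (see docs/methods.md).
DEFAULT_PATHWAYS: dict[str, TMSynapseParams] = {
    "E->E": TMSynapseParams(peak_conductance=0.30, release_prob=0.50,
                            depression_tau=670.0, facilitation_tau=17.0,
                            decay_tau=1.7, vesicle_pool=1, hill_coefficient=2.0,
                            conductance_ratio=0.8),
    "E->I": TMSynapseParams(peak_conductance=0.40, release_prob=0.70,
                            depression_tau=550.0, facilitation_tau=17.0,
                            decay_tau=0.7, vesicle_pool=1, hill_coefficient=2.0,
                            conductance_ratio=0.4),
    "I->E": TMSynapseParams(peak_conductance=1.00, release_prob=0.25,
                            depression_tau=700.0, facilitation_tau=21.0,
                            decay_tau=8.0, vesicle_pool=1, hill_coefficient=1.5),
    "I->I": TMSynapseParams(peak_conductance=0.80, release_prob=0.25,
                            depression_tau=700.0, facilitation_tau=21.0,
                            decay_tau=8.0, vesicle_pool=1, hill_coefficient=1.5),
}


def replace_pathway(params: TMSynapseParams, **kwargs) -> TMSynapseParams:
    """Return a copy of ``params`` with fields replaced."""
    return replace(params, **kwargs)
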