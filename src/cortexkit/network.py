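"""Surrogate layered network: populations, connectome, spike recordings.

A seeded point-neuron stand-in for a morphologically detailed cortical
column: nine layer-wise excitatory and inhibitory populations connected by a
sparse directed synaptic graph whose pathways carry stochastic multivesicular
Tsodyks-Markram parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .synapses import DEFAULT_PATHWAYS, TMSynapseParams

#: Canonical population order used by firing-rate vectors throughout.
POPULATIONS: tuple[str, ...] = (
    "L1_I", "L23_E", "L23_I", "L4_E", "L4_I", "L5_E", "L5_I", "L6_E", "L6_I",
)

#: Layer depth ranges in um below the pial surface (rat S1-like).
LAYER_DEPTHS: dict[str, tuple[float, float]] = {
    "L1": (0.0, 165.0),
    "L23": (165.0, 665.0),
    "L4": (665.0, 865.0),
    "L5": (865.0, 1265.0),
    "L6": (1265.0, 1890.0),
}


@dataclass(frozen=True)
class NeuronParams:
    """Leaky integrate-and-fire parameters (pF, nS, mV, ms)."""

    membrane_capacitance: float = 200.0
    leak_conductance: float = 10.0
    leak_reversal: float = -70.0
    spike_threshold: float = -50.0
    reset_potential: float = -60.0
    refractory: float = 2.0
    excitatory_reversal: float = 0.0
    inhibitory_reversal: float = -80.0
    threshold_jitter_sd: float = 3.0  # per-neuron spike-threshold spread, mV

    def __post_init__(self) -> None:
        if self.leak_conductance <= 0:
            raise ValueError("leak_conductance must be > 0")
        if self.reset_potential >= self.spike_threshold:
            raise ValueError("reset_potential must be below spike_threshold")


@dataclass(frozen=True)
class PopulationSpec:
    name: str
    synapse_class: str  # "E" or "I"
    count: int
    depth_range: tuple[float, float]
    neuron_params: NeuronParams = field(default_factory=NeuronParams)
    subpopulation: str = "none"  # PV | Sst | 5HT3aR | none, I only

    def __post_init__(self) -> None:
        if self.count <= 0:
            raise ValueError("population count must be > 0")
        if self.synapse_class not in ("E", "I"):
            raise ValueError("synapse_class must be 'E' or 'I'")
        lo, hi = self.depth_range
        if not lo < hi:
            raise ValueError("depth_range must be ordered (lo < hi)")
        if self.subpopulation != "none" and self.synapse_class != "I":
            raise ValueError("subpopulation labels apply to inhibitory populations only")


def default_populations(n_per_pop: int = 200) -> list[PopulationSpec]:
    """The nine layer-wise E/I populations of the surrogate column."""
    e_params = NeuronParams()
    i_params = NeuronParams(membrane_capacitance=100.0, leak_conductance=8.0,
                            refractory=1.5)
    subpop = {"L1_I": "5HT3aR", "L23_I": "PV", "L4_I": "PV",
              "L5_I": "Sst", "L6_I": "PV"}
    pops = []
    for name in POPULATIONS:
        layer, cls = name.rsplit("_", 1)
        pops.append(PopulationSpec(
            name=name, synapse_class=cls, count=n_per_pop,
            depth_range=LAYER_DEPTHS[layer],
            neuron_params=e_params if cls == "E" else i_params,
            subpopulation=subpop.get(name, "none"),
        ))
    return pops


@dataclass
class Connectome:
    """Sparse directed synaptic graph with per-pathway synapse parameters."""

    pre: np.ndarray        # int64, presynaptic neuron ids
    post: np.ndarray       # int64
    nsyn: np.ndarray       # int64, synapses per connection (>= 1)
    delay_ms: np.ndarray   # float64, > 0
    pathway: np.ndarray    # int64 index into pathway_labels
    pathway_labels: list[str]
    pathway_params: dict[str, TMSynapseParams]
    n_neurons: int

    def __post_init__(self) -> None:
        n = len(self.pre)
        for arr in (self.post, self.nsyn, self.delay_ms, self.pathway):
            if len(arr) != n:
                raise ValueError("edge arrays must have equal length")
        if n and np.any(self.pre == self.post):
            raise ValueError("self-edges are not allowed")
        if n and np.any(self.delay_ms <= 0):
            raise ValueError("delays must be > 0")
        for lab in self.pathway_labels:
            if lab not in self.pathway_params:
                raise ValueError(f"pathway '{lab}' has no parameters")

    @property
    def n_edges(self) -> int:
        return len(self.pre)

    @property
    def total_synapses(self) -> int:
        return int(self.nsyn.sum())

    def copy(self) -> "Connectome":
        return Connectome(self.pre.copy(), self.post.copy(), self.nsyn.copy(),
                          self.delay_ms.copy(), self.pathway.copy(),
                          list(self.pathway_labels), dict(self.pathway_params),
                          self.n_neurons)

    def subset(self, keep: np.ndarray) -> "Connectome":
        return Connectome(self.pre[keep], self.post[keep], self.nsyn[keep],
                          self.delay_ms[keep], self.pathway[keep],
                          list(self.pathway_labels), dict(self.pathway_params),
                          self.n_neurons)


@dataclass
class Network:
    """Populations plus connectome plus per-neuron placement."""

    populations: list[PopulationSpec]
    connectome: Connectome
    depth_um: np.ndarray   # per-neuron cortical depth
    pop_index: np.ndarray  # per-neuron index into populations
    vth_offset_mV: np.ndarray | None = None  # per-neuron threshold jitter

    @property
    def n_neurons(self) -> int:
        return len(self.depth_um)

    @property
    def population_names(self) -> list[str]:
        return [p.name for p in self.populations]

    def neurons_of(self, population: str) -> np.ndarray:
        idx = self.population_names.index(population)
        return np.flatnonzero(self.pop_index == idx)

    def population_of(self, neuron_id: int) -> str:
        return self.populations[self.pop_index[neuron_id]].name


@dataclass
class SimulationConfig:
    dt: float = 0.1               # ms
    duration: float = 1000.0      # ms
    calcium_Cao: float = 1.1      # mM
    seed: int = 0
    record_voltages: tuple = ()   # neuron ids

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.duration <= 0:
            raise ValueError("dt and duration must be > 0")
        if not (0.5 <= self.calcium_Cao <= 3.0):
            raise ValueError("calcium outside biological range")


@dataclass
class SpikeRecording:
    """Timestamped spikes plus the population identity of each neuron."""

    neuron_ids: np.ndarray
    times_ms: np.ndarray
    duration: float
    pop_index: np.ndarray       # per-neuron population index
    pop_labels: list[str]

    def __post_init__(self) -> None:
        if len(self.times_ms) and (self.times_ms.min() < 0
                                   or self.times_ms.max() >= self.duration):
            raise ValueError("spike times must lie in [0, duration)")
        if len(self.times_ms) > 1 and np.any(np.diff(self.times_ms) < 0):
            order = np.argsort(self.times_ms, kind="stable")
            self.times_ms = self.times_ms[order]
            self.neuron_ids = self.neuron_ids[order]

    @property
    def n_spikes(self) -> int:
        return len(self.times_ms)

    def population_spikes(self, population: str) -> np.ndarray:
        """Spike times of all neurons of one population."""
        pidx = self.pop_labels.index(population)
        mask = self.pop_index[self.neuron_ids] == pidx
        return self.times_ms[mask]

    def population_rates(self, t_start: float = 0.0,
                         t_stop: float | None = None) -> np.ndarray:
        """Mean rate (Hz) per population over [t_start, t_stop)."""
        t_stop = self.duration if t_stop is None else t_stop
        span_s = (t_stop - t_start) / 1000.0
        counts = np.zeros(len(self.pop_labels))
        in_win = (self.times_ms >= t_start) & (self.times_ms < t_stop)
        pop_of_spike = self.pop_index[self.neuron_ids[in_win]]
        np.add.at(counts, pop_of_spike, 1)
        n_per_pop = np.bincount(self.pop_index, minlength=len(self.pop_labels))
        with np.errstate(invalid="ignore", divide="ignore"):
            rates = counts / (np.maximum(n_per_pop, 1) * span_s)
        return rates

    def neuron_rates(self, t_start: float = 0.0,
                     t_stop: float | None = None) -> np.ndarray:
        t_stop = self.duration if t_stop is None else t_stop
        span_s = (t_stop - t_start) / 1000.0
        in_win = (self.times_ms >= t_start) & (self.times_ms < t_stop)
        counts = np.bincount(self.neuron_ids[in_win], minlength=len(self.pop_index))
        return counts / span_s


def build_surrogate(populations: list[PopulationSpec],
                    connectivity_rule: dict | None = None,
                    seed: int = 0) -> Network:
    """Build the seeded surrogate network.

    ``connectivity_rule`` keys (all optional):
      p_conn           scalar connection probability, or dict
                       {(pre_pop, post_pop): p} with a "default" fallback
      nsyn_mean        mean synapses per connection (>= 1; 1 + Poisson(mean-1))
      delay_range_ms   (lo, hi) uniform conduction delays
      pathway_params   map "E->E"-style labels to TMSynapseParams

    Deterministic for a given seed. Pathway labels are assigned as
    pre-synapse-class -> post-synapse-class.
    """
    if not populations:
        raise ValueError("empty population list")
    rule = dict(connectivity_rule or {})
    p_conn = rule.get("p_conn", 0.05)
    nsyn_mean = float(rule.get("nsyn_mean", 1.0))
    delay_lo, delay_hi = rule.get("delay_range_ms", (1.0, 3.0))
    pathway_params = dict(rule.get("pathway_params", DEFAULT_PATHWAYS))

    rng = np.random.default_rng(seed)
    counts = [p.count for p in populations]
    offsets = np.concatenate([[0], np.cumsum(counts)])
    n_total = int(offsets[-1])

    pop_index = np.repeat(np.arange(len(populations)), counts)
    depth_um = np.empty(n_total)
    vth_offset = np.zeros(n_total)
    for i, p in enumerate(populations):
        lo, hi = p.depth_range
        depth_um[offsets[i]:offsets[i + 1]] = rng.uniform(lo, hi, p.count)
        sd = p.neuron_params.threshold_jitter_sd
        if sd > 0:
            # truncated at 2 SD so no threshold falls near the reset potential
            vth_offset[offsets[i]:offsets[i + 1]] = np.clip(
                rng.normal(0.0, sd, p.count), -2.0 * sd, 2.0 * sd)

    labels = sorted({f"{a.synapse_class}->{b.synapse_class}"
                     for a in populations for b in populations})
    for lab in labels:
        if lab not in pathway_params:
            raise ValueError(f"no synapse parameters for pathway '{lab}'")
    lab_index = {lab: k for k, lab in enumerate(labels)}

    pre_list, post_list, path_list = [], [], []
    for i, a in enumerate(populations):
        for j, b in enumerate(populations):
            if isinstance(p_conn, dict):
                p = p_conn.get((a.name, b.name), p_conn.get("default", 0.0))
            else:
                p = float(p_conn)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"connection probability {p} outside [0, 1]")
            if p == 0.0:
                continue
            # Bernoulli over the full block, self-edges removed afterwards.
            block = rng.random((a.count, b.count)) < p
            if i == j:
                np.fill_diagonal(block, False)
            pr, po = np.nonzero(block)
            if len(pr) == 0:
                continue
            pre_list.append(pr + offsets[i])
            post_list.append(po + offsets[j])
            path_list.append(np.full(len(pr),
                                     lab_index[f"{a.synapse_class}->{b.synapse_class}"],
                                     dtype=np.int64))

    if pre_list:
        pre = np.concatenate(pre_list)
        post = np.concatenate(post_list)
        pathway = np.concatenate(path_list)
    else:
        pre = np.empty(0, dtype=np.int64)
        post = np.empty(0, dtype=np.int64)
        pathway = np.empty(0, dtype=np.int64)

    n_edges = len(pre)
    nsyn = np.ones(n_edges, dtype=np.int64)
    if nsyn_mean > 1.0:
        nsyn += rng.poisson(nsyn_mean - 1.0, n_edges)
    delay = rng.uniform(delay_lo, delay_hi, n_edges)

    conn = Connectome(pre=pre, post=post, nsyn=nsyn, delay_ms=delay,
                      pathway=pathway, pathway_labels=labels,
                      pathway_params=pathway_params, n_neurons=n_total)
    return Network(populations=list(populations), connectome=conn,
                   depth_um=depth_um, pop_index=pop_index,
                   vth_offset_mV=vth_offset)


def disconnect(obj: Network | Connectome) -> Network | Connectome:
    """Copy with all recurrent edges removed (external hooks untouched)."""
    if isinstance(obj, Network):
        return replace(obj, connectome=disconnect(obj.connectome))
    empty = np.empty(0, dtype=np.int64)
    return Connectome(pre=empty, post=empty.copy(), nsyn=empty.copy(),
                      delay_ms=np.empty(0), pathway=empty.copy(),
                      pathway_labels=list(obj.pathway_labels),
                      pathway_params=dict(obj.pathway_params),
                      n_neurons=obj.n_neurons)
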