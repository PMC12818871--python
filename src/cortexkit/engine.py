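"""Fixed-step network simulation engine.

Conductance-based leaky integrate-and-fire dynamics with exponential-Euler
integration (default dt = 0.1 ms), stochastic multivesicular Tsodyks-Markram
synapses, bi-exponential postsynaptic conductances (AMPA + voltage-dependent
NMDA on excitatory pathways, GABA_A on inhibitory ones), per-neuron
Ornstein-Uhlenbeck background conductance injection, somatic step currents,
and external conductance events (thalamic fibers).

The inner loop is compiled with numba; all randomness derives from a single
integer seed, so spike tables are bit-identical across runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .background import OUInjectionTable
from .network import Network, SimulationConfig, SpikeRecording
from .synapses import CA_HILL_K_DEFAULT, biexp_normalization, hill_scaled_use

# Receptor kinetics not carried by the pathway tables (ms / mM).
TAU_RISE_AMPA = 0.2
TAU_RISE_NMDA = 2.9
TAU_DECAY_NMDA = 43.0
TAU_RISE_GABA = 0.25
MG_CONC_DEFAULT = 1.0   # mM
MG_K = 3.57             # Jahr-Stevens block: 1/(1 + mg/MG_K * exp(-MG_GAMMA V))
MG_GAMMA = 0.062        # 1/mV


class SpikeOverflowError(RuntimeError):
    """Spike buffer exhausted: runaway (bursting-like) activity."""


class NumericalDivergenceError(RuntimeError):
    """A membrane state became non-finite during integration."""


@dataclass
class StepCurrent:
    """Square somatic current pulse with a linear ramp-down at offset."""

    amplitude_nA: np.ndarray  # per neuron
    onset_ms: float
    offset_ms: float
    ramp_ms: float = 0.0


@dataclass
class ExternalEvents:
    """Pre-scheduled conductance quanta (e.g. thalamic fiber releases).

    Weights are peak conductances in nS added to the AMPA (and optionally
    NMDA) channel of the target neuron at the given time.
    """

    times_ms: np.ndarray
    post: np.ndarray
    weight_ampa: np.ndarray
    weight_nmda: np.ndarray | None = None


@njit(inline="always")
def _fast_expm(x):
    # exp(-x) for small non-negative x (membrane integration factor)
    if x < 0.2:
        return 1.0 - x * (1.0 - x * (0.5 - x * (1.0 / 6.0 - x / 24.0)))
    return math.exp(-x)


@njit(cache=True)
def _run_core(seed, n_steps, dt,
              # neurons
              C, gL, EL, Vth, Vreset, Ee, Ei, ref_steps,
              # CSR connectivity (by presynaptic neuron)
              indptr, e_post, e_pool, e_delay, e_u, e_D, e_F,
              e_w_ampa, e_w_nmda, e_is_gaba,
              # synapse state
              syn_unavail, syn_fac, syn_last,
              # channel decay factors per neuron
              dAr_a, dAd_a, dAr_n, dAd_n, dAr_g, dAd_g,
              # ring buffers
              L, buf_a, buf_n, buf_g,
              # OU (decay/fluct computed for ou_stride * dt)
              ou_g0, ou_decay, ou_fluct, E_ou, ou_stride,
              # Mg block lookup over V (index (V + 120) / 0.05)
              mg_table,
              # currents (pA)
              I_hold, I_amp, i_on, i_off, i_ramp_steps,
              # external events, sorted by step
              ev_step, ev_post, ev_wa, ev_wn,
              # spontaneous release events, sorted by step
              sp_step, sp_edge,
              # recording
              rec_map, V_rec,
              # spike output
              spk_t, spk_id):
    np.random.seed(seed)
    n = C.shape[0]
    V = EL.copy()
    refr = np.zeros(n, dtype=np.int64)
    # rise (A) / decay (B) states per channel
    Aa = np.zeros(n); Ba = np.zeros(n)
    An = np.zeros(n); Bn = np.zeros(n)
    Ag = np.zeros(n); Bg = np.zeros(n)
    g_ou = ou_g0.copy()
    has_ou = False
    for i in range(n):
        if ou_g0[i] != 0.0 or ou_fluct[i] != 0.0:
            has_ou = True
            break
    n_spk = 0
    max_spk = spk_t.shape[0]
    ev_i = 0
    sp_i = 0
    n_ev = ev_step.shape[0]
    n_sp = sp_step.shape[0]
    mg_n = mg_table.shape[0]

    for step in range(n_steps):
        t = step * dt
        slot = step % L
        # external events arriving this step
        while ev_i < n_ev and ev_step[ev_i] == step:
            i = ev_post[ev_i]
            Aa[i] += ev_wa[ev_i]; Ba[i] += ev_wa[ev_i]
            An[i] += ev_wn[ev_i]; Bn[i] += ev_wn[ev_i]
            ev_i += 1
        # spontaneous single-vesicle releases
        while sp_i < n_sp and sp_step[sp_i] == step:
            e = sp_edge[sp_i]
            dtl = t - syn_last[e]
            if syn_unavail[e] > 0 and dtl > 0:
                p_rec = 1.0 - math.exp(-dtl / e_D[e])
                syn_unavail[e] -= np.random.binomial(syn_unavail[e], p_rec)
            syn_fac[e] = syn_fac[e] * math.exp(-dtl / e_F[e]) if dtl > 0 else syn_fac[e]
            syn_last[e] = t
            if e_pool[e] - syn_unavail[e] > 0:
                syn_unavail[e] += 1
                i = e_post[e]
                arr = (step + e_delay[e]) % L
                if e_is_gaba[e] == 1:
                    buf_g[arr, i] += e_w_ampa[e]
                else:
                    buf_a[arr, i] += e_w_ampa[e]
                    buf_n[arr, i] += e_w_nmda[e]
            sp_i += 1

        step_fac = 0.0
        if i_on <= step < i_off:
            step_fac = 1.0
        elif i_ramp_steps > 0 and i_off <= step < i_off + i_ramp_steps:
            step_fac = 1.0 - (step - i_off) / i_ramp_steps
        do_ou = has_ou and step % ou_stride == 0

        for i in range(n):
            # deliver buffered synaptic quanta
            wa = buf_a[slot, i]
            if wa != 0.0:
                Aa[i] += wa; Ba[i] += wa; buf_a[slot, i] = 0.0
            wn = buf_n[slot, i]
            if wn != 0.0:
                An[i] += wn; Bn[i] += wn; buf_n[slot, i] = 0.0
            wg = buf_g[slot, i]
            if wg != 0.0:
                Ag[i] += wg; Bg[i] += wg; buf_g[slot, i] = 0.0
            # channel decays (tiny states flushed to zero: avoids denormal
            # stalls and keeps the zero-conductance fast path)
            Aa[i] *= dAr_a[i]; Ba[i] *= dAd_a[i]
            An[i] *= dAr_n[i]; Bn[i] *= dAd_n[i]
            Ag[i] *= dAr_g[i]; Bg[i] *= dAd_g[i]
            if Ba[i] < 1e-12 and Ba[i] != 0.0:
                Ba[i] = 0.0; Aa[i] = 0.0
            if Bn[i] < 1e-12 and Bn[i] != 0.0:
                Bn[i] = 0.0; An[i] = 0.0
            if Bg[i] < 1e-12 and Bg[i] != 0.0:
                Bg[i] = 0.0; Ag[i] = 0.0
            # OU update (exact discretisation at the stride interval)
            if do_ou:
                g_ou[i] = ou_g0[i] + (g_ou[i] - ou_g0[i]) * ou_decay[i] \
                    + ou_fluct[i] * np.random.standard_normal()
            gb = g_ou[i] if g_ou[i] > 0.0 else 0.0

            if refr[i] > 0:
                refr[i] -= 1
                V[i] = Vreset[i]
                continue

            g_a = Ba[i] - Aa[i]
            g_nr = Bn[i] - An[i]
            if g_nr != 0.0:
                mi = int((V[i] + 120.0) * 20.0)
                if mi < 0:
                    mi = 0
                elif mi >= mg_n:
                    mi = mg_n - 1
                g_n = g_nr * mg_table[mi]
            else:
                g_n = 0.0
            g_g = Bg[i] - Ag[i]
            I_ext = I_hold[i] + I_amp[i] * step_fac
            g_tot = gL[i] + g_a + g_n + g_g + gb
            V_inf = (gL[i] * EL[i] + (g_a + g_n) * Ee[i] + g_g * Ei[i]
                     + gb * E_ou + I_ext) / g_tot
            V[i] = V_inf + (V[i] - V_inf) * _fast_expm(dt * g_tot / C[i])
            lo = Ei[i] - 30.0
            if V[i] < lo:
                V[i] = lo
            elif V[i] > 60.0:
                V[i] = 60.0

            if V[i] >= Vth[i]:
                if n_spk >= max_spk:
                    return n_spk, 2
                spk_t[n_spk] = t
                spk_id[n_spk] = i
                n_spk += 1
                V[i] = Vreset[i]
                refr[i] = ref_steps[i]
                # propagate through outgoing connections
                for e in range(indptr[i], indptr[i + 1]):
                    dtl = t - syn_last[e]
                    if syn_unavail[e] > 0 and dtl > 0:
                        p_rec = 1.0 - math.exp(-dtl / e_D[e])
                        syn_unavail[e] -= np.random.binomial(syn_unavail[e], p_rec)
                    u = e_u[e] + syn_fac[e] * (1.0 - e_u[e]) * math.exp(-dtl / e_F[e])
                    syn_fac[e] = u
                    syn_last[e] = t
                    avail = e_pool[e] - syn_unavail[e]
                    if avail > 0:
                        k = np.random.binomial(avail, u)
                        if k > 0:
                            syn_unavail[e] += k
                            j = e_post[e]
                            arr = (step + e_delay[e]) % L
                            if e_is_gaba[e] == 1:
                                buf_g[arr, j] += k * e_w_ampa[e]
                            else:
                                buf_a[arr, j] += k * e_w_ampa[e]
                                buf_n[arr, j] += k * e_w_nmda[e]

        # voltage recording
        for r in range(rec_map.shape[0]):
            V_rec[r, step] = V[rec_map[r]]

        if step % 200 == 0:
            ok = True
            for i in range(n):
                if not math.isfinite(V[i]):
                    ok = False
                    break
            if not ok:
                return n_spk, 1
    return n_spk, 0


def _mg_lookup(mg_mM: float) -> np.ndarray:
    """Jahr-Stevens Mg-block factor tabulated over V in [-120, 60] mV
    (0.05 mV resolution, direct indexing in the inner loop)."""
    v = np.arange(-120.0, 60.0 + 0.05, 0.05)
    return 1.0 / (1.0 + (mg_mM / MG_K) * np.exp(-MG_GAMMA * v))


def _neuron_arrays(network: Network):
    pops = network.populations
    idx = network.pop_index
    def gather(attr):
        vals = np.array([getattr(p.neuron_params, attr) for p in pops])
        return vals[idx]
    return dict(
        C=gather("membrane_capacitance"),
        gL=gather("leak_conductance"),
        EL=gather("leak_reversal"),
        Vth=gather("spike_threshold"),
        Vreset=gather("reset_potential"),
        Ee=gather("excitatory_reversal"),
        Ei=gather("inhibitory_reversal"),
        refractory=gather("refractory"),
    )


def _receptor_taus(network: Network):
    """Per-neuron AMPA/GABA decay constants from the incoming pathway tables."""
    conn = network.connectome
    cls = np.array([p.synapse_class for p in network.populations])[network.pop_index]
    tau_a = np.full(network.n_neurons, 1.7)
    tau_g = np.full(network.n_neurons, 8.0)
    for post_class in ("E", "I"):
        mask = cls == post_class
        pe = conn.pathway_params.get(f"E->{post_class}")
        pi = conn.pathway_params.get(f"I->{post_class}")
        if pe is not None:
            tau_a[mask] = pe.decay_tau
        if pi is not None:
            tau_g[mask] = pi.decay_tau
    return tau_a, tau_g


def simulate(network: Network, config: SimulationConfig,
             ou_table: OUInjectionTable | None = None,
             g_in: dict[str, float] | None = None,
             external: ExternalEvents | None = None,
             step_current: StepCurrent | None = None,
             hold_current_nA: np.ndarray | float = 0.0,
             quantal_convention: str = "vesicle",
             ca_hill_k: float = CA_HILL_K_DEFAULT,
             mg_mM: float = MG_CONC_DEFAULT,
             ) -> tuple[SpikeRecording, np.ndarray]:
    """Simulate the network; returns (spike recording, voltage traces).

    ``ou_table`` supplies per-population background injection; percentages are
    scaled by ``g_in`` (defaults to each population's leak conductance).
    ``quantal_convention`` 'vesicle' makes every released vesicle contribute a
    peak conductance of ghat; 'connection' divides ghat by the vesicle pool.

    Voltage traces are returned for ``config.record_voltages`` as an array of
    shape (n_recorded, n_steps), rows ordered like the id list.
    """
    conn = network.connectome
    n = network.n_neurons
    dt = config.dt
    n_steps = int(round(config.duration / dt))
    na = _neuron_arrays(network)
    if network.vth_offset_mV is not None:
        na["Vth"] = na["Vth"] + network.vth_offset_mV
    ref_steps = np.maximum(np.round(na["refractory"] / dt).astype(np.int64), 1)

    # --- connectivity, CSR by presynaptic neuron ---
    order = np.argsort(conn.pre, kind="stable")
    pre_s = conn.pre[order]
    indptr = np.searchsorted(pre_s, np.arange(n + 1))
    e_post = conn.post[order].astype(np.int64)
    e_nsyn = conn.nsyn[order]
    e_path = conn.pathway[order]
    e_delay = np.maximum(np.round(conn.delay_ms[order] / dt).astype(np.int64), 1)

    n_edges = conn.n_edges
    e_pool = np.empty(n_edges, dtype=np.int64)
    e_u = np.empty(n_edges)
    e_D = np.empty(n_edges)
    e_F = np.empty(n_edges)
    e_w_ampa = np.empty(n_edges)
    e_w_nmda = np.zeros(n_edges)
    e_is_gaba = np.zeros(n_edges, dtype=np.int64)
    e_spont = np.zeros(n_edges)

    tau_a_post, tau_g_post = _receptor_taus(network)
    norm_nmda = biexp_normalization(TAU_RISE_NMDA, TAU_DECAY_NMDA)

    for k, label in enumerate(conn.pathway_labels):
        p = conn.pathway_params[label]
        sel = e_path == k
        if not np.any(sel):
            continue
        is_gaba = label.startswith("I")
        ghat = p.peak_conductance
        if quantal_convention == "connection":
            ghat = ghat / p.vesicle_pool
        elif quantal_convention != "vesicle":
            raise ValueError("quantal_convention must be 'vesicle' or 'connection'")
        tau_r = TAU_RISE_GABA if is_gaba else TAU_RISE_AMPA
        norm = biexp_normalization(tau_r, p.decay_tau)
        e_pool[sel] = e_nsyn[sel] * int(p.vesicle_pool)
        e_u[sel] = hill_scaled_use(p, config.calcium_Cao, k_half=ca_hill_k)
        e_D[sel] = p.depression_tau
        e_F[sel] = p.facilitation_tau
        e_w_ampa[sel] = ghat * norm
        if is_gaba:
            e_is_gaba[sel] = 1
        else:
            e_w_nmda[sel] = ghat * p.conductance_ratio * norm_nmda
        e_spont[sel] = p.spontaneous_rate * e_nsyn[sel]

    # --- channel decay factors ---
    dAr_a = np.exp(-dt / np.full(n, TAU_RISE_AMPA))
    dAd_a = np.exp(-dt / tau_a_post)
    dAr_n = np.exp(-dt / np.full(n, TAU_RISE_NMDA))
    dAd_n = np.exp(-dt / np.full(n, TAU_DECAY_NMDA))
    dAr_g = np.exp(-dt / np.full(n, TAU_RISE_GABA))
    dAd_g = np.exp(-dt / tau_g_post)

    # --- ring buffers ---
    L = int(e_delay.max()) + 2 if n_edges else 2
    buf_a = np.zeros((L, n))
    buf_n = np.zeros((L, n))
    buf_g = np.zeros((L, n))

    # --- OU ---
    ou_g0 = np.zeros(n)
    ou_sigma = np.zeros(n)
    ou_tau = np.full(n, 3.0)
    E_ou = 0.0
    if ou_table is not None:
        g_in = g_in or {}
        for pi, pop in enumerate(network.populations):
            params = ou_table.params.get(pop.name)
            if params is None:
                continue
            gin = g_in.get(pop.name, pop.neuron_params.leak_conductance)
            mask = network.pop_index == pi
            ou_g0[mask] = params.OU_mu / 100.0 * gin
            ou_sigma[mask] = params.OU_sigma / 100.0 * gin
            ou_tau[mask] = params.tau
            E_ou = params.reversal
    # OU states are refreshed every ou_stride steps (exact discretisation at
    # that interval); the stride keeps dt_OU <= tau/5.
    ou_stride = max(int(min(ou_tau) / (5.0 * dt)), 1)
    ou_decay = np.exp(-ou_stride * dt / ou_tau)
    ou_fluct = ou_sigma * np.sqrt(1.0 - ou_decay ** 2)

    # --- currents (pA internally) ---
    if np.isscalar(hold_current_nA):
        I_hold = np.full(n, float(hold_current_nA) * 1000.0)
    else:
        I_hold = np.asarray(hold_current_nA, dtype=float) * 1000.0
    if step_current is not None:
        I_amp = np.asarray(step_current.amplitude_nA, dtype=float) * 1000.0
        i_on = int(round(step_current.onset_ms / dt))
        i_off = int(round(step_current.offset_ms / dt))
        i_ramp = int(round(step_current.ramp_ms / dt))
    else:
        I_amp = np.zeros(n)
        i_on, i_off, i_ramp = 0, 0, 0

    # --- external events (weights are peak conductances; scale to the
    #     channel-state increment that produces that peak) ---
    if external is not None and len(external.times_ms):
        ev_order = np.argsort(external.times_ms, kind="stable")
        ev_step = np.round(external.times_ms[ev_order] / dt).astype(np.int64)
        keep = (ev_step >= 0) & (ev_step < n_steps)
        ev_step = ev_step[keep]
        ev_post = external.post[ev_order][keep].astype(np.int64)
        norm_a_post = np.array([biexp_normalization(TAU_RISE_AMPA, ta)
                                for ta in tau_a_post])
        ev_wa = external.weight_ampa[ev_order][keep].astype(float) \
            * norm_a_post[ev_post]
        if external.weight_nmda is not None:
            ev_wn = external.weight_nmda[ev_order][keep].astype(float) * norm_nmda
        else:
            ev_wn = np.zeros(len(ev_step))
    else:
        ev_step = np.empty(0, dtype=np.int64)
        ev_post = np.empty(0, dtype=np.int64)
        ev_wa = np.empty(0)
        ev_wn = np.empty(0)

    # --- spontaneous release schedule (Poisson per connection) ---
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5EED]))
    active = np.flatnonzero(e_spont > 0)
    if len(active):
        counts = rng.poisson(e_spont[active] * config.duration / 1000.0)
        sp_edge = np.repeat(active, counts)
        sp_t = rng.uniform(0, config.duration, len(sp_edge))
        so = np.argsort(sp_t, kind="stable")
        sp_step = np.round(sp_t[so] / dt).astype(np.int64)
        sp_step = np.minimum(sp_step, n_steps - 1)
        sp_edge = sp_edge[so].astype(np.int64)
    else:
        sp_step = np.empty(0, dtype=np.int64)
        sp_edge = np.empty(0, dtype=np.int64)

    # --- synapse state ---
    syn_unavail = np.zeros(n_edges, dtype=np.int64)
    syn_fac = np.zeros(n_edges)
    syn_last = np.full(n_edges, -1e12)

    # --- recording & spike buffers ---
    rec_ids = list(config.record_voltages)
    rec_map = np.array(rec_ids, dtype=np.int64) if rec_ids else np.empty(0, dtype=np.int64)
    V_rec = np.zeros((len(rec_ids), n_steps))
    # buffer for an average of 100 Hz across the network (generous for
    # asynchronous states; exceeded only by runaway activity)
    max_spk = max(int(n * config.duration / 1000.0 * 100), 10000)
    spk_t = np.empty(max_spk)
    spk_id = np.empty(max_spk, dtype=np.int64)

    core_seed = int(np.random.SeedSequence([config.seed, 0xC0DE]).generate_state(1)[0] % (2 ** 31))
    n_spk, status = _run_core(
        core_seed, n_steps, dt,
        na["C"], na["gL"], na["EL"], na["Vth"], na["Vreset"], na["Ee"], na["Ei"],
        ref_steps,
        indptr.astype(np.int64), e_post, e_pool, e_delay, e_u, e_D, e_F,
        e_w_ampa, e_w_nmda, e_is_gaba,
        syn_unavail, syn_fac, syn_last,
        dAr_a, dAd_a, dAr_n, dAd_n, dAr_g, dAd_g,
        L, buf_a, buf_n, buf_g,
        ou_g0, ou_decay, ou_fluct, E_ou, ou_stride,
        _mg_lookup(mg_mM),
        I_hold, I_amp, i_on, i_off, i_ramp,
        ev_step, ev_post, ev_wa, ev_wn,
        sp_step, sp_edge,
        rec_map, V_rec,
        spk_t, spk_id)

    if status == 1:
        raise NumericalDivergenceError(
            "non-finite membrane state encountered; check parameters")
    if status == 2:
        raise SpikeOverflowError(
            f"more than {max_spk} spikes in {config.duration} ms "
            f"({n} neurons): runaway activity")

    rec = SpikeRecording(
        neuron_ids=spk_id[:n_spk].copy(), times_ms=spk_t[:n_spk].copy(),
        duration=config.duration, pop_index=network.pop_index,
        pop_labels=network.population_names)
    return rec, V_rec


def external_events_from_trains(trains: dict[int, np.ndarray],
                                targets: dict[int, np.ndarray],
                                g_peak_nS: float,
                                nmda_ratio: float = 0.0) -> ExternalEvents:
    """Flatten fiber spike trains into engine events.

    Each spike of fiber f delivers a conductance quantum of peak ``g_peak_nS``
    (plus ``nmda_ratio`` times that on the NMDA channel) to every neuron in
    ``targets[f]``.
    """
    times, posts = [], []
    for fib, t in trains.items():
        tgt = np.asarray(targets.get(fib, ()), dtype=np.int64)
        if len(tgt) == 0 or len(t) == 0:
            continue
        times.append(np.repeat(np.asarray(t, dtype=float), len(tgt)))
        posts.append(np.tile(tgt, len(t)))
    if not times:
        empty = np.empty(0)
        return ExternalEvents(times_ms=empty, post=np.empty(0, dtype=np.int64),
                              weight_ampa=empty.copy())
    times = np.concatenate(times)
    posts = np.concatenate(posts)
    wa = np.full(len(times), g_peak_nS)
    wn = np.full(len(times), g_peak_nS * nmda_ratio) if nmda_ratio else None
    return ExternalEvents(times_ms=times, post=posts, weight_ampa=wa,
                          weight_nmda=wn)


# ---------------------------------------------------------------------------
# Single-neuron probes
# ---------------------------------------------------------------------------

def _single_neuron_trace(params, dt, duration, I_probe_nA=0.0, tonic_g_nS=0.0,
                         tonic_reversal=0.0, probe_onset_ms=0.0):
    """Deterministic single LIF neuron; returns (V trace, spike times)."""
    n_steps = int(round(duration / dt))
    V = params.leak_reversal
    gL = params.leak_conductance
    trace = np.empty(n_steps)
    spikes = []
    refr = 0
    ref_steps = max(int(round(params.refractory / dt)), 1)
    I_pA = I_probe_nA * 1000.0
    on = int(round(probe_onset_ms / dt))
    for s in range(n_steps):
        if refr > 0:
            refr -= 1
            V = params.reset_potential
            trace[s] = V
            continue
        I = I_pA if s >= on else 0.0
        g_tot = gL + tonic_g_nS
        V_inf = (gL * params.leak_reversal + tonic_g_nS * tonic_reversal + I) / g_tot
        V = V_inf + (V - V_inf) * math.exp(-dt * g_tot / params.membrane_capacitance)
        if V >= params.spike_threshold:
            spikes.append(s * dt)
            V = params.reset_potential
            refr = ref_steps
        trace[s] = V
    return trace, spikes


def measure_input_conductance(neuron_params, tonic_g_nS: float = 0.0,
                              tonic_reversal: float = 0.0,
                              probe_nA: float = -0.005,
                              dt: float = 0.1, settle_ms: float = 400.0,
                              probe_ms: float = 400.0) -> float:
    """Input conductance G_in = 1/R_in from a small hyperpolarizing step.

    The cell is held at rest (with any tonic synaptic background open), a
    small negative current step is applied, and G_in is the ratio of the step
    amplitude to the steady-state voltage deflection. For a passive point
    neuron this equals the leak (plus tonic) conductance to within 1%.
    """
    if probe_nA >= 0:
        raise ValueError("probe must be hyperpolarizing (negative)")
    duration = settle_ms + probe_ms
    base, spk0 = _single_neuron_trace(neuron_params, dt, settle_ms,
                                      tonic_g_nS=tonic_g_nS,
                                      tonic_reversal=tonic_reversal)
    trace, spikes = _single_neuron_trace(neuron_params, dt, duration,
                                         I_probe_nA=probe_nA,
                                         tonic_g_nS=tonic_g_nS,
                                         tonic_reversal=tonic_reversal,
                                         probe_onset_ms=settle_ms)
    if spikes or spk0:
        raise RuntimeError("neuron spiked during the conductance probe; "
                           "reduce the probe amplitude")
    tail = int(round(probe_ms * 0.25 / dt))
    v_rest = base[-tail:].mean()
    v_probe = trace[-tail:].mean()
    dV = v_probe - v_rest
    if dV == 0:
        raise RuntimeError("no measurable deflection")
    return probe_nA * 1000.0 / dV  # pA / mV = nS


def find_rheobase(neuron_params, tol: float = 0.01, max_nA: float = 5.0,
                  step_ms: float = 500.0, dt: float = 0.1
                  ) -> tuple[float, bool]:
    """Minimal 500 ms step current (nA) eliciting at least one spike.

    Bisection between a non-spiking lower and a spiking upper bound until the
    interval is narrower than ``tol`` (relative). Returns (rheobase, flag);
    flag is True when the neuron fires with no injected current, in which
    case the reported rheobase is 0.
    """

    def spikes_at(i_nA):
        _, s = _single_neuron_trace(neuron_params, dt, step_ms, I_probe_nA=i_nA)
        return len(s) > 0

    if spikes_at(0.0):
        return 0.0, True
    lo, hi = 0.0, 0.05
    while not spikes_at(hi):
        lo = hi
        hi *= 2.0
        if hi > max_nA:
            raise RuntimeError(f"no spike up to {max_nA} nA")
    while (hi - lo) > tol * hi:
        mid = 0.5 * (lo + hi)
        if spikes_at(mid):
            hi = mid
        else:
            lo = mid
    return hi, False
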