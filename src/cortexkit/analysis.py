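"""Spontaneous and evoked activity metrics.

PSTHs with Gaussian smoothing and baseline/max normalization, evoked-response
latency/decay validation criteria, connected/unconnected rate ratios, E-I
histogram correlations, population-rate spectra, firing-rate distribution
statistics, subthreshold-cell selection, and mutual information between
spiking and a binary stimulus signal with a circular-shift shuffle control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import periodogram
from scipy.stats import pearsonr

from .network import SpikeRecording
from .stimuli import BinarySignal


@dataclass
class PSTH:
    bin_ms: float
    times_ms: np.ndarray        # bin centers
    values: np.ndarray          # Hz per neuron (or normalized)
    smoothing_sigma_bins: float = 1.0
    normalization: str = "none"  # none | baseline_max
    baseline: float = 0.0        # pre-normalization baseline (Hz)


def psth(spike_times_ms: np.ndarray, n_neurons: int, t_start: float,
         t_stop: float, bin_ms: float = 5.0, sigma_bins: float = 1.0,
         n_trials: int = 1, normalization: str = "none",
         baseline_window_ms: tuple[float, float] | None = None) -> PSTH:
    """Trial-averaged, smoothed, optionally normalized response histogram.

    Rates are per neuron (Hz). ``normalization='baseline_max'`` subtracts the
    baseline (mean over ``baseline_window_ms``, default the span before the
    window midpoint) and divides by the post-subtraction maximum.
    """
    if n_neurons <= 0:
        raise ValueError("empty population")
    edges = np.arange(t_start, t_stop + bin_ms * 0.5, bin_ms)
    counts, _ = np.histogram(spike_times_ms, bins=edges)
    rate = counts / (n_neurons * n_trials * bin_ms / 1000.0)
    if sigma_bins > 0:
        rate = gaussian_filter1d(rate, sigma_bins, mode="nearest")
    centers = 0.5 * (edges[:-1] + edges[1:])
    base = 0.0
    if baseline_window_ms is not None:
        sel = (centers >= baseline_window_ms[0]) & (centers < baseline_window_ms[1])
        base = float(rate[sel].mean()) if sel.any() else 0.0
    if normalization == "baseline_max":
        if baseline_window_ms is None:
            half = centers < 0.5 * (t_start + t_stop)
            base = float(rate[half].mean()) if half.any() else 0.0
        shifted = rate - base
        peak = shifted.max()
        rate = shifted / peak if peak > 0 else np.zeros_like(shifted)
    elif normalization != "none":
        raise ValueError("normalization must be 'none' or 'baseline_max'")
    return PSTH(bin_ms=bin_ms, times_ms=centers, values=rate,
                smoothing_sigma_bins=sigma_bins, normalization=normalization,
                baseline=base)


def psth_from_recording(recording: SpikeRecording, population: str,
                        **kwargs) -> PSTH:
    n = int(np.sum(recording.pop_index == recording.pop_labels.index(population)))
    times = recording.population_spikes(population)
    kwargs.setdefault("t_start", 0.0)
    kwargs.setdefault("t_stop", recording.duration)
    return psth(times, n, **kwargs)


@dataclass
class EvokedMetrics:
    latency_ms: float
    decay50_ms: float
    decay25_ms: float
    R_E: float
    sparsity: float = float("nan")
    responsive: bool = True
    baseline_hz: float = 0.0
    peak_hz: float = 0.0


def evoked_metrics(p: PSTH, stim_onset_ms: float,
                   baseline_window_ms: float = 500.0) -> EvokedMetrics:
    """Latency, 50%/25% decay points and evoked ratio from a smoothed PSTH.

    Latency is the first post-onset time the PSTH exceeds baseline + 5% of
    the peak-minus-baseline amplitude (mirroring the EPSP rise-to-5%-of-peak
    latency convention); decay points are the first post-peak times it falls
    to 50% / 25% of the amplitude above baseline; R_E is peak over baseline.
    """
    t, v = p.times_ms, p.values
    pre = (t >= stim_onset_ms - baseline_window_ms) & (t < stim_onset_ms)
    base = float(v[pre].mean()) if pre.any() else 0.0
    post = t >= stim_onset_ms
    if not post.any():
        raise ValueError("no post-onset bins")
    vp = v[post]
    tp = t[post]
    peak_i = int(np.argmax(vp))
    peak = float(vp[peak_i])
    amp = peak - base
    if amp <= 0:
        return EvokedMetrics(latency_ms=math.nan, decay50_ms=math.nan,
                             decay25_ms=math.nan,
                             R_E=peak / base if base > 0 else math.nan,
                             responsive=False, baseline_hz=base, peak_hz=peak)
    above = vp > base + 0.05 * amp
    latency = float(tp[np.argmax(above)]) - stim_onset_ms if above.any() else math.nan

    def first_below(frac):
        tail = vp[peak_i:]
        below = tail < base + frac * amp
        if not below.any():
            return float("inf")
        return float(tp[peak_i:][np.argmax(below)]) - stim_onset_ms

    r_e = peak / base if base > 0 else float("inf")
    return EvokedMetrics(latency_ms=latency, decay50_ms=first_below(0.5),
                         decay25_ms=first_below(0.25), R_E=r_e,
                         baseline_hz=base, peak_hz=peak)


def response_sparsity(recording: SpikeRecording, population: str,
                      window_ms: tuple[float, float]) -> float:
    """Proportion of neurons spiking at least once in the window."""
    pidx = recording.pop_labels.index(population)
    members = np.flatnonzero(recording.pop_index == pidx)
    sel = (recording.times_ms >= window_ms[0]) & (recording.times_ms < window_ms[1])
    active = np.unique(recording.neuron_ids[sel])
    active = active[np.isin(active, members)]
    return len(active) / len(members)


@dataclass
class CriteriaResult:
    latency_pass: dict[str, bool]
    decay50_pass: dict[str, bool]
    decay25_pass: dict[str, bool]
    secondary_rise_pass: dict[str, bool]
    excluded: tuple[str, ...]
    overall: bool


def criteria_check(model_metrics: dict[str, EvokedMetrics],
                   reference_metrics: dict[str, EvokedMetrics],
                   model_psths: dict[str, PSTH] | None = None,
                   stim_onset_ms: float = 0.0,
                   exclude: tuple[str, ...] = ("L1_I",),
                   latency_slack_ms: float = 10.0,
                   decay50_slack_ms: float = 10.0,
                   decay25_slack_ms: float = 40.0,
                   secondary_rise_after_ms: float = 75.0,
                   secondary_rise_level: float = 0.35) -> CriteriaResult:
    """Evoked-response similarity criteria against an in-vivo reference.

    Model latencies / 50% / 25% decay points must be no more than 10 / 10 /
    40 ms later than the reference population's, and no population's
    baseline-normalized PSTH may rise above 35% of its peak after 75 ms
    post-onset (secondary rise). L1_I is excluded (no reference response).
    """
    lat, d50, d25, sec = {}, {}, {}, {}
    for pop, m in model_metrics.items():
        if pop in exclude:
            continue
        if pop not in reference_metrics:
            raise KeyError(f"missing reference population '{pop}'")
        ref = reference_metrics[pop]
        lat[pop] = bool(m.latency_ms <= ref.latency_ms + latency_slack_ms)
        d50[pop] = bool(m.decay50_ms <= ref.decay50_ms + decay50_slack_ms)
        d25[pop] = bool(m.decay25_ms <= ref.decay25_ms + decay25_slack_ms)
        sec[pop] = True
        if model_psths and pop in model_psths:
            p = model_psths[pop]
            if p.normalization != "baseline_max":
                raise ValueError("secondary-rise test needs baseline_max PSTHs")
            late = p.times_ms >= stim_onset_ms + secondary_rise_after_ms
            if late.any() and np.nanmax(p.values[late]) > secondary_rise_level:
                sec[pop] = False
    overall = all(lat.values()) and all(d50.values()) and all(d25.values()) \
        and all(sec.values())
    return CriteriaResult(latency_pass=lat, decay50_pass=d50, decay25_pass=d25,
                          secondary_rise_pass=sec, excluded=exclude,
                          overall=overall)


def rcu_ratio(connected_rates: np.ndarray, unconnected_rates: np.ndarray
              ) -> tuple[np.ndarray, np.ndarray]:
    """Element-wise connected/unconnected rate ratio R_C/U.

    Returns (ratios, flags); 0/0 yields NaN and x/0 yields +inf, both
    flagged.
    """
    c = np.asarray(connected_rates, dtype=float)
    u = np.asarray(unconnected_rates, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = c / u
    flags = u == 0
    return r, flags


def ei_correlation(recording: SpikeRecording, bin_ms: float = 5.0,
                   sigma_bins: float = 1.0, t_start: float = 0.0
                   ) -> dict[str, float]:
    """Pearson r between smoothed E and I population histograms.

    Returns per-layer correlations plus 'overall' (all E vs all I spikes).
    """
    labels = recording.pop_labels
    layers = sorted({lab.rsplit("_", 1)[0] for lab in labels})
    edges = np.arange(t_start, recording.duration + bin_ms * 0.5, bin_ms)

    def hist(pops):
        sel = np.isin(recording.pop_index[recording.neuron_ids],
                      [labels.index(p) for p in pops if p in labels])
        h, _ = np.histogram(recording.times_ms[sel], bins=edges)
        return gaussian_filter1d(h.astype(float), sigma_bins) if sigma_bins > 0 \
            else h.astype(float)

    out = {}
    for layer in layers:
        e_pop, i_pop = f"{layer}_E", f"{layer}_I"
        if e_pop in labels and i_pop in labels:
            he, hi = hist([e_pop]), hist([i_pop])
            if he.std() > 0 and hi.std() > 0:
                out[layer] = float(pearsonr(he, hi)[0])
            else:
                out[layer] = float("nan")
    he = hist([p for p in labels if p.endswith("_E")])
    hi = hist([p for p in labels if p.endswith("_I")])
    out["overall"] = float(pearsonr(he, hi)[0]) \
        if he.std() > 0 and hi.std() > 0 else float("nan")
    return out


def rate_spectrum(recording: SpikeRecording, bin_ms: float = 5.0
                  ) -> tuple[np.ndarray, np.ndarray]:
    """One-sided periodogram of the mean-subtracted population rate,
    reported as relative power (normalized to total power)."""
    edges = np.arange(0.0, recording.duration + bin_ms * 0.5, bin_ms)
    h, _ = np.histogram(recording.times_ms, bins=edges)
    x = h - h.mean()
    freqs, power = periodogram(x, fs=1000.0 / bin_ms)
    total = power.sum()
    return freqs, power / total if total > 0 else power


# ---------------------------------------------------------------------------
# Mutual information with shuffle control
# ---------------------------------------------------------------------------

def _plugin_mi(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in mutual information (bits) between two discrete series."""
    xs, xi = np.unique(x, return_inverse=True)
    ys, yi = np.unique(y, return_inverse=True)
    joint = np.zeros((len(xs), len(ys)))
    np.add.at(joint, (xi, yi), 1.0)
    joint /= joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log2(joint[nz] / (px @ py)[nz])))


def _miller_madow(x: np.ndarray, y: np.ndarray) -> float:
    n = len(x)
    kx = len(np.unique(x))
    ky = len(np.unique(y))
    kxy = len({(a, b) for a, b in zip(x, y)})
    corr = (kx - 1) + (ky - 1) - (kxy - 1)
    return _plugin_mi(x, y) + corr / (2.0 * n * math.log(2))


@dataclass
class MIResult:
    mi_bits: np.ndarray           # per analyzed cell
    significant: np.ndarray       # per analyzed cell
    threshold_bits: np.ndarray    # shuffle (1-alpha) quantile per cell
    cell_ids: np.ndarray          # cells with at least one spike


def mutual_information(signal: BinarySignal,
                       spikes_per_cell: dict[int, np.ndarray],
                       duration_s: float | None = None,
                       window: str = "all_bins", bin_ms: float = 50.0,
                       n_shuffles: int = 100, alpha: float = 0.05,
                       count_cap: int = 5, seed: int = 0,
                       bias_corrected: bool = False) -> MIResult:
    """MI between each cell's binned spike count and the binary signal state.

    ``window='all_bins'`` uses every bin; ``'first_bin'`` restricts to the
    bin immediately following each state switch. Significance compares each
    cell's MI with the (1-alpha) quantile of MI under circular time-shifts of
    the signal (which preserve its dwell-time structure). Cells that never
    spike are excluded.
    """
    duration_s = signal.duration_s if duration_s is None else duration_s
    bin_s = bin_ms / 1000.0
    n_bins = int(duration_s / bin_s)
    if n_bins < 2:
        raise ValueError("recording too short")
    starts = np.arange(n_bins) * bin_s
    states = signal.state_at(starts)
    if len(np.unique(states)) < 2:
        raise ValueError("fewer than 2 distinct signal states in the span")

    if window == "all_bins":
        sel = np.ones(n_bins, dtype=bool)
    elif window == "first_bin":
        sel = np.zeros(n_bins, dtype=bool)
        idx = np.minimum((signal.switch_times_s / bin_s).astype(int), n_bins - 1)
        sel[idx] = True
    else:
        raise ValueError("window must be 'all_bins' or 'first_bin'")

    rng = np.random.default_rng(seed)
    shifts = rng.integers(1, n_bins, size=n_shuffles)
    estimator = _miller_madow if bias_corrected else _plugin_mi

    ids, mis, sigs, thr = [], [], [], []
    for cid, times in spikes_per_cell.items():
        times = np.asarray(times, dtype=float)
        counts = np.bincount(np.clip((times / bin_s).astype(int), 0, n_bins - 1),
                             minlength=n_bins)
        if counts.sum() == 0:
            continue
        counts = np.minimum(counts, count_cap)
        mi = estimator(counts[sel], states[sel])
        null = np.array([estimator(counts[sel], np.roll(states, s)[sel])
                         for s in shifts])
        q = float(np.quantile(null, 1.0 - alpha))
        ids.append(cid)
        mis.append(mi)
        thr.append(q)
        sigs.append(mi > q)
    return MIResult(mi_bits=np.asarray(mis), significant=np.asarray(sigs),
                    threshold_bits=np.asarray(thr),
                    cell_ids=np.asarray(ids, dtype=np.int64))


# ---------------------------------------------------------------------------
# Subthreshold L2/3 cell selection
# ---------------------------------------------------------------------------

def select_l23_cells(control_spikes: dict[int, np.ndarray],
                     opto_spikes: dict[int, np.ndarray],
                     control_voltages: dict[int, np.ndarray],
                     innervated_ids: set[int],
                     stim_onset_ms: float, stim_duration_ms: float,
                     dt_ms: float = 0.1, flank_ms: float = 200.0,
                     dvdt_threshold: float = 1.0,
                     dvdt_window_ms: float = 20.0) -> set[int]:
    """Cells meeting the three whisker-hold inclusion criteria.

    (1) subthreshold (no spikes) during the stimulus and the 200 ms flanking
    windows, in both control and optogenetic runs; (2) innervated by at least
    one active thalamic fiber; (3) voltage derivative crossing 1 mV/ms within
    20 ms after stimulus onset in the control run. Downstream averaging is
    across cells, not trials.
    """
    w0 = stim_onset_ms - flank_ms
    w1 = stim_onset_ms + stim_duration_ms + flank_ms
    selected = set()
    for cid, v in control_voltages.items():
        if cid not in innervated_ids:
            continue

        def spiked(spk):
            t = np.asarray(spk.get(cid, ()), dtype=float)
            return np.any((t >= w0) & (t < w1))

        if spiked(control_spikes) or spiked(opto_spikes):
            continue
        i0 = int(stim_onset_ms / dt_ms)
        i1 = int((stim_onset_ms + dvdt_window_ms) / dt_ms)
        dvdt = np.diff(v[i0:i1 + 1]) / dt_ms
        if len(dvdt) and dvdt.max() >= dvdt_threshold:
            selected.add(cid)
    return selected


# ---------------------------------------------------------------------------
# Firing-rate distribution statistics
# ---------------------------------------------------------------------------

@dataclass
class RateStats:
    mean_hz: float         # including silent neurons
    sparsity: float        # proportion of neurons spiking at least once
    lognorm_mu: float      # of log-rates of active neurons
    lognorm_sigma: float


def rate_distribution_stats(recording: SpikeRecording, t_start: float = 0.0
                            ) -> dict[str, RateStats]:
    """Per-population mean rate, sparsity and lognormal fit of active rates."""
    rates = recording.neuron_rates(t_start=t_start)
    out = {}
    for pi, pop in enumerate(recording.pop_labels):
        r = rates[recording.pop_index == pi]
        if len(r) == 0:
            continue
        active = r[r > 0]
        if len(active):
            logr = np.log(active)
            mu, sigma = float(logr.mean()), float(logr.std())
        else:
            mu, sigma = float("nan"), float("nan")
        out[pop] = RateStats(mean_hz=float(r.mean()),
                             sparsity=float(np.mean(r > 0)),
                             lognorm_mu=mu, lognorm_sigma=sigma)
    return out
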