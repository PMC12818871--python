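"""Sensory input pipeline: rate fields, transfer functions, spiking processes.

Thalamic fibers are assigned a stimulus rate signal rho(x, y, t), optionally
transformed by a kinetic transfer function upsilon (position / velocity /
acceleration / direction coding), and converted to spikes by a stochastic
process psi (PSTH replay, or an adapting Markov process). Binary-signal
encoders for the rate/synchrony coding paradigm live here as well.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

DT_STIMULUS_MS = 0.1      # submillisecond evaluation resolution
R_MAX_WHISKER_HZ = 150.0  # thalamic rate at the fiber's preferred feature value
TAU_ADAPT_MS = 100.0

#: Grating defaults from the rank-score stimulus calibration.
GRATING_FP = 1.0
GRATING_R_PEAK = 10.0     # Hz at full contrast
GRATING_R_BK = 0.2        # Hz background at zero contrast
GRATING_F_TEMP = 2.0      # Hz
GRATING_F_SPAT = 0.001    # cycles/um
CONTRAST_LEVELS = (0.06, 0.12, 0.24, 0.5, 1.0)

TRANSFER_KINDS = ("identity", "pos", "vel", "acc", "dir")
#: Fractions of thalamic kinetic response types (pos, vel, acc, dir).
TRANSFER_FRACTIONS = {"pos": 0.11, "vel": 0.58, "acc": 0.11, "dir": 0.20}


def spatial_frequency_cycles_per_um(cycles_per_degree: float,
                                    magnification_um_per_degree: float = 30.0
                                    ) -> float:
    """Convert a visual spatial frequency to cortical cycles/um via the
    cortical magnification factor."""
    return cycles_per_degree / magnification_um_per_degree


def pattern_window_probability(rate_hz: float, window_ms: float) -> float:
    """Probability that a Poisson pattern at ``rate_hz`` falls in a window."""
    return rate_hz * window_ms / 1000.0


@dataclass
class ThalamicFiber:
    fiber_id: int
    x: float                    # flat location, um
    y: float
    linear_position: float = 0.0  # projection onto the grating axis, um
    transfer: str = "identity"
    innervated_targets: frozenset = field(default_factory=frozenset)
    in_column: bool = True

    def __post_init__(self) -> None:
        if self.transfer not in TRANSFER_KINDS:
            raise ValueError(f"unknown transfer kind '{self.transfer}'")
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError("fiber location must be finite")


def make_fiber_grid(n_fibers: int, extent_um: float = 520.0, seed: int = 0,
                    axis_deg: float = 0.0) -> list[ThalamicFiber]:
    """Uniformly scattered fibers in a flat square; linear positions are the
    projections of the flat locations onto the grating axis."""
    rng = np.random.default_rng(seed)
    xy = rng.uniform(0, extent_um, size=(n_fibers, 2))
    ca, sa = math.cos(math.radians(axis_deg)), math.sin(math.radians(axis_deg))
    return [ThalamicFiber(fiber_id=i, x=float(x), y=float(y),
                          linear_position=float(x * ca + y * sa))
            for i, (x, y) in enumerate(xy)]


def assign_transfer_functions(fibers: list[ThalamicFiber], seed: int = 0,
                              fractions: dict[str, float] | None = None
                              ) -> list[ThalamicFiber]:
    """Randomly assign kinetic transfer functions with the stated fractions."""
    fr = dict(fractions or TRANSFER_FRACTIONS)
    kinds = list(fr)
    probs = np.array([fr[k] for k in kinds], dtype=float)
    probs = probs / probs.sum()
    rng = np.random.default_rng(seed)
    choice = rng.choice(len(kinds), size=len(fibers), p=probs)
    for f, c in zip(fibers, choice):
        f.transfer = kinds[c]
    return fibers


# ---------------------------------------------------------------------------
# PSTH replay (whisker deflection / touch)
# ---------------------------------------------------------------------------

def psth_replay(psth_time_ms: np.ndarray, psth_rate_hz: np.ndarray,
                n_fibers: int, F_P: float, n_trials: int = 10,
                inter_trial_ms: float = 1000.0, seed: int = 0,
                mode: str = "single_spike") -> dict[int, np.ndarray]:
    """Draw fiber spike times from an in-vivo PSTH.

    A uniformly random subset of round(F_P * n_fibers) fibers is selected once
    per experiment. In the default mode each selected fiber draws exactly one
    spike time per trial from the PSTH treated as a probability density;
    ``mode='poisson'`` instead samples an inhomogeneous Poisson train per
    trial. Trial t is offset by t * inter_trial_ms. Returns
    {fiber_id: sorted spike times (ms)} for the selected fibers.
    """
    t = np.asarray(psth_time_ms, dtype=float)
    r = np.asarray(psth_rate_hz, dtype=float)
    if len(t) == 0:
        raise ValueError("empty PSTH")
    if np.any(r < 0):
        raise ValueError("PSTH rates must be >= 0")
    if r.sum() == 0:
        raise ValueError("all-zero PSTH")
    if not (0.0 < F_P <= 1.0):
        raise ValueError("F_P must be in (0, 1]")

    widths = np.diff(t)
    widths = np.append(widths, widths[-1] if len(widths) else 1.0)
    rng = np.random.default_rng(seed)
    n_active = int(round(F_P * n_fibers))
    selected = rng.choice(n_fibers, size=n_active, replace=False)

    out: dict[int, np.ndarray] = {}
    if mode == "single_spike":
        p = (r * widths) / (r * widths).sum()
        for fib in selected:
            bins = rng.choice(len(t), size=n_trials, p=p)
            times = t[bins] + rng.uniform(0, widths[bins]) \
                + np.arange(n_trials) * inter_trial_ms
            out[int(fib)] = np.sort(times)
    elif mode == "poisson":
        for fib in selected:
            trains = []
            for trial in range(n_trials):
                lam = r * widths / 1000.0
                counts = rng.poisson(lam)
                for b in np.flatnonzero(counts):
                    trains.append(t[b] + rng.uniform(0, widths[b], counts[b])
                                  + trial * inter_trial_ms)
            out[int(fib)] = np.sort(np.concatenate(trains)) if trains \
                else np.empty(0)
    else:
        raise ValueError("mode must be 'single_spike' or 'poisson'")
    return out


# ---------------------------------------------------------------------------
# Whisker-hold transfer functions
# ---------------------------------------------------------------------------

def step_stimulus(duration_ms: float, onset_ms: float = 2000.0,
                  offset_ms: float = 2500.0,
                  dt: float = DT_STIMULUS_MS) -> np.ndarray:
    """The whisker-hold step: rho = 1 on [onset, offset), else 0."""
    t = np.arange(0.0, duration_ms, dt)
    return ((t >= onset_ms) & (t < offset_ms)).astype(float)


def whisker_transfer(rho: np.ndarray, kind: str,
                     r_max: float = R_MAX_WHISKER_HZ) -> np.ndarray:
    """Kinetic transfer functions of thalamic relay neurons.

    pos: r_max * rho(t);   vel: r_max * (rho(t+1) - rho(t));
    acc: r_max * (rho(t+1) - 2 rho(t) + rho(t-1));
    dir: r_max * |rho(t+1) - rho(t)| (responds to movement in either
    direction; the spiking stage truncates any negative rate at zero).
    Finite differences are taken per evaluation step.
    """
    rho = np.asarray(rho, dtype=float)
    nxt = np.append(rho[1:], rho[-1] if len(rho) else 0.0)
    prv = np.concatenate([[rho[0]], rho[:-1]]) if len(rho) else rho
    if kind in ("identity", "pos"):
        out = rho.copy()
        if kind == "pos":
            out *= r_max
        return out if kind == "pos" else rho
    if kind == "vel":
        return r_max * (nxt - rho)
    if kind == "acc":
        return r_max * (nxt - 2.0 * rho + prv)
    if kind == "dir":
        return r_max * np.abs(nxt - rho)
    raise ValueError(f"unknown transfer kind '{kind}'")


# ---------------------------------------------------------------------------
# Drifting-grating rate field
# ---------------------------------------------------------------------------

def inverse_michelson(C: float, mean_luminance: float = 0.5
                      ) -> tuple[float, float]:
    """Normalized (L_min, L_max) for a Michelson contrast about the mean."""
    if not (0.0 <= C <= 1.0):
        raise ValueError("contrast must be in [0, 1]")
    return mean_luminance * (1.0 - C), mean_luminance * (1.0 + C)


def michelson_contrast(l_min: float, l_max: float) -> float:
    """|L_max - L_min| / (L_max + L_min)."""
    if l_min + l_max == 0:
        raise ValueError("degenerate luminances")
    return abs(l_max - l_min) / (l_max + l_min)


def _luminance_to_rate(L: float, R_peak: float, R_bk: float) -> float:
    # linear map anchored at R(0.5) = R_bk and R(1.0) = R_peak
    return R_bk + (R_peak - R_bk) * (L - 0.5) / 0.5


def grating_rate(fiber: ThalamicFiber, t_s, C: float,
                 f_temp: float = GRATING_F_TEMP,
                 f_spat: float = GRATING_F_SPAT,
                 R_peak: float = GRATING_R_PEAK,
                 R_bk: float = GRATING_R_BK):
    """Sinusoidal drifting-grating input rate (Hz) for one fiber.

    rho(t, l) = R_min + 0.5 (R_max - R_min) [1 + sin(2 pi f_temp t
                - 2 pi f_spat l)] truncated at zero; fibers outside the
    targeted column return 0.
    """
    t_s = np.asarray(t_s, dtype=float)
    if not fiber.in_column:
        return np.zeros_like(t_s)
    l_min, l_max = inverse_michelson(C)
    r_min = _luminance_to_rate(l_min, R_peak, R_bk)
    r_max = _luminance_to_rate(l_max, R_peak, R_bk)
    phase = 2.0 * math.pi * f_temp * t_s - 2.0 * math.pi * f_spat * fiber.linear_position
    rate = r_min + 0.5 * (r_max - r_min) * (1.0 + np.sin(phase))
    return np.maximum(rate, 0.0)


# ---------------------------------------------------------------------------
# Adapting Markov spiking process
# ---------------------------------------------------------------------------

def adapting_markov_spikes(rate_hz: np.ndarray, tau_adapt_ms: float = TAU_ADAPT_MS,
                           dt: float = DT_STIMULUS_MS, seed: int = 0,
                           adapt_increment_hz: float = 2.0) -> np.ndarray:
    """Spikes from a rate series via a spike-frequency-adapting hazard.

    The hazard is the requested rate minus an adaptation state that jumps by
    ``adapt_increment_hz`` on each emitted spike and decays exponentially with
    ``tau_adapt_ms``. The drive is pre-scaled by (1 + increment * tau) so that
    for a constant input rate r the long-run emitted rate is r (within 5%);
    the negative-feedback loop makes the train more regular than Poisson.
    """
    rate = np.asarray(rate_hz, dtype=float)
    if np.any(rate < 0):
        raise ValueError("negative input rates must be truncated beforehand")
    rng = np.random.default_rng(seed)
    tau_s = tau_adapt_ms / 1000.0
    gain = 1.0 + adapt_increment_hz * tau_s
    decay = math.exp(-dt / tau_adapt_ms)
    a = 0.0
    spikes = []
    dts = dt / 1000.0
    u = rng.random(len(rate))
    for i, r in enumerate(rate):
        a *= decay
        lam = gain * r - a
        if lam > 0 and u[i] < lam * dts:
            spikes.append(i * dt)
            a += adapt_increment_hz
    return np.asarray(spikes)


# ---------------------------------------------------------------------------
# Binary-signal encoders (rate / synchrony coding)
# ---------------------------------------------------------------------------

@dataclass
class BinarySignal:
    """Alternating down/up signal with random 2-7 s dwell times."""

    switch_times_s: np.ndarray   # ascending; state flips at each switch
    duration_s: float
    initial_state: int = 0       # 0 = down, 1 = up

    def __post_init__(self) -> None:
        sw = np.asarray(self.switch_times_s, dtype=float)
        intervals = np.diff(np.concatenate([[0.0], sw, [self.duration_s]]))
        # the trailing interval may be cut short by the recording end
        if len(intervals) > 1 and (np.any(intervals[:-1] < 2.0 - 1e-9)
                                   or np.any(intervals[:-1] > 7.0 + 1e-9)):
            raise ValueError("inter-switch intervals must lie in [2, 7] s")

    def state_at(self, t_s: np.ndarray) -> np.ndarray:
        n_flips = np.searchsorted(self.switch_times_s, np.asarray(t_s), side="right")
        return (self.initial_state + n_flips) % 2

    def intervals(self) -> list[tuple[float, float, int]]:
        """(start, stop, state) tuples covering [0, duration)."""
        edges = np.concatenate([[0.0], self.switch_times_s, [self.duration_s]])
        out = []
        state = self.initial_state
        for a, b in zip(edges[:-1], edges[1:]):
            out.append((float(a), float(b), state))
            state = 1 - state
        return out


def make_binary_signal(duration_s: float, seed: int = 0,
                       min_interval_s: float = 2.0,
                       max_interval_s: float = 7.0,
                       initial_state: int = 0) -> BinarySignal:
    rng = np.random.default_rng(seed)
    switches = []
    t = rng.uniform(min_interval_s, max_interval_s)
    while t < duration_s:
        switches.append(t)
        t += rng.uniform(min_interval_s, max_interval_s)
    return BinarySignal(switch_times_s=np.asarray(switches),
                        duration_s=duration_s, initial_state=initial_state)


def _poisson_train(rate_hz: float, t0_s: float, t1_s: float,
                   rng: np.random.Generator) -> np.ndarray:
    n = rng.poisson(rate_hz * (t1_s - t0_s))
    return np.sort(rng.uniform(t0_s, t1_s, n))


def binary_code_trains(signal: BinarySignal, n_stim_neurons: int,
                       scheme: str, seed: int = 0,
                       up_rate_hz: float | None = None,
                       down_rate_hz: float | None = None
                       ) -> list[np.ndarray]:
    """Spike trains (seconds) encoding the binary signal.

    scheme='rate': independent Poisson per neuron at the state-dependent
    rate (defaults 30 Hz up / 10 Hz down). scheme='sync': equal rates in both
    states (default 20 Hz), but during up states all neurons share one master
    Poisson train while down states use independent trains.
    """
    if scheme not in ("rate", "sync"):
        raise ValueError("scheme must be 'rate' or 'sync'")
    if not (1 <= n_stim_neurons <= 10 ** 6):
        raise ValueError("n_stim_neurons outside [1, 1e6]")
    if scheme == "rate":
        up = 30.0 if up_rate_hz is None else up_rate_hz
        down = 10.0 if down_rate_hz is None else down_rate_hz
    else:
        up = 20.0 if up_rate_hz is None else up_rate_hz
        down = up if down_rate_hz is None else down_rate_hz
    rng = np.random.default_rng(seed)
    trains: list[list[np.ndarray]] = [[] for _ in range(n_stim_neurons)]
    for t0, t1, state in signal.intervals():
        r = up if state == 1 else down
        if scheme == "sync" and state == 1:
            master = _poisson_train(r, t0, t1, rng)
            for k in range(n_stim_neurons):
                trains[k].append(master)
        else:
            for k in range(n_stim_neurons):
                trains[k].append(_poisson_train(r, t0, t1, rng))
    return [np.concatenate(tr) if tr else np.empty(0) for tr in trains]
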