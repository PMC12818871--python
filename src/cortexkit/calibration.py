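"""Calibration loops for missing-input compensation and synapse physiology.

Three procedures:

1. Population-wise OU compensation calibration. A first mapping
   chi: (R_OU, unconnected rate) -> OU_mu is learned from short simulations of
   the disconnected network along the line OU_sigma = R_OU * OU_mu. A second
   mapping phi: U_FR -> C_FR from unconnected to connected rates is learned
   iteratively by fitting an exponential C = alpha * exp(beta * U) + kappa and
   inverting it to propose unconnected-rate targets for the next iteration.
   Targets are proportions P_FR of a reference in-vivo rate vector V_FR.

2. Pathway PSP calibration: peak conductance scales the mean somatic PSP
   amplitude, the vesicle-pool size adjusts its trial-to-trial CV.

3. mPSC calibration: the per-synapse spontaneous release rate reproducing a
   target miniature-PSC frequency is interpolated from a logarithmic fit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import curve_fit

from .background import OUInjectionTable
from .engine import SpikeOverflowError, simulate
from .network import Network, SimulationConfig, disconnect
from .synapses import TMSynapseParams, biexp_normalization, hill_scaled_use
from .engine import TAU_RISE_AMPA


@dataclass(frozen=True)
class MetaParams:
    """Meta-parameters of the spontaneous state."""

    calcium_Cao: float = 1.05  # mM
    R_OU: float = 0.4
    P_FR: float = 0.3

    def __post_init__(self) -> None:
        if not (0.0 <= self.P_FR <= 1.0):
            raise ValueError("P_FR must be in [0, 1]")
        if self.R_OU <= 0:
            raise ValueError("R_OU must be > 0")


@dataclass
class FRVector:
    """Ordered firing rates (Hz) for the nine populations."""

    rates: np.ndarray
    role: str = "V_FR"  # V_FR | C_FR | U_FR
    populations: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        if len(self.rates) != 9:
            raise ValueError("expected exactly 9 population rates")
        if np.any(self.rates < 0):
            raise ValueError("rates must be >= 0")


# In-vivo-like layer-wise reference rates (Hz) used as the surrogate's V_FR,
# ordered L1_I, L23_E, L23_I, L4_E, L4_I, L5_E, L5_I, L6_E, L6_I.
DEFAULT_VFR = np.array([1.5, 0.3, 0.96, 0.6, 1.2, 1.3, 2.4, 0.5, 1.5])


# ---------------------------------------------------------------------------
# chi: (R_OU, unconnected rate) <-> OU_mu
# ---------------------------------------------------------------------------

@dataclass
class ChiMapping:
    """Per-population interpolation table OU_mu <-> unconnected rate."""

    R_OU: float
    mu_grid: np.ndarray                 # percent of G_in
    rates: np.ndarray                   # (n_pops, n_grid) Hz
    populations: list[str]

    def _monotone(self, p: int) -> tuple[np.ndarray, np.ndarray]:
        """Strictly increasing (rate, mu) support for inversion.

        Leading zero-rate grid points are collapsed onto the last one (the
        firing onset), so small targets interpolate across the onset interval
        rather than the whole silent stretch."""
        mu, r = self.mu_grid, self.rates[p]
        start = 0
        for i in range(len(r)):
            if r[i] == 0.0:
                start = i
            else:
                break
        keep_mu = [mu[start]]
        keep_r = [r[start]]
        for m, v in zip(mu[start + 1:], r[start + 1:]):
            if v > keep_r[-1]:
                keep_mu.append(m)
                keep_r.append(v)
        return np.array(keep_r), np.array(keep_mu)

    def invert(self, population: str, target_rate: float) -> tuple[float, bool]:
        """OU_mu achieving ``target_rate`` when unconnected; (mu, in_range)."""
        p = self.populations.index(population)
        r, mu = self._monotone(p)
        if len(r) < 2 or target_rate <= r[0]:
            return float(self.mu_grid[0]), target_rate <= r[0] if len(r) else False
        if target_rate > r[-1]:
            return float(mu[-1]), False
        return float(np.interp(target_rate, r, mu)), True

    def forward(self, population: str, mu: float) -> float:
        p = self.populations.index(population)
        return float(np.interp(mu, self.mu_grid, self.rates[p]))


def learn_chi(network: Network, R_OU: float,
              mu_grid=(0.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 35.0, 40.0),
              sim_duration: float = 1000.0, transient: float = 200.0,
              seed: int = 0, calcium: float = 1.05,
              g_in: dict[str, float] | None = None) -> ChiMapping:
    """Learn chi from 1-second simulations of the disconnected network.

    One simulation per grid point suffices because, unconnected, the
    populations are mutually independent. chi is independent of calcium
    (no recurrent synapses are active).
    """
    mu_grid = np.asarray(sorted(mu_grid), dtype=float)
    if len(mu_grid) < 5:
        raise ValueError("need at least 5 grid points")
    dnet = disconnect(network)
    pops = network.population_names
    rates = np.zeros((len(pops), len(mu_grid)))
    for gi, mu in enumerate(mu_grid):
        table = OUInjectionTable.from_mu({p: mu for p in pops}, R_OU)
        cfg = SimulationConfig(duration=sim_duration, calcium_Cao=calcium,
                               seed=int(np.random.SeedSequence([seed, gi]).generate_state(1)[0] % 2**31))
        rec, _ = simulate(dnet, cfg, ou_table=table, g_in=g_in)
        rates[:, gi] = rec.population_rates(t_start=transient)
    if np.all(rates == 0):
        raise RuntimeError("all rates zero over the OU_mu grid; grid too low")
    return ChiMapping(R_OU=R_OU, mu_grid=mu_grid, rates=rates, populations=list(pops))


def extend_chi(chi: ChiMapping, network: Network, seed: int = 0,
               calcium: float = 1.05, g_in=None,
               sim_duration: float = 1000.0, transient: float = 200.0) -> ChiMapping:
    """Double the top grid point (extension policy for unreachable targets)."""
    new_top = 2.0 * chi.mu_grid[-1] if chi.mu_grid[-1] > 0 else 20.0
    grid = np.append(chi.mu_grid, new_top)
    dnet = disconnect(network)
    table = OUInjectionTable.from_mu({p: new_top for p in chi.populations}, chi.R_OU)
    cfg = SimulationConfig(duration=sim_duration, calcium_Cao=calcium,
                           seed=int(np.random.SeedSequence([seed, len(grid)]).generate_state(1)[0] % 2**31))
    rec, _ = simulate(dnet, cfg, ou_table=table, g_in=g_in)
    rates = np.column_stack([chi.rates, rec.population_rates(t_start=transient)])
    return ChiMapping(R_OU=chi.R_OU, mu_grid=grid, rates=rates,
                      populations=chi.populations)


# ---------------------------------------------------------------------------
# phi: U_FR -> C_FR
# ---------------------------------------------------------------------------

class TargetUnreachableError(ValueError):
    """phi inversion undefined for the requested target (below kappa)."""


@dataclass
class PhiFit:
    alpha: float
    beta: float
    kappa: float
    residual: float = 0.0
    linear: bool = False  # beta degenerated; (alpha, kappa) = (slope, intercept)


@dataclass
class PhiMapping:
    """Exponential map C_FR = alpha * exp(beta * U_FR) + kappa, per population."""

    fits: dict[str, PhiFit] = field(default_factory=dict)
    identity: bool = False

    @classmethod
    def make_identity(cls) -> "PhiMapping":
        return cls(identity=True)

    def forward(self, population: str, u: float) -> float:
        if self.identity:
            return u
        f = self.fits[population]
        if f.linear:
            return f.alpha * u + f.kappa
        return f.alpha * math.exp(f.beta * u) + f.kappa

    def invert(self, population: str, target_c: float) -> float:
        return invert_phi(self, population, target_c)


def fit_phi(samples: dict[str, tuple[np.ndarray, np.ndarray]],
            beta_degenerate_span: float = 0.05) -> PhiMapping:
    """Fit the exponential unconnected->connected rate map per population.

    ``samples`` maps population -> (U_FR, C_FR) arrays (>= 3 distinct points).
    If the fitted exponent is negligible over the sampled span the fit falls
    back to a flagged linear model with kappa absorbing the intercept.
    """
    fits = {}
    for pop, (u, c) in samples.items():
        u = np.asarray(u, dtype=float)
        c = np.asarray(c, dtype=float)
        if len(np.unique(u)) < 3:
            raise ValueError(f"{pop}: need >= 3 distinct U_FR points")
        if not (np.all(np.isfinite(u)) and np.all(np.isfinite(c))):
            raise ValueError(f"{pop}: non-finite inputs")
        fits[pop] = _fit_exponential(u, c, beta_degenerate_span)
    return PhiMapping(fits=fits)


def _fit_exponential(u: np.ndarray, c: np.ndarray,
                     beta_degenerate_span: float) -> PhiFit:
    span = u.max() - u.min()
    slope, intercept = np.polyfit(u, c, 1)
    lin_res = float(np.sum((slope * u + intercept - c) ** 2))

    # initialisation: scan kappa below min(c), linearise log(c - kappa)
    best = None
    c_range = max(c.max() - c.min(), 1e-9)
    for frac in (0.1, 0.5, 1.0, 2.0, 5.0):
        kappa0 = c.min() - frac * c_range
        y = np.log(c - kappa0)
        b0, loga0 = np.polyfit(u, y, 1)
        try:
            popt, _ = curve_fit(lambda x, a, b, k: a * np.exp(b * x) + k,
                                u, c, p0=(math.exp(loga0), b0, kappa0),
                                maxfev=20000)
        except RuntimeError:
            continue
        res = float(np.sum((popt[0] * np.exp(popt[1] * u) + popt[2] - c) ** 2))
        if best is None or res < best[1]:
            best = (popt, res)
    if best is None:
        return PhiFit(alpha=slope, beta=0.0, kappa=intercept,
                      residual=lin_res, linear=True)
    (alpha, beta, kappa), res = best
    if abs(beta) * span < beta_degenerate_span or res >= lin_res * (1 - 1e-12):
        return PhiFit(alpha=slope, beta=0.0, kappa=intercept,
                      residual=lin_res, linear=True)
    return PhiFit(alpha=float(alpha), beta=float(beta), kappa=float(kappa),
                  residual=res)


def invert_phi(phi: PhiMapping, population: str, target_c: float) -> float:
    """U_FR = ln((C - kappa)/alpha) / beta, clamped at zero below.

    Raises TargetUnreachableError when the target lies at or below the
    asymptote kappa (caller widens the search grid).
    """
    if phi.identity:
        return max(target_c, 0.0)
    f = phi.fits[population]
    if f.linear:
        if f.alpha == 0:
            raise TargetUnreachableError(f"{population}: flat linear mapping")
        return max((target_c - f.kappa) / f.alpha, 0.0)
    ratio = (target_c - f.kappa) / f.alpha
    if ratio <= 0 or f.beta == 0:
        raise TargetUnreachableError(
            f"{population}: target {target_c} unreachable (kappa={f.kappa})")
    return max(math.log(ratio) / f.beta, 0.0)


# ---------------------------------------------------------------------------
# The iterative compensation calibration
# ---------------------------------------------------------------------------

def detect_bursting(recording, bin_ms: float = 5.0, cv_threshold: float = 2.0,
                    quiet_fraction: float = 0.3, t_start: float = 0.0,
                    min_rate_hz: float = 0.5) -> bool:
    """Network-wide all-or-nothing events: high CV of the population rate
    histogram with near-silent bins between peaks.

    Sparse asynchronous activity below ``min_rate_hz`` (mean per neuron) is
    never classified as bursting, however irregular its count histogram."""
    edges = np.arange(t_start, recording.duration + bin_ms, bin_ms)
    counts, _ = np.histogram(recording.times_ms, bins=edges)
    if counts.sum() == 0 or counts.mean() == 0:
        return False
    span_s = (recording.duration - t_start) / 1000.0
    if counts.sum() / (len(recording.pop_index) * span_s) < min_rate_hz:
        return False
    cv = counts.std() / counts.mean()
    quiet = np.mean(counts < 0.05 * counts.max())
    return bool(cv > cv_threshold and quiet > quiet_fraction)


@dataclass
class IterationRecord:
    iteration: int
    P_max: float
    levels: np.ndarray
    distances: np.ndarray           # per level, RMS over populations
    ou_mu: np.ndarray               # (n_levels, n_pops)
    observed_rates: np.ndarray      # (n_levels, n_pops)
    bursting: np.ndarray            # per-level flags


@dataclass
class CalibrationResult:
    tables: list[OUInjectionTable]  # per level, final iteration
    levels: np.ndarray              # P_FR values
    phi: PhiMapping
    chi: ChiMapping
    iterations: int
    converged: bool
    log: list[IterationRecord]
    unreachable: list[str] = field(default_factory=list)

    def table_for(self, P_FR: float) -> OUInjectionTable:
        i = int(np.argmin(np.abs(self.levels - P_FR)))
        return self.tables[i]


def calibrate_compensation(network: Network, calcium: float, R_OU: float,
                           V_FR: np.ndarray | FRVector,
                           n_levels: int = 10, max_iter: int = 10,
                           tol: float = 0.1, seed: int = 0,
                           chi: ChiMapping | None = None,
                           warm_start_phi: PhiMapping | None = None,
                           sim_duration: float = 6500.0,
                           transient: float = 1500.0,
                           g_in: dict[str, float] | None = None,
                           chi_grid=(0.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 35.0, 40.0),
                           ) -> CalibrationResult:
    """Iterative population-wise calibration of the OU compensation.

    Each iteration simulates the connected network at ``n_levels`` target
    proportions P_FR of V_FR (first cold iteration: P_max = 0.5, afterwards
    P_max = 1.0), measures connected rates, refits phi and re-inverts.
    Terminates when every level's RMS distance (over populations, in
    normalized P_FR units) between observed and target falls below ``tol``.
    """
    vfr = V_FR.rates if isinstance(V_FR, FRVector) else np.asarray(V_FR, float)
    pops = network.population_names
    if len(vfr) != len(pops):
        raise ValueError("V_FR length must match population count")
    if chi is None:
        chi = learn_chi(network, R_OU, mu_grid=chi_grid, seed=seed,
                        calcium=calcium, g_in=g_in)

    # populations that fire at rest cannot reach a zero (or tiny) target
    unreachable = []
    rest_rates = chi.rates[:, np.searchsorted(chi.mu_grid, 0.0)] \
        if chi.mu_grid[0] == 0.0 else np.zeros(len(pops))
    for p, name in enumerate(pops):
        if vfr[p] == 0 and rest_rates[p] > 0:
            unreachable.append(name)

    phi = warm_start_phi if warm_start_phi is not None else PhiMapping.make_identity()
    cold = warm_start_phi is None
    active = vfr > 0

    log: list[IterationRecord] = []
    tables: list[OUInjectionTable] = []
    levels = np.array([])
    converged = False
    n_iter = 0
    # (proposed U, observed C) samples from recent iterations; the phi refit
    # uses a two-iteration sliding window: one iteration's 10 points alone
    # condition the exponential poorly, while older samples would dominate
    # the fit with stale high-leverage points
    hist_u = {name: [] for name in pops}
    hist_c = {name: [] for name in pops}
    window = 2 * n_levels

    for it in range(1, max_iter + 1):
        n_iter = it
        P_max = 0.5 if (cold and it == 1 and phi.identity) else 1.0
        levels = P_max * np.arange(1, n_levels + 1) / n_levels

        # propose U_FR and OU_mu per level
        mu_per_level = np.zeros((n_levels, len(pops)))
        u_prop = np.zeros((n_levels, len(pops)))
        for li, P in enumerate(levels):
            for p, name in enumerate(pops):
                target_c = P * vfr[p]
                try:
                    u = phi.invert(name, target_c)
                except TargetUnreachableError:
                    u = 0.0
                if hist_u[name]:
                    # trust region: never extrapolate proposals far beyond
                    # the unconnected-rate range already explored
                    u = min(u, 2.0 * max(hist_u[name]) + 1.0)
                mu, in_range = chi.invert(name, u)
                if not in_range and u > 0:
                    chi = extend_chi(chi, network, seed=seed, calcium=calcium,
                                     g_in=g_in)
                    mu, _ = chi.invert(name, u)
                mu_per_level[li, p] = mu
                u_prop[li, p] = u

        # simulate the connected network at each level
        obs = np.zeros((n_levels, len(pops)))
        burst = np.zeros(n_levels, dtype=bool)
        for li in range(n_levels):
            table = OUInjectionTable.from_mu(
                dict(zip(pops, mu_per_level[li])), R_OU)
            sim_seed = int(np.random.SeedSequence([seed, it, li]).generate_state(1)[0] % 2**31)
            cfg = SimulationConfig(duration=sim_duration, calcium_Cao=calcium,
                                   seed=sim_seed)
            try:
                rec, _ = simulate(network, cfg, ou_table=table, g_in=g_in)
            except SpikeOverflowError:
                burst[li] = True
                obs[li] = np.nan
                continue
            if detect_bursting(rec, t_start=transient):
                burst[li] = True
            obs[li] = rec.population_rates(t_start=transient)

        with np.errstate(invalid="ignore", divide="ignore"):
            obs_P = np.where(active, obs / np.where(active, vfr, 1.0), 0.0)
        dists = np.full(n_levels, np.inf)
        for li in range(n_levels):
            if burst[li]:
                continue
            err = obs_P[li, active] - levels[li]
            dists[li] = float(np.sqrt(np.mean(err ** 2)))

        tables = [OUInjectionTable.from_mu(dict(zip(pops, mu_per_level[li])), R_OU)
                  for li in range(n_levels)]
        log.append(IterationRecord(iteration=it, P_max=P_max, levels=levels,
                                   distances=dists, ou_mu=mu_per_level,
                                   observed_rates=obs, bursting=burst))

        ok_levels = ~burst
        if P_max == 1.0 and np.all(dists[ok_levels] < tol) and ok_levels.any():
            converged = True
            break

        # refit phi on the accumulated proposed-U / observed-C samples
        good = ~burst
        if good.sum() >= 3:
            new_fits = {}
            for p, name in enumerate(pops):
                hist_u[name] = (hist_u[name] + u_prop[good, p].tolist())[-window:]
                hist_c[name] = (hist_c[name] + obs[good, p].tolist())[-window:]
                u = np.array(hist_u[name])
                c = np.array(hist_c[name])
                if len(np.unique(u)) >= 3:
                    new_fits[name] = _fit_exponential(u, c, 0.05)
                else:
                    # degenerate sampling (targets collapsed); scale linearly
                    ratio = c.sum() / u.sum() if u.sum() > 0 else 1.0
                    new_fits[name] = PhiFit(alpha=ratio, beta=0.0, kappa=0.0,
                                            linear=True)
            phi = PhiMapping(fits=new_fits)
        else:
            warnings.warn("too few non-bursting levels to refit phi")

    return CalibrationResult(tables=tables, levels=levels, phi=phi, chi=chi,
                             iterations=n_iter, converged=converged, log=log,
                             unreachable=unreachable)


# ---------------------------------------------------------------------------
# PSP calibration of (ghat, N_RRP)
# ---------------------------------------------------------------------------

def _unit_psp_peak(post_params, decay_tau: float, hold_mV: float,
                   dt: float = 0.1, window_ms: float = 100.0) -> float:
    """Somatic PSP peak (mV) per nS of peak synaptic conductance, at hold."""
    n = int(window_ms / dt)
    t = np.arange(n) * dt
    norm = biexp_normalization(TAU_RISE_AMPA, decay_tau)
    g = norm * (np.exp(-t / decay_tau) - np.exp(-t / TAU_RISE_AMPA))
    gL = post_params.leak_conductance
    C = post_params.membrane_capacitance
    I_hold = gL * (hold_mV - post_params.leak_reversal)
    V = hold_mV
    peak = 0.0
    Ee = post_params.excitatory_reversal
    for i in range(n):
        g_tot = gL + g[i]
        V_inf = (gL * post_params.leak_reversal + g[i] * Ee + I_hold) / g_tot
        V = V_inf + (V - V_inf) * math.exp(-dt * g_tot / C)
        peak = max(peak, V - hold_mV)
    return peak


@dataclass
class PSPCalibrationResult:
    ghat: float
    nrrp: int
    mean_mV: float
    cv: float
    converged: bool
    at_univesicular_bound: bool
    iterations: int


def _psp_sample(params: TMSynapseParams, nrrp: int, n_pairs: int, n_reps: int,
                calcium: float, unit_peak: float, n_syn: int,
                pair_jitter_sd: float, cv_aggregation: str,
                rng: np.random.Generator) -> tuple[float, float]:
    u = hill_scaled_use(replace(params, vesicle_pool=nrrp), calcium)
    pool = n_syn * nrrp
    pair_scale = np.exp(rng.normal(0.0, pair_jitter_sd, n_pairs))
    released = rng.binomial(pool, u, size=(n_pairs, n_reps))
    amps = released * params.peak_conductance * unit_peak * pair_scale[:, None]
    pair_means = amps.mean(axis=1)
    if cv_aggregation == "per_pair":
        with np.errstate(invalid="ignore", divide="ignore"):
            cvs = np.where(pair_means > 0, amps.std(axis=1) / pair_means, 0.0)
        cv = float(cvs.mean())
    else:  # pooled
        cv = float(amps.std() / amps.mean()) if amps.mean() > 0 else 0.0
    return float(pair_means.mean()), cv


def calibrate_synapse_psp(params: TMSynapseParams, target_mean_mV: float,
                          target_cv: float, n_pairs: int = 50, n_reps: int = 35,
                          seed: int = 0, calcium: float = 2.0,
                          post_params=None, hold_mV: float = -70.0,
                          tol_mean: float = 0.05, tol_cv: float = 0.10,
                          max_iter: int = 30, n_syn_per_connection: int = 5,
                          pair_jitter_sd: float = 0.2,
                          cv_aggregation: str = "per_pair",
                          ) -> PSPCalibrationResult:
    """Bivariate search for (ghat, N_RRP) matching a PSP mean and CV.

    The postsynaptic cell is held at ``hold_mV`` in current clamp; each of
    ``n_pairs`` sampled pairs is stimulated ``n_reps`` times. ghat rescales
    the mean amplitude (linear subthreshold regime); the vesicle pool size is
    stepped to move the CV, bounded below by univesicular release.
    ``cv_aggregation``: 'per_pair' computes the CV across repetitions within
    each pair then averages over pairs; 'pooled' uses all repetitions at once.
    """
    if post_params is None:
        from .network import NeuronParams
        post_params = NeuronParams()
    unit_peak = _unit_psp_peak(post_params, params.decay_tau, hold_mV)
    ghat = params.peak_conductance
    nrrp = int(params.vesicle_pool)
    at_bound = False
    for it in range(1, max_iter + 1):
        rng = np.random.default_rng(np.random.SeedSequence([seed, it]))
        mean, cv = _psp_sample(replace(params, peak_conductance=ghat), nrrp,
                               n_pairs, n_reps, calcium, unit_peak,
                               n_syn_per_connection, pair_jitter_sd,
                               cv_aggregation, rng)
        mean_ok = abs(mean - target_mean_mV) <= tol_mean * target_mean_mV
        cv_ok = abs(cv - target_cv) <= tol_cv * target_cv
        if mean_ok and (cv_ok or at_bound):
            return PSPCalibrationResult(ghat=ghat, nrrp=nrrp, mean_mV=mean,
                                        cv=cv, converged=cv_ok,
                                        at_univesicular_bound=at_bound,
                                        iterations=it)
        if mean > 0:
            ghat *= target_mean_mV / mean
        if not cv_ok:
            if cv < target_cv and not at_bound:
                if nrrp > 1:
                    nrrp -= 1
                else:
                    at_bound = True  # CV unreachable from below pool = 1
            elif cv > target_cv:
                nrrp += 1
                at_bound = False
    return PSPCalibrationResult(ghat=ghat, nrrp=nrrp, mean_mV=mean, cv=cv,
                                converged=False, at_univesicular_bound=at_bound,
                                iterations=max_iter)


# ---------------------------------------------------------------------------
# mPSC spontaneous-rate calibration
# ---------------------------------------------------------------------------

@dataclass
class MpscCalibrationResult:
    spontaneous_rate: float   # Hz per synapse
    fit_a: float
    fit_b: float
    frequencies: np.ndarray   # measured somatic mPSC frequency per candidate
    candidate_rates: np.ndarray
    extrapolated: bool


def measure_mpsc_frequency(n_cells: int, n_synapses: int, rate_hz: float,
                           duration_s: float, dead_time_ms: float = 2.0,
                           seed: int = 0) -> float:
    """Somatic mPSC detection frequency for voltage-clamped cells.

    Spontaneous single-vesicle releases are independent Poisson events across
    synapses; somatic events closer than the detector dead time merge into
    one (coincidence losses at high rates)."""
    rng = np.random.default_rng(seed)
    freqs = np.empty(n_cells)
    lam = n_synapses * rate_hz * duration_s
    for c in range(n_cells):
        n_ev = rng.poisson(lam)
        if n_ev == 0:
            freqs[c] = 0.0
            continue
        t = np.sort(rng.uniform(0, duration_s * 1000.0, n_ev))
        # greedy merge within the dead time
        detected = 1
        last = t[0]
        for x in t[1:]:
            if x - last >= dead_time_ms:
                detected += 1
                last = x
        freqs[c] = detected / duration_s
    return float(freqs.mean())


def calibrate_mpsc(target_freq_hz: float, candidate_rates,
                   n_cells: int = 100, n_synapses: int = 100,
                   duration_s: float = 10.0, dead_time_ms: float = 2.0,
                   seed: int = 0) -> MpscCalibrationResult:
    """Interpolate the spontaneous release rate from a logarithmic fit.

    Simulates voltage-clamped cells at each candidate per-synapse rate,
    counts detected somatic mPSCs, fits freq = a*ln(rate) + b and returns the
    rate matching the target frequency. Targets outside the measured range
    are flagged as extrapolations."""
    candidates = np.asarray(sorted(candidate_rates), dtype=float)
    if np.any(candidates <= 0):
        raise ValueError("candidate rates must be > 0")
    freqs = np.array([
        measure_mpsc_frequency(n_cells, n_synapses, r, duration_s,
                               dead_time_ms,
                               seed=int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % 2**31))
        for i, r in enumerate(candidates)])
    a, b = np.polyfit(np.log(candidates), freqs, 1)
    if a == 0:
        raise RuntimeError("degenerate logarithmic fit")
    rate = float(np.exp((target_freq_hz - b) / a))
    extrapolated = not (freqs.min() <= target_freq_hz <= freqs.max())
    if extrapolated:
        warnings.warn("target mPSC frequency outside the fitted range; "
                      "extrapolating")
    return MpscCalibrationResult(spontaneous_rate=rate, fit_a=float(a),
                                 fit_b=float(b), frequencies=freqs,
                                 candidate_rates=candidates,
                                 extrapolated=extrapolated)
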