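"""Ornstein-Uhlenbeck somatic conductance injection.

Compensates for synapses from brain regions outside the modelled volume by
injecting, at each soma, an excitatory conductance following a mean-reverting
OU process. The mean and standard deviation of the process are expressed as
percentages (OU_mu, OU_sigma) of the cell's input conductance G_in, and the
two are tied by a fixed ratio R_OU = OU_sigma / OU_mu during calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Default OU time constant (ms); excitatory point-conductance convention.
OU_TAU_DEFAULT = 3.0

#: Default reversal potential of the injected conductance (mV, excitatory).
OU_REVERSAL_DEFAULT = 0.0


@dataclass(frozen=True)
class OUParams:
    """Per-population OU injection parameters (percent of G_in)."""

    OU_mu: float                      # percent of G_in
    OU_sigma: float                   # percent of G_in
    tau: float = OU_TAU_DEFAULT       # ms
    reversal: float = OU_REVERSAL_DEFAULT  # mV

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.OU_sigma < 0:
            raise ValueError("OU_sigma must be >= 0")

    @property
    def diffusion(self) -> float:
        """Diffusion coefficient D = 2 sigma^2 / tau (in percent^2/ms)."""
        return 2.0 * self.OU_sigma ** 2 / self.tau


@dataclass
class OUInjectionTable:
    """Map population name -> OUParams, with the noise ratio R_OU recorded."""

    params: dict[str, OUParams] = field(default_factory=dict)
    R_OU: float = 0.4

    @classmethod
    def from_mu(cls, mu_percent: dict[str, float], R_OU: float,
                tau: float = OU_TAU_DEFAULT,
                reversal: float = OU_REVERSAL_DEFAULT) -> "OUInjectionTable":
        """Build through the ratio constraint OU_sigma = OU_mu * R_OU."""
        table = {name: OUParams(OU_mu=mu, OU_sigma=mu * R_OU, tau=tau,
                                reversal=reversal)
                 for name, mu in mu_percent.items()}
        return cls(params=table, R_OU=R_OU)

    def mu_vector(self, order: list[str]) -> np.ndarray:
        return np.array([self.params[name].OU_mu for name in order])


def scale_to_cell(params: OUParams, G_in: float) -> tuple[float, float]:
    """Absolute (g0, sigma) in nS for a cell with input conductance G_in."""
    if G_in <= 0:
        raise ValueError("G_in must be > 0")
    return (params.OU_mu / 100.0) * G_in, (params.OU_sigma / 100.0) * G_in


def ou_trace(g0: float, sigma: float, tau: float, dt: float, duration: float,
             seed: int | np.random.Generator = 0,
             clip: bool = False) -> np.ndarray:
    """Sample one OU conductance trace with the exact discretisation.

    g(t+dt) = g0 + (g(t) - g0) e^(-dt/tau) + sigma sqrt(1 - e^(-2 dt/tau)) N(0,1)

    Returns the raw (pre-clipping) series by default; ``clip=True`` applies
    the rectification at zero that is used at the point of injection.
    """
    if tau <= 0 or dt <= 0 or duration <= 0:
        raise ValueError("tau, dt and duration must be > 0")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if dt > tau:
        raise ValueError("dt > tau: discretisation invalid")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration / dt))
    decay = np.exp(-dt / tau)
    fluct = sigma * np.sqrt(1.0 - decay ** 2)
    g = np.empty(n)
    g[0] = g0
    noise = rng.standard_normal(n - 1) if n > 1 else np.empty(0)
    for i in range(1, n):
        g[i] = g0 + (g[i - 1] - g0) * decay + fluct * noise[i - 1]
    if clip:
        g = np.maximum(g, 0.0)
    return g
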