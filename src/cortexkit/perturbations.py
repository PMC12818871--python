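"""In-silico experimental manipulations: optogenetics and pathway lesions.

Optogenetic stimulation is a somatic current injection proportional to each
cell's rheobase, attenuated with cortical depth following a modified
Beer-Lambert law. Lesions remove all synaptic connections between selected
pre- and postsynaptic neuron sets.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .engine import StepCurrent
from .network import Connectome, Network

#: (mu_a, mu_s') in 1/mm for the wavelengths used by the recreated paradigms.
WAVELENGTH_COEFFICIENTS = {
    595.0: (0.49, 4.12),   # yellow (inhibitory opsin paradigm)
    470.0: (0.46, 5.38),   # blue (interneuron activation paradigm)
}


@dataclass(frozen=True)
class LightField:
    """Surface light intensity and tissue attenuation parameters.

    ``I0`` is a signed percentage of each targeted cell's rheobase at the
    cortical surface (negative for hyperpolarizing opsins).
    """

    I0_percent: float
    mu_a: float            # absorption coefficient, 1/mm
    mu_s_prime: float      # reduced scattering coefficient, 1/mm
    wavelength_nm: float | None = None
    n_depth_bins: int = 5
    ramp_ms: float = 100.0

    def __post_init__(self) -> None:
        if self.mu_a <= 0 or self.mu_s_prime < 0:
            raise ValueError("attenuation coefficients must be positive")
        if self.n_depth_bins < 1:
            raise ValueError("n_depth_bins must be >= 1")

    @classmethod
    def for_wavelength(cls, wavelength_nm: float, I0_percent: float,
                       **kwargs) -> "LightField":
        if wavelength_nm not in WAVELENGTH_COEFFICIENTS:
            raise KeyError(f"no built-in coefficients for {wavelength_nm} nm; "
                           "pass mu_a and mu_s_prime explicitly")
        mu_a, mu_s = WAVELENGTH_COEFFICIENTS[wavelength_nm]
        return cls(I0_percent=I0_percent, mu_a=mu_a, mu_s_prime=mu_s,
                   wavelength_nm=wavelength_nm, **kwargs)

    @property
    def mu_eff_per_mm(self) -> float:
        return mu_eff(self.mu_a, self.mu_s_prime)


def mu_eff(mu_a: float, mu_s_prime: float) -> float:
    """Effective attenuation coefficient sqrt(3 mu_a (mu_a + mu_s'))."""
    if mu_a <= 0 or mu_s_prime < 0:
        raise ValueError("coefficients must be positive")
    return math.sqrt(3.0 * mu_a * (mu_a + mu_s_prime))


def intensity_at_depth(I0: float, mu_eff_per_mm: float, depth_mm):
    """Beer-Lambert attenuation I(d) = I0 exp(-mu_eff d)."""
    return I0 * np.exp(-mu_eff_per_mm * np.asarray(depth_mm, dtype=float))


def depth_bins(depths_mm: np.ndarray, mu_eff_per_mm: float, n_bins: int
               ) -> tuple[np.ndarray, np.ndarray, bool]:
    """Assign targeted cells to depth bins of equal intensity increments.

    Bin edges are spaced equally in injected-current (intensity) terms
    between the shallowest and deepest targeted cell, so bins grow wider
    with depth under the exponential attenuation profile. Each cell uses the
    intensity at its bin's center (midpoint in intensity). A cell exactly on
    an internal edge goes to the shallower bin.

    Returns (bin assignment per cell, relative intensity per cell in units
    of the surface intensity at the shallowest cell, collapsed flag).
    """
    d = np.asarray(depths_mm, dtype=float)
    if len(d) == 0:
        raise ValueError("no targeted cells")
    d_lo, d_hi = d.min(), d.max()
    collapsed = False
    if d_lo == d_hi:
        if n_bins > 1:
            collapsed = True
            warnings.warn("all cells at one depth; collapsing to one bin")
        n_bins = 1
    i_top = math.exp(-mu_eff_per_mm * d_lo)
    i_bot = math.exp(-mu_eff_per_mm * d_hi)
    i_edges = np.linspace(i_top, i_bot, n_bins + 1)
    # depth edges corresponding to the intensity edges (increasing in depth)
    d_edges = -np.log(i_edges) / mu_eff_per_mm
    d_edges[0], d_edges[-1] = d_lo, d_hi
    # side='left': a cell exactly on an internal edge joins the shallower bin
    assign = np.clip(np.searchsorted(d_edges, d, side="left") - 1, 0, n_bins - 1)
    bin_intensity = 0.5 * (i_edges[:-1] + i_edges[1:])
    return assign, bin_intensity[assign], collapsed


def opto_injection(depths_mm: np.ndarray, rheobase_nA: np.ndarray,
                   light: LightField, onset_ms: float, duration_ms: float
                   ) -> tuple[np.ndarray, StepCurrent]:
    """Per-cell optogenetic current amplitudes and the pulse waveform.

    amplitude(cell) = (I0/100) * rheobase(cell) * I(bin)/I(surface), where
    the surface intensity is taken at the top of the targeted population.
    The pulse is square with a linear ramp of ``light.ramp_ms`` at offset
    (avoiding rebound spikes after strong hyperpolarization).
    """
    d = np.asarray(depths_mm, dtype=float)
    rheo = np.asarray(rheobase_nA, dtype=float)
    if len(d) != len(rheo):
        raise ValueError("depths and rheobase arrays must align")
    if np.any(~np.isfinite(rheo)):
        raise ValueError("missing rheobase for some cells")
    mu = light.mu_eff_per_mm
    _, rel_intensity, _ = depth_bins(d, mu, light.n_depth_bins)
    i_surface = math.exp(-mu * d.min())
    amps = (light.I0_percent / 100.0) * rheo * rel_intensity / i_surface
    wave = StepCurrent(amplitude_nA=amps, onset_ms=onset_ms,
                       offset_ms=onset_ms + duration_ms,
                       ramp_ms=light.ramp_ms)
    return amps, wave


@dataclass(frozen=True)
class LesionSpec:
    """Pre- and postsynaptic neuron-id selectors."""

    pre_ids: frozenset
    post_ids: frozenset

    @classmethod
    def between_populations(cls, network: Network, pre_population: str,
                            post_population: str) -> "LesionSpec":
        return cls(pre_ids=frozenset(network.neurons_of(pre_population).tolist()),
                   post_ids=frozenset(network.neurons_of(post_population).tolist()))


def lesion(connectome: Connectome, spec: LesionSpec) -> Connectome:
    """Remove all (and only) edges from spec.pre_ids to spec.post_ids."""
    if not spec.pre_ids or not spec.post_ids:
        warnings.warn("lesion selector resolves to an empty set; no-op")
        return connectome.copy()
    pre_arr = np.fromiter(spec.pre_ids, dtype=np.int64)
    post_arr = np.fromiter(spec.post_ids, dtype=np.int64)
    drop = np.isin(connectome.pre, pre_arr) & np.isin(connectome.post, post_arr)
    return connectome.subset(~drop)


def lesion_network(network: Network, pre_population: str, post_population: str
                   ) -> Network:
    """Convenience: lesion one population-to-population pathway."""
    from dataclasses import replace
    spec = LesionSpec.between_populations(network, pre_population, post_population)
    return replace(network, connectome=lesion(network.connectome, spec))
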