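# Methods

cortexkit reproduces, at desk scale, the physiology and in-silico
experimentation workflow of large biophysically detailed cortical column
models: compensating for synaptic input from unmodelled brain regions,
calibrating that compensation against in-vivo reference firing rates,
driving the network with structured thalamic stimuli, perturbing it
optogenetically or by lesioning pathways, and analysing the resulting
activity and its relation to connectome structure. The morphologically
detailed circuit is replaced by a seeded surrogate network of point
neurons; every algorithm downstream of the simulator operates on rates,
spikes, conductances and graphs, and is therefore agnostic to the neuron
model.

## The surrogate network

Nine layer-wise populations (L1_I, L23_E/I, L4_E/I, L5_E/I, L6_E/I) of
conductance-based leaky integrate-and-fire neurons. Default parameters:
excitatory cells C = 200 pF, g_L = 10 nS; inhibitory cells C = 100 pF,
g_L = 8 nS; E_L = -70 mV, threshold -50 mV, reset -60 mV, refractory
2 ms (E) / 1.5 ms (I), reversals 0 / -80 mV. Spike thresholds carry a
per-neuron jitter (SD 3 mV, truncated at +/-2 SD so no threshold
approaches the reset potential). The jitter stands in for the
morphological and electrical diversity of real cortical populations; it
matters operationally because it spreads the population's
frequency-input curve over a wide input range, which keeps the
calibration mappings well-conditioned. Neurons are placed uniformly in
layer-specific depth ranges (rat S1-like, 0-1890 um).

Connectivity is Erdős–Rényi at p = 0.05 by default (any per-pair table
can be supplied), with uniform 1-3 ms conduction delays and one synapse
per connection unless configured otherwise. Synaptic parameters are
carried per pathway class (E->E, E->I, I->E, I->I); the defaults encode
typical depressing cortical phenotypes with conductances chosen so the
default surrogate sits in a stable, asynchronous, inhibition-stabilised
regime across the whole calibration range.

## Synapse model

Connections use the stochastic Tsodyks–Markram model extended to
multivesicular release. Each connection owns a pool of
`nsyn * N_RRP` vesicles. On a presynaptic spike, vesicles that are
available release independently with probability `u`; `u` follows
`u_+ = U_eff + u (1 - U_eff) exp(-dt/F)`, so a first spike releases
with exactly U_eff and `u` relaxes back to U_eff over the facilitation
time constant. Released vesicles recover independently with the
depression time constant D. U_eff scales U_SE with extracellular
calcium through a Hill relation (coefficient U_Hill per pathway)
normalised so that U_eff(2.0 mM) = U_SE; the half-saturation constant
is not an experimentally printed quantity and is a configuration
parameter (default 2.5 mM, chosen so that lowering calcium from the
in-vitro reference 2.0 mM to the in-vivo range 1.05-1.1 mM roughly
halves release probability, the qualitative behaviour reported for
cortical synapses).

Each released vesicle contributes a bi-exponential conductance
transient with peak ghat (quantal convention `vesicle`; the alternative
`connection` convention, ghat/N_RRP per vesicle, is a switch on
`simulate`). Excitatory pathways carry AMPA plus NMDA weighted by the
NMDA/AMPA ratio and a sigmoidal Jahr–Stevens magnesium block
(1/(1 + [Mg]/3.57 mM * exp(-0.062 V)), [Mg] = 1 mM default).
Inhibitory pathways carry GABA_A; the slow GABA_B component is omitted
by default because the surrogate does not distinguish the neurogliaform
cells it would belong to. Spontaneous single-vesicle releases are
independent Poisson events per synapse at the pathway's spontaneous
rate and deplete the pool (switchable view: they are scheduled releases
that fail silently when the pool is empty).

## Integration

Fixed-step exponential Euler at dt = 0.1 ms. Channel states are
difference-of-exponential pairs per receptor per neuron; the AMPA/GABA
decay constants come from the incoming pathway tables (all inputs of
one receptor class onto a given post-synaptic class share a decay
constant), NMDA uses tau_rise 2.9 ms / tau_decay 43 ms. The magnesium
factor is evaluated through a 0.05 mV lookup table and the membrane
update factor exp(-dt g_tot/C) through a 4th-order expansion below
x = 0.2 (relative error < 1e-5); channel states below 1e-12 nS flush
to zero. Voltages are clamped to [E_inh - 30 mV, +60 mV] and any
non-finite state aborts with a diagnostic. The OU background state is
refreshed with the exact discretisation at the largest stride keeping
its sampling interval at or below tau/5 (6 steps at the default
tau = 3 ms). All randomness derives from the one simulation seed, so
spike tables are bit-identical across runs and machines.

## Background input and its calibration

Missing extrinsic input is an excitatory somatic conductance following
an Ornstein–Uhlenbeck process, one independent stream per neuron, with
mean and SD expressed as percentages (OU_mu, OU_sigma) of the cell's
input conductance G_in = 1/R_in (measured by a small hyperpolarising
step at rest; for the passive point neuron it equals the leak plus any
tonic conductance). OU_sigma is tied to OU_mu by the meta-parameter
R_OU. tau (3 ms) and the reversal (0 mV) are configuration defaults;
negative excursions are clipped at the point of injection only, and all
statistical contracts refer to the pre-clipping process.

Calibration finds, for every target activity level P_FR (a proportion
of the in-vivo reference rate vector V_FR), the per-population OU_mu
that realises it:

1. chi — unconnected transfer. 1-second simulations of the
   disconnected network over an OU_mu grid (default 0-40% in 5% steps,
   doubled at the top when targets are out of range) give a
   per-population interpolation table from injection to unconnected
   rate U_FR. Inversion uses the strictly increasing part of the table,
   with leading silent grid points collapsed onto the firing onset.
   chi depends on R_OU but, with no recurrent synapses active, not on
   calcium.
2. phi — connected transfer. C_FR = alpha exp(beta U_FR) + kappa per
   population, refit each iteration by nonlinear least squares on a
   two-iteration sliding window of (proposed U_FR, observed C_FR)
   samples — one iteration's points alone condition the exponential
   poorly, while older samples would dominate it with stale
   high-leverage points. If the fitted exponent is negligible over the
   sampled span the fit falls back, flagged, to a linear model. The
   initial guess is the identity.
3. Iteration. Each iteration simulates the connected network at 10
   levels P_FR in (0, P_max] (P_max = 0.5 on the cold first iteration,
   1.0 afterwards) for 6.5 s, discards a 1.5 s transient, measures
   C_FR, refits phi and re-inverts U_FR = phi^-1(P_FR V_FR). Proposals
   are capped at twice the largest U_FR explored so far (a trust
   region that prevents overshoot from extrapolating a freshly fitted
   exponential). The loop stops when, for every level, the RMS over
   populations of (observed - target) P_FR falls below tol
   (default 0.1; the termination tolerance is not an experimentally
   printed value). A warm start from a previously calibrated phi skips
   the identity iteration. Levels whose simulation shows network-wide
   bursting — count-histogram CV above 2 with more than 30% near-silent
   bins, at a mean rate above 0.5 Hz, or an outright runaway — are
   flagged and excluded from the fit. Populations whose target is zero
   while they fire at rest are reported unreachable.

On the default 9 x 200 surrogate, a cold start converges in 4
iterations and a warm start at a neighbouring R_OU in 3, at tol = 0.1.

## Synapse physiology calibration

PSP calibration reproduces the paired-recording protocol: 50 sampled
pairs, 35 repetitions each, postsynaptic cell current-clamped at
-70 mV. Amplitudes are simulated as binomial vesicle releases scaled by
the unit PSP peak of the passive membrane (numerically integrated once;
the subthreshold regime is linear to within the tolerances used) with
lognormal pair-to-pair heterogeneity (SD 0.2). ghat rescales the mean
amplitude each iteration; N_RRP steps up when the CV is too high and
down when too low, bounded below by univesicular release (flagged when
the target CV is unreachable there). The CV is computed across
repetitions within each pair and then averaged over pairs by default;
pooling all repetitions is a switch (`cv_aggregation="pooled"`), since
the aggregation order is ambiguous in the source protocols.

mPSC calibration simulates voltage-clamped cells whose synapses release
spontaneously at candidate rates, counts somatic events after merging
those closer than the detector dead time (2 ms default; the origin of
coincidence losses), fits frequency = a ln(rate) + b and interpolates
the rate matching the in-vitro target frequency. Targets outside the
measured range are flagged extrapolations.

## Stimuli

Sensory drive follows the three-step composition: a rate field
rho(x, y, t) per thalamic fiber, an optional kinetic transfer function
upsilon, and a stochastic spiking process psi.

- PSTH replay: round(F_P n) fibers are selected once per experiment;
  each selected fiber draws exactly one spike time per trial from the
  PSTH treated as a density (an inhomogeneous-Poisson mode is a flag).
- Whisker-hold transfer functions: position r_max rho(t), velocity
  r_max (rho(t+1) - rho(t)), acceleration r_max second difference,
  direction r_max |rho(t+1) - rho(t)| — the direction channel responds
  to movement in either direction, with the rectification of negative
  rates left to the spiking stage. r_max = 150 Hz. Assignment fractions:
  11% position, 58% velocity, 11% acceleration, 20% direction.
- Drifting gratings: Michelson contrast C about mean normalised
  luminance 0.5 (implemented as |L_max - L_min|/(L_max + L_min); the
  orientation of the difference is irrelevant once luminances are
  constructed by the inverse relation), linear luminance-to-rate map
  anchored at R(0.5) = R_bk and R(1.0) = R_peak, and a travelling
  sinusoid in the fiber's linear position truncated at zero. Defaults
  F_P = 1.0, R_peak = 10 Hz, R_bk = 0.2 Hz, f_temp = 2 Hz,
  f_spat = 0.001 cycles/um (0.03 cycles/degree at a 30 um/degree
  magnification factor).
- Adapting Markov process: hazard = gain * rate - a, where a jumps by a
  fixed increment (2 Hz default) per emitted spike and decays with
  tau = 100 ms; gain = 1 + increment * tau makes the long-run emitted
  rate equal a constant requested rate (within 5%), and the negative
  feedback yields sub-Poisson count statistics. The precise hazard form
  is this package's choice; only the adaptation time constant and the
  submillisecond evaluation grid are externally fixed.
- Binary-signal encoders: a two-state signal with uniform 2-7 s dwell
  times; the rate scheme uses independent Poisson trains at 30/10 Hz
  (the 5/0.5 Hz original is a parameter choice away), the synchrony
  scheme one shared master train during up states at equal 20 Hz rates.

## Perturbations

Optogenetics: somatic current injection proportional to each cell's
rheobase (found by bisection on 500 ms steps), scaled by the
Beer–Lambert attenuation I(d) = I0 exp(-mu_eff d),
mu_eff = sqrt(3 mu_a (mu_a + mu_s')). Built-in coefficient pairs:
595 nm (0.49, 4.12) mm^-1 and 470 nm (0.46, 5.38) mm^-1. Targeted
cells are grouped into bins of equal intensity increment (not equal
depth); each cell uses its bin's midpoint intensity, normalised by the
intensity at the top of the targeted population. Pulses end in a
linear ramp (100 ms default) to avoid rebound spikes. Lesions remove
all and only the edges from a presynaptic to a postsynaptic selector
set; an empty selector warns and no-ops.

## Analysis

PSTHs are binned (5 ms spontaneous, 1 ms tuning), Gaussian-smoothed
(1 sigma default) and optionally baseline-subtracted-max-normalised.
Evoked latency is the first post-onset crossing of baseline + 5% of the
peak-minus-baseline amplitude (the operational definition mirrors the
EPSP rise-to-5% convention; none is fixed for population PSTHs by the
source protocols); decay50/decay25 are the first post-peak returns to
50%/25% of that amplitude; R_E is peak over a 500 ms pre-stimulus
baseline. The validation criteria require model latency, decay50 and
decay25 to be no more than 10, 10 and 40 ms later than the reference,
and no baseline-normalised PSTH above 35% after 75 ms post-onset; L1_I
is excluded for lack of a reference.

Mutual information between a cell's binned spike counts (50 ms bins,
counts capped at 5) and the binary signal state uses the plug-in
estimator (Miller–Madow correction behind a flag); significance
compares against the 95th percentile of MI under circular time-shifts
of the signal, which preserve its dwell-time structure where a plain
permutation would not. The measured false-positive rate on independent
spikes stays within alpha + 2%.

The rate spectrum is a one-sided periodogram of the mean-subtracted
5 ms-binned population rate, reported as relative power. Firing-rate
distributions are summarised by the mean including silent cells,
sparsity (fraction spiking at least once) and a lognormal fit to the
active cells' rates.

## Tuning models

Contrast responses normalised by the no-opto highest-contrast mean are
fitted with R(c) = R_max c^n/(c^n + c50^n) + m by multi-start least
squares. Stimulus parameter selection ranks the normalised first/second
peak difference (lower better), c50 (lower better) and n (higher
better), excludes peak rates below 30 Hz and c50 > 0.95 (the printed
border-case exclusion carries no number; 0.95 is this package's
threshold), and maximises the rank product with ties broken by the
lowest peak difference. Robust tuning requires > 0.5 Hz under all
conditions and strictly increasing curves.

Optogenetic modulation models hold the baseline sigmoid fixed and fit
only their own terms: divisive R/g, subtractive max(R - h, 0), and
saturation-additive R + S c^-n/(c^-n + c50^-n) + A. Because the
divisive family is exactly nested in the saturation-additive family
(the suppressive term equals S (1 - sigma(c))), the model-comparison
harness ranks models by small-sample-corrected AIC rather than raw r^2,
which cannot separate nested models; per-fit r^2 values are still
reported. The conductance-based PC model [Delta V(c) - 3.4 mV]^3 with
the printed constants (g_L = 6 nS, E_leak = -50 mV, reversals 0/-65 mV,
V_r = -50 mV, Delta g_IE = 2 nS) is fitted in two stages: (c50,
g_E_min, g_E_max, n) on baseline responses with S = A = 0, then (S, A)
per photostimulation condition with the stage-1 values held
bit-identical. Fits are unweighted (per-point SDs, when present, are
not used) and canonicalised by contrast order so they are
order-invariant.

## Topology

Directed n-simplices are ordered (n+1)-tuples with an edge from every
earlier to every later node; each feed-forward ordering counts once, so
a reciprocal pair contributes two 1-simplices and Par_1 is the total
degree. The built-in counter enumerates extension chains with
intersected out-neighbourhoods and is validated against an independent
subset-dynamic-programming oracle on 200 random digraphs of up to 12
nodes. Participation-weighted means are plain weighted averages
(values . Par_k / sum Par_k); the variant with an additional 1/N factor
is available behind `compat_normalization` for compatibility with an
alternative printed convention. Enrichment of a class within the top 5%
of participation (ties at the cutoff included) uses exact
hypergeometric tails.

Meso-scale analysis bins flat locations into a regular hexagonal tiling
(flat-to-flat diameter = adjacent-center pitch, cube rounding, boundary
ties to the lower axial index), counts synapses between subvolumes into
S, and correlates pooled 5 ms spike-count series into F, with the
within-subvolume diagonal computed between the E and I series. Input
correlations into subvolume i weight F by the pair-count matrix
S_i S_i^T. The rich club thresholds S (>= threshold, off-diagonal) and
reports undirected connected components by default (a directed variant
is a flag), plus per-subvolume adjacency-to-member flags at one tiling
pitch. Missing-synapse estimates use max(0, round(1.1 synapses/um *
dendritic length) - existing).

## Problem sizes and tolerances in the test suite

The unit and property suites use a 9 x 50 surrogate with 3 s
simulations per calibration level; the acceptance suite runs the full
9 x 200 surrogate with 10 levels of 6.5 s, matching the study
conditions, and checks cold-start convergence within 5 iterations and
warm-start convergence within 3 at tol = 0.1. Monte-Carlo contracts
(OU moments, binomial release, MI false-positive rate) state their
sample sizes and standard-error-based tolerances inline.

## What the surrogate does and does not show

Passing tests establish that the algorithms are implemented correctly
and behave as designed on a stable recurrent spiking network:
mappings invert, the calibration loop contracts and recovers known
compensation tables, stimuli compose, perturbation arithmetic is
exact, and the analyses agree with closed-form oracles. They do not
certify quantitative fidelity to a morphologically detailed cortical
circuit: the surrogate has no dendrites, no cell-type-specific
connectivity motifs, far fewer neurons and synapses, and a weaker
recurrent regime. Quantities that depend on those properties — absolute
evoked amplitudes, layer-specific R_C/U profiles, simplex-dimension
spectra of the real connectome — should be read qualitatively here.
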