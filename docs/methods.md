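# Methods

## Model

### Neuron

The unit is a current-based generalized integrate-and-fire (GIF) neuron
with spike-frequency adaptation. The subthreshold membrane obeys

    C dV/dt = -g_L (V - E_L) - sum_j eta(t - t_j) + I(t),

where the sum runs over the neuron's own past spike times t_j and
eta(t) = eta_1(t) + eta_2(t) is a pair of exponentially decaying
spike-triggered currents. Spikes are emitted stochastically with the
escape-noise intensity

    lambda(t) = lambda_0 exp((V(t) - V_T(t)) / Delta_V),
    V_T(t)   = V_T* + sum_j gamma(t - t_j),

where gamma(t) = gamma_1(t) + gamma_2(t) is a pair of exponential
threshold kernels. After a spike, V is reset to V_reset and the neuron is
absolutely refractory for tau_ref = 4 ms. Three parameter sets
(excitatory, inhibitory, and a second inhibitory type used only in one
chain variant) are built in (`excinet.neuron`); they are experimental
fits, including the counter-intuitive features that V_reset lies *above*
V_T* (a depolarized reset, so bursts are terminated by threshold build-up
rather than by the reset itself) and that the fast inhibitory threshold
kernel is negative (firing transiently *lowers* the threshold of
fast-spiking cells). The excitatory fast threshold kernel amplitude is
3.26 mV in chain models and 13.05 mV in the multicolumn grid.

### Synapses

A presynaptic spike at t_f makes the postsynaptic current jump by the
synaptic weight w (pA) at t_f + delay (delay = 1 ms everywhere) and decay
with tau_syn. Weights are reported both as PSC amplitudes and as the peak
PSP they evoke in a passive postsynaptic membrane; the conversion is the
closed-form peak of the double-exponential filter response
(`psc_to_psp_peak`, with the equal-time-constant limit w*tau/(C*e)
handled explicitly). Optional Tsodyks-Markram short-term plasticity keeps
per-edge release/resource variables (u, x); release uses the pre-update
values (amplitude u*x*w), then depletes x and facilitates u. Facilitation
experiments use (tau_rec, tau_facil) = (0.001, 500) ms on the
inter-assembly excitatory synapses; depression experiments use (800,
0.001) ms on the inter-group excitatory-to-inhibitory synapses with the
weight renormalized to w/U so the first PSC is U-independent, plus a
~7-fold stronger intra-group inhibitory-to-excitatory weight (1.07 mV).

### Networks

Connectivity is independent Bernoulli per ordered pair (no autapses, no
multi-edges per block), deterministic in the connectivity seed. The
*chain* consists of 70-neuron excitatory assemblies (internal p = 0.5,
w = 22.1 pA) coupled to nearest neighbors (p = 0.1, weight w_exc), each
optionally paired with a 70-neuron inhibitory population (intra-group
rows of the printed table; inter-group excitatory-to-inhibitory weight
w_inh at p = 0.3); inhibitory populations never project between groups.
The *grid* is a 5x5 lattice of barrel columns (rows A-E, arcs 1-5), each
with a 70-neuron assembly, 380 non-assembly excitatory neurons and 70
inhibitory neurons; only excitatory neurons connect between 4-neighbor
columns (p = 0.10, or 0.15 for horizontal neighbors in the anisotropic
variant; w = 7.1 pA), and the boundary is absorbing. The slow threshold
kernel gamma_2 can be initialized per column from a clipped normal
(sigma = 3 mV) to set each column dormant or excitable.

## Simulation scheme

Clock-driven, fixed-step exponential Euler at dt = 0.1 ms (configurable):
leak, adaptation traces and synaptic accumulators decay with exact
exponential factors; the synaptic drive is held constant across a step.
Synaptic currents are pooled into one exponential accumulator per
(neuron, tau_syn) class, which is exact for exponential PSCs. The
per-step spike probability is 1 - exp(-lambda dt) evaluated with the
post-integration V; during refractoriness V is clamped at V_reset and
lambda = 0 while traces and currents keep evolving (the clamped reading
of "integration restarts"). Kernel increments apply at the spike time.
Randomness is split into named streams (stimulus, escape noise) spawned
from one master seed; connectivity has its own seed, so sweeps can freeze
topology while varying dynamics. Halving dt to 0.05 ms moves mean
per-step delays by under ~1 ms (tested).

The transient stimulus is 25 independent 5 Hz Poisson sources firing for
25 ms, each connected to every target neuron with 180 pA. Chain
experiments stimulate one assembly; grid experiments stimulate all
neurons of one column (assembly-only stimulation leaves the non-assembly
relay silent and the evoked wave dies within one ring). Because the
expected stimulus spike count is only ~3.1, ignition itself fails in
roughly one trial in six; trial drivers therefore redraw the dynamics
seed until the stimulated assembly ignites, and propagation reliability
is judged conditional on ignition.

## Analyses

*Activation time* of an assembly: the mean first-spike time of its
neurons within an activation episode, where episodes are runs of assembly
spikes separated by >= 100 ms of assembly silence and require at least
half the neurons to participate (this keeps the ~0.02 Hz spontaneous
trickle from counting as activity). The alternative half-count definition
(time of the ceil(N/2)-th first spike) agrees within 2 ms on simulated
rasters (tested). Per-step delay = difference of consecutive activation
times; speed = 1/(total delay). Grid trials are classified no_spread /
spread / circulation by column-level episode counts; survival is the end
of the last column episode minus stimulus onset, clamped at 1000 ms.

*Mean-field analysis*: the noisy gain g(<I>, sigma_I) is estimated by
Monte-Carlo simulation of independent GIF neurons (50 per current by
default, windows of 10 ms; window 0 starts from rest and is the
non-adapted gain). The fluctuating current is white noise filtered by the
PSC kernel and normalized by sqrt(q2), q2 = tau_syn/2, so the realized
current SD is exactly sigma_I (tested). sigma_I defaults to 20 pA where a
value is needed; the fixed-point structure (below) is insensitive to
moderate changes. Fixed points are sign changes of g(I) - I/C_fb on the
sampled grid (linear interpolation), with C_fb = N p q w and q = tau_syn;
one crossing = only the quiet state, three = low/switch/high. Counts
other than 1 or 3 raise with the crossing list rather than truncating.

*Delay theory*: with a burst-aligned rate template r(t) from one
simulation, t1 solves integral r dt = 1; the mean input into the next
assembly is the forward term N p_exc w_exc (alpha*r)(t - delay) plus the
self term (N-1) p_self w_self (alpha*r)(t - delay - x); the non-adapted
membrane response, escape hazard, and first-passage density give t2, and
x solves the self-consistency x = t2 - t1 (1 ms scan + bisection to
0.1 ms; evaluation horizon 300 ms with the residual tail mass reported).

### Conditioning of the delay theory

The components validate individually: the constructed currents match the
engine's per-source current probe, and the first-passage machinery fed
with the *true* probed current reproduces the simulated mean first-spike
time to < 1 ms. The self-consistency itself, however, is ill-conditioned:
t2(x) is approximately x plus the first-passage time measured from the
assembly's own onset, which nearly cancels against t1, so the map
x -> t2(x) - t1 deviates from the identity with slope of only ~0.05-0.1.
The fixed point therefore amplifies (by 10-20x) the small systematic
difference between the expected-count-reaches-1 functional used for t1
and the true mean-first-spike functional — a bias inherent in the t1
definition (it counts repeat spikes of early-firing neurons). With
measured templates, the solved x comes out at roughly a quarter to a half
of the simulated delay; alternative t1 functionals and template
treatments (source regime, onset thresholds, averaging, smoothing) move
the solution across a wide range without a principled way to pin it. The
implementation keeps the printed construction; the w_exc *trend* of x
(faster with stronger coupling) is robust and tested, the absolute value
is not.

## Problem sizes used by the shipped experiments

Chains use 11 groups by default (tests and the delay-theory comparison
use 6-9 to keep the suite brisk). Sweep points use 10
ignition-conditioned trials with frozen topology. The reliability sweeps
descend w_exc over 0.24-0.40 mV (excitatory-only) and cover a 4x4
(w_exc, w_inh) grid of 0.40-0.55 x 0.6-1.5 mV (with inhibition); the
reference operating point for rate measurements is (w_exc, w_inh) =
(0.40, 0.30) mV. Grid runs simulate all 13,000 neurons at dt = 0.1 ms.

## Known limitations

* The maximum reliable per-step delay with inhibitory populations comes
  out near ~31-37 ms — essentially the same ceiling as the
  excitatory-only chain (~33 ms) — rather than extending to ~56 ms. The
  failure boundary in the (w_exc, w_inh) plane is soft: near it,
  propagation dies stochastically in a fraction of trials, so demanding
  all 10 trials succeed caps the attainable delay. Slow-but-reliable
  propagation beyond this ceiling *is* reached with facilitating
  inter-assembly synapses (delays up to ~60 ms at U ~ 0.25).
* Assembly bursts begin with refractory-locked volleys (the depolarized
  reset), so the peak 10 ms-binned rate lands at ~210-225 Hz, slightly
  above the nominal ~200 Hz; the second inhibitory population, whose
  printed coupling (-5 pA at p = 0.5) is an order of magnitude below the
  assembly's recurrent drive, shaves little off that peak instead of
  halving it.
* In the grid, a stimulated column's burst recruits its non-assembly
  majority, and the resulting inter-column drive (hundreds of pA)
  overwhelms any slow-threshold initial pattern; the evoked spread is
  robust, but steered circulation of activity around the lattice is not
  reproduced under this wiring. The trial classifier and shuffling
  machinery are exercised against synthetic rasters instead.
* The delay theory's absolute values are ill-conditioned (above).
* Short-term-plasticity time constants are non-knobs for speed (tested),
  matching their advertised role; only U matters.
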