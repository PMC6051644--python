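"""Self-consistent theory of the per-step propagation delay.

Given the population-rate time course r(t) of one assembly burst (the same
shape is assumed for every assembly of an excitatory-only chain), the
activation-time difference x between consecutive assemblies solves a
self-consistency problem:

* t1 -- the activation time of the (already active) assembly 1, defined as
  the moment its expected per-neuron spike count reaches one:
  integral_0^t1 r dt = 1;
* the mean current into an assembly-2 neuron is the forward drive
  N p_exc w_exc (alpha * r)(t - delay) plus the self-feedback
  (N-1) p_self w_self (alpha * r)(t - delay - x), which assumes assembly 2
  starts firing x after assembly 1;
* the (non-adapted) membrane responds with
  V(t) = E_L + (1/C) (exp(-t/tau_m) * I_syn)(t), the escape-noise hazard
  lambda(t) = lambda0 exp((V - V_T*)/DeltaV) gives the first-spike density
  P(t) = lambda exp(-int_0^t lambda), and t2 = E[t] under P;
* the output delay is x_out = t2 - t1; the solution is the fixed point
  x_out(x) = x, found by a coarse scan plus bisection.

Adaptation is neglected (first spikes only), and the per-neuron spike
count is treated as Poisson, so t1 is a mild underestimate when single
neurons fire more than once early in the burst.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import SpikeData
from .neuron import GIFParameters

__all__ = [
    "TheoryInputs",
    "TheoryResult",
    "t1_from_rate",
    "input_currents",
    "first_spike_stats",
    "solve_delay",
    "rate_template_from_spikes",
]


@dataclass
class TheoryInputs:
    """Rate template plus the coupling and neuron constants of the chain.

    ``rate_hz`` is the burst-aligned population rate (Hz) sampled at ``dt``
    (ms), zero before activation onset.  ``p_exc``/``w_exc`` couple
    neighboring assemblies, ``p_self``/``w_self`` the assembly to itself.
    """

    rate_hz: np.ndarray
    dt: float
    N: int
    p_exc: float
    w_exc: float
    p_self: float
    w_self: float
    delay: float
    tau_syn: float
    params: GIFParameters

    def __post_init__(self) -> None:
        self.rate_hz = np.asarray(self.rate_hz, dtype=float)
        if np.any(self.rate_hz < 0):
            raise ValueError("rate template must be non-negative")


@dataclass
class TheoryResult:
    t1: float
    t2: float
    x: float
    first_spike_density: np.ndarray
    converged: bool
    residual: float


def t1_from_rate(rate_hz: np.ndarray, dt: float) -> float:
    """First time (ms) the running per-neuron spike count reaches one.

    The count is the integral of r(t) (in spikes/ms); linear interpolation
    between samples.
    """
    r = np.asarray(rate_hz, dtype=float) / 1000.0  # spikes per ms
    cum = np.concatenate(([0.0], np.cumsum((r[1:] + r[:-1]) / 2.0) * dt))
    if cum[-1] < 1.0:
        raise ValueError(
            f"expected spike count only reaches {cum[-1]:.3f} within the template"
        )
    k = int(np.searchsorted(cum, 1.0))
    frac = (1.0 - cum[k - 1]) / (cum[k] - cum[k - 1])
    return (k - 1 + frac) * dt


def _alpha_kernel(dt: float, tau_syn: float, delay: float, horizon: float) -> np.ndarray:
    t = np.arange(0.0, horizon, dt)
    return np.where(t >= delay, np.exp(-(t - delay) / tau_syn), 0.0)


def _shift(r: np.ndarray, shift_ms: float, dt: float) -> np.ndarray:
    """r(t - shift) on the same grid, linear interpolation, zero before."""
    n = len(r)
    t = np.arange(n) * dt
    return np.interp(t - shift_ms, t, r, left=0.0, right=r[-1])


def input_currents(
    inputs: TheoryInputs, x_guess: float, horizon: float = 200.0
) -> np.ndarray:
    """Mean synaptic current (pA) into an assembly-2 neuron, on the theory grid.

    Forward drive delayed by the transmission delay; self-feedback
    additionally delayed by ``x_guess``.
    """
    if x_guess < 0:
        raise ValueError("x_guess must be non-negative")
    dt = inputs.dt
    n = int(round(horizon / dt))
    r = np.zeros(n)
    m = min(n, len(inputs.rate_hz))
    r[:m] = inputs.rate_hz[:m] / 1000.0  # spikes/ms
    alpha = _alpha_kernel(dt, inputs.tau_syn, inputs.delay, horizon)
    conv = np.convolve(alpha, r)[:n] * dt
    fwd = inputs.N * inputs.p_exc * inputs.w_exc * conv
    self_term = (
        (inputs.N - 1)
        * inputs.p_self
        * inputs.w_self
        * _shift(conv, x_guess, dt)
    )
    return fwd + self_term


def first_spike_stats(
    I_syn: np.ndarray,
    params: GIFParameters,
    dt: float,
    horizon: float | None = None,
    tail_tol: float = 0.01,
) -> tuple[np.ndarray, float, float]:
    """First-spike density P(t) and mean first-spike time of a fresh neuron.

    The membrane is passive and non-adapted (threshold fixed at V_T*, no
    spike-triggered current): V is the current filtered with
    exp(-t/tau_m)/C, lambda the escape-noise hazard, and
    P(t) = lambda exp(-int lambda) the first-passage density.

    Returns (P, t2, tail_mass); ``tail_mass`` is the probability of no
    spike before the horizon.  t2 uses the density normalized over the
    horizon (bias < tail_tol when the tail is small).
    """
    n = len(I_syn) if horizon is None else min(len(I_syn), int(round(horizon / dt)))
    I = np.asarray(I_syn, dtype=float)[:n]
    decay = np.exp(-dt / params.tau_m)
    # exponential-Euler filter: drive constant within each step
    V = np.empty(n)
    v = params.E_L
    for k in range(n):
        v_inf = params.E_L + I[k] / params.g_L
        v = v_inf + (v - v_inf) * decay
        V[k] = v
    lam = params.lambda0 * np.exp(
        np.clip((V - params.VT_star) / params.DeltaV, -700, 30)
    )  # Hz
    lam_ms = lam / 1000.0
    H = np.concatenate(([0.0], np.cumsum((lam_ms[1:] + lam_ms[:-1]) / 2.0) * dt))
    P = lam_ms * np.exp(-H)  # density per ms
    t = np.arange(n) * dt
    mass = float(np.trapezoid(P, t))
    tail = 1.0 - mass
    if mass <= 0:
        return P, float("inf"), 1.0
    t2 = float(np.trapezoid(t * P, t) / mass)
    return P, t2, tail


def solve_fixed_point(
    x_out_fn,
    tol: float = 0.1,
    x_max: float = 100.0,
    scan_step: float = 1.0,
) -> tuple[float, bool]:
    """Fixed point of a scalar map: x with x_out_fn(x) = x.

    Coarse scan over [0, x_max] brackets a sign change of
    ``x_out_fn(x) - x``, then bisection refines it to ``tol``.  Returns
    (x, converged); x is NaN when no bracket is found.
    """
    prev_g = None
    bracket = None
    for x in np.arange(0.0, x_max + scan_step, scan_step):
        g = x_out_fn(float(x)) - x
        if prev_g is not None and prev_g > 0 >= g:
            bracket = (float(x - scan_step), float(x))
            break
        prev_g = g
    if bracket is None:
        return float("nan"), False
    lo, hi = bracket
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if x_out_fn(mid) - mid > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi), True


def solve_delay(
    inputs: TheoryInputs,
    tol: float = 0.1,
    horizon: float = 300.0,
    x_max: float = 100.0,
    scan_step: float = 1.0,
) -> TheoryResult:
    """Self-consistent activation-time difference: solve x_out(x) = x.

    Note the map is shallow (x_out(x) ~ x + small residual, because the
    first-spike time after the self-feedback kick largely cancels against
    t1), so the solution is sensitive to the template's exact early rise;
    see the methods note for the conditioning discussion.
    """
    t1 = t1_from_rate(inputs.rate_hz, inputs.dt)

    def x_out(x: float) -> float:
        I = input_currents(inputs, x, horizon=horizon)
        _, t2, _ = first_spike_stats(I, inputs.params, inputs.dt)
        return t2 - t1

    x_star, converged = solve_fixed_point(
        x_out, tol=tol, x_max=x_max, scan_step=scan_step
    )
    if not converged:
        I0 = input_currents(inputs, 0.0, horizon=horizon)
        P0, t2_0, _ = first_spike_stats(I0, inputs.params, inputs.dt)
        return TheoryResult(
            t1=t1, t2=t2_0, x=float("nan"),
            first_spike_density=P0, converged=False, residual=float("inf"),
        )
    I = input_currents(inputs, x_star, horizon=horizon)
    P, t2, _ = first_spike_stats(I, inputs.params, inputs.dt)
    return TheoryResult(
        t1=t1,
        t2=t2,
        x=x_star,
        first_spike_density=P,
        converged=True,
        residual=abs((t2 - t1) - x_star),
    )


def rate_template_from_spikes(
    spikes: SpikeData,
    assembly: str,
    dt: float = 0.1,
    bin_ms: float = 1.0,
    pad_ms: float = 150.0,
) -> np.ndarray:
    """Burst-aligned rate template r(t) in Hz, sampled at ``dt``.

    The assembly's first activation episode is binned at ``bin_ms``,
    shifted so the burst onset (last empty bin before the episode) sits at
    t = 0, and linearly resampled to the theory grid; the template is
    padded with zeros to ``pad_ms``.
    """
    from .metrics import activation_episodes

    eps = activation_episodes(spikes, assembly)
    if not eps:
        raise ValueError(f"assembly {assembly!r} never activated")
    ep = eps[0]
    _, size = spikes.population_slice(assembly)
    t, _ = spikes.for_population(assembly)
    t = t[(t >= ep["start"]) & (t <= ep["end"])]
    onset = ep["start"] - bin_ms
    edges = np.arange(onset, ep["end"] + 2 * bin_ms, bin_ms)
    counts, _ = np.histogram(t, bins=edges)
    rate = counts / (size * bin_ms * 1e-3)  # Hz
    centers = edges[:-1] - onset + bin_ms / 2.0
    grid = np.arange(0.0, max(pad_ms, centers[-1] + bin_ms), dt)
    out = np.interp(grid, centers, rate, left=0.0, right=0.0)
    return np.clip(out, 0.0, None)
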