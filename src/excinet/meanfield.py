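"""Rate-current self-consistency of a recurrent population.

Two relations link the population rate r to the mean synaptic current:

* the neuron's *noisy gain function* r = g(<I_syn>, sigma_I), estimated by
  Monte-Carlo simulation of independent GIF neurons driven by a current
  with mean <I_syn> and a fluctuating part obtained by filtering white
  noise through the PSC kernel alpha (normalized by sqrt(q2),
  q2 = integral of alpha^2 = tau_syn/2, so the current's stationary
  standard deviation is exactly sigma_I);
* the *network line* r = <I_syn> / C_fb imposed by recurrent feedback,
  with C_fb = N p q w the network feedback coefficient (pA*ms).

Intersections of the two curves are the population's fixed points.  A
strongly coupled assembly has three (low / switch / high); a weakly
coupled population only the low one.  Because the neurons adapt, the gain
measured in successive 10 ms windows after current onset drops, which is
how an active assembly eventually falls back to the low point (the
dormant mode).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .neuron import GIFParameters

__all__ = [
    "GainCurve",
    "FixedPoint",
    "FixedPointSet",
    "estimate_gain",
    "sample_gain_curve",
    "network_line",
    "find_fixed_points",
]


@dataclass
class GainCurve:
    """Windowed Monte-Carlo gain estimates.

    ``table`` columns: mean_current (pA), sigma_I (pA), window_index
    (0 = non-adapted, neurons start from rest), rate_hz, sem_hz.
    """

    table: pd.DataFrame
    window_ms: float = 10.0

    def window(self, index: int = 0) -> pd.DataFrame:
        sub = self.table[self.table.window_index == index]
        return sub.sort_values("mean_current").reset_index(drop=True)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


@dataclass(frozen=True)
class FixedPoint:
    current: float  # pA
    rate: float  # Hz
    label: str  # low | switch | high


@dataclass
class FixedPointSet:
    C_fb: float
    points: list[FixedPoint]

    @property
    def count(self) -> int:
        return len(self.points)

    def __getitem__(self, label: str) -> FixedPoint:
        for p in self.points:
            if p.label == label:
                return p
        raise KeyError(label)


def filtered_noise(
    tau_syn: float,
    sigma_I: float,
    n_steps: int,
    dt: float,
    rng: np.random.Generator,
    shape: tuple = (),
) -> np.ndarray:
    """Fluctuating current: white noise filtered by the PSC kernel.

    Returns an array of shape (n_steps, *shape).  The filter output
    y = alpha * xi has stationary variance q2 = tau_syn/2, and the current
    sigma_I * y / sqrt(q2) therefore has standard deviation sigma_I
    exactly; the recursion integrates the Ornstein-Uhlenbeck dynamics
    exactly per step.
    """
    q2 = tau_syn / 2.0
    decay = np.exp(-dt / tau_syn)
    sd = np.sqrt(q2 * (1.0 - decay**2))
    out = np.empty((n_steps,) + shape)
    y = rng.normal(0.0, np.sqrt(q2), size=shape)
    for n in range(n_steps):
        y = y * decay + rng.normal(0.0, sd, size=shape)
        out[n] = y
    return sigma_I * out / np.sqrt(q2)


def estimate_gain(
    params: GIFParameters,
    mean_current,
    sigma_I: float = 20.0,
    n_neurons: int = 50,
    window: float = 10.0,
    n_windows: int = 1,
    dt: float = 0.1,
    tau_syn: float = 7.7,
    seed: int = 0,
) -> GainCurve:
    """Monte-Carlo estimate of the noisy gain function.

    ``mean_current`` may be a scalar or an array of currents (pA); all
    currents are simulated in one vectorized pass of ``n_neurons``
    independent adapting GIF neurons each, switched on at t = 0 from rest.
    The rate of window k is the mean spike count of the group in
    [k*window, (k+1)*window) divided by n_neurons * window; the SEM is
    over neurons.
    """
    if np.any(np.asarray(sigma_I) < 0):
        raise ValueError("sigma_I must be non-negative")
    currents = np.atleast_1d(np.asarray(mean_current, dtype=float))
    n_cur = len(currents)
    rng = np.random.default_rng(np.random.SeedSequence(int(seed) % 2**31))
    shape = (n_cur, n_neurons)

    eta_amp = np.array([k.amplitude for k in params.eta_kernels])
    eta_tau = np.array([k.tau for k in params.eta_kernels])
    gam_amp = np.array([k.amplitude for k in params.gamma_kernels])
    gam_tau = np.array([k.tau for k in params.gamma_kernels])
    eta_decay = np.exp(-dt / eta_tau)
    gam_decay = np.exp(-dt / gam_tau)
    decay_m = np.exp(-dt / params.tau_m)

    V = np.full(shape, params.E_L)
    eta = np.zeros(shape + (2,))
    gamma = np.zeros(shape + (2,))
    refr = np.zeros(shape)

    n_steps = int(round(n_windows * window / dt))
    steps_per_window = int(round(window / dt))
    counts = np.zeros((n_windows,) + shape)
    dt_s = dt * 1e-3
    noise = filtered_noise(tau_syn, sigma_I, n_steps, dt, rng, shape=shape)

    for n in range(n_steps):
        I = currents[:, None] + noise[n]
        eta *= eta_decay
        gamma *= gam_decay
        refr = np.maximum(refr - dt, 0.0)
        drive = I - eta.sum(axis=-1)
        v_inf = params.E_L + drive / params.g_L
        V = v_inf + (V - v_inf) * decay_m
        refractory = refr > 0
        V[refractory] = params.V_reset
        expo = np.clip(
            (V - params.VT_star - gamma.sum(axis=-1)) / params.DeltaV, -30, 30
        )
        lam = params.lambda0 * np.exp(expo)
        lam[refractory] = 0.0
        fired = rng.random(shape) < -np.expm1(-lam * dt_s)
        if fired.any():
            V[fired] = params.V_reset
            refr[fired] = params.tau_ref
            eta[fired] += eta_amp
            gamma[fired] += gam_amp
            counts[n // steps_per_window][fired] += 1

    rows = []
    for k in range(n_windows):
        per_neuron_hz = counts[k] / (window * 1e-3)
        rate = per_neuron_hz.mean(axis=1)
        sem = per_neuron_hz.std(axis=1, ddof=1) / np.sqrt(n_neurons)
        for i, c in enumerate(currents):
            rows.append(
                {
                    "mean_current": c,
                    "sigma_I": sigma_I,
                    "window_index": k,
                    "rate_hz": rate[i],
                    "sem_hz": sem[i],
                }
            )
    return GainCurve(table=pd.DataFrame(rows), window_ms=window)


def sample_gain_curve(
    params: GIFParameters,
    i_max: float,
    sigma_I: float = 20.0,
    n_points: int = 40,
    **kwargs,
) -> GainCurve:
    """Gain curve on a regular grid of mean currents from 0 to ``i_max`` pA."""
    currents = np.linspace(0.0, i_max, n_points)
    return estimate_gain(params, currents, sigma_I=sigma_I, **kwargs)


def network_line(C_fb: float):
    """The feedback relation r(I) = I / C_fb, returned in Hz for I in pA.

    C_fb is in pA*ms, so I/C_fb is a rate in spikes/ms; the returned
    callable converts to Hz (I = C_fb gives 1000 Hz).
    """
    if C_fb == 0:
        raise ValueError("C_fb must be non-zero")

    def line(I):
        return 1000.0 * np.asarray(I, dtype=float) / C_fb

    return line


def find_fixed_points(gain: GainCurve, C_fb: float, window_index: int = 0) -> FixedPointSet:
    """Intersections of the window-``window_index`` gain curve with the network line.

    Sign changes of g(I) - I/C_fb are located by linear interpolation on
    the sampled grid.  One crossing means only the low point exists; three
    are labelled low / switch / high in order of current.  Any other count
    is ambiguous and raised as an error listing the crossings found.
    """
    sub = gain.window(window_index)
    I = sub.mean_current.to_numpy()
    g = sub.rate_hz.to_numpy()
    line = network_line(C_fb)
    f = g - line(I)

    crossings: list[float] = []
    if f[0] == 0.0 or (f[0] < 0 and I[0] == 0.0):
        # the quiescent state: at I = 0 both relations give (near) zero rate
        crossings.append(I[0])
    for i in range(len(f) - 1):
        if f[i] == 0.0 and i > 0:
            crossings.append(I[i])
        elif f[i] * f[i + 1] < 0:
            frac = f[i] / (f[i] - f[i + 1])
            crossings.append(I[i] + frac * (I[i + 1] - I[i]))
    if f[-1] == 0.0:
        crossings.append(I[-1])
    crossings = sorted(set(crossings))

    if len(crossings) == 1:
        labels = ["low"]
    elif len(crossings) == 3:
        labels = ["low", "switch", "high"]
    else:
        raise ValueError(
            f"ambiguous fixed-point structure: {len(crossings)} crossings at "
            f"currents {np.round(crossings, 2)} pA (expected 1 or 3); "
            "sample the gain more densely or reduce Monte-Carlo noise"
        )
    points = [
        FixedPoint(current=c, rate=float(line(c)), label=lab)
        for c, lab in zip(crossings, labels)
    ]
    return FixedPointSet(C_fb=C_fb, points=points)
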