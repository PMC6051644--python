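"""Generalized integrate-and-fire (GIF) neuron with spike-frequency adaptation.

The neuron is a leaky integrator with two spike-triggered current kernels
``eta_k(t) = a_k exp(-t/tau_k)`` (pA, subtracted from the drive), a moving
firing threshold ``V_T(t) = V_T* + sum_k gamma_k(t)`` built from two
exponential threshold kernels (mV), and stochastic spike emission with
escape-noise intensity

    lambda(t) = lambda0 * exp((V(t) - V_T(t)) / DeltaV).

After a spike the membrane is reset to ``V_reset`` and clamped there for an
absolute refractory period ``tau_ref`` during which ``lambda = 0``; kernel
traces keep decaying throughout.

All state-update functions accept scalar or ndarray state fields, so the
same formulas serve both the single-neuron reference path and the
vectorized network engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "AdaptationKernel",
    "GIFParameters",
    "NeuronState",
    "EXCITATORY",
    "INHIBITORY",
    "INHIBITORY2",
    "decay_traces",
    "integrate_membrane",
    "spike_intensity",
    "draw_spike",
    "apply_spike",
]

# exponent clip keeps lambda finite for strongly suprathreshold drive;
# exp(30) * lambda0 already saturates the per-step spike probability
_EXP_CLIP = 30.0


@dataclass(frozen=True)
class AdaptationKernel:
    """One exponentially decaying adaptation kernel ``a * exp(-t/tau)``.

    ``amplitude`` is in pA for spike-triggered-current (eta) kernels and in
    mV for threshold (gamma) kernels; it may be negative. ``tau`` is in ms.
    """

    amplitude: float
    tau: float

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError(f"kernel time constant must be positive, got {self.tau}")


@dataclass(frozen=True)
class GIFParameters:
    """Parameter set of one GIF neuron type.

    Units: C pF, g_L nS, voltages mV, times ms, lambda0 Hz.
    """

    C: float
    g_L: float
    E_L: float
    V_reset: float
    tau_ref: float
    eta_kernels: tuple[AdaptationKernel, AdaptationKernel]
    gamma_kernels: tuple[AdaptationKernel, AdaptationKernel]
    lambda0: float
    DeltaV: float
    VT_star: float

    def __post_init__(self) -> None:
        if self.C <= 0 or self.g_L <= 0:
            raise ValueError("C and g_L must be positive")
        if self.DeltaV <= 0:
            raise ValueError("DeltaV must be positive")
        if self.lambda0 <= 0:
            raise ValueError("lambda0 must be positive")
        if self.tau_ref < 0:
            raise ValueError("tau_ref must be non-negative")

    @property
    def tau_m(self) -> float:
        """Membrane time constant C/g_L in ms (pF/nS = ms)."""
        return self.C / self.g_L

    def with_gamma1_amplitude(self, amplitude: float) -> "GIFParameters":
        """Copy with the first (fast) threshold kernel's amplitude replaced."""
        g1, g2 = self.gamma_kernels
        return replace(self, gamma_kernels=(AdaptationKernel(amplitude, g1.tau), g2))


@dataclass
class NeuronState:
    """Evolving state: membrane potential, kernel traces, refractory clock.

    Fields may be scalars (one neuron) or ndarrays with trailing kernel axis
    of length 2 for the traces (a population). ``eta_traces`` are pA,
    ``gamma_traces`` mV, ``refractory_remaining`` ms.
    """

    V: np.ndarray | float
    eta_traces: np.ndarray = field(default_factory=lambda: np.zeros(2))
    gamma_traces: np.ndarray = field(default_factory=lambda: np.zeros(2))
    refractory_remaining: np.ndarray | float = 0.0

    @classmethod
    def at_rest(cls, params: GIFParameters, n: int | None = None) -> "NeuronState":
        """Resting state: V = E_L, all traces zero, not refractory."""
        if n is None:
            return cls(V=params.E_L)
        return cls(
            V=np.full(n, params.E_L),
            eta_traces=np.zeros((n, 2)),
            gamma_traces=np.zeros((n, 2)),
            refractory_remaining=np.zeros(n),
        )


def _kernel_taus(kernels: tuple[AdaptationKernel, ...]) -> np.ndarray:
    return np.array([k.tau for k in kernels])


def _kernel_amps(kernels: tuple[AdaptationKernel, ...]) -> np.ndarray:
    return np.array([k.amplitude for k in kernels])


def decay_traces(state: NeuronState, params: GIFParameters, dt: float) -> NeuronState:
    """Decay every eta/gamma trace by one step: multiply by exp(-dt/tau_k)."""
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    eta = state.eta_traces * np.exp(-dt / _kernel_taus(params.eta_kernels))
    gamma = state.gamma_traces * np.exp(-dt / _kernel_taus(params.gamma_kernels))
    return NeuronState(
        V=state.V,
        eta_traces=eta,
        gamma_traces=gamma,
        refractory_remaining=state.refractory_remaining,
    )


def integrate_membrane(
    state: NeuronState, params: GIFParameters, I_syn: float, dt: float
) -> NeuronState:
    """Advance V one exponential-Euler step of the membrane equation.

    The total drive ``I_syn - sum(eta_traces)`` is held constant over the
    step, so the update is exact for constant input:

        V <- V_inf + (V - V_inf) exp(-dt/tau_m),
        V_inf = E_L + (I_syn - sum eta)/g_L.

    While refractory the membrane stays clamped at V_reset.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    drive = I_syn - np.sum(state.eta_traces, axis=-1)
    v_inf = params.E_L + drive / params.g_L
    v_new = v_inf + (state.V - v_inf) * np.exp(-dt / params.tau_m)
    refractory = np.asarray(state.refractory_remaining) > 0
    v_new = np.where(refractory, params.V_reset, v_new)
    if np.ndim(state.V) == 0:
        v_new = float(v_new)
    return NeuronState(
        V=v_new,
        eta_traces=state.eta_traces,
        gamma_traces=state.gamma_traces,
        refractory_remaining=state.refractory_remaining,
    )


def spike_intensity(state: NeuronState, params: GIFParameters) -> np.ndarray | float:
    """Escape-noise firing intensity lambda(t) in Hz; zero while refractory."""
    v_t = params.VT_star + np.sum(state.gamma_traces, axis=-1)
    exponent = np.clip((state.V - v_t) / params.DeltaV, -_EXP_CLIP, _EXP_CLIP)
    lam = params.lambda0 * np.exp(exponent)
    lam = np.where(np.asarray(state.refractory_remaining) > 0, 0.0, lam)
    return float(lam) if np.ndim(state.V) == 0 else lam


def draw_spike(
    state: NeuronState,
    params: GIFParameters,
    dt: float,
    rng: np.random.Generator,
) -> np.ndarray | bool:
    """Bernoulli spike draw with probability 1 - exp(-lambda*dt).

    ``dt`` in ms, lambda in Hz; the hazard per step is lambda*dt/1000.
    """
    lam = spike_intensity(state, params)
    p = -np.expm1(-np.asarray(lam) * dt * 1e-3)
    u = rng.random(size=np.shape(p)) if np.ndim(p) else rng.random()
    fired = u < p
    return bool(fired) if np.ndim(p) == 0 else fired


def apply_spike(state: NeuronState, params: GIFParameters) -> NeuronState:
    """Post-spike update: reset V, start refractory clock, bump each trace."""
    return NeuronState(
        V=params.V_reset,
        eta_traces=state.eta_traces + _kernel_amps(params.eta_kernels),
        gamma_traces=state.gamma_traces + _kernel_amps(params.gamma_kernels),
        refractory_remaining=params.tau_ref,
    )


# --- published parameter sets -------------------------------------------------
# Fitted cortical-neuron values used throughout the chain and grid models.
# The excitatory gamma_1 amplitude is 3.26 mV in the chain simulations and
# 13.05 mV in the multicolumn (barrel grid) model; use
# EXCITATORY.with_gamma1_amplitude(13.05) for the latter (network_builder
# does this automatically).

EXCITATORY = GIFParameters(
    C=63.0,
    g_L=8.1,
    E_L=-58.6,
    V_reset=-31.9,
    tau_ref=4.0,
    eta_kernels=(AdaptationKernel(36.3, 39.2), AdaptationKernel(0.7, 700.0)),
    gamma_kernels=(AdaptationKernel(3.26, 45.0), AdaptationKernel(2.52, 204.3)),
    lambda0=0.1,
    DeltaV=1.76,
    VT_star=-56.0,
)

INHIBITORY = GIFParameters(
    C=54.2,
    g_L=5.5,
    E_L=-59.8,
    V_reset=-38.7,
    tau_ref=4.0,
    eta_kernels=(AdaptationKernel(47.4, 19.1), AdaptationKernel(-0.8, 282.1)),
    gamma_kernels=(AdaptationKernel(-7.3, 28.3), AdaptationKernel(3.7, 347.7)),
    lambda0=0.1,
    DeltaV=1.24,
    VT_star=-44.5,
)

INHIBITORY2 = GIFParameters(
    C=29.4,
    g_L=2.9,
    E_L=-61.6,
    V_reset=-40.2,
    tau_ref=4.0,
    eta_kernels=(AdaptationKernel(15.2, 13.2), AdaptationKernel(16.2, 70.7)),
    gamma_kernels=(AdaptationKernel(5.8, 31.9), AdaptationKernel(1.9, 382.2)),
    lambda0=0.1,
    DeltaV=1.30,
    VT_star=-56.1,
)

#: excitatory gamma_1 amplitude used by the multicolumn barrel-grid model
GRID_GAMMA1_AMPLITUDE = 13.05
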