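"""Exponential current synapses and Tsodyks-Markram short-term plasticity.

A spike of the presynaptic neuron at time t_f makes the postsynaptic current
jump by the synaptic weight w (pA) at t_f + delay and decay with tau_syn:
``alpha(t) = exp(-(t - delay)/tau_syn)`` for t >= delay, zero before.

Short-term plasticity follows the two-variable resource model: u is the
release fraction (relaxing to U with tau_facil), x_res the available
resource fraction (recovering to 1 with tau_rec). A spike releases
``u * x_res * w`` (evaluated with pre-update values), then depletes
``x_res -= u * x_res`` and facilitates ``u += U * (1 - u)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SynapseParameters",
    "STPParameters",
    "STPState",
    "FACILITATION_TAUS",
    "DEPRESSION_TAUS",
    "psc_shape",
    "stp_relax",
    "stp_on_spike",
    "depression_weight_normalization",
    "psc_to_psp_peak",
    "psp_to_psc",
]

#: (tau_rec, tau_facil) in ms for the facilitating-synapse experiments
FACILITATION_TAUS = (0.001, 500.0)
#: (tau_rec, tau_facil) in ms for the depressing-synapse experiments
DEPRESSION_TAUS = (800.0, 0.001)


@dataclass(frozen=True)
class SynapseParameters:
    """Weight (PSC amplitude, pA; sign encodes exc/inh), delay and tau_syn (ms)."""

    weight_w: float
    delay: float = 1.0
    tau_syn: float = 7.7

    def __post_init__(self) -> None:
        if self.delay <= 0:
            raise ValueError("delay must be positive")
        if self.tau_syn <= 0:
            raise ValueError("tau_syn must be positive")


@dataclass(frozen=True)
class STPParameters:
    """Usage parameter U in (0, 1], recovery and facilitation time constants (ms)."""

    U: float
    tau_rec: float
    tau_facil: float

    def __post_init__(self) -> None:
        if not 0 < self.U <= 1:
            raise ValueError("U must be in (0, 1]")
        if self.tau_rec <= 0 or self.tau_facil <= 0:
            raise ValueError("STP time constants must be positive")


@dataclass
class STPState:
    """Release fraction u and resource fraction x_res; rest state is (U, 1)."""

    u: np.ndarray | float
    x_res: np.ndarray | float

    @classmethod
    def at_rest(cls, params: STPParameters, n: int | None = None) -> "STPState":
        if n is None:
            return cls(u=params.U, x_res=1.0)
        return cls(u=np.full(n, params.U), x_res=np.ones(n))


def psc_shape(t: np.ndarray | float, params: SynapseParameters) -> np.ndarray | float:
    """Unit PSC shape alpha(t): exp(-(t-delay)/tau_syn) for t >= delay, else 0."""
    t = np.asarray(t, dtype=float)
    out = np.where(t >= params.delay, np.exp(-(t - params.delay) / params.tau_syn), 0.0)
    return float(out) if out.ndim == 0 else out


def stp_relax(state: STPState, params: STPParameters, dt: float) -> STPState:
    """Exact integration of the continuous STP dynamics over dt (no spikes).

    x_res -> 1 - (1 - x_res) exp(-dt/tau_rec);  u -> U - (U - u) exp(-dt/tau_facil).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    x = 1.0 - (1.0 - np.asarray(state.x_res)) * math.exp(-dt / params.tau_rec)
    u = params.U - (params.U - np.asarray(state.u)) * math.exp(-dt / params.tau_facil)
    if np.ndim(state.u) == 0:
        return STPState(u=float(u), x_res=float(x))
    return STPState(u=u, x_res=x)


def stp_on_spike(
    state: STPState, params: STPParameters, weight_w: float | np.ndarray
) -> tuple[np.ndarray | float, STPState]:
    """Release on a presynaptic spike.

    Returns the effective PSC amplitude ``u * x_res * weight_w`` computed with
    the pre-update (u, x_res), and the post-spike state with the resource
    depleted by u*x_res and the release fraction facilitated by U*(1-u).
    """
    u0 = np.asarray(state.u, dtype=float)
    x0 = np.asarray(state.x_res, dtype=float)
    amplitude = u0 * x0 * weight_w
    x1 = x0 - u0 * x0
    u1 = u0 + params.U * (1.0 - u0)
    if np.ndim(state.u) == 0 and np.ndim(weight_w) == 0:
        return float(amplitude), STPState(u=float(u1), x_res=float(x1))
    return amplitude, STPState(u=u1, x_res=x1)


def depression_weight_normalization(
    params: STPParameters, target_first_psc: float
) -> float:
    """Weight that makes the first PSC from rest equal ``target_first_psc``.

    From rest (u, x_res) = (U, 1) the first release is U*w, so w = target/U.
    Used so depression sweeps over U keep the initial PSC amplitude fixed.
    """
    if params.U <= 0:
        raise ValueError("U must be positive")
    return target_first_psc / params.U


def _passive_psp(t: np.ndarray, weight_w: float, tau_syn: float, C: float, tau_m: float) -> np.ndarray:
    """Passive-membrane voltage deflection (mV) at times t for one PSC."""
    if abs(tau_m - tau_syn) < 1e-9 * tau_m:
        return (weight_w / C) * t * np.exp(-t / tau_m)
    pref = weight_w / C / (1.0 / tau_m - 1.0 / tau_syn)
    return pref * (np.exp(-t / tau_syn) - np.exp(-t / tau_m))


def psc_to_psp_peak(weight_w: float, tau_syn: float, target_params) -> float:
    """Peak PSP deflection (mV) of a passive membrane for one PSC of ``weight_w``.

    The membrane filter exp(-t/tau_m)/C applied to w*exp(-t/tau_syn) peaks at
    t* = ln(tau_m/tau_syn) * tau_m*tau_syn/(tau_m - tau_syn) (t* = tau in the
    equal-time-constant limit, peak w*tau/(C*e)). pF*mV = pA*ms makes the
    units work out directly.
    """
    if tau_syn <= 0:
        raise ValueError("tau_syn must be positive")
    tau_m = target_params.tau_m
    C = target_params.C
    if abs(tau_m - tau_syn) < 1e-9 * tau_m:
        t_star = tau_m
    else:
        t_star = math.log(tau_m / tau_syn) * tau_m * tau_syn / (tau_m - tau_syn)
    return float(_passive_psp(np.asarray(t_star, dtype=float), weight_w, tau_syn, C, tau_m))


def psp_to_psc(peak_mV: float, tau_syn: float, target_params) -> float:
    """PSC amplitude (pA) whose passive PSP peak equals ``peak_mV``.

    The peak is linear in the weight, so this is an exact inversion.
    """
    unit_peak = psc_to_psp_peak(1.0, tau_syn, target_params)
    return peak_mV / unit_peak
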