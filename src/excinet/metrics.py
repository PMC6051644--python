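"""Activation times, propagation profiles and grid trial classification.

The activation time of an assembly is the mean first-spike time of its
neurons after at least 100 ms of assembly-level quiescence; equivalently
(and interchangeably for propagation measurements) the time at which half
the neurons have fired such a first spike.  An *activation episode* is a
run of assembly spikes separated from the previous one by >= 100 ms in
which at least half the neurons participate -- isolated spontaneous spikes
(the resting rate is ~0.02 Hz per neuron) never qualify.

Per-step propagation delay = difference of consecutive assemblies'
activation times; propagation speed = 1 / (total delay first->last).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import SpikeData, population_rate

__all__ = [
    "QUIESCENCE_MS",
    "ActivationProfile",
    "TrialOutcome",
    "activation_episodes",
    "activation_time_mean_first",
    "activation_time_half_count",
    "propagation_profile",
    "classify_grid_trial",
    "peak_assembly_rate",
]

#: minimum assembly-level silent gap separating activation episodes (ms)
QUIESCENCE_MS = 100.0


@dataclass
class ActivationProfile:
    """Per-assembly activation times along a chain (NaN = never activated)."""

    assemblies: list[str]
    activation_times: np.ndarray  # ms, NaN when undefined
    failed: bool

    @property
    def step_delays(self) -> np.ndarray:
        return np.diff(self.activation_times)

    @property
    def total_delay(self) -> float:
        return float(self.activation_times[-1] - self.activation_times[0])

    @property
    def speed(self) -> float:
        """Propagation speed in groups per ms (1 / total delay)."""
        return 1.0 / self.total_delay

    def to_dataframe(self) -> pd.DataFrame:
        step = np.concatenate(([np.nan], self.step_delays))
        return pd.DataFrame(
            {
                "assembly": self.assemblies,
                "activation_time_ms": self.activation_times,
                "per_step_delay_ms": step,
            }
        )


@dataclass
class TrialOutcome:
    """Classification of one grid trial."""

    category: str  # no_spread | spread | circulation
    survival_ms: float
    column_activations: dict[str, list[float]]  # activation times per column


def _episodes_from_times(times: np.ndarray) -> list[tuple[int, int]]:
    """Index ranges [i, j) of spike-time runs separated by >= QUIESCENCE_MS."""
    if len(times) == 0:
        return []
    gaps = np.nonzero(np.diff(times) >= QUIESCENCE_MS)[0]
    starts = np.concatenate(([0], gaps + 1))
    ends = np.concatenate((gaps + 1, [len(times)]))
    return list(zip(starts, ends))


def activation_episodes(
    spikes: SpikeData, assembly: str, min_fraction: float = 0.5
) -> list[dict]:
    """Activation episodes of one assembly.

    Returns a list of dicts with keys ``first_spikes`` (per participating
    neuron, ms), ``t_mean`` (mean first-spike time), ``t_half`` (time the
    ceil(N/2)-th neuron fires its first episode spike), ``start``/``end``
    (episode extent, ms).  Episodes in which fewer than ``min_fraction`` of
    the neurons fire are dropped.
    """
    t, ids = spikes.for_population(assembly)
    order = np.argsort(t, kind="stable")
    t, ids = t[order], ids[order]
    _, size = spikes.population_slice(assembly)
    need = math.ceil(size * min_fraction)
    out = []
    for i, j in _episodes_from_times(t):
        seg_t, seg_ids = t[i:j], ids[i:j]
        _, first_idx = np.unique(seg_ids, return_index=True)
        firsts = np.sort(seg_t[first_idx])
        if len(firsts) < need:
            continue
        out.append(
            {
                "first_spikes": firsts,
                "t_mean": float(firsts.mean()),
                "t_half": float(firsts[need - 1]),
                "start": float(seg_t[0]),
                "end": float(seg_t[-1]),
            }
        )
    return out


def activation_time_mean_first(
    spikes: SpikeData, assembly: str, t_min: float = 0.0
) -> float:
    """Mean first-spike time (ms) of the first activation episode at/after t_min.

    NaN when the assembly never activates (fewer than half its neurons fire
    within one episode).
    """
    for ep in activation_episodes(spikes, assembly):
        if ep["start"] >= t_min:
            return ep["t_mean"]
    return float("nan")


def activation_time_half_count(
    spikes: SpikeData, assembly: str, t_min: float = 0.0
) -> float:
    """Time (ms) at which ceil(N/2) neurons have fired a first episode spike."""
    for ep in activation_episodes(spikes, assembly):
        if ep["start"] >= t_min:
            return ep["t_half"]
    return float("nan")


def propagation_profile(
    spikes: SpikeData, chain_order: list[str], t_min: float = 0.0
) -> ActivationProfile:
    """Activation profile along an ordered chain of assemblies."""
    if len(chain_order) < 2:
        raise ValueError("need at least two assemblies")
    times = np.array(
        [activation_time_mean_first(spikes, a, t_min) for a in chain_order]
    )
    return ActivationProfile(
        assemblies=list(chain_order),
        activation_times=times,
        failed=bool(np.isnan(times).any()),
    )


def classify_grid_trial(
    spikes: SpikeData,
    layout,
    stimulus_onset: float = 100.0,
    clamp_ms: float = 1000.0,
) -> TrialOutcome:
    """Classify one grid trial from its column-assembly activation episodes.

    * ``no_spread``   -- fewer than all 25 columns ever activate;
    * ``spread``      -- every column activates exactly once;
    * ``circulation`` -- some column re-activates (a second activation
      episode after >= 100 ms of column quiescence).

    ``survival_ms`` is the end of the last column activation episode minus
    the stimulus onset, clamped at ``clamp_ms`` (stray spontaneous spikes,
    which trickle in at the ~0.02 Hz resting rate, do not extend it).
    """
    col_act: dict[str, list[float]] = {}
    last_end = stimulus_onset
    for key in layout.columns:
        assem, _, _ = layout.pops(key)
        eps = activation_episodes(spikes, assem)
        col_act[key] = [ep["t_mean"] for ep in eps]
        if eps:
            last_end = max(last_end, eps[-1]["end"])
    n_active = sum(1 for v in col_act.values() if v)
    if any(len(v) > 1 for v in col_act.values()) and n_active > 1:
        category = "circulation"
    elif n_active < len(layout.columns):
        category = "no_spread"
    else:
        category = "spread"
    survival = min(max(last_end - stimulus_onset, 0.0), clamp_ms)
    return TrialOutcome(category=category, survival_ms=survival, column_activations=col_act)


def peak_assembly_rate(
    spikes: SpikeData,
    assembly: str,
    bin_ms: float = 10.0,
    episode_rate_hz: float = 10.0,
    t_min: float = 0.0,
) -> float:
    """Peak binned population rate (Hz) during the assembly's active episode.

    The active episode is the maximal run of consecutive bins with
    population rate above ``episode_rate_hz`` that contains the activation
    time.  Raises if the assembly never activates.
    """
    t_act = activation_time_mean_first(spikes, assembly, t_min)
    if np.isnan(t_act):
        raise ValueError(f"assembly {assembly!r} never activated")
    trace = population_rate(spikes, assembly, bin_ms)
    k = min(int(t_act // bin_ms), len(trace.rate_hz) - 1)
    hot = trace.rate_hz > episode_rate_hz
    if not hot[k]:  # activation bin itself may straddle the episode edge
        candidates = np.nonzero(hot)[0]
        if len(candidates) == 0:
            return float(trace.rate_hz[k])
        k = candidates[np.argmin(np.abs(candidates - k))]
    lo = k
    while lo > 0 and hot[lo - 1]:
        lo -= 1
    hi = k
    while hi + 1 < len(hot) and hot[hi + 1]:
        hi += 1
    return float(trace.rate_hz[lo : hi + 1].max())
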