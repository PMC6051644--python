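"""Experiment drivers: weight/STP sweeps, grid trials, theory comparison.

Conventions shared by all experiments:

* Synaptic weights are specified as PSP peak amplitudes (mV) on the target
  membrane and converted to PSC amplitudes (pA) internally; w_exc uses the
  excitatory membrane with tau_syn = 7.7 ms, w_inh the inhibitory membrane
  with tau_syn = 9.9 ms.
* One master seed per experiment; network topology is frozen per sweep
  point while each trial draws its own dynamics (stimulus + escape-noise)
  seed, as required for trial-averaged delay maps.
* The transient stimulus itself is stochastic and sometimes fails to
  ignite the stimulated assembly; trials are conditioned on ignition
  (non-igniting dynamics seeds are redrawn), matching the convention that
  propagation reliability is judged only where the stimulus took hold.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import SpikeData, StimulusSpec, run
from .metrics import (
    ActivationProfile,
    classify_grid_trial,
    peak_assembly_rate,
    propagation_profile,
)
from .network import (
    GridLayout,
    NetworkModel,
    build_chain,
    build_grid,
    set_gamma2_pattern,
    shuffle_column_means,
)
from .neuron import EXCITATORY, INHIBITORY
from .synapse import (
    DEPRESSION_TAUS,
    FACILITATION_TAUS,
    STPParameters,
    psp_to_psc,
)
from .theory import TheoryInputs, rate_template_from_spikes, solve_delay

__all__ = [
    "SweepSpec",
    "REFERENCE_W_EXC_PSP",
    "REFERENCE_W_INH_PSP",
    "chain_model",
    "run_chain_trial",
    "chain_trials",
    "run_sweep",
    "max_reliable_step_delay",
    "peak_rate_experiment",
    "theory_vs_simulation",
    "carved_path_means",
    "run_grid_trials",
    "make_fixture_raster",
]

#: mid-range reference weights (PSP mV) at which the chain with one
#: inhibitory population propagates reliably at a moderate speed
REFERENCE_W_EXC_PSP = 0.40
REFERENCE_W_INH_PSP = 0.30

_MAX_IGNITION_ATTEMPTS = 10


@dataclass
class SweepSpec:
    """Axes of a parameter sweep and its trial/seed bookkeeping."""

    axes: list[tuple[str, list[float]]]
    trials: int = 10
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not self.axes:
            raise ValueError("need at least one sweep axis")
        if self.trials < 1:
            raise ValueError("need at least one trial per point")


def _sub_seed(*keys: int) -> int:
    ss = np.random.SeedSequence([int(k) % 2**31 for k in keys])
    return int(ss.generate_state(1)[0] % 2**31)


def chain_model(
    variant: str = "exc_inh",
    n_groups: int = 11,
    w_exc_psp: float = REFERENCE_W_EXC_PSP,
    w_inh_psp: float = REFERENCE_W_INH_PSP,
    seed: int = 0,
    stp_mode: str | None = None,
    U: float = 1.0,
    tau_rec: float | None = None,
    tau_facil: float | None = None,
) -> NetworkModel:
    """Build a chain from PSP-unit weights, optionally with STP.

    ``stp_mode='facilitation'`` puts facilitating synapses on the
    inter-assembly excitatory connections; ``'depression'`` puts depressing
    synapses on the inter-group excitatory-to-inhibitory connections (with
    the first-PSC amplitude pinned at w_inh) and raises the intra-group
    inhibitory-to-excitatory weight to 1.07 mV.
    """
    w_exc = psp_to_psc(w_exc_psp, 7.7, EXCITATORY)
    w_inh = psp_to_psc(w_inh_psp, 9.9, INHIBITORY)
    stp_exc = stp_inh = None
    inh_to_exc = None
    if stp_mode == "facilitation":
        tr, tf = FACILITATION_TAUS
        stp_exc = STPParameters(U, tau_rec or tr, tau_facil or tf)
    elif stp_mode == "depression":
        tr, tf = DEPRESSION_TAUS
        stp_inh = STPParameters(U, tau_rec or tr, tau_facil or tf)
        inh_to_exc = psp_to_psc(1.07, 7.7, EXCITATORY)
    elif stp_mode is not None:
        raise ValueError(f"unknown stp_mode {stp_mode!r}")
    return build_chain(
        n_groups=n_groups,
        w_exc=w_exc,
        w_inh=w_inh,
        variant=variant,
        seed=seed,
        stp_exc=stp_exc,
        stp_inh=stp_inh,
        inh_to_exc_psc=inh_to_exc,
    )


def _chain_duration(n_groups: int, onset: float) -> float:
    # generous room for the slowest reliable waves (~60 ms per step)
    return onset + 80.0 * n_groups + 150.0


def run_chain_trial(
    model: NetworkModel,
    seed: int,
    stimulate: str = "exc_1",
    T: float | None = None,
    dt: float = 0.1,
    onset: float = 100.0,
) -> tuple[SpikeData, ActivationProfile]:
    """One chain simulation plus its activation profile along the assemblies."""
    n_groups = sum(1 for p in model.populations if p.role == "assembly")
    if T is None:
        T = _chain_duration(n_groups, onset)
    res = run(model, [StimulusSpec(target=stimulate, onset=onset)], T=T, dt=dt, seed=seed)
    order = [f"exc_{g}" for g in range(1, n_groups + 1)]
    return res.spikes, propagation_profile(res.spikes, order)


def chain_trials(
    model: NetworkModel,
    n_trials: int,
    master_seed: int,
    stimulate: str = "exc_1",
    T: float | None = None,
    dt: float = 0.1,
    point_key: int = 0,
) -> pd.DataFrame:
    """Ignition-conditioned trials: per trial the mean/total step delay.

    Dynamics seeds are redrawn (up to a cap) until the stimulated assembly
    ignites; ``propagated`` records whether the wave then reached the far
    end of the chain.
    """
    rows = []
    for trial in range(n_trials):
        profile = None
        for attempt in range(_MAX_IGNITION_ATTEMPTS):
            seed = _sub_seed(master_seed, point_key, trial, attempt)
            spikes, prof = run_chain_trial(model, seed, stimulate, T=T, dt=dt)
            if not np.isnan(prof.activation_times[0]):
                profile = prof
                break
        if profile is None:
            rows.append(
                {"trial": trial, "ignited": False, "propagated": False,
                 "mean_step_delay_ms": np.nan, "total_delay_ms": np.nan}
            )
            continue
        ok = not profile.failed
        rows.append(
            {
                "trial": trial,
                "ignited": True,
                "propagated": ok,
                "mean_step_delay_ms": float(np.nanmean(profile.step_delays)) if ok else np.nan,
                "total_delay_ms": profile.total_delay if ok else np.nan,
            }
        )
    return pd.DataFrame(rows)


def run_sweep(
    spec: SweepSpec,
    variant: str = "exc_inh",
    n_groups: int = 11,
    stp_mode: str | None = None,
    base: dict | None = None,
    T: float | None = None,
) -> pd.DataFrame:
    """Sweep chain parameters; per point: mean +- SD delay and failure fraction.

    Axis names: ``w_exc_psp``, ``w_inh_psp`` (PSP mV) and ``U`` (STP usage,
    requires ``stp_mode``).  Topology is frozen across the sweep (one
    connectivity seed); every trial uses a fresh dynamics seed.
    """
    base = dict(base or {})
    names = [n for n, _ in spec.axes]
    for n in names:
        if n not in ("w_exc_psp", "w_inh_psp", "U"):
            raise ValueError(f"unknown sweep axis {n!r}")
    rows = []
    for k, values in enumerate(itertools.product(*(v for _, v in spec.axes))):
        point = dict(base)
        point.update(dict(zip(names, values)))
        model = chain_model(
            variant=variant,
            n_groups=n_groups,
            seed=spec.master_seed,
            stp_mode=stp_mode,
            **point,
        )
        df = chain_trials(
            model, spec.trials, spec.master_seed, T=T, point_key=k + 1
        )
        delays = df.mean_step_delay_ms.to_numpy()
        row = {n: v for n, v in zip(names, values)}
        row.update(
            {
                "mean_step_delay_ms": float(np.nanmean(delays)) if np.isfinite(delays).any() else np.nan,
                "sd_step_delay_ms": float(np.nanstd(delays, ddof=1)) if np.isfinite(delays).sum() > 1 else np.nan,
                "failure_fraction": float(1.0 - df.propagated.mean()),
                "n_trials": spec.trials,
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)


def max_reliable_step_delay(
    variant: str,
    axis: str,
    values: list[float],
    trials: int = 10,
    master_seed: int = 0,
    n_groups: int = 11,
    base: dict | None = None,
) -> tuple[float, dict, pd.DataFrame]:
    """Largest mean per-step delay among sweep points where ALL trials propagate.

    Returns (delay_ms, point_parameters, sweep_table).
    """
    spec = SweepSpec(axes=[(axis, list(values))], trials=trials, master_seed=master_seed)
    table = run_sweep(spec, variant=variant, n_groups=n_groups, base=base)
    ok = table[table.failure_fraction == 0.0]
    if ok.empty:
        return float("nan"), {}, table
    best = ok.loc[ok.mean_step_delay_ms.idxmax()]
    return float(best.mean_step_delay_ms), {axis: float(best[axis])}, table


def peak_rate_experiment(
    variant: str,
    n_seeds: int = 5,
    master_seed: int = 0,
    n_groups: int = 8,
    w_exc_psp: float = REFERENCE_W_EXC_PSP,
    w_inh_psp: float = REFERENCE_W_INH_PSP,
) -> float:
    """Peak 10 ms-binned assembly rate (Hz), averaged over assemblies and seeds.

    The stimulated assembly is excluded (its burst rides on the stimulus
    current); assemblies that fail to activate in a trial are skipped.
    """
    model = chain_model(
        variant=variant, n_groups=n_groups,
        w_exc_psp=w_exc_psp, w_inh_psp=w_inh_psp, seed=master_seed,
    )
    peaks = []
    for s in range(n_seeds):
        for attempt in range(_MAX_IGNITION_ATTEMPTS):
            seed = _sub_seed(master_seed, 99, s, attempt)
            spikes, prof = run_chain_trial(model, seed)
            if not np.isnan(prof.activation_times[0]):
                break
        for g in range(2, n_groups + 1):
            if np.isnan(prof.activation_times[g - 1]):
                continue
            peaks.append(peak_assembly_rate(spikes, f"exc_{g}"))
    return float(np.mean(peaks))


def theory_vs_simulation(
    w_exc_psps: list[float],
    trials: int = 10,
    master_seed: int = 0,
    n_groups: int = 8,
    template_w_exc_psp: float | None = None,
    dt: float = 0.1,
) -> pd.DataFrame:
    """Self-consistent theory vs simulated per-step delay, per w_exc.

    The rate template is extracted once, from a mid-chain assembly of a
    single simulation (the template shape is dominated by self-feedback and
    so is reused across w_exc values).  Simulated delays are the mean of
    the interior consecutive activation-time differences over
    ignition-conditioned trials.
    """
    template_w = template_w_exc_psp if template_w_exc_psp is not None else w_exc_psps[0]
    model0 = chain_model(
        variant="exc_only", n_groups=n_groups, w_exc_psp=template_w, seed=master_seed
    )
    for attempt in range(_MAX_IGNITION_ATTEMPTS):
        seed = _sub_seed(master_seed, 7, attempt)
        spikes0, prof0 = run_chain_trial(model0, seed)
        if not prof0.failed:
            break
    mid = f"exc_{n_groups // 2 + 1}"
    template = rate_template_from_spikes(spikes0, mid, dt=dt)

    rows = []
    for k, w_psp in enumerate(w_exc_psps):
        w_pa = psp_to_psc(w_psp, 7.7, EXCITATORY)
        inputs = TheoryInputs(
            rate_hz=template, dt=dt, N=70,
            p_exc=0.10, w_exc=w_pa, p_self=0.50, w_self=22.1,
            delay=1.0, tau_syn=7.7, params=EXCITATORY,
        )
        theo = solve_delay(inputs)
        model = chain_model(
            variant="exc_only", n_groups=n_groups, w_exc_psp=w_psp, seed=master_seed
        )
        sim_means = []
        for trial in range(trials):
            for attempt in range(_MAX_IGNITION_ATTEMPTS):
                seed = _sub_seed(master_seed, 13, k, trial, attempt)
                _, prof = run_chain_trial(model, seed)
                if not np.isnan(prof.activation_times[0]):
                    break
            if prof.failed:
                continue
            steps = prof.step_delays[1:-1]  # interior: skip stimulus-boosted
            sim_means.append(float(np.mean(steps)))
        rows.append(
            {
                "w_exc_psp_mv": w_psp,
                "x_theory_ms": theo.x,
                "x_sim_ms": float(np.mean(sim_means)) if sim_means else np.nan,
                "sim_sd_ms": float(np.std(sim_means, ddof=1)) if len(sim_means) > 1 else np.nan,
                "n_sim": len(sim_means),
                "converged": theo.converged,
            }
        )
    df = pd.DataFrame(rows)
    df["abs_error_ms"] = (df.x_theory_ms - df.x_sim_ms).abs()
    return df


# --- grid experiments --------------------------------------------------------


def carved_path_means(
    layout: GridLayout,
    excitable: float = 0.0,
    graded: tuple[float, float] = (18.0, 30.0),
    center_mean: float = 45.0,
    inner_mean: float = 30.0,
    path_len: int = 10,
) -> dict[str, float]:
    """Synthetic 'carved path' initial-threshold pattern for circulation.

    The 16 border columns form a ring; a contiguous segment of
    ``path_len`` columns starting at the A1 corner is made excitable
    (mean 0).  The remaining border columns are dormant, with means graded
    from ``graded[0]`` (the column the wave will need first, right after
    the excitable segment) up to ``graded[1]`` (needed last), so they
    recover in wave order as their offsets decay with the slow threshold
    kernel's ~200 ms time constant.  Inner non-center columns are dormant
    and the center column very dormant, which keeps the wave on the ring;
    once running, dormancy behind the wave is maintained by the
    spike-triggered threshold buildup of each burst.  The pattern stands
    in for the hand-tuned per-column map, whose values exist only
    graphically, and is sized against the ~130 pA forward drive one
    bursting column delivers (offsets well below ~15 mV do not block it).
    """
    n = layout.n_rows
    ring = []
    for a in range(n):
        ring.append((0, a))
    for r in range(1, n):
        ring.append((r, n - 1))
    for a in range(n - 2, -1, -1):
        ring.append((n - 1, a))
    for r in range(n - 2, 0, -1):
        ring.append((r, 0))
    means = {}
    n_border = len(ring)
    for i, (r, a) in enumerate(ring):
        key = layout.key(r, a)
        if i < path_len:
            means[key] = excitable
        else:
            frac = (i - path_len) / max(n_border - path_len - 1, 1)
            means[key] = graded[0] + frac * (graded[1] - graded[0])
    for r in range(1, n - 1):
        for a in range(1, n - 1):
            key = layout.key(r, a)
            means[key] = inner_mean
    means[layout.center] = center_mean
    return means


def run_grid_trials(
    n_trials: int,
    column_means: dict[str, float],
    shuffle: bool = True,
    master_seed: int = 0,
    model: NetworkModel | None = None,
    layout: GridLayout | None = None,
    sigma: float = 3.0,
    stimulate: str = "A1",
    onset: float = 100.0,
    T: float = 1250.0,
    dt: float = 0.1,
) -> pd.DataFrame:
    """Repeated grid trials with (optionally shuffled) initial-value patterns.

    Per trial: the column means are shuffled (if requested), every neuron
    redraws its initial slow-threshold offset, the corner column is
    stimulated at ``onset``, and the outcome is classified as
    no_spread / spread / circulation with its survival duration.
    """
    if model is None or layout is None:
        model, layout = build_grid(seed=master_seed)
    rows = []
    for trial in range(n_trials):
        means = (
            shuffle_column_means(column_means, seed=_sub_seed(master_seed, 31, trial))
            if shuffle
            else dict(column_means)
        )
        set_gamma2_pattern(model, layout, means, sigma=sigma,
                           seed=_sub_seed(master_seed, 37, trial))
        res = run(
            model,
            [StimulusSpec(target=layout.pops(stimulate), onset=onset)],
            T=T, dt=dt,
            seed=_sub_seed(master_seed, 41, trial),
        )
        outcome = classify_grid_trial(res.spikes, layout, stimulus_onset=onset)
        rows.append(
            {
                "trial": trial,
                "seed": _sub_seed(master_seed, 41, trial),
                "category": outcome.category,
                "survival_ms": outcome.survival_ms,
                "n_columns_active": sum(1 for v in outcome.column_activations.values() if v),
            }
        )
    return pd.DataFrame(rows)


# --- synthetic rasters -------------------------------------------------------


@dataclass
class FixtureEvent:
    """One scheduled activation of a population in a synthetic raster."""

    population: str
    t: float
    jitter: float = 0.0
    fraction: float = 1.0  # fraction of neurons that participate
    n_extra: int = 0  # extra (non-first) spikes per participating neuron
    duration: float = 30.0  # episode length over which extras are spread


@dataclass
class FixtureRaster:
    spikes: SpikeData
    schedule: list[FixtureEvent] = field(default_factory=list)


def make_fixture_raster(
    schedule: list[FixtureEvent],
    sizes: dict[str, int],
    T: float | None = None,
    seed: int = 0,
) -> FixtureRaster:
    """Synthetic SpikeData realizing a prescribed activation schedule.

    Per event, ``fraction`` of the population's neurons fire a first spike
    at ``t`` plus a centered jitter (offsets are re-centered so the mean
    first-spike time equals ``t`` exactly), followed by ``n_extra`` spikes
    each spread over ``duration``.  Built for exercising the metrics layer
    without a simulation.
    """
    rng = np.random.default_rng(np.random.SeedSequence(int(seed) % 2**31))
    names = sorted(sizes)
    offsets = {}
    acc = 0
    for nm in names:
        offsets[nm] = acc
        acc += sizes[nm]
    times, ids = [], []
    for ev in schedule:
        size = sizes[ev.population]
        n_act = max(1, int(round(ev.fraction * size)))
        neurons = np.arange(n_act)
        if ev.jitter > 0 and n_act > 1:
            off = rng.normal(0.0, ev.jitter, size=n_act)
            off -= off.mean()
        else:
            off = np.zeros(n_act)
        first = ev.t + off
        times.append(first)
        ids.append(neurons + offsets[ev.population])
        for k in range(ev.n_extra):
            extra = first + (k + 1) * ev.duration / (ev.n_extra + 1)
            times.append(extra)
            ids.append(neurons + offsets[ev.population])
    t = np.concatenate(times) if times else np.empty(0)
    i = np.concatenate(ids).astype(np.int64) if ids else np.empty(0, np.int64)
    order = np.argsort(t, kind="stable")
    t, i = t[order], i[order]
    total_T = T if T is not None else (float(t.max()) + 50.0 if len(t) else 100.0)
    spikes = SpikeData(
        times=t,
        ids=i,
        duration=total_T,
        populations=[(nm, offsets[nm], sizes[nm]) for nm in names],
    )
    return FixtureRaster(spikes=spikes, schedule=list(schedule))
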