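"""Clock-driven network simulation.

Fixed-step exponential-Euler integration (default dt = 0.1 ms): the leak,
the adaptation traces and the synaptic current accumulators all decay with
their exact exponential factors, and the synaptic drive is held constant
over each step.  Per step the engine

1. decays synaptic accumulators and adaptation traces,
2. delivers the spikes scheduled one transmission delay earlier (the
   matching accumulator jumps by the -- possibly STP-scaled -- weight),
3. advances the membrane potentials,
4. draws spikes with per-step probability 1 - exp(-lambda dt) from the
   post-integration potential,
5. applies resets, bumps the adaptation traces and schedules the new
   deliveries.

Synaptic currents are pooled into one exponential accumulator per
(neuron, tau_syn class); this is exact for the exponential PSC kernel.
Short-term plasticity keeps per-edge (u, x_res) state, updated lazily at
presynaptic spike times.

Randomness is split into named streams (stimulus, escape noise) derived
from the one master seed, so identical (model, stimuli, T, dt, seed) runs
are bit-reproducible; connectivity has its own seed at build time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .network import NetworkModel

__all__ = [
    "StimulusSpec",
    "SpikeData",
    "RateTrace",
    "CurrentTrace",
    "SimulationResult",
    "run",
    "make_poisson_stimulus",
    "population_rate",
    "gaussian_smooth",
]


@dataclass(frozen=True)
class StimulusSpec:
    """Transient Poisson stimulus onto one or more populations.

    ``n_poisson`` independent Poisson sources at ``rate`` Hz fire during
    [onset, onset + duration); every source contacts every neuron of every
    target population with PSC amplitude ``weight`` (pA) and the target's
    excitatory synaptic time constant.  ``target`` may be a single
    population name or a tuple of names (e.g. all populations of a grid
    column) sharing the same source spike trains.
    """

    target: str | tuple[str, ...]

    @property
    def targets(self) -> tuple[str, ...]:
        return (self.target,) if isinstance(self.target, str) else tuple(self.target)
    n_poisson: int = 25
    rate: float = 5.0
    duration: float = 25.0
    onset: float = 100.0
    weight: float = 180.0
    tau_syn: float = 7.7
    delay: float = 1.0

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("rate must be non-negative")
        if self.duration <= 0:
            raise ValueError("duration must be positive")


@dataclass
class SpikeData:
    """Spike records (time ms, global neuron id) plus the population table."""

    times: np.ndarray
    ids: np.ndarray
    duration: float
    populations: list[tuple[str, int, int]]  # (name, offset, size)

    def population_slice(self, name: str) -> tuple[int, int]:
        for nm, off, size in self.populations:
            if nm == name:
                return off, size
        raise KeyError(f"no population named {name!r}")

    def population_of(self, neuron_id: int) -> str:
        for nm, off, size in self.populations:
            if off <= neuron_id < off + size:
                return nm
        raise KeyError(f"neuron id {neuron_id} out of range")

    def for_population(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        """(times, local ids) of one population, time-sorted."""
        off, size = self.population_slice(name)
        m = (self.ids >= off) & (self.ids < off + size)
        return self.times[m], self.ids[m] - off

    @property
    def n_spikes(self) -> int:
        return len(self.times)

    def to_dataframe(self) -> pd.DataFrame:
        pop = np.empty(len(self.ids), dtype=object)
        for nm, off, size in self.populations:
            m = (self.ids >= off) & (self.ids < off + size)
            pop[m] = nm
        return pd.DataFrame(
            {"time_ms": self.times, "neuron_id": self.ids, "population": pop}
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass
class RateTrace:
    """Population rate in fixed bins: rate = count / (N * bin), in Hz."""

    population: str
    bin_ms: float
    t_ms: np.ndarray  # bin left edges
    rate_hz: np.ndarray


@dataclass
class CurrentTrace:
    """Per-source mean synaptic current onto one target population (pA)."""

    target: str
    t_ms: np.ndarray
    by_source: dict[str, np.ndarray]

    @property
    def total(self) -> np.ndarray:
        return np.sum(list(self.by_source.values()), axis=0)


@dataclass
class SimulationResult:
    spikes: SpikeData
    currents: CurrentTrace | None
    final_state: dict[str, np.ndarray]


def make_poisson_stimulus(
    spec: StimulusSpec, seed_seq: np.random.SeedSequence
) -> list[np.ndarray]:
    """Per-source Poisson spike times (ms) within [onset, onset+duration)."""
    rng = np.random.default_rng(seed_seq)
    out = []
    lam = spec.rate * spec.duration * 1e-3  # expected spikes per source
    for _ in range(spec.n_poisson):
        n = rng.poisson(lam)
        out.append(np.sort(spec.onset + rng.random(n) * spec.duration))
    return out


def _build_param_arrays(model: NetworkModel):
    N = model.n_neurons
    a = {
        k: np.empty(N)
        for k in ("E_L", "V_reset", "tau_ref", "lambda0", "DeltaV", "VT_star", "inv_gL", "tau_m")
    }
    eta_amp = np.empty((N, 2))
    eta_tau = np.empty((N, 2))
    gam_amp = np.empty((N, 2))
    gam_tau = np.empty((N, 2))
    off = 0
    for p in model.populations:
        sl = slice(off, off + p.size_N)
        q = p.neuron_params
        a["E_L"][sl] = q.E_L
        a["V_reset"][sl] = q.V_reset
        a["tau_ref"][sl] = q.tau_ref
        a["lambda0"][sl] = q.lambda0
        a["DeltaV"][sl] = q.DeltaV
        a["VT_star"][sl] = q.VT_star
        a["inv_gL"][sl] = 1.0 / q.g_L
        a["tau_m"][sl] = q.tau_m
        eta_amp[sl] = [k.amplitude for k in q.eta_kernels]
        eta_tau[sl] = [k.tau for k in q.eta_kernels]
        gam_amp[sl] = [k.amplitude for k in q.gamma_kernels]
        gam_tau[sl] = [k.tau for k in q.gamma_kernels]
        off += p.size_N
    return a, eta_amp, eta_tau, gam_amp, gam_tau


class _Adjacency:
    """CSR-like adjacency over global pre ids for one delivery group."""

    def __init__(self, n_neurons: int, pre, post, weight):
        order = np.argsort(pre, kind="stable")
        self.post = np.asarray(post)[order]
        self.weight = np.asarray(weight)[order]
        counts = np.bincount(np.asarray(pre), minlength=n_neurons)
        self.indptr = np.concatenate(([0], np.cumsum(counts)))
        self.perm = order  # original edge order -> CSR order

    def gather(self, pre_ids: np.ndarray):
        """Concatenated (edge indices, posts, weights) for the given pres."""
        starts = self.indptr[pre_ids]
        counts = self.indptr[pre_ids + 1] - starts
        total = int(counts.sum())
        if total == 0:
            return (np.empty(0, np.int64),) * 2 + (np.empty(0),)
        cum = np.cumsum(counts) - counts
        idx = np.repeat(starts - cum, counts) + np.arange(total)
        return idx, self.post[idx], self.weight[idx]


def run(
    model: NetworkModel,
    stimuli: list[StimulusSpec],
    T: float,
    dt: float = 0.1,
    seed: int = 0,
    current_probe: str | None = None,
    hazard_warn: float = 0.1,
) -> SimulationResult:
    """Simulate the network for ``T`` ms and return spikes and final state.

    ``current_probe`` names a target population whose incoming mean
    synaptic current is recorded, decomposed by source population.
    """
    if T <= 0:
        raise ValueError("T must be positive")
    if model.realized is None or len(model.realized) != len(model.specs):
        raise ValueError("model has no realized edges; call model.realize(seed)")

    N = model.n_neurons
    n_steps = int(round(T / dt))
    off = model.offsets()
    params, eta_amp, eta_tau, gam_amp, gam_tau = _build_param_arrays(model)
    decay_m = np.exp(-dt / params["tau_m"])
    eta_decay = np.exp(-dt / eta_tau)
    gam_decay = np.exp(-dt / gam_tau)

    # --- synaptic accumulator classes (one per distinct tau_syn) ----------
    taus = sorted(
        {s.syn.tau_syn for s in model.specs} | {st.tau_syn for st in stimuli}
    )
    class_of = {tau: i for i, tau in enumerate(taus)}
    n_cls = len(taus)
    syn_decay = np.exp(-dt / np.asarray(taus))
    I_syn = np.zeros((n_cls, N))

    # --- delivery groups ---------------------------------------------------
    delays = sorted(
        {int(round(s.syn.delay / dt)) for s in model.specs}
        | {int(round(st.delay / dt)) for st in stimuli}
    )
    if delays and delays[0] < 1:
        raise ValueError("transmission delay must be at least one time step")
    max_d = delays[-1] if delays else 1
    L = max_d + 1
    buffer = np.zeros((L, n_cls, N))

    probe_off = off[current_probe] if current_probe is not None else 0
    static_groups: dict[tuple[int, int], list] = {}
    stp_groups = []
    probe_specs = []  # static specs into the probe: (source, cls, d, pre, post, w)
    for k, rc in enumerate(model.realized):
        s = rc.spec
        pre = rc.pre_local + off[s.source]
        post = rc.post_local + off[s.target]
        w = np.full(rc.n_edges, float(s.syn.weight_w))
        cls = class_of[s.syn.tau_syn]
        d = int(round(s.syn.delay / dt))
        probed = current_probe is not None and s.target == current_probe
        if s.stp is None:
            static_groups.setdefault((cls, d), []).append((pre, post, w))
            if probed:
                probe_specs.append((s.source, cls, d, pre, post, w))
        else:
            adj = _Adjacency(N, pre, post, w)
            stp_groups.append(
                {
                    "adj": adj,
                    "params": s.stp,
                    "u": np.full(len(pre), s.stp.U),
                    "x": np.ones(len(pre)),
                    "t_last": np.zeros(N),
                    "cls": cls,
                    "d": d,
                    "probe_src": s.source if probed else None,
                }
            )

    static_adj = {
        key: _Adjacency(
            N,
            np.concatenate([g[0] for g in lst]),
            np.concatenate([g[1] for g in lst]),
            np.concatenate([g[2] for g in lst]),
        )
        for key, lst in static_groups.items()
    }

    # --- stimuli ------------------------------------------------------------
    ss = np.random.SeedSequence(int(seed) % 2**31)
    stim_ss, dyn_ss = ss.spawn(2)
    rng = np.random.default_rng(dyn_ss)
    stim_jumps = []  # (class idx, target slice, per-step delivered amplitude)
    probe_stim = []
    for st in stimuli:
        trains = make_poisson_stimulus(st, stim_ss.spawn(1)[0])
        all_t = np.concatenate(trains) if trains else np.empty(0)
        deliver_step = (np.floor(all_t / dt).astype(int) + int(round(st.delay / dt)))
        counts = np.bincount(
            deliver_step[deliver_step < n_steps], minlength=n_steps
        ).astype(float)
        for tgt in st.targets:
            o, size = off[tgt], model.population(tgt).size_N
            stim_jumps.append(
                (class_of[st.tau_syn], slice(o, o + size), counts * st.weight)
            )
            if current_probe is not None and tgt == current_probe:
                probe_stim.append(len(stim_jumps) - 1)

    # --- state --------------------------------------------------------------
    V = params["E_L"].copy()
    eta = np.zeros((N, 2))
    gamma = np.zeros((N, 2))
    for name, g2 in model.initial_gamma2.items():
        o = off[name]
        gamma[o : o + len(g2), 1] = g2
    refr = np.zeros(N)

    # --- probe accumulators -------------------------------------------------
    probe = None
    if current_probe is not None:
        p_size = model.population(current_probe).size_N
        sources = sorted(
            {src for src, *_ in probe_specs}
            | {g["probe_src"] for g in stp_groups if g["probe_src"] is not None}
        ) + (["stimulus"] if probe_stim else [])
        probe = {
            "acc": {src: np.zeros((n_cls, p_size)) for src in sources},
            "buf": {src: np.zeros((L, n_cls, p_size)) for src in sources},
            "trace": {src: np.zeros(n_steps) for src in sources},
            "by_source": {},
        }
        for src, cls, d, pre, post, w in probe_specs:
            probe["by_source"].setdefault(src, []).append(
                (cls, d, _Adjacency(N, pre, post - probe_off, w))
            )

    spike_times: list[np.ndarray] = []
    spike_ids: list[np.ndarray] = []
    warned = False
    dt_s = dt * 1e-3  # Hz * s

    for n in range(n_steps):
        t = n * dt
        # 1. decay
        I_syn *= syn_decay[:, None]
        eta *= eta_decay
        gamma *= gam_decay
        refr -= dt
        np.clip(refr, 0.0, None, out=refr)
        # 2. deliver
        row = n % L
        I_syn += buffer[row]
        buffer[row] = 0.0
        for cls, sl, jumps in stim_jumps:
            if jumps[n]:
                I_syn[cls, sl] += jumps[n]
        if probe is not None:
            for src in probe["acc"]:
                acc = probe["acc"][src]
                acc *= syn_decay[:, None]
                acc += probe["buf"][src][row]
                probe["buf"][src][row] = 0.0
            for i_st in probe_stim:
                cls, sl, jumps = stim_jumps[i_st]
                if jumps[n]:
                    probe["acc"]["stimulus"][cls] += jumps[n]
            for src in probe["acc"]:
                probe["trace"][src][n] = probe["acc"][src].sum(axis=0).mean()
        # 3. integrate membrane
        total_I = I_syn.sum(axis=0) - eta.sum(axis=1)
        v_inf = params["E_L"] + total_I * params["inv_gL"]
        V = v_inf + (V - v_inf) * decay_m
        refractory = refr > 0
        np.copyto(V, params["V_reset"], where=refractory)
        # 4. escape-noise hazard
        expo = np.clip((V - params["VT_star"] - gamma.sum(axis=1)) / params["DeltaV"], -30, 30)
        lam = params["lambda0"] * np.exp(expo)
        lam[refractory] = 0.0
        hazard = lam * dt_s
        if not warned and hazard.max() > hazard_warn:
            warnings.warn(
                f"per-step hazard reached {hazard.max():.2f} at t={t:.1f} ms; "
                "consider a smaller dt",
                RuntimeWarning,
                stacklevel=2,
            )
            warned = True
        p_spike = -np.expm1(-hazard)
        fired = np.nonzero(rng.random(N) < p_spike)[0]
        if len(fired) == 0:
            continue
        # 5. reset, adapt, schedule
        spike_times.append(np.full(len(fired), t))
        spike_ids.append(fired)
        V[fired] = params["V_reset"][fired]
        refr[fired] = params["tau_ref"][fired]
        eta[fired] += eta_amp[fired]
        gamma[fired] += gam_amp[fired]
        for (cls, d), adj in static_adj.items():
            _, posts, ws = adj.gather(fired)
            if len(posts):
                np.add.at(buffer[(n + d) % L, cls], posts, ws)
        for g in stp_groups:
            idx, posts, ws = g["adj"].gather(fired)
            if not len(posts):
                continue
            pr = g["params"]
            counts = g["adj"].indptr[fired + 1] - g["adj"].indptr[fired]
            dt_rel = np.repeat(t - g["t_last"][fired], counts)
            u = pr.U - (pr.U - g["u"][idx]) * np.exp(-dt_rel / pr.tau_facil)
            x = 1.0 - (1.0 - g["x"][idx]) * np.exp(-dt_rel / pr.tau_rec)
            amp = u * x * ws
            g["x"][idx] = x - u * x
            g["u"][idx] = u + pr.U * (1.0 - u)
            g["t_last"][fired] = t
            np.add.at(buffer[(n + g["d"]) % L, g["cls"]], posts, amp)
            if probe is not None and g["probe_src"] is not None:
                np.add.at(
                    probe["buf"][g["probe_src"]][(n + g["d"]) % L, g["cls"]],
                    posts - probe_off,
                    amp,
                )
        if probe is not None:
            for src, lst in probe["by_source"].items():
                for cls, d, adj in lst:
                    _, posts, ws = adj.gather(fired)
                    if len(posts):
                        np.add.at(probe["buf"][src][(n + d) % L, cls], posts, ws)

    times = np.concatenate(spike_times) if spike_times else np.empty(0)
    ids = np.concatenate(spike_ids).astype(np.int64) if spike_ids else np.empty(0, np.int64)
    spikes = SpikeData(
        times=times,
        ids=ids,
        duration=T,
        populations=[(p.name, off[p.name], p.size_N) for p in model.populations],
    )
    currents = None
    if probe is not None:
        currents = CurrentTrace(
            target=current_probe,
            t_ms=np.arange(n_steps) * dt,
            by_source=probe["trace"],
        )
    final_state = {"V": V, "eta": eta, "gamma": gamma, "refractory": refr}
    return SimulationResult(spikes=spikes, currents=currents, final_state=final_state)


def population_rate(spikes: SpikeData, population: str, bin_ms: float = 10.0) -> RateTrace:
    """Population rate per bin: spike count / (N * bin width), in Hz."""
    if bin_ms <= 0:
        raise ValueError("bin width must be positive")
    _, size = spikes.population_slice(population)
    if size == 0:
        raise ValueError(f"population {population!r} is empty")
    t, _ = spikes.for_population(population)
    n_bins = int(np.ceil(spikes.duration / bin_ms))
    edges = np.arange(n_bins + 1) * bin_ms
    counts, _ = np.histogram(t, bins=edges)
    rate = counts / (size * bin_ms * 1e-3)
    return RateTrace(population=population, bin_ms=bin_ms, t_ms=edges[:-1], rate_hz=rate)


def gaussian_smooth(trace: RateTrace, sigma_ms: float) -> RateTrace:
    """Gaussian temporal filter (sigma in ms), edge-renormalized; sigma=0 is identity."""
    if sigma_ms < 0:
        raise ValueError("sigma must be non-negative")
    if sigma_ms == 0:
        return RateTrace(trace.population, trace.bin_ms, trace.t_ms.copy(), trace.rate_hz.copy())
    sig = sigma_ms / trace.bin_ms
    num = ndimage.gaussian_filter1d(trace.rate_hz.astype(float), sig, mode="constant")
    den = ndimage.gaussian_filter1d(np.ones_like(trace.rate_hz, dtype=float), sig, mode="constant")
    return RateTrace(trace.population, trace.bin_ms, trace.t_ms.copy(), num / den)
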