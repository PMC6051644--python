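"""Construction of assembly chains and the 5x5 barrel-cortex grid.

Networks are built from population specs (named groups sharing one GIF
parameter set) and connection specs (source population, target population,
connection probability, synapse parameters, optional short-term
plasticity). Realization draws an independent Bernoulli variable per
ordered neuron pair (no autapses, no multi-edges per spec); the edge set is
a deterministic function of the connectivity seed.

Two builders are provided:

* :func:`build_chain` -- a bidirectional chain of excitatory assemblies
  (70 neurons each, 50% internal connectivity), optionally with one or two
  inhibitory populations per group.  Inter-group synapses target nearest
  neighbors only and inhibitory populations make no inter-group contacts.
* :func:`build_grid` -- 25 barrel columns on a 5x5 lattice (5 rows A-E,
  5 arcs 1-5), each with a 70-neuron assembly, 380 non-assembly excitatory
  neurons and 70 inhibitory neurons.  Only excitatory neurons connect
  between 4-neighborhood columns; the boundary is absorbing (edge columns
  simply have fewer neighbors).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .neuron import (
    EXCITATORY,
    GRID_GAMMA1_AMPLITUDE,
    INHIBITORY,
    INHIBITORY2,
    AdaptationKernel,
    GIFParameters,
)
from .synapse import STPParameters, SynapseParameters

__all__ = [
    "PopulationSpec",
    "ConnectionSpec",
    "RealizedConnection",
    "NetworkModel",
    "GridLayout",
    "build_chain",
    "build_grid",
    "set_gamma2_pattern",
    "shuffle_column_means",
    "network_feedback_coefficient",
    "remove_column",
    "CHAIN_VARIANTS",
]

CHAIN_VARIANTS = ("exc_only", "exc_inh", "exc_inh_inh2")

#: default population sizes
ASSEMBLY_SIZE = 70
INHIBITORY_SIZE = 70
NON_ASSEMBLY_SIZE = 380

#: uniform synaptic transmission delay (ms)
DELAY_MS = 1.0


@dataclass(frozen=True)
class PopulationSpec:
    """A named homogeneous group of neurons."""

    name: str
    size_N: int
    role: str  # assembly | non_assembly | inhibitory | inhibitory2
    neuron_params: GIFParameters
    gamma2_init: tuple[float, float, bool] | None = None  # (mean mV, sigma mV, clip)

    def __post_init__(self) -> None:
        if self.size_N <= 0:
            raise ValueError("population size must be positive")
        if self.gamma2_init is not None and self.gamma2_init[1] < 0:
            raise ValueError("gamma2 sigma must be non-negative")


@dataclass(frozen=True)
class ConnectionSpec:
    """A random-connectivity block between two populations."""

    source: str
    target: str
    p: float
    syn: SynapseParameters
    stp: STPParameters | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("connection probability must be in [0, 1]")


@dataclass
class RealizedConnection:
    """Realized directed edges of one spec, in population-local indices."""

    spec: ConnectionSpec
    pre_local: np.ndarray
    post_local: np.ndarray

    @property
    def n_edges(self) -> int:
        return len(self.pre_local)


@dataclass
class NetworkModel:
    """Populations, connection specs and the realized random graph."""

    populations: list[PopulationSpec]
    specs: list[ConnectionSpec]
    realized: list[RealizedConnection] = field(default_factory=list)
    seed: int | None = None
    initial_gamma2: dict[str, np.ndarray] = field(default_factory=dict)

    # -- bookkeeping ---------------------------------------------------------
    def population(self, name: str) -> PopulationSpec:
        for p in self.populations:
            if p.name == name:
                return p
        raise KeyError(f"no population named {name!r}")

    @property
    def population_names(self) -> list[str]:
        return [p.name for p in self.populations]

    @property
    def n_neurons(self) -> int:
        return sum(p.size_N for p in self.populations)

    def offsets(self) -> dict[str, int]:
        """Global-index offset of each population (in listed order)."""
        out, acc = {}, 0
        for p in self.populations:
            out[p.name] = acc
            acc += p.size_N
        return out

    # -- realization ---------------------------------------------------------
    def realize(self, seed: int) -> "NetworkModel":
        """Draw the Bernoulli edge sets; deterministic in ``seed``."""
        self.seed = seed
        self.realized = []
        for k, spec in enumerate(self.specs):
            rng = np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, k]))
            n_src = self.population(spec.source).size_N
            n_tgt = self.population(spec.target).size_N
            mask = rng.random((n_src, n_tgt)) < spec.p
            if spec.source == spec.target:
                np.fill_diagonal(mask, False)
            pre, post = np.nonzero(mask)
            self.realized.append(
                RealizedConnection(spec, pre.astype(np.int64), post.astype(np.int64))
            )
        return self

    # -- export --------------------------------------------------------------
    def edges_dataframe(self) -> pd.DataFrame:
        """All realized edges with global ids, as a flat table."""
        off = self.offsets()
        frames = []
        for rc in self.realized:
            frames.append(
                pd.DataFrame(
                    {
                        "pre_id": rc.pre_local + off[rc.spec.source],
                        "post_id": rc.post_local + off[rc.spec.target],
                        "weight_pA": rc.spec.syn.weight_w,
                        "delay_ms": rc.spec.syn.delay,
                        "tau_syn_ms": rc.spec.syn.tau_syn,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def to_config(self) -> dict:
        """Hierarchical description sufficient to rebuild the identical model."""

        def kern(k: AdaptationKernel) -> list[float]:
            return [k.amplitude, k.tau]

        pops = []
        for p in self.populations:
            np_ = p.neuron_params
            pops.append(
                {
                    "name": p.name,
                    "size": p.size_N,
                    "role": p.role,
                    "neuron": {
                        "C": np_.C,
                        "g_L": np_.g_L,
                        "E_L": np_.E_L,
                        "V_reset": np_.V_reset,
                        "tau_ref": np_.tau_ref,
                        "eta": [kern(k) for k in np_.eta_kernels],
                        "gamma": [kern(k) for k in np_.gamma_kernels],
                        "lambda0": np_.lambda0,
                        "DeltaV": np_.DeltaV,
                        "VT_star": np_.VT_star,
                    },
                    "gamma2_init": list(p.gamma2_init) if p.gamma2_init else None,
                }
            )
        conns = []
        for s in self.specs:
            row = {
                "source": s.source,
                "target": s.target,
                "psc_pA": s.syn.weight_w,
                "cp": s.p,
                "tau_syn_ms": s.syn.tau_syn,
                "delay_ms": s.syn.delay,
            }
            if s.stp is not None:
                row["stp"] = {
                    "U": s.stp.U,
                    "tau_rec": s.stp.tau_rec,
                    "tau_facil": s.stp.tau_facil,
                }
            conns.append(row)
        return {"populations": pops, "connections": conns, "seed": self.seed}

    @classmethod
    def from_config(cls, cfg: dict) -> "NetworkModel":
        pops = []
        for p in cfg["populations"]:
            n = p["neuron"]
            params = GIFParameters(
                C=n["C"],
                g_L=n["g_L"],
                E_L=n["E_L"],
                V_reset=n["V_reset"],
                tau_ref=n["tau_ref"],
                eta_kernels=tuple(AdaptationKernel(*k) for k in n["eta"]),
                gamma_kernels=tuple(AdaptationKernel(*k) for k in n["gamma"]),
                lambda0=n["lambda0"],
                DeltaV=n["DeltaV"],
                VT_star=n["VT_star"],
            )
            g2 = p.get("gamma2_init")
            pops.append(
                PopulationSpec(
                    p["name"], p["size"], p["role"], params,
                    tuple(g2) if g2 else None,
                )
            )
        specs = []
        for c in cfg["connections"]:
            stp = None
            if c.get("stp"):
                stp = STPParameters(**c["stp"])
            specs.append(
                ConnectionSpec(
                    c["source"],
                    c["target"],
                    c["cp"],
                    SynapseParameters(c["psc_pA"], c["delay_ms"], c["tau_syn_ms"]),
                    stp,
                )
            )
        model = cls(populations=pops, specs=specs)
        if cfg.get("seed") is not None:
            model.realize(cfg["seed"])
        return model

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_config(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "NetworkModel":
        with open(path) as fh:
            return cls.from_config(yaml.safe_load(fh))


# --- chain ------------------------------------------------------------------

# Table of intra-group synapses (PSC pA, CP, tau_syn ms); inhibitory weights
# are applied with negative sign at delivery.
_CHAIN_INTRA = {
    ("exc", "exc"): (22.1, 0.50, 7.7),
    ("exc", "inh"): (3.7, 0.10, 9.9),
    ("inh", "exc"): (-3.5, 0.22, 7.7),
    ("inh", "inh"): (-10.2, 0.30, 6.7),
    ("exc", "inh2"): (7.3, 0.30, 9.9),
    ("inh2", "exc"): (-5.0, 0.50, 7.7),
    ("inh2", "inh2"): (-10.2, 0.30, 6.7),
    ("inh", "inh2"): (-20.4, 0.30, 6.7),
}


def build_chain(
    n_groups: int = 11,
    w_exc: float = 6.6,
    w_inh: float = 1.8,
    variant: str = "exc_inh",
    seed: int = 0,
    stp_exc: STPParameters | None = None,
    stp_inh: STPParameters | None = None,
    inh_to_exc_psc: float | None = None,
) -> NetworkModel:
    """Build the bidirectional assembly chain.

    Parameters
    ----------
    w_exc, w_inh
        PSC amplitudes (pA) of the inter-group excitatory->excitatory and
        excitatory->inhibitory synapses (the two speed-control knobs).
    variant
        ``exc_only`` (assemblies only), ``exc_inh`` (one inhibitory
        population per group) or ``exc_inh_inh2`` (adds the second,
        strictly intra-group inhibitory population).
    stp_exc
        Optional facilitation on inter-group exc->exc synapses.
    stp_inh
        Optional depression on inter-group exc->inh synapses; the weight is
        renormalized to w_inh / U so the first PSC amplitude stays w_inh.
    inh_to_exc_psc
        Override for the intra-group inhibitory->excitatory PSC magnitude
        (pA); the depression experiments raise it ~7-fold.
    """
    if variant not in CHAIN_VARIANTS:
        raise ValueError(f"unknown chain variant {variant!r}")
    if n_groups < 2:
        raise ValueError("need at least 2 groups")
    if w_exc < 0 or w_inh < 0:
        raise ValueError("excitatory PSC amplitudes must be non-negative")

    with_inh = variant in ("exc_inh", "exc_inh_inh2")
    with_inh2 = variant == "exc_inh_inh2"

    pops: list[PopulationSpec] = []
    specs: list[ConnectionSpec] = []
    for g in range(1, n_groups + 1):
        pops.append(
            PopulationSpec(f"exc_{g}", ASSEMBLY_SIZE, "assembly", EXCITATORY)
        )
        if with_inh:
            pops.append(
                PopulationSpec(f"inh_{g}", INHIBITORY_SIZE, "inhibitory", INHIBITORY)
            )
        if with_inh2:
            pops.append(
                PopulationSpec(f"inh2_{g}", INHIBITORY_SIZE, "inhibitory2", INHIBITORY2)
            )

    def intra(src_role: str, tgt_role: str, g: int) -> None:
        w, p, tau = _CHAIN_INTRA[(src_role, tgt_role)]
        name = {"exc": f"exc_{g}", "inh": f"inh_{g}", "inh2": f"inh2_{g}"}
        specs.append(
            ConnectionSpec(
                name[src_role], name[tgt_role], p,
                SynapseParameters(w, DELAY_MS, tau),
            )
        )

    for g in range(1, n_groups + 1):
        intra("exc", "exc", g)
        if with_inh:
            intra("exc", "inh", g)
            if inh_to_exc_psc is not None:
                specs.append(
                    ConnectionSpec(
                        f"inh_{g}", f"exc_{g}", _CHAIN_INTRA[("inh", "exc")][1],
                        SynapseParameters(-abs(inh_to_exc_psc), DELAY_MS, 7.7),
                    )
                )
            else:
                intra("inh", "exc", g)
            intra("inh", "inh", g)
        if with_inh2:
            intra("exc", "inh2", g)
            intra("inh2", "exc", g)
            intra("inh2", "inh2", g)
            intra("inh", "inh2", g)

    # inter-group: nearest neighbors, both directions; inhibitory populations
    # make no inter-group contacts
    w_inh_eff = w_inh
    if stp_inh is not None:
        w_inh_eff = w_inh / stp_inh.U  # keep the first PSC at w_inh
    for g in range(1, n_groups):
        for a, b in ((g, g + 1), (g + 1, g)):
            specs.append(
                ConnectionSpec(
                    f"exc_{a}", f"exc_{b}", 0.10,
                    SynapseParameters(w_exc, DELAY_MS, 7.7),
                    stp=stp_exc,
                )
            )
            if with_inh:
                specs.append(
                    ConnectionSpec(
                        f"exc_{a}", f"inh_{b}", 0.30,
                        SynapseParameters(w_inh_eff, DELAY_MS, 9.9),
                        stp=stp_inh,
                    )
                )
    return NetworkModel(populations=pops, specs=specs).realize(seed)


# --- grid -------------------------------------------------------------------

_ROWS = "ABCDE"


@dataclass(frozen=True)
class GridLayout:
    """5x5 barrel lattice: rows A-E (vertical position), arcs 1-5 (horizontal).

    ``p_row`` is the connection probability toward horizontal (same-row)
    neighbors, ``p_arc`` toward vertical (same-arc) neighbors.  Edge columns
    have fewer neighbors; the boundary is absorbing.
    """

    p_row: float = 0.10
    p_arc: float = 0.10
    n_rows: int = 5
    n_arcs: int = 5

    @property
    def columns(self) -> list[str]:
        return [f"{r}{a}" for r in _ROWS[: self.n_rows] for a in range(1, self.n_arcs + 1)]

    def coords(self, key: str) -> tuple[int, int]:
        """(row index, arc index), zero-based."""
        try:
            r = _ROWS.index(key[0])
            a = int(key[1:]) - 1
        except (ValueError, IndexError):
            raise KeyError(f"unknown column {key!r}") from None
        if not (0 <= r < self.n_rows and 0 <= a < self.n_arcs):
            raise KeyError(f"unknown column {key!r}")
        return r, a

    def key(self, r: int, a: int) -> str:
        return f"{_ROWS[r]}{a + 1}"

    def neighbors(self, key: str) -> list[tuple[str, str]]:
        """[(neighbor key, 'row'|'arc'), ...] in the 4-neighborhood."""
        r, a = self.coords(key)
        out = []
        for dr, da, kind in ((-1, 0, "arc"), (1, 0, "arc"), (0, -1, "row"), (0, 1, "row")):
            rr, aa = r + dr, a + da
            if 0 <= rr < self.n_rows and 0 <= aa < self.n_arcs:
                out.append((self.key(rr, aa), kind))
        return out

    @property
    def center(self) -> str:
        return self.key(self.n_rows // 2, self.n_arcs // 2)

    def pops(self, key: str) -> tuple[str, str, str]:
        """(assembly, non-assembly, inhibitory) population names of a column."""
        self.coords(key)
        return f"{key}_assem", f"{key}_non", f"{key}_inh"


# intra-column synapses of the multicolumn model (PSC pA, CP, tau_syn ms)
_GRID_INTRA = {
    ("assem", "assem"): (22.1, 0.50, 7.7),
    ("assem", "non"): (2.2, 0.10, 7.7),
    ("non", "non"): (3.3, 0.15, 7.7),
    ("non", "assem"): (2.2, 0.10, 7.7),
    ("inh", "assem"): (-3.5, 0.22, 7.7),
    ("inh", "non"): (-3.5, 0.22, 7.7),
    ("assem", "inh"): (3.7, 0.10, 9.9),
    ("non", "inh"): (3.7, 0.10, 9.9),
    ("inh", "inh"): (-10.2, 0.30, 6.7),
}


def build_grid(
    p_row: float = 0.10,
    p_arc: float = 0.10,
    w_intercol: float = 7.1,
    seed: int = 0,
) -> tuple[NetworkModel, GridLayout]:
    """Build the 25-column barrel-cortex model.

    Excitatory neurons (assembly and non-assembly alike) project to both
    excitatory groups of the four neighboring columns with PSC amplitude
    ``w_intercol`` (default 7.1 pA = 0.32 mV PSP); inhibitory neurons stay
    strictly intra-column.  Excitatory neurons use the multicolumn fast
    threshold-kernel amplitude (13.05 mV).
    """
    layout = GridLayout(p_row=p_row, p_arc=p_arc)
    exc_params = EXCITATORY.with_gamma1_amplitude(GRID_GAMMA1_AMPLITUDE)

    pops: list[PopulationSpec] = []
    specs: list[ConnectionSpec] = []
    for key in layout.columns:
        assem, non, inh = layout.pops(key)
        pops.append(PopulationSpec(assem, ASSEMBLY_SIZE, "assembly", exc_params))
        pops.append(PopulationSpec(non, NON_ASSEMBLY_SIZE, "non_assembly", exc_params))
        pops.append(PopulationSpec(inh, INHIBITORY_SIZE, "inhibitory", INHIBITORY))

    names = {"assem": 0, "non": 1, "inh": 2}
    for key in layout.columns:
        col = layout.pops(key)
        for (src, tgt), (w, p, tau) in _GRID_INTRA.items():
            specs.append(
                ConnectionSpec(
                    col[names[src]], col[names[tgt]], p,
                    SynapseParameters(w, DELAY_MS, tau),
                )
            )
    for key in layout.columns:
        col = layout.pops(key)
        for nb_key, kind in layout.neighbors(key):
            nb = layout.pops(nb_key)
            p = layout.p_row if kind == "row" else layout.p_arc
            for src in col[:2]:
                for tgt in nb[:2]:
                    specs.append(
                        ConnectionSpec(
                            src, tgt, p, SynapseParameters(w_intercol, DELAY_MS, 7.7)
                        )
                    )
    model = NetworkModel(populations=pops, specs=specs).realize(seed)
    return model, layout


def set_gamma2_pattern(
    model: NetworkModel,
    layout: GridLayout,
    column_means: dict[str, float],
    sigma: float = 3.0,
    seed: int = 0,
) -> NetworkModel:
    """Initialize the slow threshold kernel gamma_2 per column.

    Every neuron of a column draws its initial gamma_2 offset from
    Normal(column mean, sigma), clipped below at zero.  High means make a
    column dormant, low means excitable.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    for key in column_means:
        layout.coords(key)  # raises on unknown keys
    init: dict[str, np.ndarray] = {}
    cols = sorted(column_means)
    for k, key in enumerate(cols):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, 7, k]))
        for pop_name in layout.pops(key):
            size = model.population(pop_name).size_N
            vals = rng.normal(column_means[key], sigma, size=size)
            init[pop_name] = np.clip(vals, 0.0, None)
    model.initial_gamma2 = init
    return model


def shuffle_column_means(
    column_means: dict[str, float], seed: int = 0
) -> dict[str, float]:
    """Uniformly random permutation of the mean values over the 25 columns."""
    keys = sorted(column_means)
    if len(keys) != 25:
        raise ValueError(f"expected 25 column means, got {len(keys)}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, 11]))
    values = [column_means[k] for k in keys]
    perm = rng.permutation(len(values))
    return {k: values[j] for k, j in zip(keys, perm)}


def network_feedback_coefficient(pop: PopulationSpec, conn: ConnectionSpec) -> float:
    """C_fb = N * p * q * w in pA*ms, with q = tau_syn (unit-PSC charge).

    The slope of the population's rate-current line is 1/C_fb: a recurrent
    population firing at rate r receives mean current C_fb * r.
    """
    if conn.source != pop.name or conn.target != pop.name:
        raise ValueError("conn must be the recurrent spec of pop")
    return pop.size_N * conn.p * conn.syn.tau_syn * conn.syn.weight_w


def remove_column(
    model: NetworkModel, layout: GridLayout, column_key: str
) -> NetworkModel:
    """Drop all neurons and incident edges of one grid column."""
    doomed = set(layout.pops(column_key))
    pops = [p for p in model.populations if p.name not in doomed]
    if len(pops) == len(model.populations):
        raise KeyError(f"column {column_key!r} has no populations in the model")
    keep = [
        (s, r)
        for s, r in zip(model.specs, model.realized)
        if s.source not in doomed and s.target not in doomed
    ]
    out = NetworkModel(
        populations=pops,
        specs=[s for s, _ in keep],
        realized=[r for _, r in keep],
        seed=model.seed,
        initial_gamma2={
            k: v for k, v in model.initial_gamma2.items() if k not in doomed
        },
    )
    return out
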