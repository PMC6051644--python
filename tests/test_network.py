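"""Chain/grid construction: realized graphs, initial values, bookkeeping."""

import math

import numpy as np
import pytest

from excinet.network import (
    CHAIN_VARIANTS,
    ConnectionSpec,
    GridLayout,
    NetworkModel,
    PopulationSpec,
    build_chain,
    build_grid,
    network_feedback_coefficient,
    remove_column,
    set_gamma2_pattern,
    shuffle_column_means,
)
from excinet.neuron import EXCITATORY
from excinet.synapse import SynapseParameters


class TestBuildChain:
    def test_exc_only_population_structure(self):
        m = build_chain(n_groups=11, variant="exc_only", seed=0)
        assert len(m.populations) == 11
        assert all(p.size_N == 70 and p.role == "assembly" for p in m.populations)
        assert all(s.syn.weight_w > 0 for s in m.specs)

    def test_intra_assembly_edge_count_binomial(self):
        m = build_chain(n_groups=3, variant="exc_only", seed=1)
        rc = next(r for r in m.realized if r.spec.source == r.spec.target == "exc_1")
        expected = 70 * 69 * 0.5
        sd = math.sqrt(70 * 69 * 0.5 * 0.5)
        assert abs(rc.n_edges - expected) < 4 * sd
        # no autapses
        assert not np.any(rc.pre_local == rc.post_local)

    def test_same_seed_identical_edges(self):
        a = build_chain(n_groups=3, variant="exc_inh", seed=7)
        b = build_chain(n_groups=3, variant="exc_inh", seed=7)
        for ra, rb in zip(a.realized, b.realized):
            assert np.array_equal(ra.pre_local, rb.pre_local)
            assert np.array_equal(ra.post_local, rb.post_local)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            build_chain(variant="bogus")
        with pytest.raises(ValueError):
            build_chain(n_groups=1)
        with pytest.raises(ValueError):
            build_chain(w_exc=-1.0)

    @pytest.mark.parametrize("variant", CHAIN_VARIANTS)
    def test_connection_block_completeness(self, variant):
        """One spec per printed connection row, per group / neighbor pair."""
        n = 4
        m = build_chain(n_groups=n, variant=variant, seed=0)
        kinds = {}
        for s in m.specs:
            src = s.source.rsplit("_", 1)[0]
            tgt = s.target.rsplit("_", 1)[0]
            scope = "intra" if s.source.split("_")[-1] == s.target.split("_")[-1] else "inter"
            kinds[(scope, src, tgt)] = kinds.get((scope, src, tgt), 0) + 1
        assert kinds[("intra", "exc", "exc")] == n
        assert kinds[("inter", "exc", "exc")] == 2 * (n - 1)
        if variant == "exc_only":
            assert len(kinds) == 2
        if variant in ("exc_inh", "exc_inh_inh2"):
            assert kinds[("intra", "exc", "inh")] == n
            assert kinds[("intra", "inh", "exc")] == n
            assert kinds[("intra", "inh", "inh")] == n
            assert kinds[("inter", "exc", "inh")] == 2 * (n - 1)
            # inhibitory populations never project between groups
            assert ("inter", "inh", "exc") not in kinds
        if variant == "exc_inh_inh2":
            for pair in [("exc", "inh2"), ("inh2", "exc"), ("inh2", "inh2"), ("inh", "inh2")]:
                assert kinds[("intra",) + pair] == n

    def test_directionality_independent_realizations(self):
        """Forward and backward inter-assembly draws are independent."""
        m = build_chain(n_groups=2, variant="exc_only", seed=3)
        fwd = next(r for r in m.realized if r.spec.source == "exc_1" and r.spec.target == "exc_2")
        bwd = next(r for r in m.realized if r.spec.source == "exc_2" and r.spec.target == "exc_1")
        f = set(zip(fwd.pre_local, fwd.post_local))
        b = set(zip(bwd.post_local, bwd.pre_local))  # reversed orientation
        # overlap should be near p^2, nowhere near identity
        assert len(f & b) < 0.5 * len(f)


class TestBuildGrid:
    @pytest.fixture(scope="class")
    def grid(self):
        return build_grid(seed=2)

    def test_total_neuron_count(self, grid):
        model, _ = grid
        assert model.n_neurons == 25 * (70 + 380 + 70) == 13_000

    def test_neighbor_counts(self, grid):
        _, layout = grid
        assert len(layout.neighbors("A1")) == 2  # corner
        assert len(layout.neighbors("C3")) == 4  # center
        assert len(layout.neighbors("A3")) == 3  # edge
        # symmetry of the neighbor relation
        for key in layout.columns:
            for nb, _ in layout.neighbors(key):
                assert key in [k for k, _ in layout.neighbors(nb)]

    def test_inhibitory_strictly_intra_column(self, grid):
        model, _ = grid
        for s in model.specs:
            if "inh" in s.source:
                assert s.source.split("_")[0] == s.target.split("_")[0]

    def test_anisotropic_probabilities(self):
        model, layout = build_grid(p_row=0.15, p_arc=0.10, seed=0)
        row_spec = next(
            s for s in model.specs
            if s.source == "C3_assem" and s.target == "C4_assem"
        )
        arc_spec = next(
            s for s in model.specs
            if s.source == "C3_assem" and s.target == "D3_assem"
        )
        assert row_spec.p == 0.15 and arc_spec.p == 0.10

    def test_grid_uses_multicolumn_gamma1(self, grid):
        model, _ = grid
        assem = model.population("C3_assem")
        assert assem.neuron_params.gamma_kernels[0].amplitude == 13.05
        inh = model.population("C3_inh")
        assert inh.neuron_params.gamma_kernels[0].amplitude == -7.3

    def test_intercolumn_edge_count_binomial(self, grid):
        model, _ = grid
        rc = next(
            r for r in model.realized
            if r.spec.source == "C3_non" and r.spec.target == "C4_non"
        )
        n, p = 380 * 380, 0.10
        assert abs(rc.n_edges - n * p) < 4 * math.sqrt(n * p * (1 - p))


class TestGamma2Pattern:
    def test_constant_when_sigma_zero(self):
        model, layout = build_grid(seed=0)
        set_gamma2_pattern(model, layout, {"B2": 10.0}, sigma=0.0, seed=1)
        assert np.all(model.initial_gamma2["B2_assem"] == 10.0)
        assert set(model.initial_gamma2) == {"B2_assem", "B2_non", "B2_inh"}

    def test_clipped_normal_mean(self):
        """E[max(0, N(0, 3))] = 3/sqrt(2*pi) ~ 1.197 mV."""
        model, layout = build_grid(seed=0)
        set_gamma2_pattern(model, layout, {k: 0.0 for k in layout.columns}, 3.0, 4)
        vals = np.concatenate(list(model.initial_gamma2.values()))
        assert np.all(vals >= 0)
        expected = 3.0 / math.sqrt(2 * math.pi)
        assert vals.mean() == pytest.approx(expected, abs=4 * vals.std() / math.sqrt(len(vals)))

    def test_deterministic_per_seed(self):
        model, layout = build_grid(seed=0)
        set_gamma2_pattern(model, layout, {"A1": 5.0}, 3.0, seed=9)
        first = model.initial_gamma2["A1_assem"].copy()
        set_gamma2_pattern(model, layout, {"A1": 5.0}, 3.0, seed=9)
        assert np.array_equal(model.initial_gamma2["A1_assem"], first)

    def test_unknown_column_rejected(self):
        model, layout = build_grid(seed=0)
        with pytest.raises(KeyError):
            set_gamma2_pattern(model, layout, {"Z9": 1.0}, 3.0, 0)


class TestShuffle:
    def test_multiset_preserved_and_identity_on_equal_means(self):
        layout = GridLayout()
        means = {k: float(i % 5) for i, k in enumerate(layout.columns)}
        out = shuffle_column_means(means, seed=3)
        assert sorted(out.values()) == sorted(means.values())
        same = {k: 1.5 for k in layout.columns}
        assert shuffle_column_means(same, seed=3) == same

    def test_wrong_count_rejected(self):
        with pytest.raises(ValueError):
            shuffle_column_means({"A1": 0.0}, seed=0)

    def test_distinct_permutations_across_seeds(self):
        layout = GridLayout()
        means = {k: float(i) for i, k in enumerate(layout.columns)}
        perms = {tuple(shuffle_column_means(means, seed=s).values()) for s in range(200)}
        assert len(perms) >= 199  # collisions over 25! arrangements are freak events


class TestFeedbackCoefficient:
    def test_assembly_value(self):
        pop = PopulationSpec("a", 70, "assembly", EXCITATORY)
        conn = ConnectionSpec("a", "a", 0.5, SynapseParameters(22.1, 1.0, 7.7))
        assert network_feedback_coefficient(pop, conn) == pytest.approx(5955.95)

    def test_zero_probability_and_linearity(self):
        pop = PopulationSpec("a", 70, "assembly", EXCITATORY)
        z = ConnectionSpec("a", "a", 0.0, SynapseParameters(22.1, 1.0, 7.7))
        assert network_feedback_coefficient(pop, z) == 0.0
        c1 = ConnectionSpec("a", "a", 0.5, SynapseParameters(10.0, 1.0, 7.7))
        c2 = ConnectionSpec("a", "a", 0.5, SynapseParameters(20.0, 1.0, 7.7))
        assert network_feedback_coefficient(pop, c2) == 2 * network_feedback_coefficient(pop, c1)

    def test_requires_recurrent_spec(self):
        pop = PopulationSpec("a", 70, "assembly", EXCITATORY)
        other = ConnectionSpec("a", "b", 0.5, SynapseParameters(22.1, 1.0, 7.7))
        with pytest.raises(ValueError):
            network_feedback_coefficient(pop, other)


class TestRemoveColumn:
    def test_counts_after_removal(self):
        model, layout = build_grid(seed=1)
        out = remove_column(model, layout, "C3")
        assert out.n_neurons == 13_000 - 520 == 12_480
        assert all("C3" not in s.source and "C3" not in s.target for s in out.specs)

    def test_corner_removal_keeps_neighbor_graph_connected(self):
        model, layout = build_grid(seed=1)
        out = remove_column(model, layout, "A1")
        remaining = {k for k in layout.columns if k != "A1"}
        seen = {"C3"}
        frontier = ["C3"]
        while frontier:
            k = frontier.pop()
            for nb, _ in layout.neighbors(k):
                if nb in remaining and nb not in seen:
                    seen.add(nb)
                    frontier.append(nb)
        assert seen == remaining
        assert out.n_neurons == 12_480

    def test_unknown_column_rejected(self):
        model, layout = build_grid(seed=1)
        with pytest.raises(KeyError):
            remove_column(model, layout, "Q7")


class TestConfigRoundTrip:
    def test_yaml_round_trip_reproduces_edges(self, tmp_path):
        m = build_chain(n_groups=3, variant="exc_inh", seed=42)
        path = tmp_path / "net.yaml"
        m.to_yaml(path)
        m2 = NetworkModel.from_yaml(path)
        assert m2.population_names == m.population_names
        assert len(m2.specs) == len(m.specs)
        for ra, rb in zip(m.realized, m2.realized):
            assert np.array_equal(ra.pre_local, rb.pre_local)
            assert np.array_equal(ra.post_local, rb.post_local)
            assert ra.spec.syn == rb.spec.syn

    def test_edges_dataframe_schema(self):
        m = build_chain(n_groups=2, variant="exc_only", seed=0)
        df = m.edges_dataframe()
        assert list(df.columns) == ["pre_id", "post_id", "weight_pA", "delay_ms", "tau_syn_ms"]
        assert df.pre_id.max() < m.n_neurons
        assert (df.delay_ms == 1.0).all()
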