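"""Experiment drivers: sweeps, robustness properties, synthetic rasters.

The simulation-based properties here run on short (6-group) chains with a
few trials per condition; conditions are compared through their mean
per-step delays with standard-error slack.
"""

import numpy as np
import pytest

from excinet.engine import StimulusSpec, run
from excinet.metrics import propagation_profile
from excinet.network import GridLayout
from excinet.workbench import (
    FixtureEvent,
    SweepSpec,
    carved_path_means,
    chain_model,
    chain_trials,
    make_fixture_raster,
    run_sweep,
)

N_GROUPS = 6
ORDER = [f"exc_{g}" for g in range(1, N_GROUPS + 1)]


def mean_delay(variant="exc_only", trials=3, seed=3, **kw):
    m = chain_model(variant=variant, n_groups=N_GROUPS, seed=1, **kw)
    df = chain_trials(m, trials, seed)
    d = df.mean_step_delay_ms.dropna()
    return d.mean(), d.sem() if len(d) > 1 else np.nan, df


class TestSweepContract:
    def test_single_point_sweep_reproducible(self):
        spec = SweepSpec(axes=[("w_exc_psp", [0.35])], trials=3, master_seed=5)
        a = run_sweep(spec, variant="exc_only", n_groups=N_GROUPS)
        b = run_sweep(spec, variant="exc_only", n_groups=N_GROUPS)
        assert a.equals(b)
        assert a.failure_fraction.iloc[0] == 0.0

    def test_unknown_axis_rejected(self):
        spec = SweepSpec(axes=[("bogus", [1.0])], trials=1, master_seed=0)
        with pytest.raises(ValueError):
            run_sweep(spec)
        with pytest.raises(ValueError):
            SweepSpec(axes=[], trials=1)

    def test_delay_decreases_with_w_exc(self):
        """Stronger inter-assembly excitation speeds the wave (monotone trend)."""
        spec = SweepSpec(axes=[("w_exc_psp", [0.30, 0.40, 0.55])], trials=3, master_seed=7)
        tab = run_sweep(spec, variant="exc_only", n_groups=N_GROUPS)
        d = tab.mean_step_delay_ms.to_numpy()
        s = tab.sd_step_delay_ms.to_numpy()
        assert d[1] <= d[0] + 2 * np.nanmax(s)
        assert d[2] <= d[1] + 2 * np.nanmax(s)
        assert d[2] < d[0]

    def test_very_weak_coupling_never_propagates(self):
        """Far below the boundary, every ignited trial fails end-to-end."""
        m = chain_model(variant="exc_only", n_groups=N_GROUPS, w_exc_psp=0.12, seed=1)
        df = chain_trials(m, 3, 9)
        assert df.ignited.any()
        assert not df.propagated.any()

    def test_delay_increases_with_w_inh(self):
        """Stronger drive onto inhibitory partners slows the wave."""
        spec = SweepSpec(axes=[("w_inh_psp", [0.2, 0.6, 1.0])], trials=3, master_seed=7)
        tab = run_sweep(
            spec, variant="exc_inh", n_groups=N_GROUPS, base={"w_exc_psp": 0.45}
        )
        d = tab.mean_step_delay_ms.to_numpy()
        s = np.nan_to_num(tab.sd_step_delay_ms.to_numpy(), nan=1.0)
        assert d[1] >= d[0] - 2 * s.max()
        assert d[2] >= d[1] - 2 * s.max()
        assert d[2] > d[0]


class TestSTPTrends:
    def test_facilitation_lower_U_slows_propagation(self):
        """With facilitating inter-assembly synapses, small U means weak
        early PSCs, so the wave slows; it fails outright for very low U."""
        delays = {}
        for U in (1.0, 0.5, 0.3):
            d, _, _ = mean_delay(variant="exc_inh", stp_mode="facilitation", U=U)
            delays[U] = d
        assert delays[0.5] > delays[1.0]
        assert delays[0.3] > delays[0.5]

    def test_depression_higher_U_speeds_propagation(self):
        """Depressing excitatory->inhibitory synapses (first PSC pinned):
        high U depletes the drive onto inhibition, so the wave speeds up."""
        delays = {}
        for U in (0.5, 1.0):
            d, _, _ = mean_delay(
                variant="exc_inh", stp_mode="depression", U=U, w_inh_psp=0.8
            )
            delays[U] = d
        assert delays[1.0] < delays[0.5]

    def test_u_equals_one_facilitation_matches_static(self):
        """U = 1 facilitation is the no-STP chain (same delays, same seeds)."""
        d_static, _, _ = mean_delay(variant="exc_only", w_exc_psp=0.35)
        d_stp, _, _ = mean_delay(
            variant="exc_only", w_exc_psp=0.35, stp_mode="facilitation", U=1.0
        )
        assert d_stp == pytest.approx(d_static, abs=1.0)


class TestSymmetryAndRobustness:
    def test_forward_backward_symmetry(self):
        """The bidirectional chain propagates equally fast either way."""
        m = chain_model(variant="exc_only", n_groups=N_GROUPS, w_exc_psp=0.35, seed=1)
        fwd, bwd = [], []
        for s in range(4):
            for stim, store in (("exc_1", fwd), (f"exc_{N_GROUPS}", bwd)):
                for attempt in range(8):
                    res = run(m, [StimulusSpec(target=stim)], T=700.0, dt=0.1,
                              seed=1000 + 17 * s + attempt + (0 if stim == "exc_1" else 101))
                    prof = propagation_profile(res.spikes, ORDER)
                    if not prof.failed:
                        store.append(abs(np.mean(prof.step_delays)))
                        break
        fwd, bwd = np.array(fwd), np.array(bwd)
        sem = np.sqrt(fwd.var(ddof=1) / len(fwd) + bwd.var(ddof=1) / len(bwd))
        assert abs(fwd.mean() - bwd.mean()) < 2 * sem + 1.0

    def test_stimulus_parameters_do_not_change_speed(self):
        """Interior per-step delay is insensitive to stimulus size/weight."""
        m = chain_model(variant="exc_only", n_groups=N_GROUPS, w_exc_psp=0.35, seed=1)
        means = []
        for n_poisson, weight in ((25, 180.0), (50, 180.0), (25, 360.0)):
            vals = []
            for s in range(3):
                for attempt in range(8):
                    res = run(
                        m,
                        [StimulusSpec(target="exc_1", n_poisson=n_poisson, weight=weight)],
                        T=700.0, dt=0.1, seed=500 + 13 * s + attempt,
                    )
                    prof = propagation_profile(res.spikes, ORDER)
                    if not prof.failed:
                        vals.append(np.mean(prof.step_delays[1:]))  # interior steps
                        break
            means.append(np.mean(vals))
        spread = max(means) - min(means)
        assert spread < 2.5  # a couple of SEM of the per-trial delay estimate

    def test_stp_time_constants_do_not_change_speed(self):
        """tau_facil (facilitation) is a non-knob for the propagation speed."""
        base, _, _ = mean_delay(
            variant="exc_inh", stp_mode="facilitation", U=0.5, tau_facil=500.0
        )
        alt, sem, _ = mean_delay(
            variant="exc_inh", stp_mode="facilitation", U=0.5, tau_facil=250.0
        )
        assert abs(base - alt) < 3.0

    def test_dt_halving_stability(self):
        """Halving dt to 0.05 ms leaves the mean per-step delay within ~1 ms."""
        m = chain_model(variant="exc_only", n_groups=N_GROUPS, w_exc_psp=0.35, seed=1)
        means = {}
        for dt in (0.1, 0.05):
            vals = []
            for s in range(4):
                for attempt in range(8):
                    res = run(m, [StimulusSpec(target="exc_1")], T=650.0, dt=dt,
                              seed=300 + 11 * s + attempt)
                    prof = propagation_profile(res.spikes, ORDER)
                    if not prof.failed:
                        vals.append(np.mean(prof.step_delays))
                        break
            means[dt] = np.mean(vals)
        assert abs(means[0.1] - means[0.05]) < 1.5


class TestCarvedPath:
    def test_pattern_structure(self):
        layout = GridLayout()
        means = carved_path_means(layout)
        assert set(means) == set(layout.columns)
        assert means["A1"] == 0.0  # stimulated corner is excitable
        assert means[layout.center] == max(means.values())
        n_excitable = sum(1 for v in means.values() if v == 0.0)
        assert n_excitable == 10


class TestFixtureRaster:
    def test_schedule_realized_exactly(self):
        sizes = {f"exc_{g}": 70 for g in range(1, 12)}
        schedule = [
            FixtureEvent(f"exc_{g}", t=float(20 * (g - 1)) + 10.0) for g in range(1, 12)
        ]
        raster = make_fixture_raster(schedule, sizes)
        prof = propagation_profile(raster.spikes, [f"exc_{g}" for g in range(1, 12)])
        assert np.allclose(prof.step_delays, 20.0)
        assert prof.total_delay == pytest.approx(200.0)

    def test_reactivation_schedule_classifies_as_circulation(self):
        from excinet.metrics import classify_grid_trial

        layout = GridLayout()
        sizes = {}
        for key in layout.columns:
            a, n, i = layout.pops(key)
            sizes.update({a: 70, n: 380, i: 70})
        schedule = [
            FixtureEvent(layout.pops(key)[0], 120.0 + 8.0 * k)
            for k, key in enumerate(layout.columns)
        ]
        schedule.append(FixtureEvent(layout.pops("A1")[0], 700.0))
        raster = make_fixture_raster(schedule, sizes, T=1200.0)
        assert classify_grid_trial(raster.spikes, layout).category == "circulation"
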