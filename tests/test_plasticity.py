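"""Neurogenesis reshuffling and suppression-model STDP."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import olfdrift as od
from olfdrift._exceptions import ConfigError
from olfdrift.network import GC_BLOCKS, scaled_rules
from olfdrift.plasticity import (
    AbGCRegistry, NeurogenesisSchedule, STDPConfig, STDPUpdater,
    draw_synapse_params, _get_stdp_kernel, select_cohorts, spike_efficacy,
    stdp_pair_sum, stdp_window,
)
from olfdrift.simulator import SpikeRaster


class TestCohorts:
    def test_cohort_sizes_disjoint_union(self):
        sched = NeurogenesisSchedule(fraction_per_day=0.1, n_days=11)
        cohorts = select_cohorts(1000, sched, np.random.default_rng(0))
        assert len(cohorts) == 10
        assert all(len(c) == 100 for c in cohorts)
        allgc = np.concatenate(cohorts)
        assert len(np.unique(allgc)) == 1000         # disjoint and exhaustive

    def test_with_replacement_can_repeat(self):
        sched = NeurogenesisSchedule(fraction_per_day=0.3, n_days=11,
                                     cohort_policy="with_replacement")
        cohorts = select_cohorts(100, sched, np.random.default_rng(1))
        union = np.unique(np.concatenate(cohorts))
        assert len(union) < 100 * 3   # overlap must occur

    def test_infeasible_fraction_rejected(self):
        sched = NeurogenesisSchedule(fraction_per_day=0.2, n_days=11)
        with pytest.raises(ConfigError):
            select_cohorts(100, sched, np.random.default_rng(0))

    def test_bad_policy_rejected(self):
        with pytest.raises(ConfigError):
            NeurogenesisSchedule(cohort_policy="sometimes")


class TestEfficacy:
    def test_isolated_spike_full_efficacy(self):
        assert spike_efficacy(np.array([42.0]), 34.0)[0] == 1.0

    def test_interval_equal_tau_s(self):
        eps = spike_efficacy(np.array([0.0, 34.0]), 34.0)
        assert eps[1] == pytest.approx(1 - np.exp(-1), abs=1e-12)

    def test_vanishing_interval_suppresses(self):
        eps = spike_efficacy(np.array([10.0, 10.0 + 1e-9]), 34.0)
        assert eps[1] == pytest.approx(0.0, abs=1e-9)

    def test_unsorted_rejected(self):
        with pytest.raises(ConfigError):
            spike_efficacy(np.array([5.0, 1.0]), 34.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 250), min_size=1, max_size=40))
    def test_bounds_hold_for_any_train(self, times):
        eps = spike_efficacy(np.sort(np.array(times)), 34.0)
        assert np.all(eps >= 0.0) and np.all(eps <= 1.0)


class TestWindow:
    def test_potentiation_at_tau_plus(self):
        val = stdp_window(13.3, 1.03, -0.51, 13.3, 34.5)
        assert val == pytest.approx(1.03 * np.exp(-1), abs=1e-12)

    def test_depression_at_tau_minus(self):
        val = stdp_window(-34.5, 1.03, -0.51, 13.3, 34.5)
        assert val == pytest.approx(-0.51 * np.exp(-1), abs=1e-12)

    def test_zero_lag_is_zero(self):
        assert stdp_window(0.0, 1.03, -0.51, 13.3, 34.5) == 0.0

    def test_sign_structure(self):
        dts = np.linspace(-100, 100, 201)
        F = stdp_window(dts, 1.03, -0.51, 13.3, 34.5)
        assert np.all(F[dts > 0] > 0) and np.all(F[dts < 0] < 0)

    def test_single_pair_sum_hand_value(self):
        # isolated pre at 10 ms, post at 20 ms: 1.03 * exp(-10/13.3)
        val = stdp_pair_sum(np.array([10.0]), np.array([20.0]),
                            1.03, -0.51, 13.3, 34.5)
        assert val == pytest.approx(1.03 * np.exp(-10 / 13.3), abs=1e-9)

    def test_empty_trains_zero(self):
        assert stdp_pair_sum(np.array([]), np.array([10.0]), 1.0, -0.5, 13.0, 34.0) == 0.0

    def test_param_draws_clipped(self):
        p = draw_synapse_params(5000, np.random.default_rng(0), STDPConfig())
        assert p["A_plus"].min() > 0 and p["A_minus"].max() < 0
        assert p["tau_plus"].min() > 0 and p["tau_minus"].min() > 0


# ---------------------------------------------------------------------------

def _raster_from(spec, spikes):
    """spikes: list of (pop, local_cell, time_ms)."""
    counts = [spec.n_mt, spec.n_gc, spec.n_pc, spec.n_ffi, spec.n_fbi]
    offs = np.concatenate([[0], np.cumsum(counts)])
    pops = ("mt", "gc", "pc", "ffi", "fbi")
    slices = {p: slice(int(offs[i]), int(offs[i + 1])) for i, p in enumerate(pops)}
    cells, times = [], []
    for pop, cell, t in spikes:
        cells.append(slices[pop].start + cell)
        times.append(t)
    order = np.argsort(times, kind="stable")
    return SpikeRaster(cells=np.array(cells)[order], times_ms=np.array(times, dtype=float)[order],
                       n_cells=int(offs[-1]), pop_slices=slices, trial_ms=250.0)


class TestReshuffle:
    @pytest.fixture()
    def net(self, mini_rules):
        return od.build_network(od.MINI_SPEC, mini_rules, rng=42)

    def test_untouched_synapses_bit_identical(self, net, mini_rules):
        before = {n: net.blocks[n].copy() for n in GC_BLOCKS}
        cohort = np.arange(0, 100)
        reg = AbGCRegistry.fresh(od.MINI_SPEC.n_gc)
        od.reshuffle_granule_cells(net, cohort, np.random.default_rng(1), reg,
                                   day=1, rules=mini_rules)
        assert reg.n_abgc == 100
        assert np.array_equal(np.flatnonzero(reg.abgc_mask), cohort)
        in_cohort = np.zeros(od.MINI_SPEC.n_gc, bool)
        in_cohort[cohort] = True
        for name in GC_BLOCKS:
            a, b = before[name].tocoo(), net.blocks[name].tocoo()
            if name == "gc2mc":
                keep_a = ~in_cohort[a.col]
                keep_b = ~in_cohort[b.col]
            elif name == "gc2gc":
                keep_a = ~in_cohort[a.row] & ~in_cohort[a.col]
                keep_b = ~in_cohort[b.row] & ~in_cohort[b.col]
            else:
                keep_a = ~in_cohort[a.row]
                keep_b = ~in_cohort[b.row]
            ka = sorted(zip(a.row[keep_a], a.col[keep_a], a.data[keep_a]))
            kb = sorted(zip(b.row[keep_b], b.col[keep_b], b.data[keep_b]))
            assert ka == kb, name
        # static blocks untouched entirely
        assert (net.blocks["mc2pc"] != od.build_network(
            od.MINI_SPEC, mini_rules, rng=42).blocks["mc2pc"]).nnz == 0

    def test_delays_redrawn_with_pattern(self, net, mini_rules):
        reg = AbGCRegistry.fresh(od.MINI_SPEC.n_gc)
        od.reshuffle_granule_cells(net, np.arange(50), np.random.default_rng(2),
                                   reg, day=1, rules=mini_rules)
        w, d = net.blocks["mc2gc"], net.delays_mt_gc
        assert d.nnz == w.nnz
        assert np.array_equal(d.indices, w.indices)
        assert d.data.min() >= 0 and d.data.max() <= 25.0

    def test_weight_distribution_preserved(self, net, mini_rules):
        before = np.concatenate([net.blocks[n].data for n in GC_BLOCKS])
        reg = AbGCRegistry.fresh(od.MINI_SPEC.n_gc)
        rng = np.random.default_rng(3)
        for day in range(1, 11):
            od.reshuffle_granule_cells(net, np.arange((day - 1) * 100, day * 100),
                                       rng, reg, day=day, rules=mini_rules)
        after = np.concatenate([net.blocks[n].data for n in GC_BLOCKS])
        ks = sps.ks_2samp(before, after).statistic
        assert ks < 0.02

    def test_full_reshuffle_approaches_independent_redraw(self, mini_rules):
        net = od.build_network(od.MINI_SPEC, mini_rules, rng=10)
        day0 = net.copy()
        reg = AbGCRegistry.fresh(od.MINI_SPEC.n_gc)
        rng = np.random.default_rng(4)
        od.reshuffle_granule_cells(net, np.arange(od.MINI_SPEC.n_gc), rng, reg,
                                   day=1, rules=mini_rules)
        d_reshuffled = od.weight_dissimilarity(day0, net)
        ind = od.weight_dissimilarity(
            od.build_network(od.MINI_SPEC, mini_rules, rng=11),
            od.build_network(od.MINI_SPEC, mini_rules, rng=12))
        assert d_reshuffled == pytest.approx(ind, abs=0.1)

    def test_stdp_params_follow_synapses(self, net, mini_rules):
        reg = AbGCRegistry.fresh(od.MINI_SPEC.n_gc)
        upd = STDPUpdater(net, reg, np.random.default_rng(5), rules=mini_rules)
        block = net.blocks["gc2mc"].tocoo()
        keep = block.col >= 100         # synapses from non-cohort GCs
        before = {(r, c): ap for r, c, ap in zip(
            block.row[keep], block.col[keep],
            upd.store.params["gc2mc"]["A_plus"][keep])}
        od.reshuffle_granule_cells(net, np.arange(100), np.random.default_rng(6),
                                   reg, day=1, stdp_store=upd.store, rules=mini_rules)
        after_coo = net.blocks["gc2mc"].tocoo()
        ap = upd.store.params["gc2mc"]["A_plus"]
        assert len(ap) == net.blocks["gc2mc"].nnz
        for i in range(after_coo.nnz):
            key = (after_coo.row[i], after_coo.col[i])
            if key in before:
                assert ap[i] == before[key]


class TestSTDPUpdater:
    @pytest.fixture()
    def setup(self, mini_rules):
        net = od.build_network(od.MINI_SPEC, mini_rules, rng=8)
        reg = AbGCRegistry.fresh(od.MINI_SPEC.n_gc)
        reg.mark(np.arange(0, 300), day=1)
        upd = STDPUpdater(net, reg, np.random.default_rng(9), rules=mini_rules)
        return net, reg, upd

    def test_no_spikes_no_change(self, setup):
        net, reg, upd = setup
        before = {n: net.blocks[n].data.copy() for n in GC_BLOCKS}
        changed = upd.apply_from_raster(_raster_from(od.MINI_SPEC, []))
        assert changed == {}
        for n in GC_BLOCKS:
            assert np.array_equal(net.blocks[n].data, before[n])

    def test_no_abgc_no_change(self, mini_rules):
        net = od.build_network(od.MINI_SPEC, mini_rules, rng=8)
        reg = AbGCRegistry.fresh(od.MINI_SPEC.n_gc)
        upd = STDPUpdater(net, reg, np.random.default_rng(9), rules=mini_rules)
        raster = _raster_from(od.MINI_SPEC, [("mt", 0, 10.0), ("gc", 0, 20.0)])
        assert upd.apply_from_raster(raster) == {}

    def test_only_masked_synapses_change(self, setup):
        net, reg, upd = setup
        before = {n: net.blocks[n].data.copy() for n in GC_BLOCKS}
        spikes = [("mt", m, 10.0 + m) for m in range(30)]
        spikes += [("gc", g, 25.0 + (g % 40)) for g in range(0, 600, 3)]
        spikes += [("pc", p, 15.0 + (p % 60)) for p in range(0, 300, 2)]
        changed = upd.apply_from_raster(_raster_from(od.MINI_SPEC, spikes))
        assert changed      # something was updated
        abgc = reg.abgc_mask
        for name, pos in changed.items():
            coo = net.blocks[name].tocoo()
            rows, cols = coo.row[pos], coo.col[pos]
            if name in ("mc2gc", "pc2gc"):
                assert np.all(abgc[rows])
            elif name == "gc2mc":
                assert np.all(abgc[cols])
            else:  # gc2gc: at least one endpoint is adult-born
                assert np.all(abgc[rows] | abgc[cols])
            unchanged = np.ones(net.blocks[name].nnz, bool)
            unchanged[pos] = False
            assert np.array_equal(net.blocks[name].data[unchanged],
                                  before[name][unchanged])

    def test_signs_preserved_under_extreme_learning_rate(self, mini_rules):
        net = od.build_network(od.MINI_SPEC, mini_rules, rng=8)
        reg = AbGCRegistry.fresh(od.MINI_SPEC.n_gc)
        reg.mark(np.arange(od.MINI_SPEC.n_gc), day=1)
        upd = STDPUpdater(net, reg, np.random.default_rng(9),
                          STDPConfig(lr_scale=50.0), rules=mini_rules)
        rng = np.random.default_rng(10)
        spikes = [("mt", int(m), float(t)) for m, t in zip(
            rng.integers(0, 100, 200), rng.uniform(0, 250, 200))]
        spikes += [("gc", int(g), float(t)) for g, t in zip(
            rng.integers(0, 1000, 800), rng.uniform(0, 250, 800))]
        spikes += [("pc", int(p), float(t)) for p, t in zip(
            rng.integers(0, 800, 400), rng.uniform(0, 250, 400))]
        upd.apply_from_raster(_raster_from(od.MINI_SPEC, spikes))
        for name in ("mc2gc", "pc2gc"):
            assert net.blocks[name].data.min() >= 0
            assert net.blocks[name].data.max() <= upd.cap[name] + 1e-12
        for name in ("gc2mc", "gc2gc"):
            assert net.blocks[name].data.max() <= 0
            assert net.blocks[name].data.min() >= -upd.cap[name] - 1e-12

    def test_kernel_matches_pure_numpy_fallback(self, mini_rules, monkeypatch):
        import olfdrift.plasticity as pl
        rng = np.random.default_rng(10)
        spikes = [("mt", int(m), float(t)) for m, t in zip(
            rng.integers(0, 100, 60), rng.uniform(0, 250, 60))]
        spikes += [("gc", int(g), float(t)) for g, t in zip(
            rng.integers(0, 1000, 300), rng.uniform(0, 250, 300))]
        spikes += [("pc", int(p), float(t)) for p, t in zip(
            rng.integers(0, 800, 150), rng.uniform(0, 250, 150))]
        raster = _raster_from(od.MINI_SPEC, spikes)

        results = []
        for use_kernel in (True, False):
            net = od.build_network(od.MINI_SPEC, mini_rules, rng=8)
            reg = AbGCRegistry.fresh(od.MINI_SPEC.n_gc)
            reg.mark(np.arange(0, 300), day=1)
            upd = STDPUpdater(net, reg, np.random.default_rng(9), rules=mini_rules)
            if not use_kernel:
                monkeypatch.setattr(pl, "_get_stdp_kernel", lambda: None)
            upd.apply_from_raster(raster)
            monkeypatch.undo()
            results.append({n: net.blocks[n].data.copy() for n in GC_BLOCKS})
        for n in GC_BLOCKS:
            np.testing.assert_allclose(results[0][n], results[1][n], atol=1e-5)
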