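"""Clamp-signal protocols, OU noise, classification, and screen statistics."""

import numpy as np
import pytest

import grnclamp as gc
from grnclamp.racipe_ensemble import RacipeParams
from grnclamp.topology import Topology


class TestEnumerateSignals:
    @pytest.mark.parametrize("n,expected", [(2, 3), (5, 15), (26, 351)])
    def test_singleton_plus_pair_counts(self, n, expected):
        topo = gc.make_random_grn(gc.FixtureSpec(n_nodes=n, n_edges=0, seed=0))
        sigs = gc.enumerate_signals(topo)
        assert len(sigs) == expected
        assert len(set(sigs)) == expected
        assert all(len(s.genes) in (1, 2) for s in sigs)

    def test_stable_ordering(self, random_grn5):
        assert gc.enumerate_signals(random_grn5) == gc.enumerate_signals(random_grn5)


class TestOUStep:
    def test_zero_noise_is_pure_decay(self):
        assert gc.ou_step(3.0, 1.0, 10.0, 0.0, 0.7) == pytest.approx(
            3.0 * np.exp(-0.1))

    def test_memoryless_limit(self):
        out = gc.ou_step(100.0, 1e6, 10.0, 2.0, 1.5)
        assert out == pytest.approx(2.0 * 1.5, rel=1e-6)

    def test_stationary_sd_and_autocorrelation(self):
        rng = np.random.default_rng(0)
        h, tau, d = 0.5, 10.0, 2.0
        u = 0.0
        vals = np.empty(150_000)
        for i in range(vals.size):
            u = gc.ou_step(u, h, tau, d, rng.standard_normal())
            vals[i] = u
        v = vals[2000:]
        assert v.std() == pytest.approx(d, rel=0.02)
        ac = np.corrcoef(v[:-1], v[1:])[0, 1]
        phi = np.exp(-h / tau)
        se = np.sqrt((1 - phi**2) / v.size)  # AR(1) large-sample se
        assert abs(ac - phi) < 3 * se


class TestClassifyState:
    def _refs(self):
        e = np.tile([1.0, 0.0], (30, 1))
        m = np.tile([0.0, 1.0], (30, 1))
        return np.vstack([e, m]), np.array(["E"] * 30 + ["M"] * 30)

    def test_reference_state_classifies_as_itself(self):
        ref, labels = self._refs()
        assert gc.classify_state(ref[0], ref, labels, k=1) == "E"
        assert gc.classify_state(ref[-1], ref, labels, k=1) == "M"

    def test_k1_nearest_blob(self):
        ref, labels = self._refs()
        assert gc.classify_state([0.9, 0.2], ref, labels, k=1) == "E"
        assert gc.classify_state([0.1, 0.8], ref, labels, k=1) == "M"

    def test_exact_tie_breaks_toward_m(self):
        ref, labels = self._refs()
        # with k covering the whole balanced reference the vote is 30/30
        assert gc.classify_state([0.5, 0.5], ref, labels, k=60) == "M"

    def test_k_larger_than_reference_raises(self):
        ref, labels = self._refs()
        with pytest.raises(ValueError):
            gc.classify_state([0.5, 0.5], ref, labels, k=61)


def _bistable_model(toggle_ensemble):
    bi = toggle_ensemble.bistable()
    assert bi, "toggle ensemble fixture must contain bistable models"
    return bi[0]


class TestRunPerturbation:
    def test_identity_protocol_keeps_state(self, toggle, toggle_ensemble,
                                           toggle_classifier):
        topo, _ = toggle
        m = _bistable_model(toggle_ensemble)
        proto = gc.ProtocolConfig(t_signal=0.0, t_relax=0.0)
        res = gc.run_perturbation(m, m.state("E"), m.state("M"), None,
                                  gc.OUNoiseSpec(D=0.0), proto,
                                  np.random.default_rng(0), topo,
                                  classifier=toggle_classifier)
        assert res.start_label == "E" and res.end_label == "E"
        assert not res.transitioned

    def test_clamping_every_gene_forces_transition(self, toggle,
                                                   toggle_ensemble,
                                                   toggle_classifier):
        topo, _ = toggle
        m = _bistable_model(toggle_ensemble)
        proto = gc.ProtocolConfig(t_signal=50.0, t_relax=20.0)
        res = gc.run_perturbation(m, m.state("E"), m.state("M"),
                                  gc.SignalSpec(("A", "B")),
                                  gc.OUNoiseSpec(D=0.0), proto,
                                  np.random.default_rng(1), topo,
                                  classifier=toggle_classifier)
        assert res.transitioned
        assert res.end_label == "M"

    def test_clamped_gene_pinned_at_target_in_every_signal_sample(
            self, toggle, toggle_ensemble, toggle_classifier):
        topo, _ = toggle
        m = _bistable_model(toggle_ensemble)
        proto = gc.ProtocolConfig(t_signal=20.0, t_relax=10.0, sample_every=1.0)
        res = gc.run_perturbation(m, m.state("E"), m.state("M"),
                                  gc.SignalSpec(("B",)), gc.OUNoiseSpec(D=0.2),
                                  proto, np.random.default_rng(2), topo,
                                  classifier=toggle_classifier,
                                  record_trajectory=True)
        b = topo.index("B")
        in_signal = res.times <= 20.0
        assert np.all(res.trajectory[in_signal, b] == m.state("M")[b])

    def test_deterministic_rest_at_steady_state(self, toggle, toggle_bistable,
                                                toggle_classifier):
        """D = 0 and no signal leaves every bistable model at its steady
        state over a long window (flow residual below tolerance)."""
        topo, _ = toggle
        proto = gc.ProtocolConfig(t_signal=500.0, t_relax=0.0)
        for m in toggle_bistable[:5]:
            for lab in ("E", "M"):
                start = m.state(lab)
                res = gc.run_perturbation(m, start, m.state("M" if lab == "E" else "E"),
                                          None, gc.OUNoiseSpec(D=0.0), proto,
                                          np.random.default_rng(3), topo,
                                          classifier=toggle_classifier,
                                          record_trajectory=True)
                drift = np.max(np.abs(np.log1p(res.trajectory[-1]) - np.log1p(start)))
                assert drift < 0.05
                assert res.end_label == lab


class TestEfficacyAndControls:
    def test_full_clamp_efficacy_is_100(self, toggle, toggle_bistable,
                                        toggle_classifier):
        topo, _ = toggle
        bi = toggle_bistable
        proto = gc.ProtocolConfig(t_signal=50.0, t_relax=20.0)
        pct = gc.signal_efficacy(bi, gc.SignalSpec(("A", "B")),
                                 gc.OUNoiseSpec(D=0.0), proto,
                                 np.random.default_rng(4), topo,
                                 toggle_classifier)
        assert pct == 100.0

    def test_deterministic_runs_are_trial_invariant(self, toggle,
                                                    toggle_bistable,
                                                    toggle_classifier):
        topo, _ = toggle
        bi = toggle_bistable
        sig = gc.SignalSpec(("B",))
        proto = gc.ProtocolConfig(t_signal=50.0, t_relax=20.0, n_trials=3)
        p1 = gc.signal_efficacy(bi, sig, gc.OUNoiseSpec(D=0.0), proto,
                                np.random.default_rng(5), topo, toggle_classifier)
        p2 = gc.signal_efficacy(bi, sig, gc.OUNoiseSpec(D=0.0),
                                gc.ProtocolConfig(t_signal=50.0, t_relax=20.0),
                                np.random.default_rng(99), topo, toggle_classifier)
        assert 0.0 <= p1 <= 100.0
        assert p1 == p2

    def test_empty_model_set_rejected(self, toggle, toggle_classifier):
        topo, _ = toggle
        with pytest.raises(ValueError):
            gc.signal_efficacy([], gc.SignalSpec(("A",)), gc.OUNoiseSpec(),
                               gc.ProtocolConfig(), np.random.default_rng(0),
                               topo, toggle_classifier)

    def test_no_noise_controls_never_switch(self, toggle, toggle_bistable,
                                            toggle_classifier):
        topo, _ = toggle
        bi = toggle_bistable
        proto = gc.ProtocolConfig(t_signal=100.0, t_relax=20.0)
        table = gc.spontaneous_rates(bi, [0.0], proto,
                                     np.random.default_rng(6), topo,
                                     toggle_classifier)
        assert table.emt_percent.iloc[0] == 0.0
        assert table.met_percent.iloc[0] == 0.0

    def test_large_noise_switches_both_directions(self, toggle,
                                                  toggle_bistable,
                                                  toggle_classifier):
        topo, _ = toggle
        bi = toggle_bistable
        proto = gc.ProtocolConfig(t_signal=200.0, t_relax=20.0)
        table = gc.spontaneous_rates(bi, [0.5], proto,
                                     np.random.default_rng(7), topo,
                                     toggle_classifier)
        assert table.emt_percent.iloc[0] > 0
        assert table.met_percent.iloc[0] > 0

    def test_noise_amplifies_signal_efficacy(self, toggle, toggle_bistable,
                                             toggle_classifier):
        topo, _ = toggle
        bi = toggle_bistable
        proto = gc.ProtocolConfig(t_signal=100.0, t_relax=20.0)
        sig = gc.SignalSpec(("B",))
        det = gc.signal_efficacy(bi, sig, gc.OUNoiseSpec(D=0.0), proto,
                                 np.random.default_rng(8), topo, toggle_classifier)
        noisy = gc.signal_efficacy(bi, sig, gc.OUNoiseSpec(D=0.1), proto,
                                   np.random.default_rng(8), topo, toggle_classifier)
        assert noisy >= det


class TestTransitionTime:
    def test_trajectory_starting_in_target_state_is_zero(
            self, toggle, toggle_ensemble, toggle_classifier):
        topo, _ = toggle
        m = _bistable_model(toggle_ensemble)
        proto = gc.ProtocolConfig(t_signal=5.0, t_relax=0.0)
        res = gc.run_perturbation(m, m.state("M"), m.state("M"), None,
                                  gc.OUNoiseSpec(D=0.0), proto,
                                  np.random.default_rng(9), topo,
                                  classifier=toggle_classifier,
                                  record_trajectory=True)
        res.target_label = "M"
        assert gc.transition_time(res, toggle_classifier) == 0.0

    def test_non_transitioning_trajectory_has_no_time(
            self, toggle, toggle_ensemble, toggle_classifier):
        topo, _ = toggle
        m = _bistable_model(toggle_ensemble)
        proto = gc.ProtocolConfig(t_signal=5.0, t_relax=0.0)
        res = gc.run_perturbation(m, m.state("E"), m.state("M"), None,
                                  gc.OUNoiseSpec(D=0.0), proto,
                                  np.random.default_rng(10), topo,
                                  classifier=toggle_classifier,
                                  record_trajectory=True)
        assert gc.transition_time(res, toggle_classifier) is None

    def test_requires_recorded_trajectory(self, toggle, toggle_ensemble,
                                          toggle_classifier):
        topo, _ = toggle
        m = _bistable_model(toggle_ensemble)
        res = gc.run_perturbation(m, m.state("E"), m.state("M"), None,
                                  gc.OUNoiseSpec(D=0.0),
                                  gc.ProtocolConfig(t_signal=1.0, t_relax=0.0),
                                  np.random.default_rng(11), topo,
                                  classifier=toggle_classifier)
        with pytest.raises(ValueError):
            gc.transition_time(res, toggle_classifier)


class TestNoiseThresholdScan:
    def test_zero_grid_on_stable_system_finds_nothing(self, toggle,
                                                      toggle_ensemble):
        topo, _ = toggle
        m = _bistable_model(toggle_ensemble)
        out = gc.noise_threshold_scan(m, gc.SignalSpec(("B",)), m.state("E"),
                                      m.state("M"), [0.0],
                                      gc.ProtocolConfig(t_signal=20.0),
                                      np.random.default_rng(12), topo)
        # either the clamp alone destabilizes E (threshold 0) or nothing moves
        assert out in (None, 0.0)

    def test_empty_grid_rejected(self, toggle, toggle_ensemble):
        topo, _ = toggle
        m = _bistable_model(toggle_ensemble)
        with pytest.raises(ValueError):
            gc.noise_threshold_scan(m, gc.SignalSpec(("B",)), m.state("E"),
                                    m.state("M"), [], gc.ProtocolConfig(),
                                    np.random.default_rng(13), topo)

    def test_shallow_basin_escapes_at_lower_noise(self):
        """One self-activating gene with an asymmetric double well: escaping
        the shallow low state requires less noise than the deep high one."""
        topo = Topology(nodes=("X", "Y"), edges=(("X", "X", 1),))
        # bistable: low state near G/(k*lam) ~ 2, high near G/k = 40, with
        # the barrier at ~7.5 -- far closer to the low well than the high one
        params = RacipeParams(G=np.array([40.0, 1.0]), k=np.array([1.0, 1.0]),
                              lam=np.array([20.0]), thr=np.array([10.0]),
                              hill=np.array([6.0]))
        cfg = gc.EnsembleConfig(n_models=1, n_ics=60)
        found = gc.find_steady_states(params, topo, cfg, np.random.default_rng(14))
        assert len(found) == 2
        states = sorted(found, key=lambda s: s[0])
        low, high = states[0], states[1]
        model = gc.RacipeModel(model_id=0, params=params,
                               steady_states=[low, high], labels=["E", "M"])
        sig = gc.SignalSpec(("Y",))  # clamp the bystander; X keeps its well
        grid = [0.0, 0.02, 0.05, 0.1, 0.2, 0.4, 0.8]
        proto = gc.ProtocolConfig(t_signal=200.0, n_trials=4)
        up = gc.noise_threshold_scan(model, sig, low, high, grid, proto,
                                     np.random.default_rng(15), topo,
                                     clamp_state=low)
        down = gc.noise_threshold_scan(model, sig, high, low, grid, proto,
                                       np.random.default_rng(15), topo,
                                       clamp_state=high)
        assert up is not None
        assert down is None or up <= down
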