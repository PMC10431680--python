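"""Engine behaviour: limits, conservation, determinism and SSA statistics."""

import numpy as np
import pytest

from sigbcircuit import (
    Ensemble,
    ParameterSet,
    SimulationSettings,
    StressProtocol,
    build_core_network,
    ensemble_mean,
    simulate_cle,
    simulate_ensemble,
    simulate_ode,
    simulate_ssa,
)

TINY = 1e-12


class TestDeterministicEngine:
    def test_pure_decay_matches_exponential(self):
        # production effectively off; with only sigma-B present nothing
        # couples to it except first-order degradation
        net = build_core_network(ParameterSet(v0=1e-300))
        x0 = np.zeros(10)
        x0[0] = 1.0
        traj = simulate_ode(net, settings=SimulationSettings(ode_method="adaptive"),
                            x0=x0)
        expected = np.exp(-0.7 * (traj.times + 10.0))
        assert np.abs(traj.series("sigB") - expected).max() < 1e-6

    def test_phosphatase_conserved_post_stress(self, core_network):
        traj = simulate_ode(core_network)
        total = traj.series("P") + traj.series("PVP")
        post = total[traj.times >= 0]
        assert np.abs(post - 0.4).max() < 1e-9

    def test_default_run_is_single_pulse_shaped(self, core_network):
        traj = simulate_ode(core_network)
        sig = traj.activity()
        t = traj.times
        transient_max = sig[(t >= 0) & (t <= 5)].max()
        late = sig[t >= 100]
        assert transient_max > 5 * late.max()
        # relaxed: late values essentially constant
        assert late.max() - late.min() < 1e-6

    def test_implicit_and_adaptive_agree_after_transient(self, core_network):
        imp = simulate_ode(core_network)
        ada = simulate_ode(core_network,
                           settings=SimulationSettings(ode_method="adaptive"))
        mask = imp.times > 20
        assert np.abs(imp.values[mask] - ada.values[mask]).max() < 1e-6

    def test_step_refinement_converges(self, core_network):
        # First-order scheme on a stiff pulse: halving dt moves the path a
        # little during the fast transients and not at all afterwards.
        base = simulate_ode(core_network)
        fine = simulate_ode(core_network, settings=SimulationSettings(dt=0.0025))
        diff = np.abs(base.values - fine.values)
        assert diff.max() < 0.1
        assert diff[base.times > 20].max() < 1e-6

    def test_stress_time_on_grid_with_post_stress_state(self, core_network):
        traj = simulate_ode(core_network)
        assert 0.0 in traj.times
        i0 = int(np.where(traj.times == 0.0)[0][0])
        assert traj.series("P")[i0] == pytest.approx(0.4, abs=1e-3)
        assert np.all(np.diff(traj.times) > 0)


class TestLangevinEngine:
    def test_zero_noise_limit_equals_ode(self, core_network):
        ode = simulate_ode(core_network)
        cle = simulate_cle(core_network, seed=5, eta=0.0)
        assert np.abs(ode.values - cle.values).max() < 1e-6

    def test_seed_determinism_bitwise(self, core_network, short_protocol):
        a = simulate_cle(core_network, seed=42, protocol=short_protocol)
        b = simulate_cle(core_network, seed=42, protocol=short_protocol)
        assert np.array_equal(a.values, b.values)
        c = simulate_cle(core_network, seed=43, protocol=short_protocol)
        assert not np.array_equal(a.values, c.values)

    def test_phosphatase_conserved_with_noise(self, core_network, short_protocol):
        traj = simulate_cle(core_network, seed=7, protocol=short_protocol)
        total = traj.series("P") + traj.series("PVP")
        post = total[traj.times >= 0]
        assert np.abs(post - 0.4).max() < 1e-9

    def test_transient_peak_of_mean_grows_with_noise(self, short_protocol):
        # ladder of noise amplitudes; the mean response pulse amplifies
        peaks = []
        for eta in (0.01, 0.05, 0.1):
            net = build_core_network(ParameterSet(p_stress=0.4, eta=eta))
            ens = simulate_ensemble(net, n=15, base_seed=11,
                                    protocol=short_protocol)
            mean = ensemble_mean(ens, "sigB")
            t = ens.times
            peaks.append(mean[(t >= 0) & (t <= 5)].max())
        assert peaks[0] < peaks[1] < peaks[2]


class TestModifiedModel:
    def test_total_phosphatase_conserved_at_twice_stress(self, modified_network,
                                                         short_protocol):
        traj = simulate_cle(modified_network, seed=3, protocol=short_protocol)
        total = (traj.series("P") + traj.series("PI") + traj.series("PVP"))
        post = total[traj.times >= 0]
        assert np.abs(post - 2 * 0.4).max() < 1e-9

    def test_upstream_noise_scale_is_separate(self, modified_network,
                                              short_protocol):
        # with both noise amplitudes zero the modified path is deterministic
        a = simulate_cle(modified_network, seed=1, protocol=short_protocol,
                         eta=0.0, eta_amp=0.0)
        b = simulate_cle(modified_network, seed=2, protocol=short_protocol,
                         eta=0.0, eta_amp=0.0)
        assert np.array_equal(a.values, b.values)
        # upstream noise alone perturbs the path
        c = simulate_cle(modified_network, seed=1, protocol=short_protocol,
                         eta=0.0, eta_amp=0.1)
        assert not np.array_equal(a.values, c.values)


class TestEnsembles:
    def test_single_member_equals_direct_call(self, core_network, short_protocol):
        ens = simulate_ensemble(core_network, n=1, base_seed=9,
                                protocol=short_protocol)
        direct = simulate_cle(core_network, seed=9, protocol=short_protocol)
        assert np.array_equal(ens.members[0].values, direct.values)

    def test_repeatability(self, core_network, short_protocol):
        e1 = simulate_ensemble(core_network, n=4, base_seed=3, protocol=short_protocol)
        e2 = simulate_ensemble(core_network, n=4, base_seed=3, protocol=short_protocol)
        for a, b in zip(e1, e2):
            assert np.array_equal(a.values, b.values)

    def test_mean_bounds_and_identity(self, core_network, short_protocol):
        ens = simulate_ensemble(core_network, n=5, base_seed=21,
                                protocol=short_protocol)
        mean = ensemble_mean(ens, "sigB")
        stack = np.stack([m.series("sigB") for m in ens])
        assert np.all(mean >= stack.min(axis=0) - 1e-12)
        assert np.all(mean <= stack.max(axis=0) + 1e-12)
        solo = Ensemble([ens.members[0], ens.members[0]])
        np.testing.assert_array_equal(ensemble_mean(solo, "sigB"),
                                      ens.members[0].series("sigB"))

    def test_mismatched_grids_rejected(self, core_network, short_protocol):
        a = simulate_cle(core_network, seed=1, protocol=short_protocol)
        b = simulate_cle(core_network, seed=2)
        with pytest.raises(ValueError, match="time grid"):
            Ensemble([a, b])


class TestGillespieEngine:
    def test_birth_death_stationary_mean(self):
        # only sigma-B production (constant rate) and first-order decay
        p = ParameterSet(v0=10.0, F=TINY, lambda_W=TINY, lambda_V=TINY,
                         kBw=TINY, kB1=TINY, kB2=TINY, kB3=TINY, kB4=TINY,
                         kB5=TINY, kD4=TINY, p_init=0.0, p_stress=0.0)
        net = build_core_network(p)
        proto = StressProtocol(t_burnin_start=-1.0, t_stress=0.0, t_end=20.0)
        finals = np.array([
            simulate_ssa(net, seed=s, protocol=proto).series("sigB")[-1]
            for s in range(500)
        ])
        expected = 10.0 / 0.7
        se = finals.std(ddof=1) / np.sqrt(finals.size)
        assert abs(finals.mean() - expected) < 3 * se + 1e-9

    def test_integer_counts_and_exact_conservation(self, short_protocol):
        p = ParameterSet(kP=1.0, p_init=0.0, p_stress=3.0)
        net = build_core_network(p)
        traj = simulate_ssa(net, seed=2, protocol=short_protocol)
        assert np.all(traj.values >= 0)
        assert np.all(traj.values == np.round(traj.values))
        total = traj.series("P") + traj.series("PVP")
        assert np.all(total[traj.times >= 0] == 3.0)

    def test_zero_propensity_holds_state(self):
        p = ParameterSet(v0=1e-300, F=TINY, lambda_W=TINY, lambda_V=TINY,
                         kBw=TINY, kB1=TINY, kB2=TINY, kB3=TINY, kB4=TINY,
                         kB5=TINY, kD4=TINY, p_init=0.0, p_stress=0.0)
        net = build_core_network(p)
        proto = StressProtocol(t_burnin_start=-1.0, t_stress=0.0, t_end=5.0)
        traj = simulate_ssa(net, seed=1, protocol=proto)
        assert np.all(traj.values == 0)

    def test_law_of_large_numbers_against_ode(self):
        # 100-fold scaled-up copy numbers: SSA ensemble/time average of
        # sigma-B matches the macroscopic ODE within 5%
        om = 100.0
        ps = ParameterSet(v0=0.4 * om, K=0.2 * om, kBw=3600 / om,
                          kB1=3600 / om, kB2=3600 / om, kB3=3600 / om,
                          kB4=1800 / om, kB5=3600 / om, kD4=1800 / om,
                          p_init=0.0, p_stress=round(0.2 * om))
        net = build_core_network(ps)
        proto = StressProtocol(t_burnin_start=-2.0, t_stress=0.0, t_end=30.0)
        avgs = []
        for s in range(25):
            tr = simulate_ssa(net, seed=s, protocol=proto)
            avgs.append(tr.series("sigB")[tr.times >= 10].mean())
        ode = simulate_ode(
            build_core_network(ParameterSet(p_init=0.0, p_stress=0.2)),
            protocol=proto, settings=SimulationSettings(ode_method="adaptive"))
        ref = ode.series("sigB")[ode.times >= 10].mean() * om
        assert abs(np.mean(avgs) - ref) / ref < 0.05


class TestTrajectoryIO:
    def test_csv_round_trip(self, core_network, short_protocol, tmp_path):
        traj = simulate_cle(core_network, seed=4, protocol=short_protocol)
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        back = traj.from_csv(path)
        assert back.species == traj.species
        np.testing.assert_allclose(back.values, traj.values, rtol=0, atol=1e-12)
        assert path.read_text().splitlines()[0].startswith("time_h,sigB,")

    def test_settings_validation(self):
        with pytest.raises(ValueError):
            SimulationSettings(dt=-1)
        with pytest.raises(ValueError):
            SimulationSettings(dt=0.004, sample_dt=0.01)
        with pytest.raises(ValueError):
            SimulationSettings(ode_method="rk4")
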