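"""Structure, propensities and drift of the core and modified networks."""

import numpy as np
import pytest

from sigbcircuit import (
    CORE_SPECIES,
    PARAMETER_NAMES,
    ParameterSet,
    StressProtocol,
    apply_stress,
    build_core_network,
    build_modified_network,
    evaluate_propensities,
    operon_rate,
)


def hand_written_core_rhs(x, p):
    """Independent oracle: the reaction-rate equations written out term by
    term, not assembled from the stoichiometry matrix."""
    sigB, W, W2, W2sigB, W2V, W2V2, V, VP, P, PVP = x
    f = p.v0 * (1 + p.F * sigB / (p.K + sigB))
    return np.array([
        # sigB
        f + p.kD3 * W2sigB + p.kB4 * V * W2sigB
        - p.kB3 * W2 * sigB - p.kD4 * W2V * sigB - p.kdeg * sigB,
        # W
        p.lambda_W * f + 2 * p.kDw * W2 - p.kBw * W ** 2 - p.kdeg * W,
        # W2
        p.kD1 * W2V + p.kD3 * W2sigB + p.kK1 * W2V + p.kBw * W ** 2 / 2
        - p.kB1 * W2 * V - p.kB3 * W2 * sigB - p.kDw * W2 - p.kdeg * W2,
        # W2sigB
        p.kB3 * W2 * sigB + p.kD4 * W2V * sigB - p.kB4 * W2sigB * V
        - p.kD3 * W2sigB - p.kdeg * W2sigB,
        # W2V
        p.kD2 * W2V2 + p.kK2 * W2V2 + p.kB1 * W2 * V + p.kB4 * W2sigB * V
        - p.kB2 * W2V * V - p.kD4 * W2V * sigB - p.kD1 * W2V
        - p.kK1 * W2V - p.kdeg * W2V,
        # W2V2
        p.kB2 * W2V * V - p.kD2 * W2V2 - p.kK2 * W2V2 - p.kdeg * W2V2,
        # V
        p.lambda_V * f + p.kP * PVP + p.kD1 * W2V + p.kD2 * W2V2
        + p.kD4 * W2V * sigB - p.kB1 * W2 * V - p.kB2 * W2V * V
        - p.kB4 * W2sigB * V - p.kdeg * V,
        # VP
        p.kD5 * PVP + p.kK1 * W2V + p.kK2 * W2V2 - p.kB5 * P * VP
        - p.kdeg * VP,
        # P
        p.kD5 * PVP + p.kdeg * PVP + p.kP * PVP - p.kB5 * P * VP,
        # PVP
        p.kB5 * P * VP - p.kD5 * PVP - p.kP * PVP - p.kdeg * PVP,
    ])


class TestStructure:
    def test_core_counts(self, core_network):
        assert core_network.n_species == 10
        assert core_network.n_reactions == 27
        assert core_network.species == CORE_SPECIES

    def test_parameter_table_has_24_entries(self):
        assert len(PARAMETER_NAMES) == 24
        p = ParameterSet()
        # spot values of the published defaults
        assert p.kP == 180.0 and p.kdeg == 0.7 and p.v0 == 0.4
        assert p.lambda_W == 4.0 and p.lambda_V == 4.5 and p.eta == 0.025

    def test_modified_adds_one_species_three_reactions_two_parameters(
            self, core_network, modified_network):
        assert modified_network.n_species - core_network.n_species == 1
        assert modified_network.n_reactions - core_network.n_reactions == 3
        upstream = [r for r in modified_network.reactions
                    if r.noise_group == "upstream"]
        assert len(upstream) == 3
        assert all(r.noise_group == "core" for r in core_network.reactions)
        extra_params = set(modified_network.params.to_dict()) - set(
            ParameterSet().to_dict())
        assert extra_params == {"eta_amp", "eta_freq"}

    def test_dimerisation_net_change(self, core_network):
        rxn = next(r for r in core_network.reactions if r.name == "dimerisation")
        v = rxn.net_change(core_network.species)
        assert v[core_network.species.index("W")] == -2
        assert v[core_network.species.index("W2")] == 1

    def test_phosphatase_conservation_columnwise(self, core_network,
                                                 modified_network):
        S = core_network.stoichiometry
        i_p = core_network.species.index("P")
        i_pvp = core_network.species.index("PVP")
        assert np.all(S[i_p] + S[i_pvp] == 0)
        Sm = modified_network.stoichiometry
        rows = [modified_network.species.index(s) for s in ("P", "PI", "PVP")]
        assert np.all(Sm[rows].sum(axis=0) == 0)

    def test_modified_requires_upstream_parameters(self):
        with pytest.raises(ValueError, match="eta_amp"):
            build_modified_network(ParameterSet())

    def test_invalid_parameter_rejected_by_name(self):
        with pytest.raises(ValueError, match="kB1"):
            ParameterSet(kB1=-1.0)
        with pytest.raises(ValueError, match="eta"):
            ParameterSet(eta=-0.5)


class TestPropensities:
    def test_all_zero_state_only_production(self, core_network):
        a = evaluate_propensities(core_network, np.zeros(10))
        nonzero = np.nonzero(a)[0]
        assert list(nonzero) == [0, 1, 2]
        np.testing.assert_allclose(a[:3], [0.4, 4.0 * 0.4, 4.5 * 0.4])

    def test_dimerisation_combinatorial_factor(self, core_network):
        state = np.zeros(10)
        state[core_network.species.index("W")] = 2.0
        a = evaluate_propensities(core_network, state)
        j = [r.name for r in core_network.reactions].index("dimerisation")
        assert a[j] == pytest.approx(3600 * 2.0 ** 2 / 2)  # = 7200

    def test_dissociation_uses_complex_concentration(self, core_network):
        state = np.zeros(10)
        state[core_network.species.index("W2V")] = 1.0
        a = evaluate_propensities(core_network, state)
        j = [r.name for r in core_network.reactions].index("dissociation_W2V")
        assert a[j] == pytest.approx(18.0)

    def test_linearity_in_rate_constants(self, rng):
        p = ParameterSet()
        doubled = ParameterSet(**{
            k: 2 * v for k, v in p.to_dict().items()
            if k not in ("F", "K", "lambda_W", "lambda_V", "p_init",
                         "p_stress", "eta")
        })
        net1, net2 = build_core_network(p), build_core_network(doubled)
        state = rng.uniform(0, 3, 10)
        a1 = evaluate_propensities(net1, state)
        a2 = evaluate_propensities(net2, state)
        np.testing.assert_allclose(a2, 2 * a1, rtol=1e-12)

    def test_strict_mode_rejects_negative_amounts(self, core_network):
        state = np.zeros(10)
        state[1] = -0.1
        with pytest.raises(ValueError, match="W"):
            evaluate_propensities(core_network, state, strict=True)
        # tolerant (Langevin) mode passes negatives through
        evaluate_propensities(core_network, state)

    def test_drift_matches_hand_written_rhs(self, core_network, rng):
        from sigbcircuit import _kernels
        from sigbcircuit.simulation import _kernel_args
        args = _kernel_args(core_network)
        for _ in range(100):
            x = rng.uniform(0, 5, 10)
            got = _kernels.drift(x, *args)
            want = hand_written_core_rhs(x, core_network.params)
            np.testing.assert_allclose(got, want, rtol=1e-12, atol=1e-12)

    def test_modified_drift_reduces_to_core_at_zero_switching(self, rng):
        from sigbcircuit import _kernels
        from sigbcircuit.simulation import _kernel_args
        mod = build_modified_network(ParameterSet(eta_amp=0.05, eta_freq=0.0))
        core = build_core_network(ParameterSet())
        x = rng.uniform(0, 5, 11)
        a = evaluate_propensities(mod, x)
        assert np.all(a[-3:] == 0.0)
        got = _kernels.drift(x, *_kernel_args(mod))[:10]
        want = _kernels.drift(x[:10], *_kernel_args(core))
        np.testing.assert_allclose(got, want, rtol=1e-12)

    def test_operon_rate_parses(self):
        # affine: base activity is exactly v0; shared: v0/K at zero
        assert operon_rate(0.0, 0.4, 30.0, 0.2, "affine") == pytest.approx(0.4)
        assert operon_rate(0.0, 0.4, 30.0, 0.2, "shared") == pytest.approx(2.0)
        assert operon_rate(1e9, 0.4, 30.0, 0.2, "affine") == pytest.approx(
            0.4 * 31, rel=1e-6)

    def test_jacobian_matches_finite_differences(self, core_network, rng):
        from sigbcircuit import _kernels
        from sigbcircuit.simulation import _kernel_args
        args = _kernel_args(core_network)
        x = rng.uniform(0.1, 2, 10)
        J = _kernels.drift_jacobian(x, *args)
        eps = 1e-7
        for k in range(10):
            dx = np.zeros(10)
            dx[k] = eps
            fd = (_kernels.drift(x + dx, *args) - _kernels.drift(x - dx, *args)) / (2 * eps)
            np.testing.assert_allclose(J[:, k], fd, rtol=1e-5, atol=1e-5)


class TestSubstitution:
    def test_round_trip_identity(self):
        p = ParameterSet(p_stress=0.37, kP=123.0)
        q = p.with_substitution(p.p_prod, p.p_frac)
        assert q.p_stress == pytest.approx(p.p_stress, rel=1e-12)
        assert q.kP == pytest.approx(p.kP, rel=1e-12)

    def test_from_dict_with_substituted_pair(self):
        p = ParameterSet.from_dict({"p_prod": 50.0, "p_frac": 0.1})
        assert p.p_stress == pytest.approx(np.sqrt(5.0))
        assert p.kP == pytest.approx(np.sqrt(500.0))

    def test_inconsistent_over_determination_rejected(self):
        with pytest.raises(ValueError, match="over-determination"):
            ParameterSet.from_dict(
                {"p_stress": 0.4, "kP": 180.0, "p_prod": 1.0, "p_frac": 1.0})

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError, match="k_nonsense"):
            ParameterSet.from_dict({"k_nonsense": 1.0})


class TestStress:
    def test_core_stress_step(self, core_network):
        state = core_network.initial_state()
        assert state[core_network.species.index("P")] == 0.001
        out = apply_stress(state, core_network)
        assert out[core_network.species.index("P")] == pytest.approx(0.4)
        others = [i for i in range(10) if i != core_network.species.index("P")]
        np.testing.assert_array_equal(out[others], state[others])

    def test_modified_stress_raises_both_pools(self, modified_network):
        state = modified_network.initial_state()
        out = apply_stress(state, modified_network)
        i_p = modified_network.species.index("P")
        i_pi = modified_network.species.index("PI")
        assert out[i_p] - state[i_p] == pytest.approx(0.399)
        assert out[i_pi] - state[i_pi] == pytest.approx(0.399)

    def test_degenerate_stress_is_identity(self):
        net = build_core_network(ParameterSet(p_stress=0.001))
        state = net.initial_state()
        np.testing.assert_array_equal(apply_stress(state, net), state)

    def test_protocol_ordering_enforced(self):
        with pytest.raises(ValueError):
            StressProtocol(t_burnin_start=0.0, t_stress=0.0)
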