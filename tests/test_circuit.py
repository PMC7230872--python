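import numpy as np
import pytest
import scipy.integrate
import scipy.optimize

from ctcemt import circuit as C


def toggle_network():
    return C.GeneNetwork(nodes=("A", "B"),
                         edges=(("A", "B", -1), ("B", "A", -1)))


def toggle_model(net, l=10.0, k=1.0, x0=4.0, n=4, lam=0.01):
    return C.CircuitModel(
        network=net,
        production=np.array([l, l]), degradation=np.array([k, k]),
        threshold=np.array([x0, x0]), hill=np.array([n, n]),
        fold_change=np.array([lam, lam]),
    )


class TestShiftedHill:
    def test_limits_random_draws(self):
        rng = np.random.default_rng(0)
        for _ in range(10_000):
            x0 = rng.uniform(0.1, 100)
            n = rng.integers(1, 7)
            lam = rng.uniform(0.01, 100)
            assert abs(C.shifted_hill(0.0, x0, n, lam) - 1.0) < 1e-9
            mid = C.shifted_hill(x0, x0, n, lam)
            assert abs(mid - (1 + lam) / 2) < 1e-9
            # saturation: evaluate where (X/X0)^n = 1e12
            sat = C.shifted_hill(x0 * 1e12 ** (1 / n), x0, n, lam)
            assert abs(sat - lam) < 1e-9

    def test_bounded_between_one_and_lambda(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 1000, 500)
        for lam in (0.05, 20.0):
            v = C.shifted_hill(x, 5.0, 3, lam)
            assert (v >= min(1, lam) - 1e-12).all()
            assert (v <= max(1, lam) + 1e-12).all()

    def test_domain_violations(self):
        with pytest.raises(C.CircuitError):
            C.shifted_hill(-1.0, 1.0, 2, 2.0)
        with pytest.raises(C.CircuitError):
            C.shifted_hill(1.0, 0.0, 2, 2.0)
        with pytest.raises(C.CircuitError):
            C.shifted_hill(1.0, 1.0, 0, 2.0)


class TestNetwork:
    def test_shipped_emt_network(self):
        net = C.load_emt_network()
        assert {"SNAIL", "miR200", "ZEB", "GRHL2", "CDH1", "VIM"} == set(net.nodes)
        signs = {(s, t): sig for s, t, sig in net.edges}
        # the double-negative feedback loops
        assert signs[("miR200", "ZEB")] == -1 and signs[("ZEB", "miR200")] == -1
        assert signs[("GRHL2", "ZEB")] == -1 and signs[("ZEB", "GRHL2")] == -1
        assert signs[("ZEB", "VIM")] == 1 and signs[("ZEB", "CDH1")] == -1

    def test_contradictory_duplicate_edge_rejected(self):
        with pytest.raises(C.CircuitError, match="contradictory"):
            C.GeneNetwork(("A", "B"), (("A", "B", 1), ("A", "B", -1)))

    def test_unknown_endpoint_rejected(self):
        with pytest.raises(C.CircuitError):
            C.GeneNetwork(("A",), (("A", "Z", 1),))

    def test_tsv_round_trip(self, tmp_path):
        net = toggle_network()
        p = tmp_path / "net.tsv"
        net.to_tsv(p)
        assert C.GeneNetwork.from_tsv(p).edges == net.edges


class TestSampling:
    def test_degenerate_ranges_single_model(self):
        net = toggle_network()
        r = C.ParameterRanges(production=(5, 5), degradation=(0.5, 0.5),
                              hill=(2, 2), fold_change=(10, 10))
        m = C.sample_parameters(net, r, seed=0)
        assert np.allclose(m.production, 5) and np.allclose(m.degradation, 0.5)
        assert np.allclose(m.fold_change, 0.1)  # inhibition: 1/lambda

    def test_degradation_monte_carlo_mean(self):
        net = C.GeneNetwork(("A",), ())
        rng = np.random.default_rng(123)
        ks = [C.sample_parameters(net, seed=rng).degradation[0]
              for _ in range(10_000)]
        se = np.std(ks) / np.sqrt(len(ks))
        assert abs(np.mean(ks) - 0.55) < 3 * se

    def test_seeds_differ_and_sign_constraints(self):
        net = toggle_network()
        a, b = C.sample_parameters(net, seed=1), C.sample_parameters(net, seed=2)
        assert not np.allclose(a.production, b.production)
        assert (a.fold_change < 1).all()  # both edges inhibitory

    def test_inverted_range_rejected(self):
        with pytest.raises(C.CircuitError):
            C.ParameterRanges(production=(10, 1)).validate()


class TestRHS:
    def test_isolated_node_closed_form(self):
        net = C.GeneNetwork(("A",), ())
        m = C.CircuitModel(net, np.array([7.0]), np.array([0.5]),
                           np.empty(0), np.empty(0), np.empty(0))
        rhs = C.build_rhs(net, m)
        assert rhs(0.0, np.array([14.0]))[0] == pytest.approx(0.0)
        res = C.solve_steady_states(net, m, n_inits=5, seed=0)
        assert res.n_states == 1
        assert res.states[0, 0] == pytest.approx(14.0, abs=1e-5)

    def test_neutral_edges_decouple(self):
        net = toggle_network()
        m = C.CircuitModel(net, np.array([6.0, 8.0]), np.array([1.0, 2.0]),
                           np.array([1.0, 1.0]), np.array([2, 2]),
                           np.array([1.0, 1.0]))  # lambda = 1: no regulation
        res = C.solve_steady_states(net, m, n_inits=10, seed=1)
        assert res.n_states == 1
        assert np.allclose(res.states[0], [6.0, 4.0], atol=1e-5)

    def test_probe_points_match_independent_arithmetic(self):
        net = toggle_network()
        m = toggle_model(net, l=10, k=1, x0=4, n=4, lam=0.01)
        rhs = C.build_rhs(net, m)
        for a, b in [(0.0, 0.0), (1.0, 8.0), (10.0, 0.5), (4.0, 4.0)]:
            expect_a = 10 * (0.01 + 0.99 / (1 + (b / 4) ** 4)) - a
            expect_b = 10 * (0.01 + 0.99 / (1 + (a / 4) ** 4)) - b
            assert np.allclose(rhs(0, np.array([a, b])), [expect_a, expect_b],
                               atol=1e-12)


def toggle_nullcline_states(l=10.0, k=1.0, x0=4.0, n=4, lam=0.01):
    """Independent oracle: 1D root scan of the toggle's reduced equation."""
    def a_of_b(b):
        return (l / k) * (lam + (1 - lam) / (1 + (b / x0) ** n))

    def g(b):
        return b - a_of_b(a_of_b(b))  # B must be consistent through A(B)

    grid = np.linspace(0.0, 1.2 * l / k, 4000)
    vals = np.array([g(b) for b in grid])
    roots = []
    for i in range(len(grid) - 1):
        if vals[i] == 0 or vals[i] * vals[i + 1] < 0:
            b = scipy.optimize.brentq(g, grid[i], grid[i + 1])
            a = a_of_b(b)
            if not any(abs(b - r[1]) < 1e-4 for r in roots):
                roots.append((a, b))
    return roots


class TestSteadyStates:
    def test_toggle_two_mirror_states_vs_nullcline_oracle(self):
        net = toggle_network()
        m = toggle_model(net)
        res = C.solve_steady_states(net, m, n_inits=60, seed=0)
        assert res.n_states == 2
        s = res.states[np.argsort(res.states[:, 0])]
        # mirror symmetry of the symmetric toggle
        assert np.allclose(s[0], s[1][::-1], rtol=1e-3)
        # all stable oracle roots recovered (the middle root is a saddle)
        roots = toggle_nullcline_states()
        stable = [r for r in roots if abs(r[0] - r[1]) > 1e-3]
        assert len(stable) == 2
        for a, b in stable:
            assert any(np.allclose(st, [a, b], rtol=1e-3) for st in res.states)

    def test_integration_matches_solve_ivp(self):
        # independent route: scipy's adaptive integrator from the same start
        net = toggle_network()
        m = toggle_model(net, l=14.0, k=0.7, x0=5.0, n=3, lam=0.05)
        rhs = C.build_rhs(net, m)
        x0 = np.array([1.0, 17.0])
        sol = scipy.integrate.solve_ivp(rhs, (0, 400), x0, rtol=1e-10, atol=1e-12)
        res = C.solve_steady_states(net, m, n_inits=40, seed=3)
        end = sol.y[:, -1]
        assert any(np.allclose(st, end, rtol=1e-3) for st in res.states)

    def test_monostable_one_state_regardless_of_inits(self):
        net = toggle_network()
        # weak inhibition (lambda near 1): monostable
        m = toggle_model(net, lam=0.9)
        for n_inits in (5, 25, 80):
            res = C.solve_steady_states(net, m, n_inits=n_inits, seed=2)
            assert res.n_states == 1

    def test_reported_states_satisfy_residual_independently(self):
        net = C.load_emt_network()
        m = C.sample_parameters(net, seed=5)
        res = C.solve_steady_states(net, m, n_inits=30, seed=5)
        rhs = C.build_rhs(net, m)
        for st in res.states:
            assert (st >= 0).all()
            assert np.abs(rhs(0.0, st)).max() < 1e-6


class TestEnsemble:
    def test_determinism_under_seed(self):
        net = toggle_network()
        a = C.run_ensemble(net, n_models=20, n_inits=10, replicates=2, seed=9)
        b = C.run_ensemble(net, n_models=20, n_inits=10, replicates=2, seed=9)
        cols = list(net.nodes)
        assert np.allclose(a.states[cols].to_numpy(), b.states[cols].to_numpy())

    def test_single_model_ensemble(self):
        net = toggle_network()
        e = C.run_ensemble(net, n_models=1, n_inits=10, replicates=1, seed=0)
        assert set(e.states["model"]) == {0}

    def test_replicates_agree_within_sampling_error(self):
        net = C.load_emt_network()
        e = C.run_ensemble(net, n_models=120, n_inits=15, replicates=3, seed=4)
        mean_states = e.states.groupby("replicate").size() / 120
        assert mean_states.max() - mean_states.min() < 0.3

    def test_all_ensemble_states_residual_checked(self):
        # recompute dX/dt from the recorded parameter table with plain
        # arithmetic (no package functions) and verify every reported state
        net = C.load_emt_network()
        e = C.run_ensemble(net, n_models=40, n_inits=10, replicates=1, seed=8)
        nodes = list(net.nodes)
        for _, row in e.states.iterrows():
            x = {n: float(row[n]) for n in nodes}
            p = e.parameters[(e.parameters["replicate"] == row["replicate"])
                             & (e.parameters["model"] == row["model"])].iloc[0]
            for n in nodes:
                prodterm = p[f"l_{n}"]
                for (s, t, _) in net.edges:
                    if t != n:
                        continue
                    lam = p[f"lam_{s}->{t}"]
                    ratio = (x[s] / p[f"thr_{s}->{t}"]) ** p[f"hill_{s}->{t}"]
                    prodterm *= lam + (1 - lam) / (1 + ratio)
                residual = prodterm - p[f"k_{n}"] * x[n]
                assert x[n] >= 0
                assert abs(residual) < 1e-6


class TestExpressionCorrelation:
    def test_copy_node_perfect_correlation(self):
        # B is driven only by A with neutral-free strong activation; use a
        # 2-node chain where B tracks A's level monotonically across models
        net = C.GeneNetwork(("A", "B"), (("A", "B", 1),))
        e = C.run_ensemble(net, n_models=80, n_inits=5, replicates=1, seed=1)
        r = C.expression_correlation(e, "A", "A")
        assert r["pooled"] == pytest.approx(1.0)

    def test_independent_nodes_near_zero(self):
        net = C.GeneNetwork(("A", "B"), ())
        e = C.run_ensemble(net, n_models=600, n_inits=2, replicates=1, seed=2)
        r = C.expression_correlation(e, "A", "B")
        assert abs(r["pooled"]) < 0.1

    def test_emt_circuit_negative_in_every_replicate(self):
        net = C.load_emt_network()
        e = C.run_ensemble(net, n_models=150, n_inits=15, replicates=3, seed=3)
        r = C.expression_correlation(e, "CDH1", "VIM")
        assert all(x < 0 for x in r["per_replicate"])
        assert r["pooled"] < -0.3

    def test_unknown_gene_errors(self):
        net = toggle_network()
        e = C.run_ensemble(net, n_models=5, n_inits=5, replicates=1, seed=0)
        with pytest.raises(C.CircuitError):
            C.expression_correlation(e, "A", "Z")
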