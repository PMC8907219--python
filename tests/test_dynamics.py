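import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize

from chondronet.dynamics import (
    ConvergenceError,
    IntegrationError,
    NodeParameters,
    PerturbationSpec,
    SolverConfig,
    activation,
    baseline,
    baseline_initial_condition,
    integrate_to_steady_state,
    response,
    rhs,
    total_input,
)
from chondronet.network import Edge, RegulatoryNetwork, Sign
from chondronet.synthetic import SyntheticSpec, generate_network


def phi_highprec(omega, h, digits=40):
    """Independent high-precision evaluation of the sigmoid closed form."""
    import sympy

    w = sympy.Rational(omega) if not isinstance(omega, sympy.Expr) else omega
    hh = sympy.Integer(h) if float(h).is_integer() else sympy.Rational(str(h))
    expr = (-sympy.exp(hh / 2) + sympy.exp(-hh * (w - sympy.Rational(1, 2)))) / (
        (1 - sympy.exp(hh / 2)) * (1 + sympy.exp(-hh * (w - sympy.Rational(1, 2))))
    )
    return float(expr.evalf(digits))


class TestActivation:
    @pytest.mark.parametrize("h", [1, 10, 100])
    def test_anchors(self, h):
        assert abs(activation(0.0, h) - 0.0) <= 1e-12
        assert abs(activation(0.5, h) - 0.5) <= 1e-12
        assert abs(activation(1.0, h) - 1.0) <= 1e-12

    def test_two_thirds_against_highprec(self):
        expected = phi_highprec(sympy_fraction(2, 3), 10)
        assert activation(2 / 3, 10) == pytest.approx(expected, abs=1e-12)
        assert round(expected, 3) == 0.846

    @given(st.floats(0, 1), st.floats(0, 1))
    @settings(max_examples=100, deadline=None)
    def test_strictly_increasing(self, a, b):
        lo, hi = sorted((a, b))
        assert activation(lo, 10) <= activation(hi, 10)
        if hi - lo > 1e-9:  # below that, float rounding can tie
            assert activation(lo, 10) < activation(hi, 10)

    def test_domain_error(self):
        with pytest.raises(ValueError, match="omega"):
            activation(1.5, 10)


def sympy_fraction(p, q):
    import sympy

    return sympy.Rational(p, q)


class TestTotalInput:
    def test_single_activator_saturated(self, chain_net):
        assert total_input("B", {"A": 1.0, "B": 0.0}, chain_net) == pytest.approx(1.0)

    def test_single_inhibitor_saturated(self):
        net = RegulatoryNetwork(edges=[Edge("A", "B", Sign.INHIBITION)])
        assert total_input("B", {"A": 1.0, "B": 0.0}, net) == pytest.approx(0.0)

    def test_inactive_inhibitor(self):
        net = RegulatoryNetwork(edges=[
            Edge("A", "C", Sign.ACTIVATION),
            Edge("B", "C", Sign.INHIBITION),
        ])
        omega = total_input("C", {"A": 1.0, "B": 0.0, "C": 0.0}, net)
        assert omega == pytest.approx(1.0)

    def test_half_activator(self, chain_net):
        # direct evaluation of the activator block: 2 * (0.5 / 1.5)
        omega = total_input("B", {"A": 0.5, "B": 0.0}, chain_net)
        assert omega == pytest.approx(2.0 / 3.0, abs=1e-15)

    def test_source_node_contract_error(self, chain_net):
        with pytest.raises(ValueError, match="no incoming"):
            total_input("A", {"A": 0.0, "B": 0.0}, chain_net)

    @given(st.floats(0, 1), st.floats(0, 1), st.floats(0.001, 0.999))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_regulators(self, xa, xi, bump):
        net = RegulatoryNetwork(edges=[
            Edge("A", "C", Sign.ACTIVATION),
            Edge("B", "C", Sign.INHIBITION),
        ])
        base = total_input("C", {"A": xa, "B": xi, "C": 0.0}, net)
        up_act = total_input(
            "C", {"A": min(1.0, xa + bump), "B": xi, "C": 0.0}, net
        )
        up_inh = total_input(
            "C", {"A": xa, "B": min(1.0, xi + bump), "C": 0.0}, net
        )
        assert up_act >= base - 1e-12
        assert up_inh <= base + 1e-12

    def test_bounded_for_random_weights(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            net = RegulatoryNetwork()
            n_act = rng.integers(0, 4)
            n_inh = rng.integers(0 if n_act else 1, 4)
            state = {"T": 0.0}
            for i in range(n_act):
                net.add_edge(Edge(f"A{i}", "T", Sign.ACTIVATION,
                                  weight=float(rng.uniform(0.1, 5))))
                state[f"A{i}"] = float(rng.uniform(0, 1))
            for i in range(n_inh):
                net.add_edge(Edge(f"I{i}", "T", Sign.INHIBITION,
                                  weight=float(rng.uniform(0.1, 5))))
                state[f"I{i}"] = float(rng.uniform(0, 1))
            if not net.has_node("T"):
                continue
            if net.in_degree("T") == 0:
                continue
            omega = total_input("T", state, net)
            assert -1e-12 <= omega <= 1 + 1e-12


class TestRhs:
    def test_fixed_point_at_one(self, chain_net):
        dx = rhs({"A": 1.0, "B": 1.0}, chain_net, clamps={"A": 1.0})
        assert dx["A"] == 0.0
        assert dx["B"] == pytest.approx(0.0, abs=1e-12)

    def test_off_fixed_point(self, chain_net):
        dx = rhs({"A": 0.0, "B": 0.0}, chain_net, clamps={"A": 0.0})
        assert dx["B"] == pytest.approx(0.0, abs=1e-12)

    def test_pure_decay(self, chain_net):
        dx = rhs({"A": 0.0, "B": 0.5}, chain_net, clamps={"A": 0.0})
        assert dx["B"] == pytest.approx(-0.5)


class TestIntegrate:
    def test_chain_clamped_high(self, chain_net):
        ss = integrate_to_steady_state(
            chain_net, perturbation=PerturbationSpec(clamps={"A": 1.0})
        )
        assert ss.converged
        assert ss["A"] == 1.0
        assert ss["B"] == pytest.approx(1.0, abs=1e-5)

    def test_chain_clamped_low(self, chain_net):
        ss = integrate_to_steady_state(
            chain_net, perturbation=PerturbationSpec(clamps={"A": 0.0})
        )
        assert ss["B"] == pytest.approx(0.0, abs=1e-5)

    def test_chain_clamped_half_matches_root_finding(self, chain_net):
        # independent oracle: fixed point x* = phi(2/3) found by brentq on
        # the scalar closed form
        def residual(x):
            e5, es = np.exp(5.0), np.exp(-10.0 * (2.0 / 3.0 - 0.5))
            return (-e5 + es) / ((1 - e5) * (1 + es)) - x

        expected = optimize.brentq(residual, 0, 1, xtol=1e-12)
        ss = integrate_to_steady_state(
            chain_net, perturbation=PerturbationSpec(clamps={"A": 0.5})
        )
        assert ss["B"] == pytest.approx(expected, abs=1e-5)

    def test_non_convergence_returns_flag(self, chain_net):
        solver = SolverConfig(step=0.01, t_max=0.05)
        ss = integrate_to_steady_state(
            chain_net, perturbation=PerturbationSpec(clamps={"A": 1.0}),
            solver=solver,
        )
        assert not ss.converged
        assert ss.residual > solver.tol

    def test_clamps_pinned_exactly(self, fixture_net, fast_solver):
        ss = integrate_to_steady_state(
            fixture_net,
            perturbation=PerturbationSpec(clamps={"IL1B": 0.3, "TGFB": 0.8}),
            solver=fast_solver,
        )
        assert ss["IL1B"] == 0.3
        assert ss["TGFB"] == 0.8

    def test_nan_initial_state_raises(self, chain_net):
        bad = np.array([np.nan, 0.0])
        with pytest.raises(IntegrationError, match="node"):
            integrate_to_steady_state(chain_net, _initial_vector=bad)


class TestBaseline:
    def test_seeded_determinism(self, fixture_net, fast_solver):
        a = baseline(fixture_net, seed=0, solver=fast_solver)
        b = baseline(fixture_net, seed=0, solver=fast_solver)
        assert np.array_equal(a.values, b.values)

    def test_initial_condition_is_mersenne_twister(self, fixture_net):
        expected = np.random.RandomState(7).random_sample(len(fixture_net.node_ids))
        assert np.array_equal(
            baseline_initial_condition(fixture_net, 7), expected
        )

    def test_pure_decay_network_goes_to_zero(self):
        # no activators anywhere: under the decay policy every node empties
        net = RegulatoryNetwork(nodes=[])
        net.add_node(__import__("chondronet.network", fromlist=["Node"]).Node("A"))
        net.add_node(__import__("chondronet.network", fromlist=["Node"]).Node("B"))
        for seed in (0, 1, 5):
            ss = baseline(net, seed=seed, source_node_policy="decay")
            assert np.allclose(ss.values, 0.0, atol=1e-5)

    def test_negative_seed_rejected(self, fixture_net):
        with pytest.raises(ValueError):
            baseline(fixture_net, seed=-1)

    def test_toggle_bistability_matches_root_oracle(self, toggle_net):
        # independent oracle: solve the 2-node closed form directly
        def model(v):
            a, b = v
            act = lambda x: 2 * x / (1 + x)
            omega_a = act(a) * (1 - act(b))
            omega_b = act(b) * (1 - act(a))
            e5 = np.exp(5.0)
            phi = lambda w: (-e5 + np.exp(-10 * (w - 0.5))) / (
                (1 - e5) * (1 + np.exp(-10 * (w - 0.5)))
            )
            return [phi(omega_a) - a, phi(omega_b) - b]

        ss_high_a = integrate_to_steady_state(
            toggle_net,
            perturbation=PerturbationSpec(initial={"A": 0.9, "B": 0.1}),
        )
        ss_high_b = integrate_to_steady_state(
            toggle_net,
            perturbation=PerturbationSpec(initial={"A": 0.1, "B": 0.9}),
        )
        assert ss_high_a.converged and ss_high_b.converged
        # two distinct attractors
        assert abs(ss_high_a["A"] - ss_high_b["A"]) > 0.5
        for ss in (ss_high_a, ss_high_b):
            root = optimize.root(model, [ss["A"], ss["B"]], tol=1e-12)
            assert root.success
            assert np.allclose(root.x, [ss["A"], ss["B"]], atol=1e-5)


class TestResponse:
    def test_empty_perturbation_zero_delta(self, chain_net):
        # monostable system: both runs land on the same attractor
        resp = response(chain_net, perturbation=PerturbationSpec(),
                        source_node_policy="decay")
        assert np.allclose(resp.delta, 0.0, atol=1e-5)

    def test_chain_activation_delta_one(self, chain_net):
        resp = response(
            chain_net,
            perturbation=PerturbationSpec(clamps={"A": 1.0}),
            source_node_policy="decay",
        )
        assert resp["B"] == pytest.approx(1.0, abs=1e-4)

    def test_inhibitor_flips_self_sustained_node(self):
        net = RegulatoryNetwork(edges=[
            Edge("A", "B", Sign.INHIBITION),
            Edge("B", "B", Sign.ACTIVATION),
        ])
        # seed 7 draws A ~ 0.08, B ~ 0.78: the inhibitor decays away before
        # it can quench B, so the baseline has B self-sustained near 1
        resp = response(
            net, perturbation=PerturbationSpec(clamps={"A": 1.0}),
            seed=7, source_node_policy="decay",
        )
        # clamping the inhibitor high and restarting from 0 kills B
        assert resp["B"] == pytest.approx(-1.0, abs=1e-3)

    def test_non_convergence_carries_partials(self, chain_net):
        solver = SolverConfig(step=0.01, t_max=0.05)
        with pytest.raises(ConvergenceError) as err:
            response(chain_net,
                     perturbation=PerturbationSpec(clamps={"A": 1.0}),
                     solver=solver)
        assert err.value.baseline is not None
        assert err.value.perturbed is not None

    def test_delta_in_range(self, fixture_net, fast_solver):
        resp = response(
            fixture_net,
            perturbation=PerturbationSpec(clamps={"IL1B": 1.0}),
            solver=fast_solver,
        )
        assert np.all(resp.delta >= -1.0 - 1e-9)
        assert np.all(resp.delta <= 1.0 + 1e-9)


class TestPerturbationSpec:
    def test_range_checked(self):
        with pytest.raises(ValueError):
            PerturbationSpec(clamps={"A": 1.5})

    def test_no_overlap(self):
        with pytest.raises(ValueError, match="both"):
            PerturbationSpec(initial={"A": 0.5}, clamps={"A": 1.0})

    def test_string_round_trip(self):
        spec = PerturbationSpec(initial={"B": 0.25}, clamps={"A": 1.0})
        again = PerturbationSpec.from_string(spec.to_string())
        assert again == spec


class TestProperties:
    def test_boundedness_random_networks(self, fast_solver):
        # 200 random networks x random perturbations stay inside [0, 1]
        rng = np.random.default_rng(42)
        for case in range(200):
            spec = SyntheticSpec(
                n_nodes=int(rng.integers(4, 12)),
                edge_density=float(rng.uniform(0.1, 0.5)),
                activation_fraction=float(rng.uniform(0.2, 1.0)),
                seed=case,
            )
            net = generate_network(spec)
            nodes = list(net.node_ids)
            k = int(rng.integers(0, 3))
            chosen = rng.choice(nodes, size=k, replace=False)
            perturbation = PerturbationSpec(
                clamps={n: float(rng.integers(0, 2)) for n in chosen}
            )
            ss = integrate_to_steady_state(
                net, perturbation=perturbation, solver=fast_solver
            )  # the excursion guard raises if any step leaves [0, 1]
            assert np.all(ss.values >= 0.0) and np.all(ss.values <= 1.0)

    def test_fixed_point_consistency(self, fixture_net, fast_solver):
        ss = integrate_to_steady_state(
            fixture_net,
            perturbation=PerturbationSpec(clamps={"IL1B": 1.0}),
            solver=fast_solver,
        )
        assert ss.converged
        state = ss.as_dict()
        for node in fixture_net.node_ids:
            if node in ("IL1B",) or fixture_net.in_degree(node) == 0:
                continue
            omega = total_input(node, state, fixture_net)
            assert abs(activation(omega, 10.0) - state[node]) <= 10 * fast_solver.tol

    def test_solver_independence(self, fixture_net):
        rng = np.random.default_rng(7)
        nodes = list(fixture_net.node_ids)
        rk4 = SolverConfig(step=0.01, t_max=100.0)
        adaptive = SolverConfig(method="adaptive", t_max=100.0)
        for _ in range(20):
            chosen = rng.choice(nodes, size=2, replace=False)
            perturbation = PerturbationSpec(
                clamps={n: float(rng.uniform(0, 1)) for n in chosen}
            )
            ss_fixed = integrate_to_steady_state(
                fixture_net, perturbation=perturbation, solver=rk4
            )
            ss_adapt = integrate_to_steady_state(
                fixture_net, perturbation=perturbation, solver=adaptive
            )
            assert ss_fixed.converged and ss_adapt.converged
            assert np.max(np.abs(ss_fixed.values - ss_adapt.values)) <= 1e-6

    def test_doubling_t_max_is_stable(self, chain_net):
        base = integrate_to_steady_state(
            chain_net, perturbation=PerturbationSpec(clamps={"A": 0.7})
        )
        longer = integrate_to_steady_state(
            chain_net, perturbation=PerturbationSpec(clamps={"A": 0.7}),
            solver=SolverConfig(t_max=200.0),
        )
        assert np.max(np.abs(base.values - longer.values)) <= 1e-8


def test_parameters_validate():
    with pytest.raises(ValueError):
        NodeParameters(h=0.0)
    with pytest.raises(ValueError):
        NodeParameters(gamma_overrides={"A": -1.0})


def test_baseline_ensemble(fixture_net, fast_solver):
    from chondronet.dynamics import baseline_ensemble

    ensemble = baseline_ensemble(fixture_net, seeds=(0, 1, 2),
                                 solver=fast_solver)
    assert len(ensemble) == 3
    singles = [baseline(fixture_net, seed=s, solver=fast_solver)
               for s in (0, 1, 2)]
    for member, single in zip(ensemble, singles):
        assert np.array_equal(member.values, single.values)
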