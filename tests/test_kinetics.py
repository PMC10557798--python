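"""Exact kinetic mathematics: generators, KA diagrams, steady states,
dynamics, spectral rates, and the characteristic-polynomial identities."""

import itertools

import networkx as nx
import numpy as np
import pytest
import scipy.linalg
from scipy.integrate import solve_ivp

from kinn.exceptions import DomainError, SpecificationError, StructuralError
from kinn.kinetics import (
    KineticScheme,
    RateAssignment,
    StateOccupancy,
    activity,
    build_rate_matrix,
    cas9_cycle_scheme,
    char_poly_identities,
    enumerate_ka_diagrams,
    propagate,
    scheme_from_dict,
    scheme_to_dict,
    slow_eigen_rate,
    steady_state_ka,
    total_ka_weight,
)

from conftest import log_uniform_rates, random_strongly_connected_scheme


class TestRateMatrix:
    def test_cleavage_cycle_sparsity_and_signs(self, cycle4):
        """The 4-state cycle generator has the canonical sparsity pattern:
        no direct 0->3 transition, binding rate scaled by the reservoir."""
        vals = {"k01": 2.0, "k10": 3.0, "k12": 5.0, "k21": 7.0,
                "k23": 11.0, "k32": 13.0, "k30": 17.0}
        scheme = cas9_cycle_scheme(4, reservoir_concentration=4.0)
        K = build_rate_matrix(scheme, RateAssignment(vals), True).matrix
        Du = 4.0
        expected = np.array([
            [-vals["k01"] * Du, vals["k10"], 0.0, vals["k30"]],
            [vals["k01"] * Du, -(vals["k10"] + vals["k12"]), vals["k21"], 0.0],
            [0.0, vals["k12"], -(vals["k21"] + vals["k23"]), vals["k32"]],
            [0.0, 0.0, vals["k23"], -(vals["k30"] + vals["k32"])],
        ])
        np.testing.assert_allclose(K, expected)

    def test_conservative_columns_sum_to_zero(self, rng):
        for n in (3, 4, 5, 6):
            scheme = random_strongly_connected_scheme(rng, n)
            rates = log_uniform_rates(rng, scheme)
            K = build_rate_matrix(scheme, rates, True).matrix
            scale = np.abs(K).max()
            np.testing.assert_allclose(K.sum(axis=0), 0.0, atol=1e-12 * scale)

    def test_nonconservative_cuts_only_return_entries(self, cycle4, rng):
        """K' equals K except the return entry of each activity edge,
        element-wise against an independently hand-built matrix."""
        rates = log_uniform_rates(rng, cycle4, -1, 1)
        K = build_rate_matrix(cycle4, rates, True).matrix
        Kp = build_rate_matrix(cycle4, rates, False).matrix
        oracle = K.copy()
        oracle[0, 3] = 0.0  # cut edge 3->0: remove flux into state 0
        np.testing.assert_allclose(Kp, oracle)

    def test_missing_and_nonpositive_rates_rejected(self, cycle4):
        with pytest.raises(SpecificationError):
            build_rate_matrix(
                cycle4, RateAssignment({"k01": 1.0}), True
            )
        with pytest.raises(DomainError):
            RateAssignment({"k01": -1.0})


class TestDiagramEnumeration:
    def test_two_state_scheme(self):
        scheme = KineticScheme(n_states=2, edges=((0, 1), (1, 0)))
        ds = enumerate_ka_diagrams(scheme)
        by_terminal = {d.terminal_state: d.edges for d in ds.diagrams}
        assert by_terminal == {0: frozenset({(1, 0)}), 1: frozenset({(0, 1)})}

    def test_three_state_chain_weights(self):
        """Reversible linear chain: one diagram per terminal with the
        textbook weights k10*k21, k01*k21, k01*k12."""
        scheme = KineticScheme(
            n_states=3, edges=((0, 1), (1, 0), (1, 2), (2, 1))
        )
        vals = {"k01": 2.0, "k10": 3.0, "k12": 5.0, "k21": 7.0}
        ds = enumerate_ka_diagrams(scheme)
        assert ds.n_diagrams == 3
        logw = ds.log_weights(np.log([vals[s] for s in scheme.edge_symbols]))
        weights = {int(t): float(np.exp(w))
                   for t, w in zip(ds.terminal_states, logw)}
        assert weights == pytest.approx({
            0: vals["k10"] * vals["k21"],
            1: vals["k01"] * vals["k21"],
            2: vals["k01"] * vals["k12"],
        })

    @staticmethod
    def _brute_force_diagrams(scheme):
        """Independent enumeration straight from the diagram definition:
        n-1 scheme edges, undirected-acyclic, out-degree <= 1, all paths
        ending at a single terminal."""
        found = set()
        for combo in itertools.combinations(scheme.edges, scheme.n_states - 1):
            out = {}
            ok = True
            for a, b in combo:
                if a in out:
                    ok = False
                    break
                out[a] = b
            if not ok:
                continue
            und = nx.Graph(list(combo))
            und.add_nodes_from(range(scheme.n_states))
            if len(und.edges) != scheme.n_states - 1 or not nx.is_forest(und):
                continue
            terminals = [s for s in range(scheme.n_states) if s not in out]
            if len(terminals) != 1 or not nx.is_connected(und):
                continue
            found.add((frozenset(combo), terminals[0]))
        return found

    def test_matches_brute_force_up_to_five_states(self, rng):
        for n in (3, 4, 5):
            for _ in range(5):
                scheme = random_strongly_connected_scheme(rng, n)
                ds = enumerate_ka_diagrams(scheme)
                got = {(d.edges, d.terminal_state) for d in ds.diagrams}
                assert got == self._brute_force_diagrams(scheme)

    def test_binary_matrix_rows_consistent(self, cycle4):
        ds = enumerate_ka_diagrams(cycle4)
        assert (ds.binary_matrix.sum(axis=1) == cycle4.n_states - 1).all()
        for row, diag in zip(ds.binary_matrix, ds.diagrams):
            cols = {cycle4.edges[i] for i in np.flatnonzero(row)}
            assert cols == set(diag.edges)
        # diagrams pairwise distinct
        assert len({(d.edges, d.terminal_state) for d in ds.diagrams}) == ds.n_diagrams

    def test_disconnected_scheme_rejected(self):
        scheme = KineticScheme(n_states=3, edges=((0, 1), (1, 0), (1, 2)))
        with pytest.raises(StructuralError, match="2"):
            enumerate_ka_diagrams(scheme)


class TestSteadyState:
    def test_symmetric_scheme_is_uniform(self):
        """A fully reversible cycle with equal rates has equal diagram
        counts per terminal, hence uniform occupancy."""
        scheme = KineticScheme(
            n_states=3,
            edges=((0, 1), (1, 0), (1, 2), (2, 1), (2, 0), (0, 2)),
        )
        rates = RateAssignment({s: 2.5 for s in scheme.edge_symbols})
        ss = steady_state_ka(scheme, rates)
        np.testing.assert_allclose(ss.vector, 1.0 / 3.0)

    def test_two_state_detailed_balance(self):
        scheme = KineticScheme(n_states=2, edges=((0, 1), (1, 0)))
        ss = steady_state_ka(scheme, RateAssignment({"k01": 2.0, "k10": 1.0}))
        np.testing.assert_allclose(ss.vector, [1 / 3, 2 / 3])

    def test_matches_null_space_across_random_schemes(self, rng):
        """KA diagram sums equal the kernel of the conservative generator
        even with rates spanning six decades (log-space weights)."""
        for _ in range(50):
            n = int(rng.integers(4, 7))
            scheme = random_strongly_connected_scheme(rng, n)
            rates = log_uniform_rates(rng, scheme, -3, 3)
            ka = steady_state_ka(scheme, rates)
            K = build_rate_matrix(scheme, rates, True).matrix
            kernel = scipy.linalg.null_space(K)
            assert kernel.shape[1] == 1
            v = np.abs(kernel[:, 0])
            v /= v.sum()
            np.testing.assert_allclose(ka.vector, v, atol=1e-9)


class TestDynamics:
    def test_zero_time_is_identity(self, cycle4, rng):
        rates = log_uniform_rates(rng, cycle4, -1, 1)
        s0 = StateOccupancy(rng.dirichlet(np.ones(4)))
        np.testing.assert_allclose(
            propagate(cycle4, rates, s0, 0.0).vector, s0.vector
        )

    def test_long_time_reaches_steady_state(self, cycle4, rng):
        rates = log_uniform_rates(rng, cycle4, -1, 1)
        slowest = min(rates.values.values())
        s0 = StateOccupancy(np.array([1.0, 0.0, 0.0, 0.0]))
        far = propagate(cycle4, rates, s0, 1e6 / slowest)
        ss = steady_state_ka(cycle4, rates)
        np.testing.assert_allclose(far.vector, ss.vector, atol=1e-6)

    def test_matches_ode_integration(self, cycle4, rng):
        for _ in range(10):
            rates = log_uniform_rates(rng, cycle4, -2, 2)
            s0 = StateOccupancy(rng.dirichlet(np.ones(4)))
            t = float(rng.uniform(0.05, 2.0))
            K = build_rate_matrix(cycle4, rates, True).matrix
            sol = solve_ivp(lambda _, y: K @ y, (0.0, t), s0.vector,
                            rtol=1e-11, atol=1e-13)
            got = propagate(cycle4, rates, s0, t)
            np.testing.assert_allclose(got.vector, sol.y[:, -1], atol=1e-7)
            assert got.vector.sum() == pytest.approx(1.0, abs=1e-9)

    def test_negative_time_rejected(self, cycle4, unit_rates):
        with pytest.raises(DomainError):
            propagate(cycle4, unit_rates, StateOccupancy(np.full(4, 0.25)), -1.0)


class TestActivity:
    def test_single_edge_flux(self, cycle4):
        rates = RateAssignment(dict(
            k01=1.0, k10=1.0, k12=1.0, k21=1.0, k23=1.0, k32=1.0, k30=0.5))
        occ = StateOccupancy(np.array([0.3, 0.3, 0.2, 0.2]))
        assert activity(cycle4, rates, occ) == pytest.approx(0.5 * 0.2)

    def test_linearity_over_activity_edges(self, rng):
        base = cas9_cycle_scheme(4)
        two_act = KineticScheme(
            n_states=4, edges=base.edges,
            activity_edges=((3, 0), (2, 3)),
            reservoir_concentration=1.0, binding_edge=(0, 1),
        )
        one_a = KineticScheme(n_states=4, edges=base.edges,
                              activity_edges=((3, 0),),
                              reservoir_concentration=1.0, binding_edge=(0, 1))
        one_b = KineticScheme(n_states=4, edges=base.edges,
                              activity_edges=((2, 3),),
                              reservoir_concentration=1.0, binding_edge=(0, 1))
        rates = log_uniform_rates(rng, base, -1, 1)
        occ = StateOccupancy(rng.dirichlet(np.ones(4)))
        assert activity(two_act, rates, occ) == pytest.approx(
            activity(one_a, rates, occ) + activity(one_b, rates, occ)
        )

    def test_no_activity_edges_rejected(self, rng):
        scheme = KineticScheme(n_states=2, edges=((0, 1), (1, 0)))
        with pytest.raises(SpecificationError):
            activity(scheme, RateAssignment({"k01": 1.0, "k10": 1.0}),
                     StateOccupancy(np.array([0.5, 0.5])))


class TestSlowEigenRate:
    def test_two_state_irreversible_single_exponential(self):
        """A single irreversible step decays at its own rate; the exactly
        conserved product mode (eigenvalue 0) is not the answer."""
        scheme = KineticScheme(n_states=2, edges=((0, 1),),
                               activity_edges=((0, 1),))
        rate = slow_eigen_rate(scheme, RateAssignment({"k01": 0.3}))
        assert rate == pytest.approx(0.3)

    def test_conservative_generator_has_zero_mode(self, cycle4, rng):
        rates = log_uniform_rates(rng, cycle4, -1, 1)
        K = build_rate_matrix(cycle4, rates, True).matrix
        eigvals = np.linalg.eigvals(K)
        assert np.abs(eigvals).min() < 1e-12 * np.abs(K).max()

    def test_rate_limiting_cut_approximates_activity(self, cycle4, rng):
        """When the cut step is orders slower than the rest, the slow
        eigen-rate collapses onto the steady-state activity a0/a1."""
        for _ in range(20):
            vals = dict(zip(cycle4.edge_symbols, 10 ** rng.uniform(-1, 1, 7)))
            vals["k30"] = min(v for k, v in vals.items() if k != "k30") / 500.0
            rates = RateAssignment(vals)
            lam = slow_eigen_rate(cycle4, rates)
            nu = activity(cycle4, rates, steady_state_ka(cycle4, rates))
            assert abs(lam - nu) / lam < 0.05


class TestCharPolyIdentities:
    def test_unit_rates(self, cycle4, unit_rates):
        rec = char_poly_identities(cycle4, unit_rates)
        assert rec["det_Kprime"] == pytest.approx(1.0)
        assert rec["cycle_product"] == pytest.approx(1.0)
        assert rec["det_K"] == 0.0

    def test_determinant_equals_forward_cycle_product(self, cycle4, rng):
        for _ in range(30):
            rates = log_uniform_rates(rng, cycle4, -3, 3)
            rec = char_poly_identities(cycle4, rates)
            assert rec["det_K"] == pytest.approx(0.0, abs=1e-12)
            assert rec["det_Kprime"] == pytest.approx(
                rec["cycle_product"], rel=1e-10)

    def test_linear_coefficient_equals_total_ka_weight(self, cycle4, rng):
        for _ in range(30):
            rates = log_uniform_rates(rng, cycle4, -2, 2)
            rec = char_poly_identities(cycle4, rates)
            sigma = total_ka_weight(cycle4, rates)
            assert rec["a1_K"] == pytest.approx(sigma, rel=1e-10)
            assert rec["a1_Kprime"] == pytest.approx(sigma, rel=1e-10)

    def test_wrong_topology_rejected(self):
        scheme = KineticScheme(n_states=3, edges=((0, 1), (1, 0), (1, 2), (2, 1),
                                                  (2, 0)),
                               activity_edges=((2, 0),))
        rates = RateAssignment({s: 1.0 for s in scheme.edge_symbols})
        with pytest.raises(SpecificationError):
            char_poly_identities(scheme, rates)


def test_scheme_json_round_trip(cycle4):
    again = scheme_from_dict(scheme_to_dict(cycle4))
    assert again == cycle4
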