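"""Entanglement, distinguishability, backflow and coherence measures."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import random_density_matrix, random_unitary

from spinshield import (
    MetricTrajectory,
    ModelParams,
    bell_state,
    blp_witness,
    block_coherence_decomposition,
    build_geometry,
    l1_coherence,
    log_negativity,
    negativity,
    nonmarkovianity_trajectory,
    relative_entropy_coherence,
    survival_time,
    time_grid,
    trace_distance,
)


def werner_state(p):
    phi = np.zeros(4, dtype=complex)
    phi[0] = phi[3] = 1 / np.sqrt(2)
    return p * np.outer(phi, phi.conj()) + (1 - p) * np.eye(4) / 4


class TestNegativity:
    def test_bell_state_values(self):
        assert negativity(bell_state()) == pytest.approx(0.5, abs=1e-12)
        assert log_negativity(bell_state()) == pytest.approx(1.0, abs=1e-12)

    def test_product_state_is_ppt(self, rng):
        rho = np.kron(random_density_matrix(rng, 2), random_density_matrix(rng, 2))
        assert negativity(rho) == pytest.approx(0.0, abs=1e-12)
        assert log_negativity(rho) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("p", [0.0, 1 / 3, 0.5, 0.9])
    def test_werner_closed_form(self, p):
        # N = max(0, (3p-1)/4), from the partial transpose's single possibly
        # negative eigenvalue (1 - 3p)/4
        expected = max(0.0, (3 * p - 1) / 4)
        assert negativity(werner_state(p)) == pytest.approx(expected, abs=1e-12)

    def test_werner_half_log_negativity(self):
        assert log_negativity(werner_state(0.5)) == pytest.approx(
            np.log2(1.25), abs=1e-12)

    def test_rejects_nonpositive_input(self):
        bad = np.diag([1.5, -0.5, 0.0, 0.0]).astype(complex)
        with pytest.raises(ValueError):
            negativity(bad)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_invariant_under_local_unitaries(self, seed):
        rng = np.random.default_rng(seed)
        rho = werner_state(0.8)
        u = np.kron(random_unitary(rng, 2), random_unitary(rng, 2))
        rotated = u @ rho @ u.conj().T
        assert log_negativity(rotated) == pytest.approx(
            log_negativity(rho), abs=1e-10)


class TestSurvivalTime:
    def test_never_below_threshold_gives_none(self):
        traj = MetricTrajectory(np.linspace(0, 10, 50), np.full(50, 0.5))
        assert survival_time(traj).t1 is None

    def test_exponential_decay_crossing(self):
        # E_N = exp(-t/tau): oracle = brute-force scan for the last grid
        # point at or above threshold
        tau, thr = 100.0, 1e-4
        t = np.linspace(0.0, 2000.0, 4001)
        v = np.exp(-t / tau)
        expected = None
        for k in range(len(t)):
            if np.all(v[k:] < thr):
                expected = t[k]
                break
        rec = survival_time(MetricTrajectory(t, v), threshold=thr)
        assert rec.t1 == pytest.approx(expected)
        assert rec.t1 == pytest.approx(tau * np.log(1e4), abs=1.0)

    def test_revival_uses_last_crossing(self):
        # dips below threshold at t=30, revives above at t=50, dies at t=80
        t = np.linspace(0.0, 100.0, 1001)
        v = np.where(t < 30, 1.0, 0.0)
        v = v + np.where((t >= 50) & (t <= 80), 0.01, 0.0)
        rec = survival_time(MetricTrajectory(t, v), threshold=1e-4)
        first = survival_time(MetricTrajectory(t, v), threshold=1e-4, rule="first")
        assert rec.t1 == pytest.approx(t[t > 80][0])
        assert first.t1 == pytest.approx(t[t >= 30][0])

    @given(st.floats(min_value=1e-6, max_value=0.5),
           st.floats(min_value=1.01, max_value=10.0))
    def test_monotone_in_threshold(self, thr, factor):
        t = np.linspace(0.0, 50.0, 400)
        v = np.exp(-t / 3.0) * (1 + 0.5 * np.cos(4 * t))
        lo = survival_time(MetricTrajectory(t, v), threshold=thr).t1
        hi = survival_time(MetricTrajectory(t, v), threshold=thr * factor).t1
        if lo is not None and hi is not None:
            assert hi <= lo
        elif lo is None:
            assert hi is None or hi >= 0  # larger threshold can only resolve earlier


class TestTraceDistance:
    def test_bloch_vector_closed_form(self):
        def bloch(rz):
            return np.array([[0.5 * (1 + rz), 0], [0, 0.5 * (1 - rz)]],
                            dtype=complex)
        assert trace_distance(bloch(0.6), bloch(0.2)) == pytest.approx(0.2, abs=1e-12)

    def test_identical_states(self, rng):
        rho = random_density_matrix(rng, 4)
        assert trace_distance(rho, rho) == 0.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            trace_distance(np.eye(2) / 2, np.eye(4) / 4)

    def test_contractive_under_channels(self, complete2, default_params, rng):
        from spinshield import apply_choi, central_spin_channel
        ch = central_spin_channel(complete2, default_params, time_grid(120.0, 7))
        a = random_density_matrix(rng, 2)
        b = random_density_matrix(rng, 2)
        d0 = trace_distance(a, b)
        for j in ch.chois:
            assert trace_distance(apply_choi(j, a), apply_choi(j, b)) <= d0 + 1e-8


class TestNonMarkovianity:
    def test_trajectory_properties(self, complete2, default_params):
        traj = nonmarkovianity_trajectory(complete2, default_params,
                                          time_grid(400.0, 80))
        assert traj.values[0] == pytest.approx(1.0, abs=1e-10)
        assert np.all(traj.values >= -1e-10)
        assert np.all(traj.values <= 1.0 + 1e-10)

    def test_unitary_case_keeps_distance_one(self, complete2):
        p = ModelParams(g=0.0, gamma=0.0)
        traj = nonmarkovianity_trajectory(complete2, p, time_grid(50.0, 20))
        assert np.allclose(traj.values, 1.0, atol=1e-10)

    def test_cluster_reduction_is_monotone(self, complete2, default_params):
        # the whole cluster evolves under an exact semigroup, so the
        # cluster-level distance can only contract
        traj = nonmarkovianity_trajectory(complete2, default_params,
                                          time_grid(400.0, 60),
                                          reduce_to="cluster")
        assert blp_witness(traj) == pytest.approx(0.0, abs=1e-9)

    def test_central_reduction_shows_backflow(self, complete2, default_params):
        traj = nonmarkovianity_trajectory(complete2, default_params,
                                          time_grid(400.0, 200))
        assert blp_witness(traj) > 0.01


class TestBlpWitness:
    def test_monotone_and_constant_fixtures_are_zero(self):
        t = np.arange(5.0)
        assert blp_witness(MetricTrajectory(t, np.array([1.0, 0.8, 0.5, 0.2, 0.1]))) == 0.0
        assert blp_witness(MetricTrajectory(t, np.full(5, 0.3))) == 0.0

    def test_sawtooth_sums_positive_increments(self):
        t = np.arange(5.0)
        v = np.array([1.0, 0.5, 0.8, 0.2, 0.4])
        assert blp_witness(MetricTrajectory(t, v)) == pytest.approx(0.5, abs=1e-14)

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0),
                    min_size=2, max_size=30))
    def test_nonnegative_and_bounds_total_rise(self, values):
        v = np.asarray(values)
        w = blp_witness(MetricTrajectory(np.arange(len(v), dtype=float), v))
        assert w >= 0.0
        assert w >= v[-1] - v[0] - 1e-12


class TestCoherence:
    def test_diagonal_states_have_zero_coherence(self, rng):
        d = np.diag(rng.dirichlet(np.ones(4))).astype(complex)
        assert l1_coherence(d) == pytest.approx(0.0, abs=1e-14)
        assert relative_entropy_coherence(d) == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("d", [2, 3, 5])
    def test_uniform_superposition_extremes(self, d):
        psi = np.full(d, 1 / np.sqrt(d), dtype=complex)
        rho = np.outer(psi, psi.conj())
        assert l1_coherence(rho) == pytest.approx(d - 1, abs=1e-12)
        assert relative_entropy_coherence(rho) == pytest.approx(
            np.log2(d), abs=1e-10)

    def test_plus_state_one_bit(self):
        plus = np.full((2, 2), 0.5, dtype=complex)
        assert l1_coherence(plus) == pytest.approx(1.0, abs=1e-14)
        assert relative_entropy_coherence(plus) == pytest.approx(1.0, abs=1e-10)

    def test_basis_change(self):
        plus = np.full((2, 2), 0.5, dtype=complex)
        hadamard = np.array([[1, 1], [1, -1]]) / np.sqrt(2)
        # |+> is incoherent in the x basis
        assert l1_coherence(plus, basis=hadamard) == pytest.approx(0.0, abs=1e-14)

    def test_zero_iff_diagonal(self, rng):
        rho = random_density_matrix(rng, 3)
        if np.abs(rho - np.diag(np.diag(rho))).max() > 1e-6:
            assert l1_coherence(rho) > 1e-6
            assert relative_entropy_coherence(rho) > 1e-9


class TestBlockCoherence:
    def test_product_of_diagonal_states_all_zero(self):
        rho = np.kron(np.diag([0.3, 0.7]), np.diag([0.6, 0.4])).astype(complex)
        out = block_coherence_decomposition(rho, [2, 2], [0])
        assert np.allclose(out, 0.0, atol=1e-12)

    def test_bell_state_is_purely_interblock(self):
        phi = np.zeros(4, dtype=complex)
        phi[0] = phi[3] = 1 / np.sqrt(2)
        rho = np.outer(phi, phi.conj())
        c_ab, c_a, c_b, inter = block_coherence_decomposition(rho, [2, 2], [0])
        assert c_ab == pytest.approx(1.0, abs=1e-12)
        assert c_a == pytest.approx(0.0, abs=1e-12)
        assert c_b == pytest.approx(0.0, abs=1e-12)
        assert inter == pytest.approx(1.0, abs=1e-12)

    def test_product_of_plus_states(self):
        plus = np.full((2, 2), 0.5, dtype=complex)
        rho = np.kron(plus, plus)
        c_ab, c_a, c_b, inter = block_coherence_decomposition(rho, [2, 2], [0])
        # l1 on products obeys (1 + C_A)(1 + C_B) - 1
        assert c_ab == pytest.approx(3.0, abs=1e-12)
        assert c_a == pytest.approx(1.0, abs=1e-12)
        assert c_b == pytest.approx(1.0, abs=1e-12)
        assert inter == pytest.approx(1.0, abs=1e-12)

    def test_relative_entropy_variant(self):
        phi = np.zeros(4, dtype=complex)
        phi[0] = phi[3] = 1 / np.sqrt(2)
        rho = np.outer(phi, phi.conj())
        c_ab, c_a, c_b, inter = block_coherence_decomposition(
            rho, [2, 2], [0], measure="relative_entropy")
        assert c_ab == pytest.approx(1.0, abs=1e-10)
        assert inter == pytest.approx(1.0, abs=1e-10)

    def test_invalid_partition_rejected(self):
        rho = np.eye(4, dtype=complex) / 4
        with pytest.raises(ValueError):
            block_coherence_decomposition(rho, [2, 2], [0, 1])


class TestEntanglementDecayOrdering:
    def test_connected_buffers_protect_longer_small_n(self, default_params):
        # scaled-down version of the survival comparison: at N=3 the complete
        # buffer graph holds E_N above threshold longer than the star
        from spinshield.experiments import entanglement_trajectory
        times = time_grid(3000.0, 600)
        t1 = {}
        for conn in ("vanishing", "maximal"):
            geo = build_geometry(3, conn)
            traj = entanglement_trajectory(geo, default_params, times)
            t1[conn] = survival_time(traj, geometry=geo).t1
        assert t1["maximal"] is not None and t1["vanishing"] is not None
        assert t1["maximal"] > t1["vanishing"]
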