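"""Neural-gas training: scaling, ranking, annealing, refinement, Hessians."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import hessgas as hg
from hessgas.ngas import (
    GasSchedule, NeuronSet, anneal, assign_voronoi, centroid_refine,
    fit_scaling, init_neurons, ngas_run, rank_neurons, train_epoch,
    train_ngas, voronoi_energy, build_extended_training_space,
)


class TestScaling:
    def test_affine_map_example(self):
        sm = fit_scaling(np.array([[-1.0], [0.0], [3.0]]))
        assert np.allclose(sm.forward(np.array([[-1.0], [0.0], [3.0]])).ravel(),
                           [0.0, 0.25, 1.0])

    def test_degenerate_column_maps_to_half(self):
        sm = fit_scaling(np.array([[2.0], [2.0], [2.0]]))
        assert np.allclose(sm.forward(np.array([2.0])), 0.5)
        assert sm.inverse(np.array([0.5]))[0] == 2.0

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_round_trip(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(7, 3)) * rng.uniform(0.1, 50)
        sm = fit_scaling(pts)
        back = np.array([sm.inverse(sm.forward(p)) for p in pts])
        assert np.max(np.abs(back - pts)) < 1e-12 * max(1.0, np.abs(pts).max())

    def test_forward_maps_training_set_into_unit_box(self):
        pts = np.random.default_rng(0).normal(size=(50, 4)) * 12
        sm = fit_scaling(pts)
        Q = sm.forward(pts)
        assert Q.min() >= 0.0 and Q.max() <= 1.0

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            fit_scaling(np.array([[1.0], [np.inf]]))


class TestInitAndRank:
    def test_stride_indices(self):
        pts = np.arange(10, dtype=float)[:, None]
        sm = fit_scaling(pts)
        neurons = init_neurons(sm.forward(pts), 2, sm)
        assert np.allclose(neurons.scaled_positions.ravel(),
                           sm.forward(pts)[[0, 5]].ravel())

    def test_saturation_and_budget_error(self):
        pts = np.random.default_rng(1).uniform(size=(6, 2))
        sm = fit_scaling(pts)
        sat = init_neurons(sm.forward(pts), 6, sm)
        assert np.allclose(sat.scaled_positions, sm.forward(pts))
        with pytest.raises(ValueError):
            init_neurons(sm.forward(pts), 7, sm)

    def test_150_neurons_over_3000_steps_use_stride_20(self):
        pts = np.linspace(0, 1, 3000)[:, None]
        sm = fit_scaling(pts)
        neurons = init_neurons(sm.forward(pts), 150, sm)
        # neuron j sits on step 20·j
        assert np.allclose(neurons.scaled_positions.ravel(),
                           sm.forward(pts)[::20].ravel())

    def test_rank_examples(self):
        sm = fit_scaling(np.zeros((1, 1)))
        neurons = NeuronSet(scaled_positions=[[0.5], [0.1], [0.2]], scaling=sm)
        assert rank_neurons(np.array([0.0]), neurons).tolist() == [2, 0, 1]
        single = NeuronSet(scaled_positions=[[0.3]], scaling=sm)
        assert rank_neurons(np.array([0.0]), single).tolist() == [0]
        tie = NeuronSet(scaled_positions=[[1.0], [-1.0]], scaling=sm)
        assert rank_neurons(np.array([0.0]), tie).tolist() == [0, 1]


class TestAnneal:
    @pytest.mark.parametrize("n_epochs", [1, 7, 40])
    def test_endpoints_exact(self, n_epochs):
        sched = GasSchedule(n_epochs=n_epochs)
        assert anneal(sched, "alpha", 0) == 0.3
        assert anneal(sched, "alpha", n_epochs) == pytest.approx(0.05, abs=0)
        assert anneal(sched, "lambda", 0) == 30.0
        assert anneal(sched, "lambda", n_epochs) == pytest.approx(0.01, abs=0)

    def test_geometric_midpoint(self):
        sched = GasSchedule(n_epochs=40)
        assert anneal(sched, "alpha", 20) == pytest.approx(
            np.sqrt(0.3 * 0.05), rel=1e-12)

    def test_schedule_validation(self):
        with pytest.raises(ValueError):
            GasSchedule(alpha_final=0.4)
        with pytest.raises(ValueError):
            GasSchedule(lambda_init=-1.0)


class TestTrainEpoch:
    def _one_point_setup(self, neuron_pos):
        sm = fit_scaling(np.zeros((1, 1)))
        return NeuronSet(scaled_positions=neuron_pos, scaling=sm)

    def test_rank0_update_moves_by_alpha(self):
        neurons = self._one_point_setup([[0.0]])
        sched = GasSchedule(alpha_init=0.3, alpha_final=0.3,
                            lambda_init=1.0, lambda_final=1.0, n_epochs=1)
        train_epoch(neurons, np.array([[1.0]]), sched, 0,
                    np.random.default_rng(0))
        assert neurons.scaled_positions[0, 0] == pytest.approx(0.3)

    def test_rank1_update_attenuated_by_neighbourhood(self):
        # second neuron on top of the data point wins rank 0; the far
        # neuron at 0 has K=1 and moves by alpha·e^{−1/λ}·distance
        neurons = self._one_point_setup([[0.0], [1.0]])
        sched = GasSchedule(alpha_init=0.3, alpha_final=0.3,
                            lambda_init=1.0, lambda_final=1.0, n_epochs=1)
        train_epoch(neurons, np.array([[1.0]]), sched, 0,
                    np.random.default_rng(0))
        assert neurons.scaled_positions[0, 0] == pytest.approx(
            0.3 * np.exp(-1.0), rel=1e-12)

    def test_vanishing_alpha_leaves_neurons_in_place(self):
        neurons = self._one_point_setup([[0.0]])
        sched = GasSchedule(alpha_init=1e-300, alpha_final=1e-300,
                            lambda_init=1.0, lambda_final=1.0, n_epochs=1)
        train_epoch(neurons, np.array([[1.0]]), sched, 0,
                    np.random.default_rng(0))
        assert abs(neurons.scaled_positions[0, 0]) < 1e-250

    def test_frozen_gas_updates_only_rank0_neuron(self):
        # at the final epoch λ = 0.01 → e^{−1/λ} ~ e^{−100}: only the
        # nearest neuron moves by more than machine noise
        sched = GasSchedule()
        lam = anneal(sched, "lambda", sched.n_epochs)
        weights = np.exp(-np.arange(1, 10) / lam)
        assert np.all(weights < 1e-12)

    def test_training_deterministic_under_seed(self, quartic3):
        _, _, traj = quartic3
        a, _, _ = train_ngas(traj.positions[:300], 20, GasSchedule(seed=9))
        b, _, _ = train_ngas(traj.positions[:300], 20, GasSchedule(seed=9))
        assert np.array_equal(a.scaled_positions, b.scaled_positions)

    def test_neurons_stay_near_unit_box(self, quartic3):
        _, _, traj = quartic3
        neurons, _, _ = train_ngas(traj.positions, 40, GasSchedule(seed=2))
        W = neurons.scaled_positions
        assert W.min() > -0.5 and W.max() < 1.5


class TestCentroidRefine:
    def test_centroid_example(self):
        sm = fit_scaling(np.zeros((1, 2)))
        neurons = NeuronSet(scaled_positions=[[0.0, 0.0]], scaling=sm)
        pts = np.array([[0.0, 0.0], [2.0, 4.0]])
        neurons, assignment = centroid_refine(neurons, pts)
        assert np.allclose(neurons.scaled_positions[0], [1.0, 2.0])

    def test_saturated_cells_land_on_trajectory(self):
        pts = np.random.default_rng(5).uniform(size=(8, 2))
        sm = fit_scaling(pts)
        Q = sm.forward(pts)
        neurons = init_neurons(Q, 8, sm)
        neurons, _ = centroid_refine(neurons, Q)
        assert np.allclose(np.sort(neurons.scaled_positions, axis=0),
                           np.sort(Q, axis=0))

    def test_quantization_error_never_increases(self):
        # the refinement target (cell centroid) minimizes the mean squared
        # member distance, so a single pass cannot raise the error
        for seed in range(50):
            rng = np.random.default_rng(seed)
            pts = rng.uniform(size=(rng.integers(10, 60), rng.integers(1, 5)))
            sm = fit_scaling(pts)
            Q = sm.forward(pts)
            neurons = init_neurons(Q, int(rng.integers(1, 8)), sm)
            # scramble neurons so the starting point is not already optimal
            neurons.scaled_positions += rng.normal(scale=0.2,
                                                   size=neurons.scaled_positions.shape)
            before = voronoi_energy(neurons, Q)
            neurons, _ = centroid_refine(neurons, Q)
            after = voronoi_energy(neurons, Q)
            assert after <= before + 1e-15

    def test_empty_cells_flagged_and_retained(self):
        sm = fit_scaling(np.zeros((1, 1)))
        neurons = NeuronSet(scaled_positions=[[0.0], [10.0]], scaling=sm)
        pts = np.array([[0.0], [0.1]])
        neurons, _ = centroid_refine(neurons, pts)
        assert neurons.empty_cells.tolist() == [False, True]
        assert neurons.scaled_positions[1, 0] == 10.0


class TestHessianAttachment:
    def test_harmonic_hessians_all_identical_and_budget_counted(self, harmonic6_traj):
        surf, _, traj = harmonic6_traj
        seq, neurons, assignment = ngas_run(traj, surf, 12)
        H0 = surf.hessian(traj.positions[0])
        assert np.allclose(neurons.hessians, H0[None])
        assert neurons.budget == 12
        assert np.allclose(seq, H0[None])

    def test_neuron_on_trajectory_matches_reference(self, quartic3):
        surf, _, traj = quartic3
        pts = traj.positions[:50]
        sm = hg.fit_scaling(pts)
        neurons = init_neurons(sm.forward(pts), 50, sm)  # on-trajectory init
        hg.attach_hessians(neurons, surf)
        for p, H in zip(pts, neurons.hessians):
            assert np.allclose(H, surf.hessian(p), atol=1e-12)

    def test_saturated_init_limit_zero_error(self, quartic3):
        # one neuron per step, no training drift: the assignment is the
        # identity and the approximation reproduces all-Hessians exactly
        surf, _, traj = quartic3
        sub = traj[:120]
        sm = hg.fit_scaling(sub.positions)
        Q = sm.forward(sub.positions)
        neurons = init_neurons(Q, 120, sm)
        neurons, assignment = centroid_refine(neurons, Q)
        hg.attach_hessians(neurons, surf)
        seq = hg.approximate_trajectory_hessians(neurons, assignment)
        ref = hg.exact_hessian_sequence(sub, surf)
        assert hg.sigma_hess(ref, seq).sigma_hess < 1e-14

    def test_single_neuron_shares_one_hessian(self, quartic3):
        surf, _, traj = quartic3
        seq, neurons, _ = ngas_run(traj[:200], surf, 1)
        assert np.allclose(seq, seq[0][None])

    def test_piecewise_constant_output(self, quartic3):
        surf, _, traj = quartic3
        seq, _, _ = ngas_run(traj[:300], surf, 7)
        uniq = np.unique(seq.reshape(seq.shape[0], -1), axis=0)
        assert uniq.shape[0] <= 7

    def test_failed_off_trajectory_evaluation_falls_back_to_member(self):
        # a surface that only evaluates on the trajectory's own grid points
        # forces the documented fallback: the neuron borrows the Hessian of
        # its nearest trajectory member, with a warning
        from hessgas.surfaces import PotentialSurface, SurfaceEvaluationError
        pts = np.linspace(0.0, 1.0, 11)[:, None]

        def picky_hessian(q):
            if not np.any(np.abs(pts.ravel() - q[0]) < 1e-9):
                raise SurfaceEvaluationError("off-grid")
            return np.array([[q[0]]])

        surf = PotentialSurface(n_dof=1, energy_at=lambda q: 0.0,
                                hessian_at=picky_hessian)
        sm = hg.fit_scaling(pts)
        Q = sm.forward(pts)
        neurons = init_neurons(Q, 2, sm)
        neurons.scaled_positions[:] = [[0.033], [0.71]]  # off-grid geometries
        with pytest.warns(UserWarning, match="falling back"):
            hg.attach_hessians(neurons, surf, scaled_points=Q,
                               original_points=pts)
        # nearest members of 0.033 and 0.71 are grid points 0.0 and 0.7
        assert neurons.hessians[0][0, 0] == pytest.approx(0.0)
        assert neurons.hessians[1][0, 0] == pytest.approx(0.7)

    def test_quadratic_sigma_zero_for_any_neuron_count(self, harmonic6_traj):
        surf, _, traj = harmonic6_traj
        ref = hg.exact_hessian_sequence(traj, surf)
        for n in (1, 3, 30):
            seq, _, _ = ngas_run(traj, surf, n)
            assert hg.sigma_hess(ref, seq).sigma_hess == 0.0


class TestExtendedSpace:
    def test_shape_is_twice_n_dof(self, quartic3):
        _, _, traj = quartic3
        ext = build_extended_training_space(traj)
        assert ext.shape == (traj.n_steps, 2 * traj.n_dof)

    def test_missing_gradients_signalled(self, quartic3):
        _, _, traj = quartic3
        bare = hg.TrajectoryRecord(dt=traj.dt, positions=traj.positions,
                                   momenta=traj.momenta, energies=traj.energies,
                                   coordinate_tag=traj.coordinate_tag)
        with pytest.raises(ValueError, match="coords"):
            build_extended_training_space(bare)

    def test_zero_gradient_block_degenerates_to_coordinate_clustering(self):
        surf = hg.builtin_surface("harmonic_nd", omega=[1.0, 2.0])
        # artificial trajectory with a zero gradient block: the extended
        # components are degenerate and clustering matches coordinates-only
        traj = hg.TrajectoryRecord(
            dt=1.0, positions=np.linspace(-1, 1, 40)[:, None] * [1.0, 0.0],
            momenta=np.zeros((40, 2)), energies=np.zeros(40),
            gradients=np.zeros((40, 2)), coordinate_tag="normal_mode")
        seq_c, _, a_c = ngas_run(traj, surf, 4, GasSchedule(seed=0),
                                 training_space="coords")
        seq_e, _, a_e = ngas_run(traj, surf, 4, GasSchedule(seed=0),
                                 training_space="coords_plus_gradients")
        assert np.array_equal(a_c.labels, a_e.labels)

    def test_budget_matches_neuron_count_in_extended_space(self, quartic3):
        surf, _, traj = quartic3
        seq, neurons, _ = ngas_run(traj[:200], surf, 10, GasSchedule(seed=1),
                                   training_space="coords_plus_gradients")
        assert neurons.budget == 10
        assert neurons.d_train == 2 * traj.n_dof


def test_budget_accuracy_monotone_trend(quartic3):
    surf, _, traj = quartic3
    sub = traj[:400]
    ref = hg.exact_hessian_sequence(sub, surf)
    medians = []
    for n in (1, 8, 40, 400):
        sig = [hg.sigma_hess(ref, ngas_run(sub, surf, n, GasSchedule(seed=s))[0]).sigma_hess
               for s in (0, 1, 2)]
        medians.append(np.median(sig))
    assert all(b <= a + 1e-15 for a, b in zip(medians, medians[1:]))
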