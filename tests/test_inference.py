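"""Trajectory -> pair potential pipeline."""

import numpy as np
import pandas as pd
import pytest

from memcurv import (
    SphereBrownianConfig,
    build_transition_matrix,
    geodesic_separation,
    infer_potential,
    potential_from_distribution,
    potential_from_histogram,
    reconstruct_3d,
    simulate_pair_on_sphere,
    stationary_distribution,
)
from memcurv.errors import InsufficientDataError, OutOfSphereError, UndefinedDirectionError
from memcurv.inference import TransitionMatrix, separation_series


def table_row(x, y, wrapped, R=10.0, frame=0, particle=0):
    return pd.DataFrame({
        "frame": [frame], "particle": [particle], "x_um": [x], "y_um": [y],
        "wrapped": [wrapped], "xc_um": [0.0], "yc_um": [0.0], "R_um": [R],
    })


class TestReconstruct3D:
    def test_particle_over_centre(self):
        out = reconstruct_3d(table_row(0.0, 0.0, wrapped=False), D_p=1.0)
        assert abs(out["z_rel"].iloc[0]) == pytest.approx(10.5)

    def test_wrapped_particle_inside(self):
        out = reconstruct_3d(table_row(0.0, 0.0, wrapped=True), D_p=1.0)
        assert abs(out["z_rel"].iloc[0]) == pytest.approx(9.5)

    def test_equatorial_point(self):
        out = reconstruct_3d(table_row(10.5, 0.0, wrapped=False), D_p=1.0)
        assert out["z_rel"].iloc[0] == pytest.approx(0.0)

    def test_small_excursion_clamped_large_raises(self):
        out = reconstruct_3d(table_row(10.6, 0.0, wrapped=False), D_p=1.0, slack=0.2)
        assert out["clamped"].iloc[0]
        assert np.hypot(out["x_rel"].iloc[0], out["y_rel"].iloc[0]) == pytest.approx(10.5)
        with pytest.raises(OutOfSphereError):
            reconstruct_3d(table_row(11.0, 0.0, wrapped=False), D_p=1.0, slack=0.2)

    def test_roundtrip_recovers_true_separations(self):
        """2-D projection -> reconstruction is exact on recorded frames."""
        cfg = SphereBrownianConfig(R=3.0, D=1.0, dt=0.05, n_steps=3000, seed=6)
        tab, truth = simulate_pair_on_sphere(cfg)
        series = separation_series(tab, D_p=cfg.D_p)
        got = np.concatenate(series)
        expected = truth["separations"][truth["same_hemisphere"]]
        assert np.allclose(got, expected, atol=1e-6)


class TestGeodesicSeparation:
    def test_identical_directions(self):
        assert geodesic_separation([0, 0, 5.0], [0, 0, 9.0], 10.0) == pytest.approx(0.0)

    def test_antipodal(self):
        assert geodesic_separation([0, 0, 1.0], [0, 0, -2.0], 10.0) == pytest.approx(10 * np.pi)

    def test_orthogonal_quarter_circle(self):
        assert geodesic_separation([1.0, 0, 0], [0, 3.0, 0], 10.0) == pytest.approx(5 * np.pi)

    def test_zero_vector_raises(self):
        with pytest.raises(UndefinedDirectionError):
            geodesic_separation([0.0, 0, 0], [1.0, 0, 0], 10.0)


class TestTransitionMatrix:
    def test_hand_counted_transitions(self):
        tm = build_transition_matrix(np.array([1.1, 2.1, 1.2]),
                                     np.array([1.0, 2.0, 3.0]), lag=1)
        assert tm.counts[0, 1] == 1
        assert tm.counts[1, 0] == 1
        assert tm.counts.sum() == 2

    def test_constant_series_identity_row(self):
        tm = build_transition_matrix(np.full(50, 1.5), np.array([1.0, 2.0, 3.0]), lag=1)
        P = tm.probabilities
        assert P[0, 0] == pytest.approx(1.0)
        assert 1 in tm.empty_rows

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        tm = build_transition_matrix(rng.uniform(0, 5, 500), np.linspace(0, 5, 11), lag=2)
        P = tm.probabilities
        nonzero = tm.counts.sum(axis=1) > 0
        assert np.allclose(P[nonzero].sum(axis=1), 1.0)

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            build_transition_matrix(np.array([1.0]), np.array([0.0, 2.0]), lag=1)


class TestStationaryDistribution:
    def test_single_bin(self):
        tm = build_transition_matrix(np.full(20, 0.5), np.array([0.0, 1.0, 2.0]), lag=1)
        pi = stationary_distribution(tm)
        assert pi[0] == pytest.approx(1.0)

    def test_two_state_balance(self):
        # equilibrium counts of the chain P = [[0.9, 0.1], [0.2, 0.8]],
        # whose stationary vector is (2/3, 1/3)
        C = np.array([[600, 67], [67, 266]])
        tm = TransitionMatrix(np.array([0.0, 1.0, 2.0]), C, 1)
        pi = stationary_distribution(tm)
        assert pi[0] == pytest.approx(2 / 3, abs=0.01)
        assert pi[1] == pytest.approx(1 / 3, abs=0.01)

    def test_doubly_stochastic_gives_uniform(self):
        C = np.full((4, 4), 25)
        tm = TransitionMatrix(np.linspace(0, 4, 5), C, 1)
        pi = stationary_distribution(tm)
        assert np.allclose(pi, 0.25)

    def test_reducible_chain_warns_and_uses_largest(self):
        C = np.zeros((4, 4), dtype=int)
        C[0, 1] = C[1, 0] = 50
        C[2, 3] = C[3, 2] = 5
        tm = TransitionMatrix(np.linspace(0, 4, 5), C, 1)
        with pytest.warns(RuntimeWarning):
            pi = stationary_distribution(tm)
        assert pi[:2].sum() == pytest.approx(1.0)
        assert pi[2:].sum() == pytest.approx(0.0)


class TestBoltzmannInversion:
    def test_ideal_gas_gives_zero_potential(self):
        edges = np.linspace(0.1, np.pi * 10 - 0.1, 30)
        s = 0.5 * (edges[:-1] + edges[1:])
        pi = np.sin(s / 10.0) * np.diff(edges)
        pi /= pi.sum()
        curve = potential_from_distribution(pi, edges, 10.0)
        assert np.allclose(curve.u, 0.0, atol=1e-12)

    def test_exact_algebraic_inversion(self):
        edges = np.linspace(0.1, np.pi * 10 - 0.1, 30)
        s = 0.5 * (edges[:-1] + edges[1:])
        v = -2.0 * np.exp(-0.5 * ((s - 8) / 2) ** 2)  # far field ~ 0
        pi = np.sin(s / 10.0) * np.diff(edges) * np.exp(-v)
        pi /= pi.sum()
        curve = potential_from_distribution(pi, edges, 10.0)
        assert np.allclose(curve.u, v, atol=1e-6)

    def test_far_field_average_is_zero(self):
        rng = np.random.default_rng(1)
        edges = np.linspace(0.1, np.pi * 5, 20)
        s = 0.5 * (edges[:-1] + edges[1:])
        pi = np.sin(s / 5.0) * rng.uniform(0.5, 2.0, len(s))
        pi /= pi.sum()
        curve = potential_from_distribution(pi, edges, 5.0)
        n_far = max(int(round(len(curve.u) / 3)), 1)
        assert np.nanmean(curve.u[-n_far:]) == pytest.approx(0.0, abs=1e-9)


class TestPipeline:
    @pytest.fixture(scope="class")
    def null_run(self):
        cfg = SphereBrownianConfig(R=2.0, D=1.0, dt=0.05, n_steps=15000, seed=21)
        tab, truth = simulate_pair_on_sphere(cfg)
        return tab, truth

    def test_null_potential_within_two_sigma(self, null_run):
        tab, _ = null_run
        curve = infer_potential(tab, D_p=1.0, bin_width=0.35, n_bootstrap=60, seed=0)
        good = np.isfinite(curve.u) & (curve.counts > 10)
        assert good.sum() >= 10
        assert np.all(np.abs(curve.u[good]) < 2.5 * np.maximum(curve.stderr[good], 0.1))

    def test_transition_and_histogram_routes_agree(self, null_run):
        """On equilibrated data the dynamics-based and occupancy-based
        estimates of u(s) coincide."""
        tab, _ = null_run
        series = separation_series(tab, D_p=1.0)
        edges = np.arange(0.0, 6.4, 0.4)
        tm = build_transition_matrix(series, edges, 1)
        pi = stationary_distribution(tm)
        cnt, _ = np.histogram(np.concatenate(series), edges)
        a = potential_from_distribution(pi, edges, 2.0, counts=cnt,
                                        hemisphere_censored=True)
        b = potential_from_histogram(series, edges, 2.0, hemisphere_censored=True)
        good = cnt > 30
        assert np.allclose(a.u[good], b.u[good], atol=0.2)

    def test_frame_shuffling_preserves_occupancy_potential(self, null_run):
        tab, _ = null_run
        series = separation_series(tab, D_p=1.0)
        edges = np.arange(0.0, 6.4, 0.4)
        cnt, _ = np.histogram(np.concatenate(series), edges)
        base = potential_from_distribution(
            stationary_distribution(build_transition_matrix(series, edges, 1)),
            edges, 2.0, counts=cnt, hemisphere_censored=True)
        rng = np.random.default_rng(0)
        shuffled = [rng.permutation(s) for s in series]
        shuf = potential_from_distribution(
            stationary_distribution(build_transition_matrix(shuffled, edges, 1)),
            edges, 2.0, counts=cnt, hemisphere_censored=True)
        good = cnt > 30
        assert np.allclose(base.u[good], shuf.u[good], atol=0.25)

    def test_rotation_invariance_of_inputs(self, null_run):
        tab, _ = null_run
        c0 = infer_potential(tab, D_p=1.0, bin_width=0.4, n_bootstrap=0)
        rot = tab.copy()
        th = 1.1
        x, y = rot["x_um"].to_numpy(), rot["y_um"].to_numpy()
        rot["x_um"] = np.cos(th) * x - np.sin(th) * y
        rot["y_um"] = np.sin(th) * x + np.cos(th) * y
        c1 = infer_potential(rot, D_p=1.0, bin_width=0.4, n_bootstrap=0)
        assert np.allclose(np.nan_to_num(c0.u), np.nan_to_num(c1.u), atol=1e-9)
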