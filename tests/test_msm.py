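"""Markov-model and landscape estimators against brute-force oracles."""

import itertools

import numpy as np
import pytest

from twistslide import msm
from twistslide.fixtures import markov_sampler, toy_well_sampler


class TestBoltzmannInvert:
    def test_uniform_samples_flat_profile(self, rng):
        fep = msm.boltzmann_invert(rng.uniform(0, 1, 200000), np.linspace(0, 1, 11))
        assert np.nanmax(np.abs(fep.F)) < 0.1

    def test_gaussian_recovers_harmonic_well(self, rng):
        fep = msm.boltzmann_invert(rng.normal(0, 1, 400000), np.linspace(-2, 2, 21))
        (c,) = fep.centers
        expect = 0.5 * c**2
        expect -= expect.min()
        assert np.nanmax(np.abs(fep.F - expect)) < 0.15

    def test_two_state_log_ratio(self, rng):
        samples = np.concatenate([np.zeros(75000), np.ones(25000)]) + rng.uniform(-0.1, 0.1, 100000)
        fep = msm.boltzmann_invert(samples, [np.array([-0.5, 0.5, 1.5])])
        assert fep.F[1] - fep.F[0] == pytest.approx(np.log(3), abs=0.05)

    def test_undersampled_bins_masked(self, rng):
        fep = msm.boltzmann_invert(rng.normal(0, 0.1, 1000), np.linspace(-3, 3, 31))
        assert np.isnan(fep.F[0]) and np.isnan(fep.F[-1])
        assert fep.counts[0] >= 0  # counts retained, never imputed


class TestDiscretize:
    def test_identity_on_prebinned(self):
        d, states = msm.discretize(np.array([0.5, 1.5, 0.5]), grid_edges=[np.array([0.0, 1.0, 2.0])])
        assert d.tolist() == [0, 1, 0]

    def test_out_of_range_clipped_to_boundary(self):
        d, _ = msm.discretize(np.array([-5.0, 5.0]), grid_edges=[np.array([0.0, 1.0, 2.0])])
        assert d.tolist() == [0, 1]

    def test_labeler_mode(self):
        d, states = msm.discretize(["b", "a", "b"], labeler=lambda v: v)
        assert states == ["a", "b"] and d.tolist() == [1, 0, 1]


class TestCountMatrix:
    def test_lag_one_by_hand(self):
        C = msm.count_matrix(np.array([0, 0, 1, 1]), lag=1)
        assert C[0, 0] == 1 and C[0, 1] == 1 and C[1, 1] == 1 and C[1, 0] == 0

    def test_lag_two_matches_pair_enumeration(self, rng):
        d = rng.integers(0, 3, size=200)
        for lag in (1, 2, 5):
            C = msm.count_matrix(d, lag=lag, n_states=3)
            brute = np.zeros((3, 3))
            for t in range(len(d) - lag):
                brute[d[t], d[t + lag]] += 1
            assert np.array_equal(C, brute)

    def test_no_cross_trajectory_pairs(self):
        C = msm.count_matrix([np.array([0, 0]), np.array([1, 1])], lag=1, n_states=2)
        assert C[0, 1] == 0 and C[1, 0] == 0

    def test_lag_longer_than_data_rejected(self):
        with pytest.raises(ValueError):
            msm.count_matrix(np.array([0, 1]), lag=5)


class TestTransitionMatrix:
    def test_symmetric_two_state(self):
        model = msm.transition_matrix(np.array([[9.0, 1.0], [1.0, 9.0]]))
        assert np.allclose(model.T, [[0.9, 0.1], [0.1, 0.9]])
        assert np.allclose(model.pi, [0.5, 0.5])

    def test_rows_sum_to_one_and_detailed_balance(self, rng):
        C = rng.integers(1, 50, size=(5, 5)).astype(float)
        model = msm.transition_matrix(C, symmetrize=True)
        assert np.allclose(model.T.sum(axis=1), 1.0, atol=1e-12)
        flux = model.pi[:, None] * model.T
        assert np.allclose(flux, flux.T, atol=1e-10)

    def test_recovers_true_matrix_from_sampled_chain(self):
        T_true = np.array([[0.90, 0.08, 0.02], [0.05, 0.90, 0.05], [0.02, 0.08, 0.90]])
        d = markov_sampler(T_true, 100000, seed=11)
        model = msm.transition_matrix(msm.count_matrix(d, lag=1, n_states=3), lag=1.0)
        # binomial standard error per element
        counts = np.bincount(d[:-1], minlength=3)
        se = np.sqrt(T_true * (1 - T_true) / counts[:, None])
        assert np.all(np.abs(model.T - T_true) < 3 * se + 0.005)

    def test_disconnected_states_dropped(self):
        C = np.zeros((3, 3))
        C[0, 0] = C[0, 1] = C[1, 0] = 10
        C[2, 2] = 5
        with pytest.warns(UserWarning):
            model = msm.transition_matrix(C)
        assert len(model.T) == 2

    def test_chapman_kolmogorov_on_sampled_chain(self):
        T_true = np.array([[0.9, 0.1], [0.2, 0.8]])
        d = markov_sampler(T_true, 200000, seed=5)
        m1 = msm.transition_matrix(msm.count_matrix(d, lag=1, n_states=2))
        m2 = msm.transition_matrix(msm.count_matrix(d, lag=2, n_states=2))
        assert np.allclose(m1.T @ m1.T, m2.T, atol=0.01)


class TestImpliedTimescales:
    def test_two_state_analytic_eigenvalue(self):
        """Switch probabilities 0.1/0.2 give lambda2 = 0.7 and
        t2 = -1/ln 0.7 ~ 2.804 lag units."""
        T = np.array([[0.9, 0.1], [0.2, 0.8]])
        d = markov_sampler(T, 400000, seed=2)
        table = msm.implied_timescales([np.asarray(d)], lags=[1], k=1)
        assert table.t2.iloc[0] == pytest.approx(-1.0 / np.log(0.7), rel=0.05)

    def test_identity_chain_has_no_finite_timescale(self):
        model = msm.transition_matrix(np.array([[10.0, 0.5], [0.5, 10.0]]) * 0 + np.eye(2) * 10)
        # eigenvalues 1,1: masked
        assert np.all(np.isnan(model.timescales(k=1)))

    def test_timescales_non_increasing(self):
        T_true = np.array(
            [[0.90, 0.05, 0.05], [0.05, 0.90, 0.05], [0.05, 0.05, 0.90]]
        )
        d = markov_sampler(T_true, 50000, seed=3)
        model = msm.transition_matrix(msm.count_matrix(d, lag=1, n_states=3))
        ts = model.timescales(k=2)
        assert ts[0] >= ts[1] or np.isnan(ts[1])


class TestMfpt:
    def test_source_equals_target_is_zero(self):
        model = msm.transition_matrix(np.array([[9.0, 1.0], [1.0, 9.0]]), lag=1.0)
        assert msm.mfpt(model, [0])[0] == 0.0

    def test_two_state_geometric_law(self):
        p = 0.25
        T = np.array([[1 - p, p], [0.5, 0.5]])
        model = msm.MarkovModel(T=T, pi=np.array([0.5, 0.5]), counts=T, lag=1.0,
                                active=np.arange(2))
        assert msm.mfpt(model, [1])[0] == pytest.approx(1.0 / p)

    def test_matches_brute_force_first_passage(self, rng):
        T = np.array(
            [
                [0.80, 0.10, 0.05, 0.05, 0.00],
                [0.10, 0.70, 0.10, 0.05, 0.05],
                [0.05, 0.10, 0.70, 0.10, 0.05],
                [0.05, 0.05, 0.10, 0.70, 0.10],
                [0.00, 0.05, 0.05, 0.10, 0.80],
            ]
        )
        model = msm.MarkovModel(T=T, pi=np.full(5, 0.2), counts=T, lag=1.0,
                                active=np.arange(5))
        solved = msm.mfpt(model, [4])[0]
        # direct simulation of first passage from state 0 to state 4
        n_rep = 20000
        cum = np.cumsum(T, axis=1)
        times = np.empty(n_rep)
        u = rng.random((n_rep, 2000))
        for r in range(n_rep):
            s, t = 0, 0
            while s != 4:
                s = int(np.searchsorted(cum[s], u[r, t]))
                t += 1
            times[r] = t
        se = times.std(ddof=1) / np.sqrt(n_rep)
        assert abs(times.mean() - solved) < 3 * se

    def test_invalid_targets_rejected(self):
        model = msm.transition_matrix(np.array([[9.0, 1.0], [1.0, 9.0]]))
        with pytest.raises(ValueError):
            msm.mfpt(model, [7])


class TestStationaryFreeEnergy:
    def test_uniform_is_flat(self):
        model = msm.transition_matrix(np.ones((4, 4)))
        assert np.allclose(msm.stationary_free_energy(model).F, 0.0)

    def test_three_to_one_ratio(self):
        model = msm.MarkovModel(
            T=np.eye(2), pi=np.array([0.75, 0.25]), counts=np.eye(2), lag=1.0,
            active=np.arange(2)
        )
        F = msm.stationary_free_energy(model).F
        assert F[1] - F[0] == pytest.approx(np.log(3))

    def test_recovers_constructed_boltzmann_chain(self):
        """Build a detailed-balance chain from known energies; the
        stationary free energies reproduce them."""
        E = np.array([0.0, 1.2, 0.4])
        pi = np.exp(-E) / np.exp(-E).sum()
        # Metropolis-style reversible chain
        T = np.zeros((3, 3))
        for i in range(3):
            for j in range(3):
                if i != j:
                    T[i, j] = min(1.0, pi[j] / pi[i]) / 4
            T[i, i] = 1 - T[i].sum()
        d = markov_sampler(T, 300000, seed=9)
        model = msm.transition_matrix(msm.count_matrix(d, lag=1, n_states=3))
        F = msm.stationary_free_energy(model).F
        assert np.allclose(F, E - E.min(), atol=0.05)


class TestMinEnergyPath:
    def make_fep(self, F):
        F = np.asarray(F, dtype=float)
        edges = (np.arange(F.shape[0] + 1, dtype=float), np.arange(F.shape[1] + 1, dtype=float))
        return msm.FreeEnergyProfile(edges=edges, F=F, counts=np.ones_like(F))

    def test_single_cell_path(self):
        fep = self.make_fep([[1.0, 2.0], [3.0, 4.0]])
        res = msm.min_energy_path(fep, (0, 0), (0, 0))
        assert res.cells == [(0, 0)] and res.profile.tolist() == [1.0]

    def brute_force_minimax(self, F, source, sink):
        """Enumerate all simple 8-connected paths on a small grid."""
        nrow, ncol = F.shape
        nb = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]
        best = None

        def walk(cell, visited, bneck, tot):
            nonlocal best
            if cell == sink:
                cand = (bneck, tot)
                if best is None or cand < best:
                    best = cand
                return
            for di, dj in nb:
                nxt = (cell[0] + di, cell[1] + dj)
                if 0 <= nxt[0] < nrow and 0 <= nxt[1] < ncol and nxt not in visited:
                    if np.isfinite(F[nxt]):
                        walk(nxt, visited | {nxt}, max(bneck, F[nxt]), tot + F[nxt])

        walk(source, {source}, F[source], F[source])
        return best

    def test_valley_path_matches_exhaustive_enumeration(self, rng):
        for trial in range(5):
            F = np.round(rng.uniform(0, 5, (4, 4)), 2)
            fep = self.make_fep(F)
            res = msm.min_energy_path(fep, (0, 0), (3, 3))
            brute = self.brute_force_minimax(F, (0, 0), (3, 3))
            assert res.bottleneck == pytest.approx(brute[0])

    def test_flat_grid_deterministic_tie_break(self):
        fep = self.make_fep(np.zeros((3, 3)))
        a = msm.min_energy_path(fep, (0, 0), (2, 2))
        b = msm.min_energy_path(fep, (0, 0), (2, 2))
        assert a.cells == b.cells

    def test_masked_cells_impassable(self):
        F = np.zeros((3, 3))
        F[:, 1] = np.nan
        fep = self.make_fep(F)
        with pytest.raises(ValueError):
            msm.min_energy_path(fep, (0, 0), (0, 2))


def test_toy_well_and_invert_end_to_end():
    """Exact samples from a harmonic well invert back to the potential."""
    k = 4.0
    samples = toy_well_sampler(lambda x: 0.5 * k * x * x, 300000, seed=6)
    assert samples.var() == pytest.approx(1.0 / k, rel=0.03)
    fep = msm.boltzmann_invert(samples, np.linspace(-1.2, 1.2, 25))
    (c,) = fep.centers
    expect = 0.5 * k * c**2
    expect -= np.nanmin(expect[~np.isnan(fep.F)])
    ok = ~np.isnan(fep.F)
    assert np.nanmax(np.abs(fep.F[ok] - (expect[ok] - expect[ok].min()))) < 0.2
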