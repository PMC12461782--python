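"""Microstate/macrostate model estimation, validation and rate conversion."""

import numpy as np
import pytest

import chelkin as ck
from chelkin import msm
from chelkin.constants import N_AVOGADRO


def sample_chain(T: np.ndarray, n_steps: int, seed: int, start: int = 0) -> np.ndarray:
    rng = np.random.default_rng(seed)
    cum = np.cumsum(T, axis=1)
    out = np.empty(n_steps, dtype=np.int64)
    s = start
    for t in range(n_steps):
        out[t] = s
        s = int(np.searchsorted(cum[s], rng.random()))
    return out


def fundamental_matrix_mfpt(T: np.ndarray, source: int, target: int, lag_time: float) -> float:
    """Oracle: explicit fundamental matrix N = (I-Q)^-1, m = N 1."""
    keep = [i for i in range(T.shape[0]) if i != target]
    Q = T[np.ix_(keep, keep)]
    N = np.linalg.inv(np.eye(len(keep)) - Q)
    m = N @ np.ones(len(keep)) * lag_time
    return float(m[keep.index(source)])


def random_reversible_chain(n: int, rng) -> np.ndarray:
    X = rng.uniform(0.1, 1.0, size=(n, n))
    X = X + X.T
    return X / X.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# discretization


class TestAssignMicrostates:
    def test_exact_points_recovered(self):
        pts = np.array([[0.0, 6.0], [2.0, 4.0], [4.0, 2.0]])
        frames = np.tile(pts, (50, 1))
        traj = ck.CoordTrajectory(dt=0.1, frames=frames)
        model = ck.assign_microstates([traj], k=3, seed=0)
        got = set(map(tuple, np.round(model.centers, 10)))
        assert got == set(map(tuple, pts))

    def test_two_blobs_fully_separated(self):
        rng = np.random.default_rng(1)
        a = rng.normal([0, 6], 0.1, size=(300, 2))
        b = rng.normal([4, 2], 0.1, size=(300, 2))
        traj = ck.CoordTrajectory(dt=0.1, frames=np.vstack([a, b]))
        model = ck.assign_microstates([traj], k=2, seed=0)
        d = model.dtrajs[0]
        assert len(set(d[:300])) == 1 and len(set(d[300:])) == 1
        assert d[0] != d[-1]

    def test_every_occupied_state_captured(self):
        spec = ck.scenario_preset("cd-en")
        reals = ck.simulate_ctmc(spec, n_replicas=8, t_max=500.0, dt=0.1, seed=2)
        model = ck.assign_microstates([r.trajectory for r in reals], k=8, seed=0)
        # every occupied integer (lig, wat) pair must own >= 1 center
        occupied = {
            (int(l), int(w))
            for l, w in zip(
                spec.lig_coordination, spec.total_coordination - spec.lig_coordination
            )
        }
        nearest = {
            min(occupied, key=lambda p: np.hypot(c[0] - p[0], c[1] - p[1]))
            for c in model.centers
        }
        assert nearest == occupied

    def test_trajectory_validation(self):
        with pytest.raises(ValueError, match="dt"):
            ck.CoordTrajectory(dt=0.0, frames=np.zeros((5, 2)))
        with pytest.raises(ValueError, match="2 frames"):
            ck.CoordTrajectory(dt=0.1, frames=np.zeros((1, 2)))


# ---------------------------------------------------------------------------
# transition-matrix estimation


class TestEstimateTransitionMatrix:
    def _model(self, dtraj, n):
        centers = np.column_stack([np.arange(n, dtype=float), np.zeros(n)])
        return msm.MicrostateModel(centers=centers, dtrajs=[np.asarray(dtraj)], dt=1.0)

    def test_forced_alternation(self):
        model = self._model([0, 1] * 50, 2)
        est = msm.estimate_transition_matrix(model, lag=1, reversible=False)
        np.testing.assert_allclose(est.transition_matrix, [[0, 1], [1, 0]], atol=1e-12)

    def test_recovers_known_three_state_chain(self):
        T = np.array([[0.90, 0.08, 0.02], [0.05, 0.90, 0.05], [0.03, 0.07, 0.90]])
        d = sample_chain(T, 100_000, seed=3)
        for rev in (True, False):
            est = msm.estimate_transition_matrix(self._model(d, 3), lag=1, reversible=rev)
            assert np.abs(est.transition_matrix - T).max() < 0.02

    def test_reversible_equals_mle_on_symmetric_counts(self):
        # the cycle 0,0,1,1 repeated gives exactly symmetric counts, for
        # which the plain MLE already satisfies detailed balance and the
        # constrained estimate coincides with it
        d = np.append(np.tile([0, 0, 1, 1], 500), 0)  # close the cycle
        a = msm.estimate_transition_matrix(self._model(d, 2), lag=1, reversible=True)
        b = msm.estimate_transition_matrix(self._model(d, 2), lag=1, reversible=False)
        np.testing.assert_array_equal(b.count_matrix, b.count_matrix.T)
        np.testing.assert_allclose(a.transition_matrix, b.transition_matrix, atol=1e-10)

    def test_rows_stochastic_and_detailed_balance(self):
        rng = np.random.default_rng(5)
        d = sample_chain(random_reversible_chain(5, rng), 50_000, seed=6)
        est = msm.estimate_transition_matrix(self._model(d, 5), lag=2, reversible=True)
        T = est.transition_matrix
        np.testing.assert_allclose(T.sum(axis=1), 1.0, atol=1e-10)
        pi = msm.stationary_distribution(T)
        np.testing.assert_allclose(pi[:, None] * T, pi[None, :] * T.T, atol=1e-8)

    def test_disconnected_required_state_raises(self):
        d = np.array([0, 1, 0, 1, 0, 1, 2, 2, 2, 2])  # 2 never returns
        with pytest.raises(ValueError, match=r"\[2\]"):
            msm.estimate_transition_matrix(
                self._model(d, 3), lag=1, reversible=False, require_states=[0, 1, 2]
            )


# ---------------------------------------------------------------------------
# validation


class TestImpliedTimescales:
    def test_two_state_closed_form(self):
        a, b = 0.10, 0.05
        T = np.array([[1 - a, a], [b, 1 - b]])
        d = sample_chain(T, 200_000, seed=7)
        centers = np.array([[0.0, 0.0], [1.0, 0.0]])
        model = msm.MicrostateModel(centers=centers, dtrajs=[d], dt=1.0)
        out = msm.implied_timescales(model, lags=[1, 2, 5, 10], n_its=1)
        expected = -1.0 / np.log(1 - a - b)
        np.testing.assert_allclose(out["timescales"][:, 0], expected, rtol=0.05)
        # Markovian data: the plateau starts at the first lag
        assert out["plateau_lag"] == 1

    def test_identity_matrix_flags_infinity(self):
        out = msm.timescales_from_matrix(np.eye(3), lag_time=1.0, n_its=2)
        assert np.isinf(out).all()

    def test_increasing_lags_required(self):
        model = msm.MicrostateModel(
            centers=np.zeros((1, 2)), dtrajs=[np.zeros(10, dtype=int)], dt=1.0
        )
        with pytest.raises(ValueError, match="increasing"):
            msm.implied_timescales(model, lags=[4, 2])


class TestChapmanKolmogorov:
    def _estimated(self, d, n, lag=1):
        centers = np.column_stack([np.arange(n, dtype=float), np.zeros(n)])
        model = msm.MicrostateModel(centers=centers, dtrajs=[np.asarray(d)], dt=1.0)
        return msm.estimate_transition_matrix(model, lag=lag, reversible=False)

    def test_markovian_data_passes(self):
        rng = np.random.default_rng(8)
        T = random_reversible_chain(3, rng)
        d = sample_chain(T, 200_000, seed=9)
        out = msm.chapman_kolmogorov(self._estimated(d, 3), n_steps=5)
        assert out["passed"] and out["max_divergence"] < 0.02

    def test_hidden_phase_projection_fails(self):
        # deterministic dwell of exactly 20 steps per state: the visible
        # two-state signal hides the phase within the dwell, so the
        # one-step matrix propagated 10 steps overestimates survival
        # (geometric decay) against the true linear (uniform-phase) one
        d = np.tile([0] * 20 + [1] * 20, 500)
        out = msm.chapman_kolmogorov(self._estimated(d, 2), n_steps=10)
        assert not out["passed"]
        assert out["max_divergence"] > out["threshold"]

    def test_single_step_is_exact(self):
        d = sample_chain(np.array([[0.9, 0.1], [0.2, 0.8]]), 20_000, seed=11)
        out = msm.chapman_kolmogorov(self._estimated(d, 2), n_steps=1)
        assert out["max_divergence"] == pytest.approx(0.0, abs=1e-12)

    def test_insufficient_data_raises(self):
        d = sample_chain(np.array([[0.5, 0.5], [0.5, 0.5]]), 40, seed=12)
        with pytest.raises(ValueError, match="long enough"):
            msm.chapman_kolmogorov(self._estimated(d, 2), n_steps=100)


# ---------------------------------------------------------------------------
# PCCA+


class TestPcca:
    def test_block_structure_recovered(self):
        rng = np.random.default_rng(13)
        blocks = [(0, 1), (2, 3), (4, 5), (6, 7)]
        T = np.full((8, 8), 1e-4)
        for blk in blocks:
            sub = random_reversible_chain(2, rng)
            for i, gi in enumerate(blk):
                for j, gj in enumerate(blk):
                    T[gi, gj] = sub[i, j]
        T /= T.sum(axis=1, keepdims=True)
        d = sample_chain(T, 400_000, seed=14)
        centers = np.column_stack([np.repeat(np.arange(4.0), 2), np.zeros(8)])
        model = msm.MicrostateModel(centers=centers, dtrajs=[d], dt=1.0)
        est = msm.estimate_transition_matrix(model, lag=1, reversible=True)
        macro = msm.pcca_coarse_grain(est, 4)
        got = [tuple(np.flatnonzero(macro.macro_of_micro == a)) for a in range(4)]
        assert sorted(got) == [tuple(b) for b in blocks]

    def test_identity_memberships_when_n_macro_equals_n_micro(self):
        rng = np.random.default_rng(15)
        # metastable 3-state chain: memberships collapse to the identity
        T = np.array([[0.98, 0.01, 0.01], [0.01, 0.98, 0.01], [0.01, 0.01, 0.98]])
        d = sample_chain(T, 100_000, seed=16)
        centers = np.column_stack([np.arange(3.0), np.zeros(3)])
        model = msm.MicrostateModel(centers=centers, dtrajs=[d], dt=1.0)
        est = msm.estimate_transition_matrix(model, lag=1, reversible=True)
        macro = msm.pcca_coarse_grain(est, 3)
        perm = macro.macro_of_micro
        assert sorted(perm) == [0, 1, 2]
        chi = macro.membership
        assert chi[np.arange(3), perm] == pytest.approx(np.ones(3), abs=1e-6)

    def test_ctmc_ladder_macrostates_bijective_with_species(self):
        # bidentate four-species ladder (balanced levels so that every
        # step is sampled in both directions within short replicas)
        from chelkin.synthetic import recovery_scenarios

        spec = recovery_scenarios()["ladder"]["spec"]
        reals = ck.simulate_ctmc(spec, n_replicas=20, t_max=1000.0, dt=0.1, seed=17)
        model = ck.assign_microstates([r.trajectory for r in reals], k=8, seed=0)
        est = msm.estimate_transition_matrix(model, lag=10, reversible=True)
        macro = msm.pcca_coarse_grain(est, spec.n_species, labels=spec.labels)
        # macrostates ordered by ligand coordination land on 0, 2, 4, 6
        np.testing.assert_allclose(macro.macro_lig, spec.lig_coordination, atol=0.3)

    def test_bad_n_macro_rejected(self):
        T = np.array([[0.9, 0.1], [0.1, 0.9]])
        with pytest.raises(ValueError):
            msm.pcca_memberships(T, 5)


# ---------------------------------------------------------------------------
# MFPT


class TestMfpt:
    def test_two_state_geometric(self):
        T = np.array([[0.5, 0.5], [0.0, 1.0]])
        assert msm.mfpt(T, 0, 1, lag_time=1.0) == pytest.approx(2.0)

    def test_matches_fundamental_matrix_oracle(self):
        rng = np.random.default_rng(18)
        for _ in range(25):
            n = int(rng.integers(3, 9))
            T = random_reversible_chain(n, rng)
            src, tgt = rng.choice(n, size=2, replace=False)
            got = msm.mfpt(T, int(src), int(tgt), lag_time=0.7)
            want = fundamental_matrix_mfpt(T, int(src), int(tgt), 0.7)
            assert got == pytest.approx(want, rel=1e-10)

    def test_birth_death_summation_formula(self):
        # detailed-balance chain: T(x -> x+1) = sum_{j<=x} pi_j / (pi_x p_up)
        p_up, p_dn = 0.3, 0.2
        n = 5
        T = np.zeros((n, n))
        for i in range(n):
            if i + 1 < n:
                T[i, i + 1] = p_up
            if i > 0:
                T[i, i - 1] = p_dn
            T[i, i] = 1.0 - T[i].sum()
        pi = msm.stationary_distribution(T)
        for x in range(n - 1):
            closed = pi[: x + 1].sum() / (pi[x] * p_up)
            assert msm.mfpt(T, x, x + 1, 1.0) == pytest.approx(closed, rel=1e-9)

    def test_unreachable_target_raises(self):
        T = np.array([[1.0, 0.0], [0.5, 0.5]])
        with pytest.raises(ValueError, match="unreachable"):
            msm.mfpt(T, 0, 1, 1.0)


# ---------------------------------------------------------------------------
# rate conversion


def _macro_from_ctmc(spec, n_replicas, t_max, dt, lag, seed):
    reals = ck.simulate_ctmc(spec, n_replicas=n_replicas, t_max=t_max, dt=dt, seed=seed)
    model = ck.assign_microstates([r.trajectory for r in reals], k=4 * (spec.n_species - 1), seed=1)
    est = msm.estimate_transition_matrix(model, lag=lag, reversible=True)
    return msm.pcca_coarse_grain(est, spec.n_species, labels=spec.labels)


class TestRatesFromMsm:
    def test_one_step_parameter_recovery(self, small_box_comp):
        spec = ck.ScenarioSpec.thermoconsistent(
            ["ML0", "ML1"], [0.0, -5.0], small_box_comp, [3e10]
        )
        macro = _macro_from_ctmc(spec, 60, 2000.0, 0.1, 10, seed=19)
        res = ck.solve_equilibrium(ck.SpeciesLevels(spec.labels, spec.delta_g), spec.comp)
        rates = ck.rates_from_msm(macro, spec.comp, res, method="mfpt")
        assert rates.forward[0] == pytest.approx(spec.k_forward[0], rel=0.25)
        assert rates.backward[0] == pytest.approx(spec.k_backward[0], rel=0.25)

    def test_volume_robustness(self):
        # doubling the box at fixed concentrations leaves molar rates
        # unchanged within statistical error
        recovered = []
        for gamma in (200.0, 400.0):
            comp = ck.SolutionComposition(
                1.0 / gamma, 30.0 * (gamma / 200.0) / gamma, (0, 1),
                box_volume=gamma / N_AVOGADRO,
            )
            spec = ck.ScenarioSpec.thermoconsistent(["ML0", "ML1"], [0.0, -5.0], comp, [3e10])
            macro = _macro_from_ctmc(spec, 40, 2000.0, 0.1, 10, seed=20)
            res = ck.solve_equilibrium(ck.SpeciesLevels(spec.labels, spec.delta_g), comp)
            r = ck.rates_from_msm(macro, comp, res, method="mfpt")
            recovered.append((r.forward[0], r.backward[0]))
        (f1, b1), (f2, b2) = recovered
        assert f1 == pytest.approx(f2, rel=0.25)
        assert b1 == pytest.approx(b2, rel=0.25)

    def test_no_events_flagged_as_zero(self, small_box_comp):
        macro = msm.MacrostateModel(
            membership=np.eye(2),
            macro_of_micro=np.arange(2),
            macro_lig=np.array([0.0, 1.0]),
            transition_matrix=np.array([[0.9, 0.1], [0.01, 0.99]]),
            count_matrix=np.array([[90.0, 10.0], [0.0, 100.0]]),
            lag=1,
            dt=1.0,
        )
        res = ck.solve_equilibrium(
            ck.SpeciesLevels(["ML0", "ML1"], [0.0, -5.0]), small_box_comp
        )
        rates = ck.rates_from_msm(macro, small_box_comp, res)
        assert rates.backward[0] == 0.0
        assert "backward" in rates.flags[0]

    def test_pk_from_rates_basics(self):
        assert ck.pk_from_rates([1e5], [1.0])[0] == pytest.approx(5.0)
        assert ck.pk_from_rates([7.7], [7.7])[0] == pytest.approx(0.0)
        with pytest.raises(ValueError, match="unpaired"):
            ck.pk_from_rates([1.0, 2.0], [1.0])


class TestBayesianErrors:
    @staticmethod
    def _rate_func(T):
        return np.array([1.0 / msm.mfpt(T, 0, 1, 1.0), 1.0 / msm.mfpt(T, 1, 0, 1.0)])

    def test_interval_width_shrinks_with_counts(self):
        C = np.array([[950.0, 50.0], [100.0, 900.0]])
        small = ck.bayesian_rate_errors(C, n_samples=400, seed=0, rate_func=self._rate_func)
        big = ck.bayesian_rate_errors(C * 100, n_samples=400, seed=0, rate_func=self._rate_func)
        ratio = (small["upper"] - small["lower"]) / (big["upper"] - big["lower"])
        assert ((ratio > 5) & (ratio < 20)).all()

    def test_symmetric_counts_give_symmetric_intervals(self):
        C = np.array([[900.0, 100.0], [100.0, 900.0]])
        out = ck.bayesian_rate_errors(C, n_samples=500, seed=1, rate_func=self._rate_func)
        np.testing.assert_allclose(out["lower"][0], out["lower"][1], rtol=0.1)
        np.testing.assert_allclose(out["upper"][0], out["upper"][1], rtol=0.1)

    def test_coverage_of_true_rate(self):
        # 50 synthetic experiments; the true rate must fall inside the
        # 95% interval in at least 90% of them
        T = np.array([[0.95, 0.05], [0.10, 0.90]])
        true = self._rate_func(T)
        rng = np.random.default_rng(2)
        hits = 0
        n_exp = 50
        for _ in range(n_exp):
            C = np.vstack(
                [rng.multinomial(1500, T[0]), rng.multinomial(1500, T[1])]
            ).astype(float)
            out = ck.bayesian_rate_errors(
                C, n_samples=250, seed=int(rng.integers(2**31 - 1)), rate_func=self._rate_func
            )
            if ((out["lower"] <= true) & (true <= out["upper"])).all():
                hits += 1
        assert hits >= 0.90 * n_exp

    def test_needs_two_samples(self):
        with pytest.raises(ValueError, match="n_samples"):
            ck.bayesian_rate_errors(np.eye(2) + 1, n_samples=1, seed=0, rate_func=self._rate_func)
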