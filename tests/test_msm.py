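"""Transition counting, reversible estimation, lumping and validation."""

import numpy as np
import pytest
from scipy.optimize import minimize

from allostate import msm, synthetic
from allostate.geometry import TrajectoryEnsemble
from allostate.msm import (
    MacroModel,
    ck_test,
    cluster_microstates,
    condition_macro_T,
    count_and_trim,
    count_transitions,
    detailed_balance_error,
    estimate_T,
    implied_timescales,
    largest_scc,
    microstate_dispersion,
    pcca,
    stationary_distribution,
    timescale_from_eigenvalue,
)


class TestClustering:
    def test_k1_center_is_centroid(self):
        rng = np.random.default_rng(0)
        cv = rng.normal(size=(50, 2))
        model = cluster_microstates(cv, k=1, seed=0)
        assert np.all(model.labels == 0)
        assert np.allclose(model.centers[0], cv.mean(axis=0), atol=1e-8)

    def test_two_separated_clouds_partition_exactly(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(40, 2)) * 0.1
        b = rng.normal(size=(40, 2)) * 0.1 + 10
        cv = np.concatenate([a, b])
        model = cluster_microstates(cv, k=2, seed=0)
        # brute-force nearest-centroid check
        dists = np.linalg.norm(cv[:, None] - model.centers[None], axis=2)
        assert np.array_equal(model.labels, np.argmin(dists, axis=1))
        assert len(set(model.labels[:40])) == 1
        assert len(set(model.labels[40:])) == 1
        assert model.labels[0] != model.labels[-1]

    def test_300_distinct_points_support_300_microstates(self):
        rng = np.random.default_rng(2)
        cv = rng.normal(size=(600, 2)) * 10
        model = cluster_microstates(cv, k=300, seed=0)
        assert len(np.unique(model.labels)) == 300

    def test_k_beyond_distinct_points_rejected(self):
        cv = np.zeros((10, 2))
        with pytest.raises(ValueError, match="distinct"):
            cluster_microstates(cv, k=2, seed=0)


class TestCounting:
    def test_hand_counted_lag_one(self):
        counts = count_transitions([np.array([0, 0, 1, 1])], lag=1)
        assert np.array_equal(counts, [[1, 1], [0, 1]])

    def test_hand_counted_lag_two(self):
        counts = count_transitions([np.array([0, 1, 0, 1, 0])], lag=2)
        assert np.array_equal(counts, [[2, 0], [0, 1]])

    def test_no_cross_trajectory_transitions(self):
        # the 1->0 boundary between the two trajectories must not be counted
        counts = count_transitions([np.array([0, 1]), np.array([0, 1])], lag=1)
        assert np.array_equal(counts, [[0, 2], [0, 0]])

    def test_all_trajectories_shorter_than_lag_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            count_transitions([np.array([0, 1])], lag=5)

    def test_transient_state_trimmed(self):
        labels = np.array([0, 1, 0, 1, 0, 1, 2, 2])  # state 2 never returns
        counts, active = count_and_trim([labels], lag=1)
        assert np.array_equal(active, [0, 1])

    @pytest.mark.parametrize("seed", range(10))
    def test_active_set_matches_brute_force_scc(self, seed):
        rng = np.random.default_rng(seed)
        n = 7
        counts = (rng.random((n, n)) < 0.25) * rng.integers(1, 9, (n, n))
        if counts.sum() == 0:
            counts[0, 0] = 1
        # reachability oracle: i,j in one SCC iff i reaches j and j reaches i
        adj = counts > 0
        reach = adj | np.eye(n, dtype=bool)
        for _ in range(n):
            reach = reach | (reach @ reach)
        comp = {}
        for i in range(n):
            key = tuple(sorted(j for j in range(n) if reach[i, j] and reach[j, i]))
            comp[key] = None
        best = max(
            comp,
            key=lambda nodes: (counts[np.ix_(nodes, nodes)].sum(), len(nodes),
                               -min(nodes)),
        )
        assert np.array_equal(largest_scc(counts), np.array(best))


def _reversible_loglik_oracle(counts):
    """Direct numerical maximization over symmetric nonnegative flux matrices."""
    counts = np.asarray(counts, dtype=float)
    n = counts.shape[0]
    iu = np.triu_indices(n)

    def unpack(params):
        x = np.zeros((n, n))
        x[iu] = np.exp(params)
        x = x + np.triu(x, 1).T
        return x / x.sum(axis=1, keepdims=True)

    def neg_ll(params):
        T = unpack(params)
        with np.errstate(divide="ignore"):
            ll = np.where(counts > 0, counts * np.log(np.maximum(T, 1e-300)), 0.0)
        return -ll.sum()

    x0 = np.log((counts + counts.T + 0.5)[iu])
    res = minimize(neg_ll, x0, method="Nelder-Mead",
                   options={"maxiter": 40000, "xatol": 1e-10, "fatol": 1e-12})
    return unpack(res.x)


class TestReversibleEstimation:
    def test_symmetric_counts_give_row_normalized_mle(self):
        counts = np.array([[6, 2, 2], [2, 8, 0], [2, 0, 4]])
        model = estimate_T(counts)
        assert np.allclose(model.T, counts / counts.sum(axis=1, keepdims=True))
        assert detailed_balance_error(model) < 1e-12

    def test_matches_direct_likelihood_optimization(self):
        counts = np.array([[8, 2], [1, 9]])
        model = estimate_T(counts)
        oracle = _reversible_loglik_oracle(counts)
        assert np.allclose(model.T, oracle, atol=1e-6)

    def test_three_state_matches_direct_optimization(self):
        counts = np.array([[20, 5, 1], [3, 30, 4], [2, 6, 25]])
        model = estimate_T(counts)
        oracle = _reversible_loglik_oracle(counts)
        assert np.allclose(model.T, oracle, atol=1e-5)

    @pytest.mark.parametrize("seed", range(5))
    def test_stochasticity_and_stationarity(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(1, 50, (6, 6))
        model = estimate_T(counts)
        assert np.allclose(model.T.sum(axis=1), 1.0, atol=1e-10)
        assert np.allclose(model.pi @ model.T, model.pi, atol=1e-10)
        assert detailed_balance_error(model) < 1e-8
        assert np.max(np.abs(model.eigenvalues().imag)) < 1e-10

    def test_zero_row_rejected(self):
        counts = np.array([[1, 1], [0, 0]])
        with pytest.raises(ValueError, match="zero-count"):
            estimate_T(counts)


class TestImpliedTimescales:
    def test_closed_form_two_state(self):
        # T = [[0.9, 0.1], [0.1, 0.9]], tau = 30 ns: t2 = -30/ln(0.8) ns
        t2 = timescale_from_eigenvalue(0.8, lag_ps=30_000.0)
        assert t2 == pytest.approx(-30_000.0 / np.log(0.8))
        assert t2 / 1000 == pytest.approx(134.4, abs=0.1)

    def test_identity_matrix_reports_infinite(self):
        assert timescale_from_eigenvalue(1.0, 100.0) == np.inf

    def test_negative_and_complex_eigenvalues_undefined(self):
        assert np.isnan(timescale_from_eigenvalue(-0.3, 100.0))
        assert np.isnan(timescale_from_eigenvalue(0.5 + 0.2j, 100.0))

    def test_constant_across_lags_for_markov_chain(self):
        T = np.array([[0.95, 0.05], [0.05, 0.95]])
        chain = synthetic.sample_chain(T, 100_000, seed=11)
        table = implied_timescales([chain], lags=[1, 2, 5, 10],
                                   save_interval_ps=1.0)
        exact = -1.0 / np.log(0.9)
        assert np.allclose(table["t2_ps"], exact, rtol=0.1)


class TestPCCA:
    def test_identity_lumping_when_n_macro_equals_k(self):
        counts = np.diag([50] * 4) + 1
        model = estimate_T(counts)
        macro = pcca(model, n_macro=4)
        assert sorted(macro.membership.tolist()) == [0, 1, 2, 3]

    def _block_model(self, eps, sizes=(3, 3)):
        n = sum(sizes)
        counts = np.full((n, n), eps)
        start = 0
        for s in sizes:
            counts[start:start + s, start:start + s] = 100.0
            start += s
        return estimate_T(counts)

    def test_two_block_model_recovers_blocks(self):
        model = self._block_model(1e-3)
        macro = pcca(model, n_macro=2, seed=0)
        assert len(set(macro.membership[:3])) == 1
        assert len(set(macro.membership[3:])) == 1
        assert macro.membership[0] != macro.membership[-1]

    def test_eight_basin_model_recovers_planted_membership(self):
        rng = np.random.default_rng(4)
        sizes = rng.integers(10, 20, size=8)
        planted = np.repeat(np.arange(8), sizes)
        n = planted.size
        counts = np.full((n, n), 1e-4)
        for b in range(8):
            idx = np.where(planted == b)[0]
            counts[np.ix_(idx, idx)] = 10.0 + rng.random((idx.size, idx.size))
        macro = pcca(estimate_T(counts), n_macro=8, seed=0)
        # recovered membership must be a relabeling of the planted basins
        mapping = {}
        for rec, true in zip(macro.membership, planted):
            mapping.setdefault(true, rec)
            assert mapping[true] == rec
        assert len(set(mapping.values())) == 8

    def test_invalid_n_macro_rejected(self):
        model = estimate_T(np.diag([5] * 3) + 1)
        with pytest.raises(ValueError):
            pcca(model, n_macro=1)
        with pytest.raises(ValueError):
            pcca(model, n_macro=5)


class TestConditionSplitKinetics:
    def _identity_macro(self, n):
        return MacroModel(membership=np.arange(n), n_macro=n)

    def test_hand_counted_single_trajectory(self):
        labels = [np.array([0, 0, 1, 1, 0])]
        T, undef = condition_macro_T(labels, ["bonded"], self._identity_macro(2),
                                     np.arange(2), lag=1, condition="bonded")
        assert np.allclose(T, [[0.5, 0.5], [0.5, 0.5]])
        assert not undef.any()

    def test_rows_sum_to_one_and_empty_selection_rejected(self):
        labels = [np.array([0, 1, 0, 1])]
        T, _ = condition_macro_T(labels, ["bonded"], self._identity_macro(2),
                                 np.arange(2), lag=1, condition="bonded")
        assert np.allclose(np.nansum(T, axis=1), 1.0)
        with pytest.raises(ValueError, match="no trajectories"):
            condition_macro_T(labels, ["bonded"], self._identity_macro(2),
                              np.arange(2), lag=1, condition="non_bonded")

    def test_never_visited_macrostate_flagged(self):
        labels = [np.array([0, 1, 0, 1])]
        T, undef = condition_macro_T(labels, ["bonded"], self._identity_macro(3),
                                     np.arange(3), lag=1, condition="bonded")
        assert undef.tolist() == [False, False, True]
        assert np.isnan(T[2]).all()

    def test_condition_split_recovery_within_three_standard_errors(self):
        n = 4
        gens = {c: synthetic.default_macro_T(n, c)
                for c in ("bonded", "non_bonded")}
        labels, tags = [], []
        for c, T in gens.items():
            for s in range(3):
                labels.append(synthetic.sample_chain(T, 30_000, seed=hash((c, s)) % 2**31))
                tags.append(c)
        macro = self._identity_macro(n)
        for c, gen in gens.items():
            est, _ = condition_macro_T(labels, tags, macro, np.arange(n),
                                       lag=1, condition=c)
            counts_out = np.zeros(n)
            for l, t in zip(labels, tags):
                if t == c:
                    for s in range(n):
                        counts_out[s] += np.sum(l[:-1] == s)
            se = np.sqrt(gen * (1 - gen) / counts_out[:, None])
            assert np.all(np.abs(est - gen) <= 3 * se + 1e-12)


class TestChapmanKolmogorov:
    def test_k1_prediction_equals_estimate(self):
        labels = [synthetic.sample_chain(synthetic.default_macro_T(3, "bonded"),
                                         5000, seed=0)]
        macro = MacroModel(membership=np.arange(3), n_macro=3)
        report = ck_test(labels, macro, np.arange(3), lag=1, k_multiples=[1])
        assert np.allclose(report["predicted"], report["estimated"], atol=1e-12)

    def test_markov_chain_within_error_bars(self):
        T = synthetic.default_macro_T(3, "bonded")
        labels = [synthetic.sample_chain(T, 50_000, seed=s) for s in range(3)]
        macro = MacroModel(membership=np.arange(3), n_macro=3)
        report = ck_test(labels, macro, np.arange(3), lag=2,
                         k_multiples=[2, 3, 4, 5])
        resid = np.abs(report["predicted"] - report["estimated"])
        assert np.all(resid <= 3 * report["err_standard"] + 1e-12)

    def test_non_markov_lumping_flagged_by_gross_violation(self):
        # deterministic 3-cycle lumped to 2 states is maximally non-Markov
        cycle = np.tile([0, 1, 2], 400)
        macro = MacroModel(membership=np.array([0, 1, 1]), n_macro=2)
        report = ck_test([cycle], macro, np.arange(3), lag=1, k_multiples=[1, 3])
        k3 = report[(report["k"] == 3) & (report["macrostate"] == 0)].iloc[0]
        assert abs(k3["predicted"] - k3["estimated"]) > 10 * max(
            k3["err_standard"], 1e-6)

    def test_both_error_bars_emitted(self):
        labels = [synthetic.sample_chain(synthetic.default_macro_T(2, "bonded"),
                                         2000, seed=1)]
        macro = MacroModel(membership=np.arange(2), n_macro=2)
        report = ck_test(labels, macro, np.arange(2), lag=1, k_multiples=[2])
        assert {"err_standard", "err_count_ratio"} <= set(report.columns)
        assert (report["err_standard"] > 0).all()


class TestMicrostateDispersion:
    def _ensemble(self, frames):
        frames = np.asarray(frames, dtype=float)
        labels = [f"G{i + 37}" for i in range(frames.shape[1])]
        return TrajectoryEnsemble(labels, [frames], ["bonded"])

    def _micro(self, labels, k, cv=None):
        from allostate.msm import MicrostateModel

        labels = np.asarray(labels)
        return MicrostateModel(
            centers=np.zeros((k, 2)), labels=labels, k=k,
            frame_index=[(0, i) for i in range(labels.size)],
        )

    def test_identical_member_frames_have_zero_dispersion(self):
        rng = np.random.default_rng(5)
        frame = rng.normal(size=(6, 3))
        ens = self._ensemble(np.repeat(frame[None], 4, axis=0))
        table = microstate_dispersion(ens, self._micro([0] * 4, 1))
        assert table["dispersion_A"].iloc[0] == pytest.approx(0.0, abs=1e-10)
        assert not table["flagged"].any()

    def test_two_conformer_dispersion_matches_hand_value(self):
        # frames alternate between a square and the same square stretched
        # symmetrically by 0.5 A along x; centroid and orientation are
        # unchanged by symmetry, so superposition is the identity and the
        # dispersion is exactly half the stretch amplitude: each frame sits
        # delta/2 = 0.25 A (per stretched coordinate) from the mean.
        a, delta = 2.0, 0.5
        square = np.array([[a, a, 0.0], [-a, a, 0], [-a, -a, 0], [a, -a, 0]])
        stretched = square.copy()
        stretched[:, 0] *= (a + delta) / a
        frames = np.stack([square, stretched, square, stretched])
        ens = self._ensemble(frames)
        table = microstate_dispersion(ens, self._micro([0] * 4, 1))
        assert table["dispersion_A"].iloc[0] == pytest.approx(delta / 2, abs=1e-8)

    def test_dispersion_above_threshold_flagged(self):
        rng = np.random.default_rng(6)
        base = rng.normal(size=(5, 3)) * 10
        frames = base[None] + rng.normal(0, 2.5, size=(60, 5, 3))
        ens = self._ensemble(frames)
        table = microstate_dispersion(ens, self._micro([0] * 60, 1), threshold=2.0)
        assert table["dispersion_A"].iloc[0] > 2.0
        assert bool(table["flagged"].iloc[0])


class TestParameterRecovery:
    def test_long_chain_recovers_generator_and_stationary(self):
        T = synthetic.default_macro_T(8, "bonded")
        chain = synthetic.sample_chain(T, 100_000, seed=21)
        counts, active = count_and_trim([chain], lag=1)
        assert active.size == 8
        model = estimate_T(counts, active, lag_frames=1)
        counts_out = counts.sum(axis=1)
        se = np.sqrt(T * (1 - T) / counts_out[:, None])
        assert np.all(np.abs(model.T - T) <= 3 * se + 1e-12)
        tv = 0.5 * np.abs(model.pi - stationary_distribution(T)).sum()
        assert tv < 0.02
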