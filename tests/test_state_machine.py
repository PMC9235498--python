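import math

import numpy as np
import pytest

from mmlsub import (
    BinAlpha,
    MachineParams,
    TimeDirichletSet,
    alignment_encoding_length,
    complete_parameters,
    estimate_theta,
    expected_run_length,
    fit_dirichlet,
    fit_time_dirichlets,
    theta_statement_length,
)
from mmlsub.alignments import PairCounts


def make_counts(trans):
    t = np.zeros((3, 3))
    for (a, b), n in trans.items():
        t["mid".index(a), "mid".index(b)] = n
    return PairCounts("m", t, np.zeros((20, 20), int), np.zeros(20, int))


UNIFORM = BinAlpha(np.ones(2), np.ones(3))


class TestCompleteParameters:
    def test_gap_open_probability(self):
        table = complete_parameters(MachineParams(0.9958, 0.8, 0.1))
        assert table[0, 1] + table[0, 2] == pytest.approx(1 - 0.9958, abs=1e-12)

    def test_boundary_all_match(self):
        table = complete_parameters(MachineParams(1.0, 0.5, 0.3))
        assert table[0, 1] == 0.0 and table[0, 2] == 0.0

    def test_dependent_completion(self):
        table = complete_parameters(MachineParams(0.9, 0.5, 0.3))
        assert table[1, 2] == pytest.approx(0.2, abs=1e-12)  # Pr(d|i)
        np.testing.assert_allclose(table.sum(axis=1), 1.0, atol=1e-12)

    def test_insert_delete_symmetry_exact(self):
        table = complete_parameters(MachineParams(0.97, 0.6, 0.25))
        assert table[1, 0] == table[2, 0]
        assert table[1, 1] == table[2, 2]
        assert table[1, 2] == table[2, 1]


class TestExpectedRunLength:
    @pytest.mark.parametrize(
        "p,expect,tol",
        [(0.9958, 238.095, 1e-2), (0.8759, 8.058, 1e-2), (0.5, 2.0, 1e-12)],
    )
    def test_geometric_expectations(self, p, expect, tol):
        assert expected_run_length(p) == pytest.approx(expect, abs=tol)

    def test_infinite_expectation_rejected(self):
        with pytest.raises(ValueError):
            expected_run_length(1.0)


class TestAlignmentEncoding:
    def test_single_state_costs_initial_only(self):
        theta = MachineParams(0.9, 0.5, 0.3)
        assert alignment_encoding_length("m", theta) == pytest.approx(math.log2(3))

    def test_two_matches_at_even_odds(self):
        theta = MachineParams(0.5, 0.5, 0.3)
        assert alignment_encoding_length("mm", theta) == pytest.approx(math.log2(3) + 1.0)

    def test_zero_probability_transition_named(self):
        theta = MachineParams(1.0, 0.5, 0.3)
        with pytest.raises(ValueError, match="m->i"):
            alignment_encoding_length("mi", theta)

    def test_additivity_over_concatenation(self):
        theta = MachineParams(0.9, 0.6, 0.25)
        a, b = "mmiidmm", "mdddmim"
        joint = alignment_encoding_length(a + b, theta)
        # sharing the boundary state: the second part re-pays only a transition
        parts = (
            alignment_encoding_length(a, theta)
            + alignment_encoding_length(b, theta)
            - math.log2(3)
            + alignment_encoding_length(a[-1] + b[0], theta)
            - alignment_encoding_length(a[-1], theta)
            - alignment_encoding_length(b[0], theta)
            + math.log2(3)
        )
        assert joint == pytest.approx(parts, abs=1e-9)

    def test_long_sample_approaches_entropy(self):
        rng = np.random.default_rng(9)
        theta = MachineParams(0.8, 0.5, 0.3)
        table = complete_parameters(theta)
        n = 100_000
        st = np.empty(n, dtype=np.int8)
        st[0] = 0
        cum = table.cumsum(axis=1)
        u = rng.random(n)
        for k in range(1, n):
            st[k] = np.searchsorted(cum[st[k - 1]], u[k])
        states = "".join("mid"[s] for s in st)
        bits = alignment_encoding_length(states, theta)
        # stationary distribution of the 3-state chain, entropy rate oracle
        lam, V = np.linalg.eig(table.T)
        pi = np.real(V[:, np.argmax(np.real(lam))])
        pi /= pi.sum()
        entropy = -sum(
            pi[i] * table[i, j] * math.log2(table[i, j])
            for i in range(3)
            for j in range(3)
            if table[i, j] > 0
        )
        assert bits / (n - 1) == pytest.approx(entropy, rel=0.01)


class TestEstimateTheta:
    def test_match_posterior_worked_example(self):
        counts = make_counts({("m", "m"): 98, ("m", "i"): 1, ("m", "d"): 1,
                              ("i", "m"): 1, ("d", "m"): 1,
                              ("i", "i"): 1, ("d", "d"): 1})
        fit = estimate_theta(counts, UNIFORM)
        assert fit.theta.p_mm == pytest.approx(98.5 / 101.0, abs=1e-12)
        assert not fit.match_from_prior

    def test_no_observations_fall_back_to_prior_mean(self):
        counts = make_counts({})
        alpha = BinAlpha(np.array([3.0, 1.0]), np.array([2.0, 1.0, 1.0]))
        fit = estimate_theta(counts, alpha)
        assert fit.match_from_prior and fit.indel_from_prior
        assert fit.theta.p_mm == pytest.approx(0.75)
        assert fit.theta.p_ii == pytest.approx(0.5)

    def test_large_counts_approach_empirical_frequency(self):
        counts = make_counts({("m", "m"): 10**6, ("m", "i"): 10**5,
                              ("i", "m"): 10**5, ("i", "i"): 10**5})
        fit = estimate_theta(counts, UNIFORM)
        assert fit.theta.p_mm == pytest.approx(10**6 / (10**6 + 10**5), rel=1e-4)


class TestThetaStatement:
    def test_precision_term_scales_with_counts(self):
        base = {("m", "m"): 80, ("m", "i"): 10, ("i", "m"): 8, ("i", "i"): 6,
                ("i", "d"): 2, ("d", "i"): 2, ("d", "m"): 2, ("d", "d"): 2}
        c1 = make_counts(base)
        c2 = make_counts({k: 16 * v for k, v in base.items()})
        th = estimate_theta(c1, UNIFORM).theta
        d = theta_statement_length(th, c2, UNIFORM) - theta_statement_length(th, c1, UNIFORM)
        assert d == pytest.approx(1.5 * math.log2(16), abs=1e-9)

    def test_grid_oracle_agreement(self):
        """MML87 statement + state-string likelihood within 1 bit of a
        brute-force two-part code over a 3-parameter grid."""
        trans = {("m", "m"): 180, ("m", "i"): 5, ("m", "d"): 5,
                 ("i", "i"): 20, ("i", "m"): 6, ("i", "d"): 2,
                 ("d", "d"): 18, ("d", "m"): 5, ("d", "i"): 1}
        counts = make_counts(trans)
        th = estimate_theta(counts, UNIFORM).theta
        t = counts.transitions

        def nll(p_mm, p_ii, p_mi):
            p_di = 1 - p_ii - p_mi
            if min(p_mm, 1 - p_mm, p_ii, p_mi, p_di) <= 0:
                return math.inf
            return (
                -t[0, 0] * math.log2(p_mm)
                - (t[0, 1] + t[0, 2]) * math.log2((1 - p_mm) / 2)
                - (t[1, 1] + t[2, 2]) * math.log2(p_ii)
                - (t[1, 0] + t[2, 0]) * math.log2(p_mi)
                - (t[1, 2] + t[2, 1]) * math.log2(p_di)
            )

        mml = theta_statement_length(th, counts, UNIFORM) + nll(th.p_mm, th.p_ii, th.p_mi)
        best = math.inf
        for g1 in (8, 16, 32, 64, 128):
            c1 = (2 * np.arange(g1) + 1) / (2 * g1)
            m1 = min(
                -t[0, 0] * math.log2(p) - (t[0, 1] + t[0, 2]) * math.log2((1 - p) / 2)
                for p in c1
            )
            for g2 in (8, 16, 32, 64):
                grid = (2 * np.arange(g2) + 1) / (2 * g2)
                cells = [(a, b) for a in grid for b in grid if a + b < 1]
                m2 = min(
                    -(t[1, 1] + t[2, 2]) * math.log2(a)
                    - (t[1, 0] + t[2, 0]) * math.log2(b)
                    - (t[1, 2] + t[2, 1]) * math.log2(1 - a - b)
                    for a, b in cells
                )
                best = min(best, math.log2(g1) + math.log2(len(cells)) + m1 + m2)
        assert abs(mml - best) <= 1.0

    def test_local_optimality_of_estimate(self):
        counts = make_counts({("m", "m"): 120, ("m", "i"): 6, ("m", "d"): 6,
                              ("i", "i"): 15, ("i", "m"): 7, ("i", "d"): 2,
                              ("d", "d"): 14, ("d", "m"): 6, ("d", "i"): 2})
        alpha = BinAlpha(np.array([2.0, 1.5]), np.array([2.0, 1.5, 1.0]))
        fit = estimate_theta(counts, alpha)
        th = fit.theta
        t = counts.transitions

        def total(p_mm, p_ii, p_mi):
            cand = MachineParams(p_mm, p_ii, p_mi)
            bits = theta_statement_length(cand, counts, alpha)
            table = complete_parameters(cand)
            return bits - (t * np.log2(np.maximum(table, 1e-300))).sum()

        base = total(th.p_mm, th.p_ii, th.p_mi)
        for d in [(1e-3, 0, 0), (-1e-3, 0, 0), (0, 1e-3, 0),
                  (0, -1e-3, 0), (0, 0, 1e-3), (0, 0, -1e-3)]:
            assert total(th.p_mm + d[0], th.p_ii + d[1], th.p_mi + d[2]) >= base - 1e-6


class TestFitDirichlet:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(4)
        x = rng.dirichlet([5.0, 2.0], size=10_000)
        a = fit_dirichlet(x)
        np.testing.assert_allclose(a, [5.0, 2.0], rtol=0.10)

    def test_swap_symmetry(self):
        rng = np.random.default_rng(5)
        x = rng.dirichlet([3.0, 3.0], size=5000)
        x = np.vstack([x, x[:, ::-1]])
        a = fit_dirichlet(x)
        assert a[0] == pytest.approx(a[1], rel=1e-6)

    def test_mean_identity(self):
        rng = np.random.default_rng(6)
        x = rng.dirichlet([4.0, 2.0, 1.0], size=10_000)
        a = fit_dirichlet(x)
        np.testing.assert_allclose(a / a.sum(), x.mean(axis=0), atol=1e-2)

    def test_degenerate_samples_rejected(self):
        x = np.tile([0.6, 0.4], (100, 1))
        with pytest.raises(ValueError, match="degenerate|variance"):
            fit_dirichlet(x)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            fit_dirichlet(np.array([[0.5, 0.5]] * 3))


class TestFitTimeDirichlets:
    def test_bin_constant_alpha_recovery(self):
        rng = np.random.default_rng(8)
        alphas = {25: ([8.0, 2.0], [5.0, 3.0, 2.0]), 75: ([4.0, 3.0], [3.0, 4.0, 1.5])}
        times, thetas = [], []
        for center, (am, ai) in alphas.items():
            for _ in range(500):
                t = int(rng.integers(center - 24, center + 25))
                m = rng.dirichlet(am)
                v = rng.dirichlet(ai)
                times.append(t)
                thetas.append(MachineParams(float(np.clip(m[0], 1e-6, 1 - 1e-6)),
                                            float(np.clip(v[0], 1e-6, 0.98)),
                                            float(np.clip(v[1], 1e-6, 0.98))))
        tds = fit_time_dirichlets(times, thetas, t_max=100, bin_width=50, min_samples=30)
        np.testing.assert_allclose(tds.lookup(25).alpha_match, [8.0, 2.0], rtol=0.15)
        np.testing.assert_allclose(tds.lookup(75).alpha_match, [4.0, 3.0], rtol=0.15)
        np.testing.assert_allclose(tds.lookup(25).alpha_indel, [5.0, 3.0, 2.0], rtol=0.15)

    def test_sparse_bins_merge_rightward(self):
        rng = np.random.default_rng(10)
        times = [5] * 50 + [995] * 3
        thetas = [
            MachineParams(float(p), 0.5, 0.3)
            for p in np.clip(rng.beta(20, 2, size=53), 1e-6, 1 - 1e-6)
        ]
        tds = fit_time_dirichlets(times, thetas, t_max=1000, bin_width=10, min_samples=30)
        # the trailing sparse region resolves to the last populated bin
        assert tds.lookup(995) == tds.lookup(tds.bins[-1][0])
        assert tds.bins[0][0] == 1 and tds.bins[-1][1] == 1000

    def test_tiny_collection_uses_single_global_bin(self):
        with pytest.warns(UserWarning, match="single global"):
            tds = fit_time_dirichlets([10, 20], [MachineParams(0.9, 0.5, 0.3)] * 2,
                                      t_max=100, bin_width=10)
        assert tds.bins == [(1, 100)]

    def test_generator_trend_visible_in_bin_means(self, small_benchmark):
        # p_mm declines with generation time in the default generator
        _, truth, _, _ = small_benchmark
        lo = truth[truth.t <= 150].p_mm.mean()
        hi = truth[truth.t >= 250].p_mm.mean()
        assert lo > hi


class TestTimeDirichletSetIO:
    def test_tsv_round_trip(self, tmp_path):
        tds = TimeDirichletSet(
            [(1, 40), (41, 1000)],
            [np.array([8.0, 2.0]), np.array([4.0, 3.0])],
            [np.array([5.0, 3.0, 2.0]), np.array([3.0, 4.0, 1.5])],
        )
        path = tmp_path / "alphas.tsv"
        tds.to_tsv(path)
        again = TimeDirichletSet.from_tsv(path)
        assert again.bins == tds.bins
        for a, b in zip(again.alpha_match + again.alpha_indel,
                        tds.alpha_match + tds.alpha_indel):
            np.testing.assert_array_equal(a, b)
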