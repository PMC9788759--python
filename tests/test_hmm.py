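"""Two-state HMM: EM correctness, decoding, dwell extraction, rates."""

import itertools

import numpy as np
import pytest

from proctrace import (
    HMMFit,
    dwells_from_path,
    fit_two_state_hmm,
    fret_histogram,
    get_preset,
    simulate_experiment,
    switching_rates,
    viterbi_states,
)
from proctrace.hmm import (
    contour_data,
    forward_loglikelihood,
    rates_from_dwell_sets,
    rates_from_frame_probs,
)
from proctrace.pipeline import conformational_efficiencies
from proctrace.simulate import SimulationConfig


def _toy_fit(mean_low=0.3, mean_high=0.8, sd=0.1, p01=0.2, p10=0.4):
    A = np.array([[1 - p01, p01], [p10, 1 - p10]])
    return HMMFit(mean_low=mean_low, mean_high=mean_high, sd_low=sd,
                  sd_high=sd, transition_matrix=A,
                  startprob=np.array([0.6, 0.4]), log_likelihood=0.0,
                  ll_history=np.zeros(1), n_iterations=1, converged=True)


def _sim_conf(n_particles=60, duration=60.0, seed=0, preset="conf_wt_atp"):
    pre = get_preset(preset)
    cfg = SimulationConfig(kinetics=pre.kinetics, emission=pre.emission,
                           assay="conformational", n_particles=n_particles,
                           duration=duration)
    movies = simulate_experiment(cfg, seed)
    return movies, conformational_efficiencies(movies, pre.emission), pre


class TestEMFit:
    def test_noiseless_alternating_trace_exact(self):
        trace = np.tile([0.3, 0.3, 0.8, 0.8], 30).astype(float)
        fit = fit_two_state_hmm([trace])
        assert fit.mean_low == pytest.approx(0.3, abs=1e-6)
        assert fit.mean_high == pytest.approx(0.8, abs=1e-6)
        path = viterbi_states(trace, fit)
        np.testing.assert_array_equal(path, (trace > 0.55).astype(int))

    def test_loglikelihood_monotone_over_iterations(self):
        _, traces, _ = _sim_conf(n_particles=20, duration=30.0, seed=1)
        fit = fit_two_state_hmm(traces)
        diffs = np.diff(fit.ll_history)
        assert np.all(diffs >= -1e-7 * np.abs(fit.ll_history[:-1]))

    def test_forward_likelihood_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(2)
        fit = _toy_fit()
        trace = rng.uniform(0.1, 0.9, size=10)
        ll = forward_loglikelihood(trace, fit)
        # brute force over all 2^10 state paths
        from scipy.stats import norm

        means = fit.means
        sds = fit.sds
        A = fit.transition_matrix
        total = 0.0
        for path in itertools.product((0, 1), repeat=trace.size):
            p = fit.startprob[path[0]]
            for t in range(1, trace.size):
                p *= A[path[t - 1], path[t]]
            for t, s in enumerate(path):
                p *= norm.pdf(trace[t], means[s], sds[s])
            total += p
        assert ll == pytest.approx(np.log(total), abs=1e-8)

    def test_label_symmetry_under_swapped_init(self):
        _, traces, _ = _sim_conf(n_particles=15, duration=30.0, seed=3)
        init_a = (np.array([0.3, 0.7]), np.array([0.08, 0.08]))
        init_b = (np.array([0.7, 0.3]), np.array([0.08, 0.08]))
        fa = fit_two_state_hmm(traces, init=init_a)
        fb = fit_two_state_hmm(traces, init=init_b)
        assert fa.mean_low == pytest.approx(fb.mean_low, abs=1e-6)
        assert fa.mean_high == pytest.approx(fb.mean_high, abs=1e-6)
        np.testing.assert_allclose(fa.transition_matrix,
                                   fb.transition_matrix, atol=1e-6)

    def test_emission_recovery_within_five_percent(self):
        _, traces, pre = _sim_conf(n_particles=60, duration=60.0, seed=4)
        fit = fit_two_state_hmm(traces)
        em = pre.emission
        assert abs(fit.mean_low - em.e_low) < 0.05 * em.e_low
        assert abs(fit.mean_high - em.e_high) < 0.05 * em.e_high

    def test_rate_recovery_within_ten_percent(self):
        _, traces, pre = _sim_conf(n_particles=80, duration=60.0, seed=5)
        fit = fit_two_state_hmm(traces)
        k1, k2 = switching_rates(fit, 0.05)
        assert abs(k1 - 1.2) < 0.12
        assert abs(k2 - 4.5) < 0.45

    def test_rows_sum_to_one_and_convergence_flag(self):
        _, traces, _ = _sim_conf(n_particles=10, duration=30.0, seed=6)
        fit = fit_two_state_hmm(traces)
        np.testing.assert_allclose(fit.transition_matrix.sum(axis=1), 1.0)
        assert fit.converged

    def test_matches_hmmlearn_forward_score(self):
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        _, traces, _ = _sim_conf(n_particles=5, duration=30.0, seed=7)
        fit = fit_two_state_hmm(traces)
        model = hmmlearn.GaussianHMM(n_components=2, covariance_type="diag",
                                     init_params="")
        model.startprob_ = fit.startprob
        model.transmat_ = fit.transition_matrix
        model.means_ = fit.means.reshape(-1, 1)
        model.covars_ = (fit.sds ** 2).reshape(-1, 1)
        for tr in traces[:3]:
            mine = forward_loglikelihood(tr, fit)
            theirs = model.score(np.asarray(tr).reshape(-1, 1))
            assert mine == pytest.approx(theirs, abs=1e-6)


class TestViterbi:
    def test_well_separated_equals_threshold(self):
        rng = np.random.default_rng(8)
        fit = _toy_fit(mean_low=0.2, mean_high=0.8, sd=0.06)
        states = (rng.random(500) < 0.4).astype(int)
        trace = np.where(states, 0.8, 0.2) + rng.normal(0, 0.06, 500)
        path = viterbi_states(trace, fit)
        thresh = (trace > 0.5).astype(int)
        assert np.mean(path != thresh) < 0.02

    def test_constant_low_trace_decodes_all_low(self):
        fit = _toy_fit()
        path = viterbi_states(np.full(100, 0.3), fit)
        assert np.all(path == 0)

    def test_misassignment_rate_below_two_percent(self):
        movies, traces, _ = _sim_conf(n_particles=20, duration=60.0, seed=9)
        pairs = [(tr, e) for tr, e in zip(movies[0], traces)
                 if np.isfinite(e).sum() >= 20]
        movies = [[tr for tr, _ in pairs]]
        traces = [e for _, e in pairs]
        fit = fit_two_state_hmm(traces)
        errs, tot = 0, 0
        for tr, e in zip(movies[0], traces):
            path = viterbi_states(e, fit)
            t = (np.arange(e.size) + 0.5) * 0.05
            true = np.array([tr.ground_truth.state_at(ti) != "s1"
                             for ti in t], dtype=int)
            keep = np.isfinite(e)
            errs += int(np.sum(path[keep] != true[keep]))
            tot += int(keep.sum())
        assert errs / tot < 0.02


class TestDwells:
    def test_run_lengths_and_censoring_flags(self):
        low, high = dwells_from_path(np.array([0, 0, 0, 1, 1]), 0.05)
        assert low.durations.tolist() == [pytest.approx(0.15)]
        assert low.censored.tolist() == [True]
        assert high.durations.tolist() == [pytest.approx(0.10)]
        assert high.censored.tolist() == [True]

    def test_single_state_path_fully_censored(self):
        low, high = dwells_from_path(np.zeros(50, dtype=int), 0.05)
        assert low.n == 1 and low.censored.all()
        assert high.n == 0

    def test_dwell_count_equals_transitions_plus_one(self):
        rng = np.random.default_rng(10)
        path = (rng.random(5000) < 0.3).astype(int)
        low, high = dwells_from_path(path, 0.05)
        n_trans = int(np.sum(np.diff(path) != 0))
        assert low.n + high.n == n_trans + 1

    def test_dwell_based_rates_match_truth(self):
        _, traces, _ = _sim_conf(n_particles=80, duration=60.0, seed=11)
        fit = fit_two_state_hmm(traces)
        from proctrace.dwells import DwellSet

        lows, highs = [], []
        for e in traces:
            lo, hi = dwells_from_path(viterbi_states(e, fit), 0.05)
            lows.append(lo)
            highs.append(hi)
        k1, k2 = rates_from_dwell_sets(DwellSet.concat(lows),
                                       DwellSet.concat(highs), 0.05)
        assert abs(k1 - 1.2) < 0.12
        assert abs(k2 - 4.5) < 0.45


class TestRateConversions:
    def test_matrix_log_inverts_exact_sampling(self):
        # expm(Q dt) of a two-state generator, inverted in closed form
        k1, k2, dt = 1.2, 4.5, 0.05
        lam = k1 + k2
        decay = 1 - np.exp(-lam * dt)
        p01 = k1 / lam * decay
        p10 = k2 / lam * decay
        r1, r2 = rates_from_frame_probs(p01, p10, dt, "matrix_log")
        assert r1 == pytest.approx(k1, rel=1e-10)
        assert r2 == pytest.approx(k2, rel=1e-10)

    def test_naive_and_elementwise_underestimate_fast_rates(self):
        k1, k2, dt = 1.2, 4.5, 0.05
        lam = k1 + k2
        decay = 1 - np.exp(-lam * dt)
        p01, p10 = k1 / lam * decay, k2 / lam * decay
        for method in ("naive", "elementwise"):
            _, r2 = rates_from_frame_probs(p01, p10, dt, method)
            assert r2 < k2


class TestHistograms:
    def test_single_value_occupies_one_bin(self):
        dens, edges = fret_histogram([np.full(100, 0.5)], bins=10)
        assert np.sum(dens > 0) == 1

    def test_density_integrates_to_one(self):
        _, traces, _ = _sim_conf(n_particles=10, duration=30.0, seed=12)
        dens, edges = fret_histogram(traces, bins=40)
        assert np.sum(dens * np.diff(edges)) == pytest.approx(1.0)

    def test_telegraph_histogram_is_low_state_dominant(self):
        _, traces, _ = _sim_conf(n_particles=30, duration=60.0, seed=13)
        dens, edges = fret_histogram(traces, bins=20)
        centers = 0.5 * (edges[:-1] + edges[1:])
        low_mass = dens[centers < 0.5].sum()
        high_mass = dens[centers >= 0.5].sum()
        assert low_mass > 2 * high_mass   # s1 occupancy 4.5/5.7 = 0.79

    def test_contour_data_columns_normalized(self):
        _, traces, _ = _sim_conf(n_particles=5, duration=30.0, seed=14)
        sync = [100] * len(traces)
        hist, t_edges, e_edges = contour_data(traces, sync, 0.05)
        sums = hist.sum(axis=1)
        assert np.allclose(sums[sums > 0], 1.0)
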