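"""Event detection, phase segmentation, capture statistics, dwell scoring
and excursion counting."""

import numpy as np
import pytest

from proctrace import (
    DegradationEvent,
    EmissionParams,
    ProcessingDwellConfig,
    SegmentationConfig,
    capture_success,
    count_excursions,
    detect_binding_events,
    estimate_background,
    get_preset,
    preprocess_trace,
    score_processing_dwells,
    segment_degradation_phases,
    simulate_conformational_trajectory,
)
from proctrace.events import BackgroundError
from proctrace.pipeline import preprocess_movies, segment_movies
from proctrace.preprocess import PreprocessConfig
from proctrace.simulate import (
    SimulationConfig,
    render_fluorescence,
    simulate_event_ensemble,
    simulate_experiment,
    trajectory_to_fret,
)
from proctrace.trajectory import Segment, StateTrajectory


class TestEstimateBackground:
    def test_pure_background(self):
        x = np.random.default_rng(0).normal(100.0, 10.0, 2000)
        assert estimate_background(x) == pytest.approx(100.0, rel=0.05)

    def test_mostly_background_with_events(self):
        rng = np.random.default_rng(1)
        x = rng.normal(100.0, 10.0, 1000)
        x[200:400] = rng.normal(1000.0, 10.0, 200)   # 20% events
        assert estimate_background(x) == pytest.approx(100.0, rel=0.05)

    def test_all_signal_trace_raises(self):
        x = np.random.default_rng(2).normal(1000.0, 30.0, 500)
        with pytest.raises(BackgroundError):
            estimate_background(x)


class TestDetectBindingEvents:
    def test_flat_background_no_events(self):
        assert detect_binding_events(np.full(100, 100.0), 100.0) == []

    def test_tie_at_threshold_goes_to_background(self):
        x = np.full(100, 100.0)
        x[40:50] = 200.0   # exactly 2x background: strict inequality
        assert detect_binding_events(x, 100.0) == []

    def test_high_snr_events_recovered_exactly(self):
        rng = np.random.default_rng(3)
        truth = [(100, 160), (400, 480), (900, 920)]
        x = rng.normal(100.0, 20.0, 1000)
        for s, e in truth:
            x[s:e] += 1000.0
        found = detect_binding_events(x, 100.0)
        assert len(found) == len(truth)
        for (fs, fe), (ts, te) in zip(found, truth):
            assert abs(fs - ts) <= 1 and abs(fe - te) <= 1

    def test_raw_peak_confirmation_rejects_noise_runs(self):
        x = np.full(1000, 100.0)
        x[500:505] = 215.0           # 2x-background run without a real peak
        raw = np.random.default_rng(4).normal(100.0, 50.0, 1000)
        assert detect_binding_events(x, 100.0, raw_total=raw) == []

    def test_spike_pass_recovers_single_frame_event(self):
        x = np.full(1000, 100.0)     # smoothed total never crosses 2x
        raw = np.random.default_rng(5).normal(100.0, 50.0, 1000)
        raw[321] = 1100.0
        found = detect_binding_events(x, 100.0, raw_total=raw)
        assert found == [(321, 322)]


def _render_event(phases, em, seed=0, frame_period=0.05, lead=2.0, tail=5.0,
                  supersample=1):
    states = ["unbound", "bound_preinsert", "inserted_highFRET",
              "translocating", "unfolding", "post_translocation"]
    durs = [lead] + list(phases)
    if tail > 0:
        states = states + ["unbound"]
        durs = durs + [tail]
    traj = StateTrajectory.from_durations(states, durs)
    n = int(np.ceil(traj.end / frame_period))
    ideal = trajectory_to_fret(traj, em, frame_period=frame_period,
                               n_frames=n, supersample=supersample)
    return render_fluorescence(ideal, em, seed, ground_truth=traj)


class TestSegmentation:
    def test_noiseless_phase_boundaries_within_one_frame(self, em_quiet):
        phases = (1.8, 1.1, 0.74, 6.0, 7.3)
        tr = _render_event(phases, em_quiet, seed=0)
        pt = preprocess_trace(tr, PreprocessConfig(
            alpha=em_quiet.alpha,
            background=(em_quiet.background_donor,
                        em_quiet.background_acceptor)))
        bg = pt.background_total
        ivs = detect_binding_events(pt.total, bg, raw_total=pt.raw_total)
        assert len(ivs) == 1
        ev = segment_degradation_phases(pt.e_app, pt.total, ivs[0],
                                        pt.frame_period, bg)
        assert ev.label == "productive"
        assert ev.dur_insertion == pytest.approx(1.8, abs=0.06)
        assert ev.dur_high_fret == pytest.approx(1.1, abs=0.06)
        assert ev.dur_decay == pytest.approx(0.74, abs=0.06)
        assert ev.dur_donor_dwell == pytest.approx(13.3, abs=0.11)
        # phase durations + inter-phase gaps tile the event
        total = (ev.dur_insertion + ev.dur_high_fret + ev.dur_decay
                 + ev.dur_donor_dwell)
        assert total == pytest.approx(ev.duration, abs=0.12)

    def test_intermediate_only_event_is_nonproductive(self, em_quiet):
        traj = StateTrajectory.from_durations(
            ["unbound", "bound_preinsert", "unbound"], [2.0, 1.5, 3.0])
        n = int(np.ceil(traj.end / 0.05))
        tr = render_fluorescence(
            trajectory_to_fret(traj, em_quiet, frame_period=0.05, n_frames=n),
            em_quiet, 0)
        pt = preprocess_trace(tr, PreprocessConfig(
            alpha=em_quiet.alpha,
            background=(em_quiet.background_donor,
                        em_quiet.background_acceptor)))
        bg = pt.background_total
        ivs = detect_binding_events(pt.total, bg, raw_total=pt.raw_total)
        ev = segment_degradation_phases(pt.e_app, pt.total, ivs[0],
                                        pt.frame_period, bg)
        assert ev.label == "nonproductive"
        lo, hi = SegmentationConfig().intermediate_band
        assert lo <= ev.median_e <= hi

    def test_event_touching_trace_end_is_censored(self, em_quiet):
        tr = _render_event((1.8, 1.1, 0.74, 6.0, 30.0), em_quiet, tail=0.0)
        pt = preprocess_trace(tr, PreprocessConfig(
            alpha=em_quiet.alpha,
            background=(em_quiet.background_donor,
                        em_quiet.background_acceptor)))
        bg = pt.background_total
        ivs = detect_binding_events(pt.total, bg, raw_total=pt.raw_total)
        ev = segment_degradation_phases(pt.e_app, pt.total, ivs[-1],
                                        pt.frame_period, bg)
        assert ev.censored

    def test_noisy_ensemble_recovers_high_fret_mean(self, kin_wt):
        em = get_preset("wt").emission
        traces = simulate_event_ensemble(kin_wt, em, 200, seed=6)
        events = segment_movies(preprocess_movies([traces], em))
        from proctrace import fit_gamma_mle
        from proctrace.pipeline import phase_dwell_sets

        ds = phase_dwell_sets(events)["tau_dub"]
        fit = fit_gamma_mle(ds, n_boot=0)
        assert abs(fit.mean - kin_wt.tau_dub) < 0.15 * kin_wt.tau_dub


class TestCaptureSuccess:
    @staticmethod
    def _ev(label, censored=False):
        return DegradationEvent(start=0.0, end=1.0, label=label,
                                censored=censored)

    def test_all_productive(self):
        movies = [[self._ev("productive")] * 4]
        assert capture_success(movies).fraction == 1.0

    def test_pooled_arithmetic(self):
        movie = ([self._ev("productive")] * 34
                 + [self._ev("nonproductive")] * 66)
        stats = capture_success([movie])
        assert stats.fraction == pytest.approx(0.34)
        assert stats.n_total == 100

    def test_censored_events_excluded(self):
        movie = [self._ev("productive"), self._ev("productive", censored=True),
                 self._ev("nonproductive")]
        stats = capture_success([movie])
        assert stats.n_total == 2

    def test_invariant_to_movie_relabeling(self):
        m1 = [self._ev("productive")] * 3 + [self._ev("nonproductive")] * 7
        m2 = [self._ev("productive")] * 5 + [self._ev("nonproductive")] * 5
        a = capture_success([m1, m2])
        b = capture_success([m2, m1])
        assert a.fraction == b.fraction
        assert a.sd_across_movies == b.sd_across_movies

    def test_empty_movie_warned_and_dropped(self):
        with pytest.warns(UserWarning, match="no events"):
            stats = capture_success([[], [self._ev("productive")]])
        assert stats.n_total == 1

    def test_simulated_capture_probability_recovered(self):
        pre = get_preset("sspb")
        sim = SimulationConfig(kinetics=pre.kinetics, emission=pre.emission,
                               assay="processing", n_particles=30, n_movies=3,
                               duration=200.0)
        movies = simulate_experiment(sim, seed=21)
        stats = capture_success(segment_movies(
            preprocess_movies(movies, pre.emission)))
        assert abs(stats.fraction - 0.17) < 0.04


class TestProcessingDwells:
    def test_single_high_block_scored(self):
        dt = 0.05
        e = np.full(400, 0.25)
        e[100:314] = 0.75          # 10.7 s of high efficiency
        dwells, ds = score_processing_dwells(e, dt)
        assert len(dwells) == 1
        assert dwells[0].duration == pytest.approx(10.7, abs=0.1)
        assert not dwells[0].censored

    def test_brief_excursions_bridged(self):
        dt = 0.05
        e = np.full(500, 0.25)
        e[100:340] = 0.78
        for s in (150, 220, 290):   # three 0.2 s excursions
            e[s:s + 4] = 0.2
        dwells, _ = score_processing_dwells(e, dt)
        assert len(dwells) == 1
        assert dwells[0].duration == pytest.approx(12.0, abs=0.1)

    def test_substrate_free_telegraph_has_no_dwells(self):
        pre = get_preset("conf_wt_atp")
        sim = SimulationConfig(kinetics=pre.kinetics, emission=pre.emission,
                               assay="conformational", n_particles=30,
                               duration=100.0)
        movies = simulate_experiment(sim, seed=8)
        from proctrace.pipeline import conformational_efficiencies

        n_dwells = 0
        for e in conformational_efficiencies(movies, pre.emission):
            dwells, _ = score_processing_dwells(e, 0.05)
            n_dwells += sum(not d.censored for d in dwells)
        assert n_dwells == 0

    def test_dwell_truncated_by_trace_end_censored(self):
        e = np.full(300, 0.25)
        e[150:] = 0.78
        dwells, _ = score_processing_dwells(e, 0.05)
        assert len(dwells) == 1
        assert dwells[0].censored


class TestCountExcursions:
    def _dwell_path(self, excursions, total=30.0):
        states, durs = [], []
        t = 0.0
        for start, dur in excursions:
            states += ["non_s1", "s1_excursion"]
            durs += [start - t, dur]
            t = start + dur
        states.append("non_s1")
        durs.append(total - t)
        return StateTrajectory.from_durations(states, durs)

    def test_no_low_state_visits(self):
        path = StateTrajectory([Segment("non_s1", 0, 30.0)])
        assert count_excursions(path, (0.0, 30.0)) == 0

    def test_eleven_planted_excursions_counted(self):
        exc = [(2.0 + 2.3 * k, 0.1 + 0.02 * k) for k in range(11)]
        path = self._dwell_path(exc)
        assert count_excursions(path, (0.0, 30.0)) == 11

    def test_forty_ms_excursion_below_resolution_floor(self):
        path = self._dwell_path([(5.0, 0.040)])
        assert count_excursions(path, (0.0, 30.0), min_duration=0.05) == 0

    def test_monotone_in_min_duration(self):
        exc = [(2.0, 0.04), (5.0, 0.08), (9.0, 0.2), (14.0, 0.6)]
        path = self._dwell_path(exc)
        counts = [count_excursions(path, (0.0, 30.0), m)
                  for m in (0.0, 0.05, 0.1, 0.3, 1.0)]
        assert counts == sorted(counts, reverse=True)

    def test_efficiency_route_with_camera_integration(self, em_clean):
        # rendered with frame integration, a 40 ms dip integrates to <50 ms
        # occupancy while 100+ ms dips are counted
        exc = [(3.0, 0.04), (6.0, 0.12), (9.0, 0.15), (12.0, 0.3)]
        path = self._dwell_path(exc, total=20.0)
        ideal = trajectory_to_fret(path, em_clean, frame_period=0.05,
                                   supersample=10)
        e = ideal.efficiency
        n = count_excursions(e, (0.0, 20.0), min_duration=0.05,
                             frame_period=0.05,
                             e_high_ref=em_clean.e_high,
                             e_low_ref=em_clean.e_low)
        assert n == 3
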