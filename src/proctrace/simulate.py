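"""Forward simulation of single-molecule FRET traces of proteasomal
substrate processing.

The simulator produces ground-truth :class:`~proctrace.trajectory.StateTrajectory`
objects for three experiment types and renders them into realistic
two-channel fluorescence traces:

* **processing assay** — a substrate-attached donor dye and a motor-attached
  acceptor: each productive binding event runs through tail insertion
  (intermediate FRET), a high-FRET deubiquitination dwell, a gradual FRET
  decay as ~24 residues translocate past the acceptor, and a long
  donor-only dwell covering unfolding and peptide release; nonproductive
  events show only intermediate FRET until dissociation.
* **conformational assay** — lid- and base-attached dyes report the
  two-state s1 / non-s1 telegraph switching of the regulatory particle.
* **conformational assay during degradation** — telegraph idling
  interrupted by long non-s1 processing dwells with brief s1 excursions
  (motor slips) while the substrate's folded domain resists unfolding.

Rendering adds donor->acceptor bleedthrough, per-channel background and
noise, and single-step photobleaching, so every downstream analysis stage
can be validated by parameter recovery against the ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .params import EmissionParams, InvalidParameterError, KineticParams
from .trajectory import (
    CONFORMATIONAL_STATES,
    DONOR_PRESENT_STATES,
    PROCESSING_STATES,
    S1_LIKE_STATES,
    Segment,
    StateTrajectory,
)

RngLike = Union[int, np.random.Generator, np.random.SeedSequence]


def as_rng(seed: RngLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# ground-truth trajectories
# ---------------------------------------------------------------------------

def simulate_conformational_trajectory(
    k_s1: float,
    k_non_s1: float,
    duration: float,
    seed: RngLike,
    start_state: Optional[str] = None,
) -> StateTrajectory:
    """Continuous-time two-state telegraph path of s1/non-s1 switching.

    The chain starts from its stationary distribution (or ``start_state``),
    dwells are exponential with means ``1/k_s1`` in s1 and ``1/k_non_s1``
    in non-s1, and a rate of exactly zero pins the chain in the
    corresponding state.
    """
    if k_s1 < 0 or k_non_s1 < 0:
        raise InvalidParameterError("rates must be non-negative")
    if duration <= 0:
        raise InvalidParameterError("duration must be positive")
    if k_s1 == 0 and k_non_s1 == 0:
        raise InvalidParameterError(
            "at least one switching rate must be positive")
    rng = as_rng(seed)
    rates = {"s1": k_s1, "non_s1": k_non_s1}
    if start_state is None:
        p_s1 = k_non_s1 / (k_s1 + k_non_s1)
        state = "s1" if rng.random() < p_s1 else "non_s1"
    else:
        if start_state not in CONFORMATIONAL_STATES:
            raise InvalidParameterError(f"unknown state {start_state!r}")
        state = start_state

    segs: List[Segment] = []
    t = 0.0
    while t < duration:
        k = rates[state]
        dwell = rng.exponential(1.0 / k) if k > 0 else duration - t
        end = min(t + dwell, duration)
        segs.append(Segment(state, t, end))
        t = end
        state = "non_s1" if state == "s1" else "s1"
    return StateTrajectory(segs)


def _gamma_dwell(rng: np.random.Generator, mean: float, shape: float) -> float:
    return float(rng.gamma(shape, mean / shape))


def _poisson_excursions(
    rng: np.random.Generator,
    window: float,
    rate: float,
    mean_dur: float,
) -> List[Tuple[float, float]]:
    """Excursion (offset, duration) pairs on [0, window), non-overlapping."""
    if rate <= 0 or window <= 0:
        return []
    n = rng.poisson(rate * window)
    starts = np.sort(rng.uniform(0.0, window, size=n))
    out: List[Tuple[float, float]] = []
    cursor = 0.0
    for s in starts:
        if s < cursor:
            continue  # drop excursions that would overlap the previous one
        d = float(rng.exponential(mean_dur))
        out.append((float(s), d))
        cursor = s + 1e-9
    return out


def simulate_degradation_trajectory(
    params: KineticParams,
    seed: RngLike,
    t0: float = 0.0,
) -> StateTrajectory:
    """One substrate binding event of the processing assay.

    With probability ``p_capture`` the event is productive and runs
    ``bound_preinsert -> inserted_highFRET -> translocating -> unfolding
    (interleaved with s1 excursions) -> post_translocation``; otherwise it
    is a single ``bound_preinsert`` segment of exponential mean
    ``tau_off``.  Phase durations follow the distributions declared in
    :class:`~proctrace.params.KineticParams`.
    """
    rng = as_rng(seed)
    if rng.random() >= params.p_capture:
        dwell = float(rng.exponential(params.tau_off))
        return StateTrajectory([Segment("bound_preinsert", t0, t0 + max(dwell, 1e-9))])

    states: List[str] = ["bound_preinsert", "inserted_highFRET", "translocating"]
    durs: List[float] = [
        _gamma_dwell(rng, params.tau_ins, params.n_ins),
        _gamma_dwell(rng, params.tau_dub, params.n_dub),
        _gamma_dwell(rng, params.tau_decay, params.n_dec),
    ]

    unfold_total = float(rng.exponential(params.tau_unfold))
    window = max(unfold_total - params.excursion_free_tail, 0.0)
    excursions = _poisson_excursions(
        rng, window, params.excursion_rate, params.excursion_mean_dur)
    # excursions pause the unfolding clock: wall time is extended
    cursor = 0.0
    for off, dur in excursions:
        if off > cursor:
            states.append("unfolding")
            durs.append(off - cursor)
        states.append("s1_excursion")
        durs.append(dur)
        cursor = off
    if unfold_total > cursor:
        states.append("unfolding")
        durs.append(unfold_total - cursor)

    states.append("post_translocation")
    durs.append(float(rng.exponential(params.tau_post)))
    durs = [max(d, 1e-9) for d in durs]
    return StateTrajectory.from_durations(states, durs, t0=t0)


@dataclass
class ProcessingDwellTruth:
    start: float
    end: float
    censored: bool = False
    n_excursions: int = 0

    @property
    def duration(self) -> float:
        return self.end - self.start


def simulate_processing_conformational(
    params: KineticParams,
    duration: float,
    seed: RngLike,
) -> Tuple[StateTrajectory, List[ProcessingDwellTruth]]:
    """Conformational-assay trace containing substrate-processing dwells.

    Between degradation events the proteasome idles as a telegraph process
    at (``k_s1``, ``k_non_s1``).  Substrates arrive at ``arrival_rate``;
    each engagement pins the trace in non-s1 for a gamma-distributed
    processing dwell (mean ``tau_deg``, shape ``n_deg``) with brief s1
    excursions at ``excursion_rate`` except during the excursion-free
    tail, after which the proteasome stably returns to s1.
    """
    if params.tau_deg is None:
        raise InvalidParameterError(
            "tau_deg must be set for the conformational-processing simulator")
    if duration <= 0:
        raise InvalidParameterError("duration must be positive")
    rng = as_rng(seed)
    segs: List[Segment] = []
    dwells: List[ProcessingDwellTruth] = []
    t = 0.0
    while t < duration:
        wait = (float(rng.exponential(1.0 / params.arrival_rate))
                if params.arrival_rate > 0 else duration - t)
        idle_end = min(t + wait, duration)
        if idle_end > t:
            idle = simulate_conformational_trajectory(
                params.k_s1, params.k_non_s1, idle_end - t, rng,
                start_state="s1" if segs else None)
            for s in idle.segments:
                segs.append(Segment(s.state, s.start + t, s.end + t))
        t = idle_end
        if t >= duration:
            break
        # processing dwell
        dw = _gamma_dwell(rng, params.tau_deg, params.n_deg)
        window = max(dw - params.excursion_free_tail, 0.0)
        exc = _poisson_excursions(
            rng, window, params.excursion_rate, params.excursion_mean_dur)
        cursor = 0.0
        sub: List[Tuple[str, float]] = []
        for off, d in exc:
            d = min(d, max(window - off, 1e-3))  # excursions stay in window
            if off > cursor:
                sub.append(("non_s1", off - cursor))
            sub.append(("s1_excursion", d))
            cursor = off + d
        if dw > cursor:
            sub.append(("non_s1", dw - cursor))
        censored = t + dw > duration
        end = min(t + dw, duration)
        dwells.append(ProcessingDwellTruth(t, end, censored, len(exc)))
        tt = t
        for st, d in sub:
            if tt >= end:
                break
            segs.append(Segment(st, tt, min(tt + d, end)))
            tt = min(tt + d, end)
        t = end
    traj = StateTrajectory(segs)
    return traj, dwells


# ---------------------------------------------------------------------------
# trajectory -> ideal efficiency -> fluorescence
# ---------------------------------------------------------------------------

@dataclass
class IdealTrace:
    """Noiseless per-frame photophysics of a trajectory.

    ``donor_frac`` and ``acceptor_frac`` are the fractions of the pair
    brightness emitted in each channel (occupancy-weighted within each
    frame, i.e. camera integration); ``presence`` is the within-frame duty
    cycle of the donor dye.
    """

    donor_frac: np.ndarray
    acceptor_frac: np.ndarray
    presence: np.ndarray
    frame_period: float

    @property
    def n_frames(self) -> int:
        return self.donor_frac.size

    @property
    def efficiency(self) -> np.ndarray:
        """Apparent efficiency where the dye is present, NaN elsewhere."""
        with np.errstate(invalid="ignore", divide="ignore"):
            e = np.where(self.presence > 0,
                         self.acceptor_frac / np.maximum(self.presence, 1e-12),
                         np.nan)
        return e


_CONF_LEVELS = {"s1": "e_low", "non_s1": "e_high", "s1_excursion": "e_low"}


def _segment_efficiency_endpoints(
    traj: StateTrajectory,
    em: EmissionParams,
    cal=None,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-segment (start, end, E_start, E_end, presence) arrays."""
    states = traj.states()
    conf = states <= set(CONFORMATIONAL_STATES) | {"s1_excursion"}
    proc = states <= set(PROCESSING_STATES)
    if not (conf or proc):
        unknown = states - set(PROCESSING_STATES) - set(CONFORMATIONAL_STATES)
        raise ValueError(f"unknown state labels: {sorted(unknown)}")

    n = len(traj.segments)
    e0 = np.zeros(n)
    e1 = np.zeros(n)
    present = np.ones(n)

    if conf:
        for i, seg in enumerate(traj.segments):
            lvl = getattr(em, _CONF_LEVELS[seg.state])
            e0[i] = e1[i] = lvl
        starts, ends, _ = traj.as_arrays()
        return starts, ends, e0, e1, present

    # processing assay: track cumulative unfolding progress per event
    # (events are separated by 'unbound' segments)
    const_levels = {
        "bound_preinsert": em.e_bind,
        "inserted_highFRET": em.e_peak,
        "post_translocation": 0.0,
    }
    # total unfolding time per event, for the e_exit -> e_residual ramp
    unfold_totals: List[float] = []
    acc = 0.0
    seen_event = False
    for seg in traj.segments:
        if seg.state == "unbound":
            if seen_event:
                unfold_totals.append(acc)
            acc, seen_event = 0.0, False
        else:
            seen_event = True
            if seg.state == "unfolding":
                acc += seg.duration
    if seen_event:
        unfold_totals.append(acc)

    event_idx = -1
    in_event = False
    done = 0.0
    for i, seg in enumerate(traj.segments):
        st = seg.state
        if st == "unbound":
            present[i] = 0.0
            in_event = False
            continue
        if not in_event:
            event_idx += 1
            in_event = True
            done = 0.0
        if st in const_levels:
            e0[i] = e1[i] = const_levels[st]
        elif st == "translocating":
            # 24-residue ramp through the position calibration
            if cal is None:
                e0[i], e1[i] = em.e_peak, em.e_exit
            else:
                e0[i] = float(cal(0.0))
                e1[i] = float(cal(cal.max_offset))
        elif st in ("unfolding", "s1_excursion"):
            total = unfold_totals[event_idx]
            frac0 = done / total if total > 0 else 1.0
            lo, hi = em.e_residual, em.e_exit
            e0[i] = hi + (lo - hi) * frac0
            if st == "unfolding":
                done += seg.duration
                frac1 = done / total if total > 0 else 1.0
                e1[i] = hi + (lo - hi) * frac1
            else:  # the dye does not move during a slip
                e1[i] = e0[i]
        else:  # pragma: no cover - guarded above
            raise ValueError(f"unknown state label: {st!r}")
    starts, ends, _ = traj.as_arrays()
    return starts, ends, e0, e1, present


def trajectory_to_fret(
    traj: StateTrajectory,
    em: EmissionParams,
    cal=None,
    *,
    frame_period: float = 0.05,
    n_frames: Optional[int] = None,
    supersample: int = 1,
) -> IdealTrace:
    """Rasterize a state trajectory onto the camera frame grid.

    By default each frame carries the instantaneous efficiency and dye
    presence at its center (point sampling on the frame grid, which keeps
    the two-state telegraph statistics exactly invertible); ``supersample``
    > 1 instead integrates over sub-samples, emulating camera
    integration.  The
    translocating phase ramps from the 0.82 peak anchor to the 0.32 exit
    anchor (through ``cal``, a :class:`~proctrace.kinetics.CalibrationMap`,
    when given; linearly otherwise), and unfolding continues a slow
    decline to a small residual efficiency.
    """
    if frame_period <= 0:
        raise InvalidParameterError("frame_period must be positive")
    if n_frames is None:
        n_frames = int(np.ceil(traj.end / frame_period))
    starts, ends, e0, e1, present = _segment_efficiency_endpoints(traj, em, cal)

    ss = int(supersample)
    t = (np.arange(n_frames * ss) + 0.5) * (frame_period / ss)
    idx = np.clip(np.searchsorted(ends, t, side="right"), 0, len(ends) - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = (t - starts[idx]) / np.maximum(ends[idx] - starts[idx], 1e-12)
    frac = np.clip(frac, 0.0, 1.0)
    e_t = e0[idx] + (e1[idx] - e0[idx]) * frac
    p_t = present[idx]
    # sub-samples before the trajectory start or after its end are dark
    p_t = np.where((t >= traj.start) & (t <= traj.end), p_t, 0.0)

    acc = (e_t * p_t).reshape(n_frames, ss).mean(axis=1)
    don = ((1.0 - e_t) * p_t).reshape(n_frames, ss).mean(axis=1)
    pres = p_t.reshape(n_frames, ss).mean(axis=1)
    return IdealTrace(don, acc, pres, frame_period)


@dataclass
class FluorescenceTrace:
    """Raw two-channel intensity time series for one particle."""

    donor: np.ndarray
    acceptor: np.ndarray
    frame_period: float
    integration_time: float
    particle_id: str = "p0"
    condition: str = ""
    movie_id: str = "m0"
    ground_truth: Optional[StateTrajectory] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.donor) != len(self.acceptor):
            raise ValueError("donor and acceptor must have equal length")
        if self.frame_period <= 0:
            raise InvalidParameterError("frame_period must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.donor)

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_period


def render_fluorescence(
    ideal: IdealTrace,
    em: EmissionParams,
    seed: RngLike,
    **trace_kwargs,
) -> FluorescenceTrace:
    """Render an ideal trace into noisy two-channel counts.

    ``donor = brightness*(1-E)*presence + background + noise`` and
    ``acceptor = brightness*E*presence + alpha*donor_signal + background +
    noise``.  Single-step photobleaching times are drawn exponentially:
    one acceptor clock per trace, one donor clock per presence block
    (each binding event carries a fresh donor).
    """
    rng = as_rng(seed)
    don = ideal.donor_frac.copy()
    acc = ideal.acceptor_frac.copy()
    pres = ideal.presence.copy()
    dt = ideal.frame_period
    n = don.size

    bleach_meta = {"donor_bleach_frames": [], "acceptor_bleach_frame": None}
    if em.bleach_rate_acceptor > 0:
        # the acceptor is excited via FRET only, so its bleach clock runs
        # on accumulated acceptor emission, not wall time
        exposure = np.cumsum(acc) * dt
        budget = rng.exponential(1.0 / em.bleach_rate_acceptor)
        hit = np.flatnonzero(exposure >= budget)
        if hit.size:
            fa = int(hit[0])
            don[fa:] += acc[fa:]   # no transfer once the acceptor is dark
            acc[fa:] = 0.0
            bleach_meta["acceptor_bleach_frame"] = fa
    if em.bleach_rate_donor > 0:
        on = pres > 0
        # presence blocks = individual dye exposures
        edges = np.flatnonzero(np.diff(on.astype(int)) != 0) + 1
        blocks = np.split(np.arange(n), edges)
        for blk in blocks:
            if blk.size == 0 or not on[blk[0]]:
                continue
            t_d = rng.exponential(1.0 / em.bleach_rate_donor)
            fd = int(t_d / dt)
            if fd < blk.size:
                cut = blk[fd]
                stop = blk[-1] + 1
                don[cut:stop] = 0.0
                acc[cut:stop] = 0.0
                pres[cut:stop] = 0.0
                bleach_meta["donor_bleach_frames"].append(int(cut))

    d_sig = em.brightness * don
    a_sig = em.brightness * acc + em.alpha * em.brightness * don
    d = d_sig + em.background_donor
    a = a_sig + em.background_acceptor
    if em.noise_sd > 0 or em.noise_model == "shot":
        if em.noise_model == "shot":
            sd_d = np.sqrt(em.noise_sd ** 2 + np.maximum(d, 0.0))
            sd_a = np.sqrt(em.noise_sd ** 2 + np.maximum(a, 0.0))
        else:
            sd_d = sd_a = em.noise_sd
        d = d + rng.normal(0.0, 1.0, n) * sd_d
        a = a + rng.normal(0.0, 1.0, n) * sd_a
    meta = dict(trace_kwargs.pop("meta", {}))
    meta.update(bleach_meta)
    return FluorescenceTrace(
        donor=d, acceptor=a, frame_period=dt, integration_time=dt,
        meta=meta, **trace_kwargs)


# ---------------------------------------------------------------------------
# ensembles
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """One simulated acquisition: condition, ensemble size and acquisition.

    ``assay`` selects the experiment type: ``"processing"`` (substrate-dye
    degradation events), ``"conformational"`` (substrate-free telegraph
    switching) or ``"conformational_processing"`` (telegraph idling with
    processing dwells).
    """

    kinetics: KineticParams = field(default_factory=KineticParams)
    emission: EmissionParams = field(default_factory=EmissionParams)
    assay: str = "processing"
    condition: str = "wt"
    n_particles: int = 50
    n_movies: int = 1
    duration: float = 300.0
    frame_period: float = 0.05
    supersample: int = 1

    def __post_init__(self) -> None:
        if self.n_particles <= 0 or self.duration <= 0:
            raise InvalidParameterError(
                "n_particles and duration must be positive")
        if self.assay not in (
                "processing", "conformational", "conformational_processing"):
            raise InvalidParameterError(f"unknown assay {self.assay!r}")


def _processing_particle_trajectory(
    params: KineticParams, duration: float, rng: np.random.Generator
) -> Tuple[StateTrajectory, List[dict]]:
    """Unbound stretches with Poisson substrate arrivals (busy server)."""
    segs: List[Segment] = []
    events: List[dict] = []
    t = 0.0
    while t < duration:
        if params.arrival_rate <= 0:
            segs.append(Segment("unbound", t, duration))
            t = duration
            break
        wait = float(rng.exponential(1.0 / params.arrival_rate))
        if t + wait >= duration:
            segs.append(Segment("unbound", t, duration))
            t = duration
            break
        if wait > 0:
            segs.append(Segment("unbound", t, t + wait))
        ev = simulate_degradation_trajectory(params, rng, t0=t + wait)
        productive = "inserted_highFRET" in ev.states()
        censored = ev.end > duration
        for s in ev.segments:
            if s.start >= duration:
                break
            segs.append(Segment(s.state, s.start, min(s.end, duration)))
        events.append({
            "start": ev.start, "end": min(ev.end, duration),
            "productive": bool(productive), "censored": bool(censored),
            "phases": {st: float(ev.durations_of(st).sum())
                       for st in ev.states()},
        })
        t = min(ev.end, duration)
    if not segs:
        segs.append(Segment("unbound", 0.0, duration))
    return StateTrajectory(segs), events


def simulate_experiment(
    config: SimulationConfig, seed: RngLike
) -> List[List[FluorescenceTrace]]:
    """Simulate ``n_movies`` movies of ``n_particles`` traces each.

    Ground truth (state trajectory, event records or processing dwells)
    is kept on each trace; identical seeds give bit-identical output.
    """
    root = (seed if isinstance(seed, np.random.SeedSequence)
            else np.random.SeedSequence(seed))
    n_frames = int(round(config.duration / config.frame_period))
    movies: List[List[FluorescenceTrace]] = []
    movie_seeds = root.spawn(config.n_movies)
    for m, mseed in enumerate(movie_seeds):
        traces: List[FluorescenceTrace] = []
        for p, pseed in enumerate(mseed.spawn(config.n_particles)):
            rng = np.random.default_rng(pseed)
            meta: dict = {}
            if config.assay == "processing":
                traj, events = _processing_particle_trajectory(
                    config.kinetics, config.duration, rng)
                meta["events"] = events
            elif config.assay == "conformational":
                traj = simulate_conformational_trajectory(
                    config.kinetics.k_s1, config.kinetics.k_non_s1,
                    config.duration, rng)
            else:
                traj, dwells = simulate_processing_conformational(
                    config.kinetics, config.duration, rng)
                meta["processing_dwells"] = [asdict(d) for d in dwells]
            ideal = trajectory_to_fret(
                traj, config.emission, frame_period=config.frame_period,
                n_frames=n_frames, supersample=config.supersample)
            tr = render_fluorescence(
                ideal, config.emission, rng,
                particle_id=f"p{p:04d}", movie_id=f"m{m:02d}",
                condition=config.condition, ground_truth=traj, meta=meta)
            traces.append(tr)
        movies.append(traces)
    return movies


def simulate_event_ensemble(
    params: KineticParams,
    em: EmissionParams,
    n_events: int,
    seed: RngLike,
    *,
    frame_period: float = 0.05,
    lead_in: float = 2.0,
    margin: float = 5.0,
    supersample: int = 1,
    condition: str = "",
) -> List[FluorescenceTrace]:
    """One binding event per trace, ``n_events`` traces.

    Convenience generator for phase-duration recovery studies: each trace
    holds a single event starting after ``lead_in`` seconds, and the trace
    is long enough (event + ``margin``) that no event is censored.
    """
    root = (seed if isinstance(seed, np.random.SeedSequence)
            else np.random.SeedSequence(seed))
    traces = []
    for i, sseq in enumerate(root.spawn(n_events)):
        rng = np.random.default_rng(sseq)
        ev = simulate_degradation_trajectory(params, rng, t0=lead_in)
        segs = [Segment("unbound", 0.0, lead_in)] + list(ev.segments)
        segs.append(Segment("unbound", ev.end, ev.end + margin))
        traj = StateTrajectory(segs)
        n_frames = int(np.ceil(traj.end / frame_period))
        ideal = trajectory_to_fret(
            traj, em, frame_period=frame_period, n_frames=n_frames,
            supersample=supersample)
        traces.append(render_fluorescence(
            ideal, em, rng, particle_id=f"p{i:04d}", condition=condition,
            ground_truth=traj,
            meta={"events": [{
                "start": ev.start, "end": ev.end,
                "productive": "inserted_highFRET" in ev.states(),
                "censored": False,
                "phases": {st: float(ev.durations_of(st).sum())
                           for st in ev.states()},
            }]}))
    return traces
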