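"""End-to-end orchestration: simulate -> preprocess -> segment -> fit -> report.

`run_pipeline` executes one condition deterministically from a config and
seed, producing a report that juxtaposes every recovered constant with the
generator's ground truth (the published value encoded in the preset) and a
pass/fail at the configured tolerance.  Reports are plain dicts, written
as JSON and Markdown; identical config+seed gives byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import events as ev
from . import hmm as hm
from . import kinetics as kin
from .dwells import DwellSet
from .params import EmissionParams, KineticParams
from .preprocess import PreprocessConfig, ProcessedTrace, preprocess_trace
from .presets import ConditionPreset, get_preset
from .simulate import FluorescenceTrace, SimulationConfig, simulate_experiment


@dataclass
class AnalysisConfig:
    """Thresholds and windows of the analysis stages."""

    segmentation: ev.SegmentationConfig = field(
        default_factory=ev.SegmentationConfig)
    dwell_scoring: ev.ProcessingDwellConfig = field(
        default_factory=ev.ProcessingDwellConfig)
    smoothing_window: int = 5
    hmm_max_iter: int = 500
    rate_method: str = "matrix_log"
    tolerance: float = 0.15


@dataclass
class ExperimentConfig:
    """One pipeline run: a condition preset, ensemble size and seed."""

    preset: str = "wt"
    n_particles: int = 50
    n_movies: int = 1
    duration: float = 300.0
    seed: int = 0
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    kinetics_overrides: dict = field(default_factory=dict)
    emission_overrides: dict = field(default_factory=dict)

    def resolve(self) -> Tuple[ConditionPreset, SimulationConfig]:
        pre = get_preset(self.preset)
        kinp = pre.kinetics.evolve(**self.kinetics_overrides) \
            if self.kinetics_overrides else pre.kinetics
        emp = pre.emission.evolve(**self.emission_overrides) \
            if self.emission_overrides else pre.emission
        sim = SimulationConfig(
            kinetics=kinp, emission=emp, assay=pre.assay,
            condition=pre.name, n_particles=self.n_particles,
            n_movies=self.n_movies, duration=self.duration,
            frame_period=pre.frame_period)
        return pre, sim


# ---------------------------------------------------------------------------
# analysis stages shared by pipeline, tests and the acceptance script
# ---------------------------------------------------------------------------

def preprocess_movies(
    movies: Sequence[Sequence[FluorescenceTrace]],
    emission: EmissionParams,
    window: int = 5,
) -> List[List[ProcessedTrace]]:
    """Preprocess every trace using the known dark-level backgrounds."""
    cfg = PreprocessConfig(
        window=window, alpha=emission.alpha,
        background=(emission.background_donor, emission.background_acceptor))
    return [[preprocess_trace(tr, cfg) for tr in movie] for movie in movies]


def segment_movies(
    processed: Sequence[Sequence[ProcessedTrace]],
    seg_cfg: Optional[ev.SegmentationConfig] = None,
) -> List[List[ev.DegradationEvent]]:
    """Detect and segment all binding events, grouped by movie."""
    seg_cfg = seg_cfg or ev.SegmentationConfig()
    out: List[List[ev.DegradationEvent]] = []
    for movie in processed:
        movie_events: List[ev.DegradationEvent] = []
        for pt in movie:
            bg = pt.background_total
            intervals = ev.detect_binding_events(
                pt.total, bg, k=2.0, min_duration=2, raw_total=pt.raw_total)
            for iv in intervals:
                movie_events.append(ev.segment_degradation_phases(
                    pt.e_app, pt.total, iv, pt.frame_period, bg, seg_cfg,
                    particle_id=pt.particle_id, movie_id=pt.movie_id))
        out.append(movie_events)
    return out


_PHASE_FIELDS = {
    "tau_ins": "dur_insertion",
    "tau_dub": "dur_high_fret",
    "tau_decay": "dur_decay",
    "donor_dwell": "dur_donor_dwell",
}


def phase_dwell_sets(
    events_by_movie: Sequence[Sequence[ev.DegradationEvent]],
) -> Dict[str, DwellSet]:
    """Per-phase duration sets from productive, uncensored events."""
    good = [e for movie in events_by_movie for e in movie
            if e.label == "productive" and not e.censored]
    out = {}
    for name, attr in _PHASE_FIELDS.items():
        vals = np.array([getattr(e, attr) for e in good], dtype=float)
        vals = vals[np.isfinite(vals) & (vals > 0)]
        out[name] = DwellSet.from_durations(vals, name)
    return out


def conformational_efficiencies(
    movies: Sequence[Sequence[FluorescenceTrace]],
    emission: EmissionParams,
) -> List[np.ndarray]:
    """Unsmoothed apparent-efficiency series for HMM / dwell scoring.

    The intensity smoothing used for event scoring correlates frame noise
    and blurs fast transitions, so the conformational analyses run on the
    frame-resolution efficiency.  Each trace is truncated at its first
    masked frame: in this assay both dyes sit on the proteasome, so a
    masked frame marks a photobleach and everything after it is dark.
    """
    processed = preprocess_movies(movies, emission, window=1)
    out = []
    for movie in processed:
        for pt in movie:
            e = pt.e_app
            bad = np.flatnonzero(~np.isfinite(e))
            out.append(e[: bad[0]] if bad.size else e)
    return out


def fit_conformational_rates(
    traces_e: Sequence[np.ndarray],
    frame_period: float,
    max_iter: int = 500,
    rate_method: str = "matrix_log",
) -> Dict[str, object]:
    """HMM fit plus dwell-exponential switching rates for one condition."""
    usable = [e for e in traces_e if np.isfinite(e).sum() >= 20]
    fit = hm.fit_two_state_hmm(usable, max_iter=max_iter)
    low_sets, high_sets = [], []
    for e in usable:
        path = hm.viterbi_states(e, fit)
        lo, hi = hm.dwells_from_path(path, frame_period)
        if lo.n:
            low_sets.append(lo)
        if hi.n:
            high_sets.append(hi)
    low = DwellSet.concat(low_sets)
    high = DwellSet.concat(high_sets)
    k_s1_tm, k_non_s1_tm = hm.switching_rates(fit, frame_period, rate_method)
    k_s1_dw, k_non_s1_dw = hm.rates_from_dwell_sets(
        low, high, frame_period, rate_method)
    return {
        "fit": fit, "dwells_low": low, "dwells_high": high,
        "k_s1": k_s1_tm, "k_non_s1": k_non_s1_tm,
        "k_s1_dwell": k_s1_dw, "k_non_s1_dwell": k_non_s1_dw,
    }


def score_processing_dwell_sets(
    traces_e: Sequence[np.ndarray],
    frame_period: float,
    cfg: Optional[ev.ProcessingDwellConfig] = None,
) -> DwellSet:
    """Pooled uncensored processing dwells over a trace ensemble."""
    sets = []
    for e in traces_e:
        _, ds = ev.score_processing_dwells(e, frame_period, cfg)
        if ds.n:
            sets.append(ds)
    if not sets:
        return DwellSet.from_durations([], "processing")
    return DwellSet.concat(sets)


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def _stat_row(name: str, estimate: float, reference: Optional[float],
              tolerance: float, n: int,
              ci: Optional[Tuple[float, float]] = None) -> dict:
    row = {
        "name": name,
        "estimate": None if estimate is None else float(estimate),
        "n": int(n),
        "ci95": None if ci is None else [float(ci[0]), float(ci[1])],
        "reference": None if reference is None else float(reference),
        "tolerance": tolerance,
    }
    if reference not in (None, 0) and estimate is not None:
        row["pass"] = bool(abs(estimate - reference) <= tolerance * abs(reference))
    else:
        row["pass"] = None
    return row


def run_pipeline(config: ExperimentConfig) -> dict:
    """Execute one condition end to end and return its report dict."""
    pre, sim = config.resolve()
    acfg = config.analysis
    movies = simulate_experiment(sim, config.seed)
    truth = ConditionPreset(
        pre.name, pre.assay, sim.kinetics, sim.emission, pre.frame_period
    ).truth
    stats: List[dict] = []

    if pre.assay == "processing":
        processed = preprocess_movies(movies, sim.emission,
                                      acfg.smoothing_window)
        events_by_movie = segment_movies(processed, acfg.segmentation)
        phases = phase_dwell_sets(events_by_movie)
        for name, ds in phases.items():
            if ds.n >= 5:
                fit = kin.fit_gamma_mle(ds, n_boot=200, seed=config.seed)
                stats.append(_stat_row(name, fit.mean, truth.get(name),
                                       acfg.tolerance, fit.n, fit.ci95))
            else:
                stats.append(_stat_row(name, None, truth.get(name),
                                       acfg.tolerance, ds.n))
        try:
            cap = ev.capture_success(events_by_movie)
            stats.append(_stat_row(
                "capture_fraction", cap.fraction,
                truth.get("capture_fraction"), acfg.tolerance, cap.n_total))
        except ValueError:
            pass
    elif pre.assay == "conformational":
        traces_e = conformational_efficiencies(movies, sim.emission)
        res = fit_conformational_rates(
            traces_e, sim.frame_period, acfg.hmm_max_iter, acfg.rate_method)
        for name in ("k_s1", "k_non_s1"):
            stats.append(_stat_row(
                name, res[name], truth.get(name), acfg.tolerance,
                res["dwells_low"].n if name == "k_s1" else res["dwells_high"].n))
    else:
        traces_e = conformational_efficiencies(movies, sim.emission)
        ds = score_processing_dwell_sets(
            traces_e, sim.frame_period, acfg.dwell_scoring)
        if ds.uncensored.size >= 5:
            fit = kin.fit_gamma_mle(ds, n_boot=200, seed=config.seed)
            stats.append(_stat_row("tau_deg", fit.mean, truth.get("tau_deg"),
                                   acfg.tolerance, fit.n, fit.ci95))
        else:
            stats.append(_stat_row("tau_deg", None, truth.get("tau_deg"),
                                   acfg.tolerance, ds.n))

    return {
        "condition": pre.name,
        "assay": pre.assay,
        "seed": config.seed,
        "n_particles": config.n_particles,
        "n_movies": config.n_movies,
        "duration": config.duration,
        "frame_period": pre.frame_period,
        "ground_truth": truth,
        "stats": stats,
    }


def compare_conditions(report_a: dict, report_b: dict) -> dict:
    """Per-statistic comparison (B/A ratios) between two condition reports.

    Statistics present in only one report are listed as absent rather than
    raising.
    """
    a_stats = {s["name"]: s for s in report_a["stats"]}
    b_stats = {s["name"]: s for s in report_b["stats"]}
    rows = []
    for name in sorted(set(a_stats) | set(b_stats)):
        sa, sb = a_stats.get(name), b_stats.get(name)
        if sa is None or sb is None or sa["estimate"] in (None, 0) \
                or sb["estimate"] is None:
            rows.append({"name": name, "ratio": None, "absent_in":
                         report_a["condition"] if sa is None
                         else report_b["condition"] if sb is None else None})
            continue
        rows.append({"name": name,
                     "ratio": sb["estimate"] / sa["estimate"],
                     "absent_in": None})
    return {
        "condition_a": report_a["condition"],
        "condition_b": report_b["condition"],
        "rows": rows,
    }


def report_markdown(report: dict) -> str:
    lines = [
        f"# Condition report: {report['condition']}",
        "",
        f"assay: {report['assay']}  |  seed: {report['seed']}  |  "
        f"particles: {report['n_particles']} x {report['n_movies']} movie(s) "
        f"x {report['duration']} s at {1.0 / report['frame_period']:.0f} Hz",
        "",
        "| statistic | estimate | 95% CI | n | ground truth | pass |",
        "|---|---|---|---|---|---|",
    ]
    for s in report["stats"]:
        est = "-" if s["estimate"] is None else f"{s['estimate']:.3g}"
        ci = ("-" if not s.get("ci95")
              else f"[{s['ci95'][0]:.3g}, {s['ci95'][1]:.3g}]")
        ref = "-" if s["reference"] is None else f"{s['reference']:.3g}"
        ok = {True: "yes", False: "NO", None: "-"}[s["pass"]]
        lines.append(f"| {s['name']} | {est} | {ci} | {s['n']} | {ref} | {ok} |")
    lines.append("")
    return "\n".join(lines)


def write_report(report: dict, out_dir: Path, stem: str = "report") -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / f"{stem}.json").write_text(
        json.dumps(report, indent=1, sort_keys=True))
    (out_dir / f"{stem}.md").write_text(report_markdown(report))
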