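"""Deterministic preprocessing of raw two-channel traces.

The processing chain mirrors standard TIRF practice: centered moving-average
filtering of both channels, donor-bleedthrough correction of the acceptor,
total fluorescence for event detection, per-channel background subtraction,
and the apparent FRET efficiency E = I_A/(I_D + I_A) masked wherever the
total signal is indistinguishable from background.  Quality control selects
singly labeled particles by their intensity band and a single downward
photobleaching step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .params import InvalidParameterError
from .simulate import FluorescenceTrace


def moving_average(series: np.ndarray, window: int, mode: str = "shrink") -> np.ndarray:
    """Centered moving mean with an odd window.

    ``mode="shrink"`` (default) uses shrinking symmetric windows at the
    edges, matching the common smoothing convention; ``mode="reflect"``
    pads by reflection instead.  The operator is linear.
    """
    x = np.asarray(series, dtype=float)
    if window <= 0 or window % 2 == 0:
        raise ValueError("window must be an odd positive integer")
    if window > x.size:
        raise ValueError("window exceeds series length")
    if window == 1:
        return x.copy()
    h = window // 2
    if mode == "reflect":
        xp = np.pad(x, h, mode="reflect")
        c = np.cumsum(np.insert(xp, 0, 0.0))
        return (c[window:] - c[:-window]) / window
    if mode != "shrink":
        raise ValueError(f"unknown edge mode {mode!r}")
    c = np.cumsum(np.insert(x, 0, 0.0))
    out = np.empty_like(x)
    out[h:-h] = (c[window:] - c[:-window]) / window
    for i in range(h):
        k = i  # shrinking symmetric half-width at the edges
        out[i] = x[: 2 * k + 1].mean()
        out[-(i + 1)] = x[-(2 * k + 1):].mean()
    return out


def correct_bleedthrough(
    donor_filt: np.ndarray, acceptor_filt: np.ndarray, alpha: float
) -> np.ndarray:
    """Remove the donor -> acceptor spectral bleedthrough, floored at zero."""
    if not 0.0 <= alpha < 1.0:
        raise ValueError("alpha must be in [0, 1)")
    d = np.asarray(donor_filt, dtype=float)
    a = np.asarray(acceptor_filt, dtype=float)
    if d.shape != a.shape:
        raise ValueError("donor and acceptor must have equal length")
    return np.maximum(a - alpha * d, 0.0)


def estimate_bleedthrough(
    donor: np.ndarray,
    acceptor: np.ndarray,
    on_mask: np.ndarray,
    off_mask: np.ndarray,
) -> float:
    """Estimate alpha from acceptor-dark segments.

    ``on_mask`` selects frames where the donor is present but no energy
    transfer occurs (e.g. the post-translocation donor dwell);
    ``off_mask`` selects pure-background frames.  The acceptor excess in
    the on-frames relative to the donor excess is the bleedthrough.
    """
    d = np.asarray(donor, float)
    a = np.asarray(acceptor, float)
    on = np.asarray(on_mask, bool)
    off = np.asarray(off_mask, bool)
    if on.sum() < 3 or off.sum() < 3:
        raise ValueError("need at least 3 frames in each mask")
    dd = d[on].mean() - d[off].mean()
    if dd <= 0:
        raise ValueError("donor signal in on-frames does not exceed background")
    return float((a[on].mean() - a[off].mean()) / dd)


def apparent_fret(
    donor_filt: np.ndarray,
    acceptor_corr: np.ndarray,
    mask_threshold: float = 0.0,
) -> np.ndarray:
    """Apparent FRET efficiency E = I_A / (I_D + I_A), clamped to [0, 1].

    Frames whose total signal does not exceed ``mask_threshold`` are
    masked (NaN): outside plausible events the efficiency is undefined.
    """
    if mask_threshold < 0:
        raise ValueError("mask_threshold must be >= 0")
    d = np.asarray(donor_filt, float)
    a = np.asarray(acceptor_corr, float)
    if d.shape != a.shape:
        raise ValueError("donor and acceptor must have equal length")
    total = d + a
    valid = total > max(mask_threshold, 0.0)
    e = np.full(d.shape, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        e[valid] = a[valid] / total[valid]
    return np.clip(e, 0.0, 1.0)


def total_fluorescence(
    donor_filt: np.ndarray, acceptor_corr: np.ndarray
) -> np.ndarray:
    """Filtered sum of donor and (corrected) acceptor fluorescence."""
    d = np.asarray(donor_filt, float)
    a = np.asarray(acceptor_corr, float)
    if d.shape != a.shape:
        raise ValueError("donor and acceptor must have equal length")
    return d + a


# ---------------------------------------------------------------------------
# photobleach-step detection
# ---------------------------------------------------------------------------

def _noise_sd(series: np.ndarray, lag: int = 7) -> float:
    """Robust noise level from median absolute lagged differences.

    The lag exceeds typical smoothing windows so the estimate reflects the
    effective (possibly filtered) noise rather than the much smaller
    frame-to-frame residual of a moving average.
    """
    lag = min(lag, max(series.size - 1, 1))
    d = series[lag:] - series[:-lag]
    if d.size == 0:
        return 0.0
    return float(1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2))


def _best_split(x: np.ndarray, min_seg: int) -> Tuple[int, float]:
    """Index and |mean jump| of the strongest mean change point."""
    n = x.size
    if n < 2 * min_seg:
        return -1, 0.0
    c = np.cumsum(x)
    idx = np.arange(min_seg, n - min_seg + 1)
    left = c[idx - 1] / idx
    right = (c[-1] - c[idx - 1]) / (n - idx)
    jump = right - left
    # weight by the t-statistic factor so mid-series splits are preferred
    w = np.sqrt(idx * (n - idx) / n)
    k = int(np.argmax(np.abs(jump) * w))
    return int(idx[k]), float(jump[k])


def count_bleach_steps(
    series: np.ndarray,
    min_step: Optional[float] = None,
    min_seg: int = 5,
    max_depth: int = 6,
) -> Tuple[int, List[int]]:
    """Count downward intensity steps by binary-segmentation change points.

    A split is accepted when the mean jump exceeds ``min_step`` (default:
    3x the robust noise SD of the series).  Change points closer than one
    smoothing window are merged (a filtered step is smeared over several
    frames and must not be counted repeatedly).  Returns the number of
    downward steps and their frame indices; a singly labeled dye shows
    exactly one.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 20:
        raise ValueError("series must contain at least 20 frames")
    if min_step is None:
        min_step = 3.0 * _noise_sd(x)
        if min_step == 0.0:
            min_step = 1e-12
    splits: List[Tuple[int, float]] = []

    def recurse(lo: int, hi: int, depth: int) -> None:
        if depth > max_depth or hi - lo < 2 * min_seg:
            return
        k, jump = _best_split(x[lo:hi], min_seg)
        if k < 0 or abs(jump) < min_step:
            return
        splits.append((lo + k, jump))
        # guard band: a filtered step is smeared over a few frames that
        # must not seed further splits
        recurse(lo, max(lo, lo + k - 4), depth + 1)
        recurse(min(hi, lo + k + 4), hi, depth + 1)

    recurse(0, x.size, 0)
    down = sorted((i for i, j in splits if j < 0))
    merged: List[int] = []
    for i in down:
        if merged and i - merged[-1] <= 8:
            continue
        merged.append(i)
    return len(merged), merged


# ---------------------------------------------------------------------------
# processed trace container
# ---------------------------------------------------------------------------

@dataclass
class PreprocessConfig:
    """Knobs of the deterministic preprocessing chain."""

    window: int = 5
    edge_mode: str = "shrink"
    alpha: float = 0.08
    #: per-channel background levels; None means estimate from the trace
    background: Optional[Tuple[float, float]] = None
    #: E is masked where total <= mask_factor x total background
    mask_factor: float = 2.0


@dataclass
class ProcessedTrace:
    """Filtered, corrected and annotated view of one raw trace."""

    time: np.ndarray
    donor_filt: np.ndarray
    acceptor_corr: np.ndarray
    e_app: np.ndarray
    total: np.ndarray
    frame_period: float
    background_donor: float
    background_acceptor: float
    raw_total: np.ndarray
    particle_id: str = "p0"
    movie_id: str = "m0"
    condition: str = ""
    qc_flags: set = field(default_factory=set)
    source: Optional[FluorescenceTrace] = None

    @property
    def background_total(self) -> float:
        return self.background_donor + self.background_acceptor

    @property
    def n_frames(self) -> int:
        return self.time.size


def _estimate_channel_background(series: np.ndarray) -> float:
    """Median of the below-median frames, iterated once (robust level)."""
    med = np.median(series)
    low = series[series <= med]
    level = float(np.median(low))
    low2 = series[series <= 2.0 * level] if level > 0 else low
    if low2.size >= 10:
        level = float(np.median(low2))
    return level


def preprocess_trace(
    trace: FluorescenceTrace, config: Optional[PreprocessConfig] = None
) -> ProcessedTrace:
    """Run the full preprocessing chain on one raw trace.

    Filtering and bleedthrough correction feed the total fluorescence used
    for event detection; the apparent efficiency is computed from
    background-subtracted channels so the 0.82/0.32 anchors are unbiased,
    and masked wherever the total is below ``mask_factor`` x background.
    """
    cfg = config or PreprocessConfig()
    d_f = moving_average(trace.donor, cfg.window, cfg.edge_mode)
    a_f = moving_average(trace.acceptor, cfg.window, cfg.edge_mode)
    a_c = correct_bleedthrough(d_f, a_f, cfg.alpha)
    total = total_fluorescence(d_f, a_c)
    raw_total = total_fluorescence(
        trace.donor, correct_bleedthrough(trace.donor, trace.acceptor, cfg.alpha))

    if cfg.background is not None:
        bg_d, bg_a_raw = cfg.background
    else:
        bg_d = _estimate_channel_background(d_f)
        bg_a_raw = _estimate_channel_background(a_f)
    # background remaining in the corrected acceptor channel
    bg_a = max(bg_a_raw - cfg.alpha * bg_d, 0.0)

    mask_threshold = cfg.mask_factor * (bg_d + bg_a)
    e = apparent_fret(d_f - bg_d, np.maximum(a_c - bg_a, 0.0), 0.0)
    e[total <= mask_threshold] = np.nan

    return ProcessedTrace(
        time=trace.time,
        donor_filt=d_f,
        acceptor_corr=a_c,
        e_app=e,
        total=total,
        frame_period=trace.frame_period,
        background_donor=bg_d,
        background_acceptor=bg_a,
        raw_total=raw_total,
        particle_id=trace.particle_id,
        movie_id=trace.movie_id,
        condition=trace.condition,
        source=trace,
    )


# ---------------------------------------------------------------------------
# particle selection and down-sampling
# ---------------------------------------------------------------------------

@dataclass
class SelectionCriteria:
    """Intensity band and bleach-step limit for singly labeled particles."""

    min_total: float = 0.0
    max_total: float = np.inf
    max_donor_steps: int = 1
    signal_quantile: float = 0.9

    def intensity_of(self, pt: ProcessedTrace) -> float:
        return float(np.quantile(pt.total, self.signal_quantile))


def select_particles(
    traces: Sequence[ProcessedTrace],
    criteria: SelectionCriteria,
) -> Tuple[List[ProcessedTrace], List[ProcessedTrace]]:
    """Split traces into (kept, rejected) and record the reason as qc flags."""
    kept: List[ProcessedTrace] = []
    rejected: List[ProcessedTrace] = []
    for pt in traces:
        flags = set()
        inten = criteria.intensity_of(pt)
        if not criteria.min_total <= inten <= criteria.max_total:
            flags.add("intensity_out_of_band")
        try:
            n_steps, _ = count_bleach_steps(pt.donor_filt)
        except ValueError:
            n_steps = 0
        if n_steps > criteria.max_donor_steps:
            flags.add("multiple_bleach_steps")
        pt.qc_flags |= flags
        (rejected if flags else kept).append(pt)
    return kept, rejected


def downsample(
    trace: Union[np.ndarray, FluorescenceTrace], factor: int
) -> Union[np.ndarray, FluorescenceTrace]:
    """Non-overlapping block means of ``factor`` consecutive frames.

    The frame period is multiplied by ``factor``; a trailing remainder
    shorter than one block is dropped.
    """
    if int(factor) != factor or factor < 1:
        raise ValueError("factor must be an integer >= 1")
    factor = int(factor)

    def block(x: np.ndarray) -> np.ndarray:
        n = (x.size // factor) * factor
        if n == 0:
            raise ValueError("series shorter than one block")
        return x[:n].reshape(-1, factor).mean(axis=1)

    if isinstance(trace, FluorescenceTrace):
        if factor == 1:
            return trace
        return FluorescenceTrace(
            donor=block(trace.donor),
            acceptor=block(trace.acceptor),
            frame_period=trace.frame_period * factor,
            integration_time=trace.integration_time * factor,
            particle_id=trace.particle_id,
            condition=trace.condition,
            movie_id=trace.movie_id,
            ground_truth=trace.ground_truth,
            meta=dict(trace.meta),
        )
    x = np.asarray(trace, dtype=float)
    return x.copy() if factor == 1 else block(x)
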