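"""Two-state hidden Markov modeling of conformational FRET traces.

Maximum-likelihood Baum-Welch EM with Gaussian emissions, pooled over all
traces of a condition (every trace shares the two emission distributions
and the per-frame transition matrix).  Decoding uses Viterbi; dwell times
come from the decoded path, and switching rates from the per-frame
transition probabilities with an exact continuous-time correction: for a
two-state chain observed every ``dt`` the sampled transition matrix is
``expm(Q dt)``, which is inverted in closed form by
``lambda = -ln(1 - p01 - p10)/dt`` and ``k_ij = p_ij * lambda/(p01 + p10)``.
The elementwise ``-ln(1-p)/dt`` and naive ``p/dt`` conversions remain
available for comparison.

Missing frames (NaN, e.g. masked after photobleaching) are treated as
emitting no information.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .dwells import DwellSet

_TINY = 1e-300


@dataclass
class HMMFit:
    """Converged (or best-so-far) two-state fit.

    State 0 is the low-efficiency (s1) state, state 1 the high-efficiency
    (non-s1) state; ``transition_matrix[i, j]`` is the per-frame
    probability of moving from state i to state j.
    """

    mean_low: float
    mean_high: float
    sd_low: float
    sd_high: float
    transition_matrix: np.ndarray
    startprob: np.ndarray
    log_likelihood: float
    ll_history: np.ndarray
    n_iterations: int
    converged: bool

    def __post_init__(self) -> None:
        if not self.mean_low < self.mean_high:
            raise ValueError("mean_low must be < mean_high")
        if not np.allclose(self.transition_matrix.sum(axis=1), 1.0):
            raise ValueError("transition matrix rows must sum to 1")

    @property
    def means(self) -> np.ndarray:
        return np.array([self.mean_low, self.mean_high])

    @property
    def sds(self) -> np.ndarray:
        return np.array([self.sd_low, self.sd_high])


def _pad_traces(traces: Sequence[np.ndarray]) -> np.ndarray:
    traces = [np.asarray(t, dtype=float).ravel() for t in traces]
    if not traces:
        raise ValueError("need at least one trace")
    tmax = max(t.size for t in traces)
    x = np.full((len(traces), tmax), np.nan)
    for i, t in enumerate(traces):
        x[i, : t.size] = t
    return x


def _kmeans_1d_two(x: np.ndarray, n_iter: int = 100) -> Tuple[np.ndarray, np.ndarray]:
    """Deterministic two-cluster split of pooled efficiencies."""
    c = np.array([np.quantile(x, 0.25), np.quantile(x, 0.75)])
    if c[0] == c[1]:
        c = c + np.array([-1e-3, 1e-3])
    for _ in range(n_iter):
        assign = np.abs(x[:, None] - c[None, :]).argmin(axis=1)
        new = np.array([
            x[assign == k].mean() if np.any(assign == k) else c[k]
            for k in (0, 1)
        ])
        if np.allclose(new, c):
            break
        c = new
    assign = np.abs(x[:, None] - c[None, :]).argmin(axis=1)
    sds = np.array([
        x[assign == k].std() if np.sum(assign == k) > 1 else 0.05
        for k in (0, 1)
    ])
    return c, np.maximum(sds, 1e-3)


def _emission_probs(x: np.ndarray, means: np.ndarray, sds: np.ndarray) -> np.ndarray:
    """(N, T, 2) Gaussian densities; missing frames emit probability 1."""
    finite = np.isfinite(x)
    xz = np.where(finite, x, 0.0)
    z = (xz[..., None] - means[None, None, :]) / sds[None, None, :]
    b = np.exp(-0.5 * z ** 2) / (np.sqrt(2 * np.pi) * sds[None, None, :])
    b = np.where(finite[..., None], b, 1.0)
    return np.maximum(b, _TINY)


def _forward_backward(
    b: np.ndarray, A: np.ndarray, pi: np.ndarray
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Scaled forward-backward over an (N, T, 2) emission array."""
    n, tmax, _ = b.shape
    alpha = np.empty_like(b)
    beta = np.empty_like(b)
    c = np.empty((n, tmax))
    a = pi[None, :] * b[:, 0, :]
    c[:, 0] = a.sum(axis=1)
    alpha[:, 0, :] = a / c[:, 0, None]
    for t in range(1, tmax):
        a = (alpha[:, t - 1, :] @ A) * b[:, t, :]
        c[:, t] = a.sum(axis=1)
        alpha[:, t, :] = a / c[:, t, None]
    beta[:, -1, :] = 1.0
    for t in range(tmax - 2, -1, -1):
        beta[:, t, :] = ((b[:, t + 1, :] * beta[:, t + 1, :]) @ A.T) \
            / c[:, t + 1, None]
    ll = float(np.log(c).sum())
    return alpha, beta, c, ll


def fit_two_state_hmm(
    traces: Sequence[np.ndarray],
    init: Optional[Tuple[np.ndarray, np.ndarray]] = None,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> HMMFit:
    """Pooled Baum-Welch EM fit of a two-state Gaussian HMM.

    ``init`` may supply (means, sds); otherwise a deterministic k-means
    split of the pooled efficiencies seeds the emissions.  The fit is
    deterministic given its initialization, the log-likelihood is
    non-decreasing over EM iterations, and non-convergence within
    ``max_iter`` returns ``converged=False`` rather than raising.
    """
    x = _pad_traces(traces)
    if min(np.isfinite(xi).sum() for xi in x) < 20:
        raise ValueError("each trace must have at least 20 usable frames")
    pooled = x[np.isfinite(x)]
    if init is None:
        means, sds = _kmeans_1d_two(pooled)
    else:
        means = np.asarray(init[0], float).copy()
        sds = np.asarray(init[1], float).copy()
    order = np.argsort(means)
    means, sds = means[order], sds[order]
    A = np.array([[0.95, 0.05], [0.05, 0.95]])
    pi = np.array([0.5, 0.5])

    finite = np.isfinite(x)
    xz = np.where(finite, x, 0.0)
    ll_hist: List[float] = []
    prev_ll = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        b = _emission_probs(x, means, sds)
        alpha, beta, c, ll = _forward_backward(b, A, pi)
        ll_hist.append(ll)

        gamma = alpha * beta
        gamma /= gamma.sum(axis=2, keepdims=True)
        # transition statistics
        xi_num = np.einsum(
            "nti,ntj->ij",
            alpha[:, :-1, :],
            (b[:, 1:, :] * beta[:, 1:, :]) / c[:, 1:, None],
        ) * A
        A = xi_num / xi_num.sum(axis=1, keepdims=True)
        pi = gamma[:, 0, :].mean(axis=0)
        pi = pi / pi.sum()
        g = np.where(finite[..., None], gamma, 0.0)
        w = g.sum(axis=(0, 1))
        means = np.einsum("ntk,nt->k", g, xz) / w
        var = np.einsum("ntk,ntk->k", g, (xz[..., None] - means) ** 2) / w
        sds = np.maximum(np.sqrt(var), 1e-4)

        if ll - prev_ll < tol * abs(ll) and it > 1:
            converged = True
            break
        prev_ll = ll

    if means[0] > means[1]:  # keep state 0 = low
        means, sds = means[::-1].copy(), sds[::-1].copy()
        A = A[::-1, ::-1].copy()
        pi = pi[::-1].copy()
    return HMMFit(
        mean_low=float(means[0]), mean_high=float(means[1]),
        sd_low=float(sds[0]), sd_high=float(sds[1]),
        transition_matrix=A, startprob=pi,
        log_likelihood=float(ll_hist[-1]),
        ll_history=np.asarray(ll_hist),
        n_iterations=it, converged=converged)


def forward_loglikelihood(trace: np.ndarray, fit: HMMFit) -> float:
    """Total data likelihood of one trace under a fit (forward algorithm)."""
    x = np.asarray(trace, float)[None, :]
    b = _emission_probs(x, fit.means, fit.sds)
    _, _, _, ll = _forward_backward(b, fit.transition_matrix, fit.startprob)
    return ll


def viterbi_states(trace: np.ndarray, fit: HMMFit) -> np.ndarray:
    """Most probable state path (0 = low, 1 = high); ties stay put."""
    x = np.asarray(trace, dtype=float)
    b = _emission_probs(x[None, :], fit.means, fit.sds)[0]
    logb = np.log(b)
    logA = np.log(np.maximum(fit.transition_matrix, _TINY))
    logpi = np.log(np.maximum(fit.startprob, _TINY))
    n = x.size
    delta = np.empty((n, 2))
    psi = np.zeros((n, 2), dtype=int)
    delta[0] = logpi + logb[0]
    for t in range(1, n):
        for j in (0, 1):
            stay = delta[t - 1, j] + logA[j, j]
            move = delta[t - 1, 1 - j] + logA[1 - j, j]
            if move > stay:  # ties break toward the previous state
                delta[t, j] = move + logb[t, j]
                psi[t, j] = 1 - j
            else:
                delta[t, j] = stay + logb[t, j]
                psi[t, j] = j
    path = np.empty(n, dtype=int)
    path[-1] = int(np.argmax(delta[-1]))
    for t in range(n - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path


def dwells_from_path(
    path: np.ndarray, frame_period: float
) -> Tuple[DwellSet, DwellSet]:
    """Per-state dwell sets from a decoded path.

    Run lengths are multiplied by the frame period; the first and last
    run of the trace are flagged censored (their true start/end was not
    observed).
    """
    p = np.asarray(path, dtype=int)
    if p.size == 0:
        raise ValueError("path must be non-empty")
    edges = np.flatnonzero(np.diff(p) != 0) + 1
    bounds = np.concatenate([[0], edges, [p.size]])
    lengths = np.diff(bounds)
    states = p[bounds[:-1]]
    cens = np.zeros(lengths.size, dtype=bool)
    cens[0] = True
    cens[-1] = True
    out = []
    for k, label in ((0, "low"), (1, "high")):
        sel = states == k
        out.append(DwellSet(label,
                            lengths[sel] * frame_period,
                            cens[sel]))
    return out[0], out[1]


def switching_rates(
    fit: HMMFit, frame_period: float, method: str = "matrix_log"
) -> Tuple[float, float]:
    """(k_low->high, k_high->low) in s^-1 from the per-frame transitions."""
    p01 = float(fit.transition_matrix[0, 1])
    p10 = float(fit.transition_matrix[1, 0])
    return rates_from_frame_probs(p01, p10, frame_period, method)


def rates_from_frame_probs(
    p01: float, p10: float, frame_period: float, method: str = "matrix_log"
) -> Tuple[float, float]:
    dt = frame_period
    if method == "naive":
        return p01 / dt, p10 / dt
    if method == "elementwise":
        return -np.log1p(-p01) / dt, -np.log1p(-p10) / dt
    if method != "matrix_log":
        raise ValueError(f"unknown method {method!r}")
    s = p01 + p10
    if s <= 0:
        return 0.0, 0.0
    if s >= 1:
        # sampling faster than mixing is violated; fall back to elementwise
        return -np.log1p(-p01) / dt, -np.log1p(-p10) / dt
    lam = -np.log1p(-s) / dt
    return p01 / s * lam, p10 / s * lam


def rates_from_dwell_sets(
    low: DwellSet,
    high: DwellSet,
    frame_period: float,
    method: str = "matrix_log",
) -> Tuple[float, float]:
    """Switching rates from uncensored Viterbi dwells.

    The mean dwell in frames gives the per-frame exit probability of the
    sampled chain, which is converted to continuous-time rates exactly as
    in :func:`rates_from_frame_probs`.
    """
    mlo = float(np.mean(low.uncensored)) / frame_period
    mhi = float(np.mean(high.uncensored)) / frame_period
    return rates_from_frame_probs(1.0 / mlo, 1.0 / mhi, frame_period, method)


# ---------------------------------------------------------------------------
# ensemble histograms
# ---------------------------------------------------------------------------

def fret_histogram(
    traces: Iterable[np.ndarray],
    bins: int = 50,
    range: Tuple[float, float] = (0.0, 1.0),
) -> Tuple[np.ndarray, np.ndarray]:
    """Normalized pooled efficiency density over all finite frames."""
    pooled = np.concatenate([np.asarray(t, float).ravel() for t in traces])
    pooled = pooled[np.isfinite(pooled)]
    if pooled.size == 0:
        raise ValueError("no finite efficiency values")
    density, edges = np.histogram(pooled, bins=bins, range=range, density=True)
    return density, edges


def contour_data(
    traces: Sequence[np.ndarray],
    sync_indices: Sequence[int],
    frame_period: float,
    time_bins: int = 40,
    e_bins: int = 40,
    window: Tuple[float, float] = (-2.0, 2.0),
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Time-binned 2-D efficiency histogram of synchronized traces.

    Each trace is shifted so that its synchronization point (for decay
    contours, the frame where the drop from high efficiency initiates)
    sits at t = 0; occupancies are column-normalized per time bin.
    """
    if len(traces) != len(sync_indices):
        raise ValueError("need one sync index per trace")
    ts, es = [], []
    for tr, s in zip(traces, sync_indices):
        tr = np.asarray(tr, float)
        t_rel = (np.arange(tr.size) - s) * frame_period
        keep = np.isfinite(tr) & (t_rel >= window[0]) & (t_rel <= window[1])
        ts.append(t_rel[keep])
        es.append(tr[keep])
    t_all = np.concatenate(ts)
    e_all = np.concatenate(es)
    hist, t_edges, e_edges = np.histogram2d(
        t_all, e_all, bins=(time_bins, e_bins),
        range=(window, (0.0, 1.0)))
    col = hist.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        hist = np.where(col > 0, hist / col, 0.0)
    return hist, t_edges, e_edges
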