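"""Parameter containers for the forward model.

Two dataclasses describe a simulated experiment: :class:`KineticParams`
holds the rate constants and time constants of substrate processing and
conformational switching, and :class:`EmissionParams` holds the
photophysics (dye brightness, background, noise, bleedthrough, bleaching
and the true FRET efficiencies of each state).

All times are seconds, all rates are per second, translocation velocity
is residues per second, and intensities are camera counts per frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Optional


class InvalidParameterError(ValueError):
    """Raised when a kinetic or emission parameter violates its constraints."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise InvalidParameterError(msg)


@dataclass(frozen=True)
class KineticParams:
    """Rate constants of the substrate-processing forward model.

    The productive degradation pathway is tail insertion (gamma with mean
    ``tau_ins`` and shape ``n_ins``), a high-FRET deubiquitination dwell
    (gamma, ``tau_dub``/``n_dub``), translocation of the 24-residue linker
    past the acceptor dye (gamma, ``tau_decay``/``n_dec``), mechanical
    unfolding (exponential, ``tau_unfold``) and post-unfolding donor
    persistence until peptide release (exponential, ``tau_post``).
    Nonproductive binding events dissociate after an exponential dwell
    ``tau_off``.  Conformational switching between the engagement-competent
    s1 state and processing-competent non-s1 states is a two-state
    telegraph process with rates ``k_s1`` (s1 -> non-s1) and ``k_non_s1``
    (non-s1 -> s1).  During unfolding the motor occasionally slips back to
    s1; these excursions occur at ``excursion_rate`` (suppressed during the
    final ``excursion_free_tail`` seconds of processing, the unobstructed
    translocation of the unfolded chain) and last an exponential
    ``excursion_mean_dur``.
    """

    tau_ins: float = 1.8
    n_ins: float = 2.0
    tau_dub: float = 1.1
    n_dub: float = 2.0
    tau_decay: float = 0.74
    n_dec: float = 3.0
    tau_unfold: float = 6.0
    tau_post: float = 7.3
    k_s1: float = 1.2
    k_non_s1: float = 4.5
    k_trans: float = 32.4
    excursion_rate: float = 0.0
    excursion_mean_dur: float = 0.15
    excursion_free_tail: float = 3.0
    p_capture: float = 1.0
    tau_off: float = 0.32
    arrival_rate: float = 0.02
    # Total processing dwell in the conformational assay (engagement to
    # completed translocation), gamma with shape n_deg.  None means
    # "derive nothing": only the conformational-processing simulator uses it.
    tau_deg: Optional[float] = None
    n_deg: float = 3.0

    def __post_init__(self) -> None:
        for name in ("tau_ins", "tau_dub", "tau_decay", "tau_unfold",
                     "tau_post", "tau_off", "k_trans", "excursion_mean_dur"):
            _require(getattr(self, name) > 0, f"{name} must be > 0")
        for name in ("n_ins", "n_dub", "n_dec", "n_deg"):
            _require(getattr(self, name) >= 1, f"{name} must be >= 1")
        for name in ("k_s1", "k_non_s1", "excursion_rate", "arrival_rate",
                     "excursion_free_tail"):
            _require(getattr(self, name) >= 0, f"{name} must be >= 0")
        _require(0.0 <= self.p_capture <= 1.0, "p_capture must be in [0, 1]")
        if self.tau_deg is not None:
            _require(self.tau_deg > 0, "tau_deg must be > 0")

    def evolve(self, **changes) -> "KineticParams":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class EmissionParams:
    """Photophysics of the donor/acceptor pair and the camera.

    ``brightness`` is the total signal (donor + sensitized acceptor) of a
    dual-labeled pair per frame; ``alpha`` is the donor -> acceptor spectral
    bleedthrough fraction.  ``e_low``/``e_high`` are the true efficiencies
    of the s1 and non-s1 conformations in the conformational assay;
    ``e_bind``/``e_peak``/``e_exit`` are the efficiencies at substrate
    binding, full tail insertion and channel exit in the processing assay
    (the 0.82/0.32 anchors of the stalled-substrate calibration).
    ``e_residual`` is the small residual efficiency reached by the end of
    unfolding, before the dye leaves FRET range entirely.
    """

    brightness: float = 1000.0
    background_donor: float = 50.0
    background_acceptor: float = 50.0
    noise_sd: float = 50.0
    noise_model: str = "constant"   # "constant" | "shot"
    alpha: float = 0.08
    e_low: float = 0.25
    e_high: float = 0.75
    e_bind: float = 0.45
    e_peak: float = 0.82
    e_exit: float = 0.32
    e_residual: float = 0.05
    bleach_rate_donor: float = 0.001
    bleach_rate_acceptor: float = 0.0005

    def __post_init__(self) -> None:
        _require(self.brightness > 0, "brightness must be > 0")
        _require(0.0 <= self.alpha < 0.5, "alpha must be in [0, 0.5)")
        for name in ("e_low", "e_high", "e_bind", "e_peak", "e_exit",
                     "e_residual"):
            _require(0.0 <= getattr(self, name) <= 1.0,
                     f"{name} must be in [0, 1]")
        for name in ("background_donor", "background_acceptor", "noise_sd",
                     "bleach_rate_donor", "bleach_rate_acceptor"):
            _require(getattr(self, name) >= 0, f"{name} must be >= 0")
        _require(self.noise_model in ("constant", "shot"),
                 "noise_model must be 'constant' or 'shot'")
        _require(self.e_low < self.e_high, "e_low must be < e_high")

    @property
    def background_total(self) -> float:
        return self.background_donor + self.background_acceptor

    def evolve(self, **changes) -> "EmissionParams":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return asdict(self)
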