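"""Named condition presets for the forward simulator.

Each preset encodes the measured kinetic constants of one experimental
condition as the generator's ground truth, so a full pipeline run is a
parameter-recovery experiment: simulate at the known constants, analyze,
and compare the recovered values.

Processing-assay presets (ubiquitinated I27-V15P substrate, donor on the
substrate tail):

=============  ==========================================================
``wt``         wild-type proteasome: tail insertion 1.8 s (gamma, shape
               2), high-FRET deubiquitination dwell 1.1 s (shape 2),
               0.82->0.32 decay 0.74 s (shape 3), donor dwell ~13.3 s
               (unfolding 6 s + post-unfolding 7.3 s), capture 33%
``v80a``       Rpn11-V80A deubiquitination-slowed mutant: high-FRET dwell
               5.5 s, everything else as wild type
``sspb``       SspB-delivered nonubiquitinated substrate: insertion 3.4 s,
               capture 17%, nonproductive dissociation 0.32 s
``sspb_ub4``   SspB delivery + unanchored K48-Ub4: insertion 2.2 s,
               capture 34%
=============  ==========================================================

Conformational-assay presets (substrate-free telegraph switching):
``conf_wt_atp`` (k_s1 = 1.2, k_non-s1 = 4.5 s^-1), ``conf_rpn5``
(2.5/4.2, s1-destabilized lid-base mutant), ``conf_ub4`` (0.4/4.5,
ubiquitin-chain slowed), ``conf_sspb`` (0.8/4.5) and ``conf_sspb_ub4``
(0.4/4.5).

Conformational-processing presets (SspB-delivered substrates, dwell =
engagement to completed translocation): ``proc_i27wt`` (47 s, ~11 s1
excursions per processing, 5 Hz), ``proc_v15p`` (10.7 s, ~0.7
excursions), ``proc_v13pv15p`` (7.3 s, no resolvable excursions), plus
``_ub4`` variants (40 / 9.0 / 7.0 s).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict

from .params import EmissionParams, KineticParams


@dataclass(frozen=True)
class ConditionPreset:
    name: str
    assay: str
    kinetics: KineticParams
    emission: EmissionParams
    frame_period: float = 0.05
    description: str = ""

    @property
    def truth(self) -> Dict[str, float]:
        """Ground-truth constants a recovery run should reproduce."""
        k = self.kinetics
        out: Dict[str, float] = {}
        if self.assay == "processing":
            out.update({
                "tau_ins": k.tau_ins,
                "tau_dub": k.tau_dub,
                "tau_decay": k.tau_decay,
                "donor_dwell": k.tau_unfold + k.tau_post,
                "capture_fraction": k.p_capture,
            })
        elif self.assay == "conformational":
            out.update({"k_s1": k.k_s1, "k_non_s1": k.k_non_s1})
        else:
            out.update({"tau_deg": k.tau_deg})
        return out


_EM = EmissionParams()
_EM_CONF = EmissionParams()

_WT = KineticParams(
    tau_ins=1.8, n_ins=2, tau_dub=1.1, n_dub=2, tau_decay=0.74, n_dec=3,
    tau_unfold=6.0, tau_post=7.3, p_capture=0.33, tau_off=0.61,
    k_trans=24.0 / 0.74, arrival_rate=0.02)

PRESETS: Dict[str, ConditionPreset] = {}


def _add(name: str, assay: str, kin: KineticParams,
         em: EmissionParams = _EM, frame_period: float = 0.05,
         description: str = "") -> None:
    PRESETS[name] = ConditionPreset(name, assay, kin, em, frame_period,
                                    description)


_add("wt", "processing", _WT,
     description="wild-type proteasome, ubiquitinated I27-V15P")
_add("v80a", "processing", _WT.evolve(tau_dub=5.5, tau_decay=0.80),
     description="Rpn11-V80A, slowed deubiquitination")
_add("sspb", "processing",
     _WT.evolve(tau_ins=3.4, p_capture=0.17, tau_off=0.32,
                arrival_rate=0.035),
     description="SspB-delivered nonubiquitinated I27-V15P")
_add("sspb_ub4", "processing",
     _WT.evolve(tau_ins=2.2, p_capture=0.34, tau_off=0.32,
                arrival_rate=0.035),
     description="SspB delivery with unanchored K48-Ub4")

_add("conf_wt_atp", "conformational",
     KineticParams(k_s1=1.2, k_non_s1=4.5), _EM_CONF,
     description="substrate-free wild type in ATP")
_add("conf_rpn5", "conformational",
     KineticParams(k_s1=2.5, k_non_s1=4.2), _EM_CONF,
     description="Rpn5-VTENKIF s1-destabilized mutant")
_add("conf_ub4", "conformational",
     KineticParams(k_s1=0.4, k_non_s1=4.5), _EM_CONF,
     description="substrate-free wild type with K48-Ub4")
_add("conf_sspb", "conformational",
     KineticParams(k_s1=0.8, k_non_s1=4.5), _EM_CONF,
     description="substrate-free SspB-fused proteasome")
_add("conf_sspb_ub4", "conformational",
     KineticParams(k_s1=0.4, k_non_s1=4.5), _EM_CONF,
     description="SspB-fused proteasome with K48-Ub4")

# excursion rates convert counts-per-processing into a per-second rate over
# the excursion-eligible window (dwell minus the 3 s excursion-free tail)
_add("proc_i27wt", "conformational_processing",
     KineticParams(k_s1=1.2, k_non_s1=4.5, tau_deg=47.0, n_deg=3,
                   excursion_rate=11.0 / 44.0, arrival_rate=0.006),
     frame_period=0.2,
     description="SspB-delivered wild-type I27, 5 Hz sampling")
_add("proc_v15p", "conformational_processing",
     KineticParams(k_s1=1.2, k_non_s1=4.5, tau_deg=10.7, n_deg=3,
                   excursion_rate=0.7 / 7.7, arrival_rate=0.012),
     description="SspB-delivered I27-V15P")
_add("proc_v13pv15p", "conformational_processing",
     KineticParams(k_s1=1.2, k_non_s1=4.5, tau_deg=7.3, n_deg=3,
                   excursion_rate=0.0, arrival_rate=0.012),
     description="SspB-delivered I27-V13P/V15P")
_add("proc_i27wt_ub4", "conformational_processing",
     KineticParams(k_s1=0.4, k_non_s1=4.5, tau_deg=40.0, n_deg=3,
                   excursion_rate=11.0 / 37.0, arrival_rate=0.006),
     frame_period=0.2,
     description="wild-type I27 with K48-Ub4, 5 Hz")
_add("proc_v15p_ub4", "conformational_processing",
     KineticParams(k_s1=0.4, k_non_s1=4.5, tau_deg=9.0, n_deg=3,
                   excursion_rate=0.7 / 6.0, arrival_rate=0.012),
     description="I27-V15P with K48-Ub4")
_add("proc_v13pv15p_ub4", "conformational_processing",
     KineticParams(k_s1=0.4, k_non_s1=4.5, tau_deg=7.0, n_deg=3,
                   excursion_rate=0.0, arrival_rate=0.012),
     description="I27-V13P/V15P with K48-Ub4")


def get_preset(name: str) -> ConditionPreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None
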