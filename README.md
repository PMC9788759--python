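# proctrace

Simulation and kinetic analysis of single-molecule FRET traces of 26S
proteasome substrate processing.

The 26S proteasome recognizes polyubiquitinated substrates, removes their
ubiquitin chains and threads them through its AAA+ ATPase motor for
degradation.  Single-molecule TIRF-FRET experiments resolve this process
as a stereotyped sequence in per-particle donor/acceptor intensity
traces: a substrate-attached donor dye arrives (intermediate apparent
FRET), inserts fully between the N-ring and ATPase ring (high FRET, the
deubiquitination dwell), translocates ~24 residues past the
proteasome-attached acceptor (a gradual decay of apparent FRET from
~0.82 to ~0.32) and persists as a donor-only signal while the folded
domain is unfolded, degraded and released.  A second dye geometry reports
the machine's own conformational dynamics: two-state telegraph switching
between the engagement-competent s1 conformation (low FRET) and the
processing-competent non-s1 conformations (high FRET), interrupted during
degradation by long non-s1 "processing dwells" with brief s1 excursions
when the motor slips on a stable fold.

`proctrace` is written for single-molecule biophysicists who analyze such
traces — and anyone who wants to validate a trace-analysis pipeline by
parameter recovery.  It couples:

* a **forward simulator** of both assays (ground-truth state
  trajectories; full photophysics: bleedthrough, background, noise,
  single-step photobleaching), with presets whose defaults are the
  measured kinetic constants of each experimental condition;
* the **analysis pipeline**: moving-average filtering, donor-bleedthrough
  correction, apparent FRET efficiency `E = I_A/(I_D+I_A)`, event
  detection at twofold background, hysteresis phase segmentation with
  interpolated boundary timing, productive/nonproductive classification
  and capture-success statistics;
* a **two-state Gaussian hidden Markov model** (pooled maximum-likelihood
  Baum–Welch, Viterbi decoding, dwell extraction, exact continuous-time
  rate correction via the 2×2 matrix logarithm);
* **dwell-time kinetics**: gamma and exponential maximum likelihood
  (censoring-aware), Kaplan–Meier survival curves, the Mantel–Cox
  log-rank test, translocation-velocity/threading/unfolding calculus and
  the stalled-substrate position calibration.

Because every simulated trace carries its ground truth, each analysis
stage is testable end to end: simulate at a known constant, analyze, and
check the recovered value.

## Worked example

Recover the four processing-phase time constants of the wild-type
condition from 200 simulated degradation events:

```python
from proctrace import fit_gamma_mle, get_preset
from proctrace.pipeline import (phase_dwell_sets, preprocess_movies,
                                segment_movies)
from proctrace.simulate import simulate_event_ensemble

preset = get_preset("wt")
traces = simulate_event_ensemble(
    preset.kinetics.evolve(p_capture=1.0), preset.emission,
    n_events=200, seed=11)
events = segment_movies(preprocess_movies([traces], preset.emission))
phases = phase_dwell_sets(events)
for name in ("tau_ins", "tau_dub", "tau_decay", "donor_dwell"):
    fit = fit_gamma_mle(phases[name], seed=0)
    print(name, round(fit.mean, 2), fit.ci95, fit.n)
```

which prints

```
tau_ins       1.66 s  (95% CI 1.51-1.82, n=191)  truth 1.8
tau_dub       1.15 s  (95% CI 1.04-1.27, n=192)  truth 1.1
tau_decay     0.73 s  (95% CI 0.69-0.78, n=192)  truth 0.74
donor_dwell  13.41 s  (95% CI 12.16-14.71, n=192)  truth 13.3
```

`tau_ins` is the tail-insertion constant (substrate arrival to the first
high-FRET peak), `tau_dub` the high-FRET deubiquitination dwell,
`tau_decay` the 0.82→0.32 translocation decay (24 residues, i.e. a
velocity of ~30 aa/s) and `donor_dwell` the donor persistence covering
unfolding and peptide release.  Every recovered mean sits within its 95%
CI of the generating constant.

The same stages are scriptable from a shell:

```sh
proctrace simulate --config sim.yaml --seed 1 --out movies/
proctrace segment  --traces movies/ --out events.csv
proctrace fit      --events events.csv --what gamma --phase dur_high_fret --out fit.json
proctrace report   --preset v80a --seed 1 --out reports/
proctrace reproduce --seed 1 --out reports/
```

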