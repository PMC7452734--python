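# hydracal

Whole-body calcium-imaging analysis for *Hydra vulgaris*: extraction of
whole-body fluorescence traces from movie stacks, detection of
contraction-burst (CB) and rhythmic-potential (RP1) calcium pulses,
body-column width morphometry by moment-based ellipse fitting, and the
condition-comparison statistics used to test how media osmolarity
modulates contractile behavior. A ground-truthed synthetic-data
generator makes every stage testable end to end without any recordings.

## Who this is for

Researchers quantifying whole-animal GCaMP recordings of *Hydra* (or
similar radially simple organisms) who need a fully automatic,
reproducible version of the usual semi-manual workflow: ImageJ-style
whole-frame intensity measurement, by-eye pulse marking, and
spreadsheet statistics.

## The analysis

**Traces.** A recording is reduced to one number per frame — the mean
whole-body fluorescence F(t), sampled at 2 Hz for 2-h activity sessions
(0.5 Hz for width sessions). Normalization to ΔF/F = (F − F₀)/F₀ uses a
running 10th-percentile baseline F₀ over a 120-s window, which also
removes photobleaching trends slower than the window.

**Pulses and bursts.** Calcium transients are modeled as
difference-of-exponentials kernels A·(e^(−t/τ_d) − e^(−t/τ_r)) with
GCaMP6s-like τ_r = 0.3 s, τ_d = 1.5 s. Detection finds local maxima
with prominence and height ≥ k·σ̂ (default k = 4), where
σ̂ = 1.4826·MAD(ΔF/F first differences)/√2 is the robust noise SD. Two
complementary scans feed one candidate list: a lightly smoothed scan
for weak isolated RP1 pulses and a decay-whitened scan
(y_t = x_t − e^(−1/(τ_d·f_s))·x_{t−1}) that resolves pulses superposed
within bursts. Bursts are maximal pulse runs with inter-pulse intervals
≤ 10 s and ≥ 2 members; pulses inside bursts are CB, isolated small
pulses are RP1, and muscle-tissue recordings have no RP1 by definition.
Each recording yields six metrics: CB pulse number, burst count, CB
total time, CB pulse frequency (pulses per minute of burst time), RP1
pulse number/total time/frequency.

**Width.** Each 0.5-Hz frame is segmented (Otsu, largest component,
filled holes) and summarized by its moment-equivalent ellipse — axis
lengths 4·√(eigenvalues) of the foreground-coordinate covariance. The
minor axis is the body-column width; per-cycle width minima give the
end-of-elongation width.

**Statistics.** Group summaries are mean ± SEM; two-group factors use
the two-tailed unpaired (pooled) Student's t test; the three osmolarity
levels use one-way ANOVA with Tukey's HSD (Tukey–Kramer for unequal n)
and simultaneous 95% CIs from the studentized-range distribution.

**Synthetic data.** The generator draws CB burst onsets as a Poisson
process whose rate is scaled by an osmolarity multiplier
(low/control/high = 1.5/1.0/0.5), jittered-periodic RP1 pulses, renders
traces with bleaching and sensor noise, and renders ellipse-shaped
contraction–elongation movies — all with exported ground truth.

## Worked example

Simulate one 2-h low-osmolarity neural recording at SNR 5 and analyze
it:

```python
import hydracal as h

config = h.SimulationConfig.for_condition("low", seed=7).with_snr(5.0)
events = h.simulate_events(config)
trace = h.render_trace(events, config)
pulses, bursts, summary = h.analyze_trace(trace)
score = h.score_detection([p.time for p in pulses], events.pulse_times)
```

This prints (via the fields of `summary` and `score`):

```
true: 22 bursts, 225 pulses
detected: 22 bursts, 114 CB + 112 RP1 pulses
CB total time 194.5 s, CB pulse frequency 35.2 /min, RP1 frequency 56.0 /h
detection F1 = 0.984
```

All 22 true bursts are recovered and 98% of pulses are matched within
±1 s. The full in-silico osmolarity experiment (8 animals × 3
conditions, 2-h recordings each) runs from the command line:

```bash
hydracal run-experiment --seed 1 --n-per-condition 8 --out-dir demo_exp
```

`demo_exp/recordings.csv` then shows CB pulse numbers of
98.9 ± 9.4 (low), 57.1 ± 9.1 (control), 27.9 ± 4.1 (high) — the
bidirectional osmolarity effect — and `demo_exp/report.csv` contains
the Tukey comparison table, e.g. for `cb_pulse_number`:

```
                Description  CI_low  CI_high  Significant      p
 osmolarity: control vs low -69.929  -13.571         True 0.0034
osmolarity: control vs high   1.071   57.429         True 0.0410
    osmolarity: low vs high  42.821   99.179         True 0.0000
```

Other subcommands: `simulate`, `extract`, `detect`, `width`, `compare`,
`version` (see `hydracal --help`).

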