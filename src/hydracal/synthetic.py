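"""Ground-truthed synthetic Hydra recordings.

Generates the two kinds of data the analysis pipeline consumes:

* 2-h whole-body GCaMP fluorescence traces containing contraction-burst
  (CB) pulse clusters and isolated quasi-periodic rhythmic-potential
  (RP1) pulses, with photobleaching drift and sensor noise;
* slow (0.5 Hz) movies of an ellipse-shaped body column undergoing
  contraction--elongation cycles, where the contraction rate depends on
  media osmolarity through a dimensionless rate multiplier.

Every simulation carries its ground truth (event times, classes, burst
windows, cycle minima) so downstream detection and morphometry can be
scored without any external data.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .trace_io import FluorescenceTrace

__all__ = [
    "SimulationConfig",
    "GroundTruthEvents",
    "GeometryTrajectory",
    "CONDITION_MULTIPLIERS",
    "CONDITION_ELONGATED_WIDTHS",
    "kernel_peak_value",
    "simulate_events",
    "render_trace",
    "simulate_geometry",
    "render_movie",
    "save_ground_truth",
    "load_ground_truth",
]

#: Osmolarity-condition multipliers applied to the CB burst rate.  The
#: direction (hypo-osmolar media speed contractions up, hyperosmolar media
#: slow them down) mirrors the biology; the magnitudes are synthetic
#: defaults, not measured values.
CONDITION_MULTIPLIERS = {"low": 1.5, "control": 1.0, "high": 0.5}

#: End-of-elongation body-column width (px) per osmolarity condition.
#: Hypo-osmolar media swell the animal (wider), hyperosmolar media shrink
#: it (narrower).  Synthetic defaults.
CONDITION_ELONGATED_WIDTHS = {"low": 48.0, "control": 40.0, "high": 30.0}


def kernel_peak_value(rise_tau: float, decay_tau: float) -> float:
    """Closed-form maximum of the difference-of-exponentials kernel.

    The kernel ``k(t) = exp(-t/decay_tau) - exp(-t/rise_tau)`` peaks at
    ``t* = ln(b/a)/(b - a)`` with ``a = 1/decay_tau``, ``b = 1/rise_tau``.
    A pulse of amplitude ``A`` therefore produces a transient whose peak
    height is ``A * kernel_peak_value(rise_tau, decay_tau)``.
    """
    a, b = 1.0 / decay_tau, 1.0 / rise_tau
    t_star = math.log(b / a) / (b - a)
    return math.exp(-a * t_star) - math.exp(-b * t_star)


def _kernel_peak_delay(rise_tau: float, decay_tau: float) -> float:
    a, b = 1.0 / decay_tau, 1.0 / rise_tau
    return math.log(b / a) / (b - a)


@dataclass
class SimulationConfig:
    """Parameters of one synthetic recording.

    Times are seconds, rates are per hour, amplitudes are in dF/F units.
    The same config drives both trace rendering (at ``frame_rate``) and
    the geometric body-column model.
    """

    duration: float = 7200.0          # the 2-h imaging session
    frame_rate: float = 2.0           # Hz; activity imaging runs at 2 Hz
    cb_burst_rate: float = 6.0        # bursts/h before the osmolarity multiplier
    pulses_per_burst_mean: float = 4.0  # burst size is 1 + Poisson(this)
    intra_burst_interval: float = 2.0   # s between pulses inside a burst
    min_interburst_interval: float = 30.0  # refractory elongation phase, s
    rp1_rate: float = 60.0            # pulses/h; 0 for muscle-like recordings
    rp1_jitter_frac: float = 0.1      # SD of period jitter, fraction of period
    rp1_exclusion_pad: float = 5.0    # s around burst windows with no RP1
    cb_amplitude: float = 1.0         # dF/F
    rp1_amplitude: float = 0.4        # dF/F
    rise_tau: float = 0.3             # s, GCaMP6s-like onset
    decay_tau: float = 1.5            # s, GCaMP6s-like decay
    noise_sd: float = 0.02            # dF/F units
    bleach_tau: float = 1800.0        # s; math.inf disables bleaching
    baseline: float = 100.0           # raw fluorescence units
    condition_label: str = "control"
    osmolarity_multiplier: float = 1.0
    seed: int = 0
    # body-column geometry (px); contraction widens and shortens the column
    elongated_width_px: float = 40.0
    contracted_width_px: float = 80.0
    elongated_length_px: float = 240.0
    contracted_length_px: float = 120.0
    contraction_tau_s: float = 2.0
    elongation_tau_s: float = 30.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (self.duration > 0 and math.isfinite(self.duration)):
            raise ValueError("duration must be positive and finite")
        if not (self.frame_rate > 0 and math.isfinite(self.frame_rate)):
            raise ValueError("frame_rate must be positive and finite")
        for name in ("cb_burst_rate", "rp1_rate", "pulses_per_burst_mean",
                     "osmolarity_multiplier", "noise_sd"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        if not (self.decay_tau > self.rise_tau > 0):
            raise ValueError("need decay_tau > rise_tau > 0")
        if self.intra_burst_interval <= 0:
            raise ValueError("intra_burst_interval must be positive")
        if self.bleach_tau <= 0:
            raise ValueError("bleach_tau must be positive (inf to disable)")
        if not (self.contracted_width_px > self.elongated_width_px > 0):
            raise ValueError("need contracted_width_px > elongated_width_px > 0")
        if not (self.elongated_length_px > self.contracted_length_px > 0):
            raise ValueError("need elongated_length_px > contracted_length_px > 0")

    @property
    def effective_cb_peak(self) -> float:
        """Peak dF/F of a single CB transient."""
        return self.cb_amplitude * kernel_peak_value(self.rise_tau, self.decay_tau)

    @property
    def effective_rp1_peak(self) -> float:
        return self.rp1_amplitude * kernel_peak_value(self.rise_tau, self.decay_tau)

    @property
    def snr(self) -> float:
        """Peak of the weakest event class present, over the noise SD.

        Detectability is governed by the smallest transient the detector
        must find, so the recording's SNR is referenced to RP1 pulses when
        they are present and to CB pulses otherwise.
        """
        weakest = self.effective_cb_peak
        if self.rp1_rate > 0:
            weakest = min(weakest, self.effective_rp1_peak)
        return math.inf if self.noise_sd == 0 else weakest / self.noise_sd

    def with_snr(self, snr: float) -> "SimulationConfig":
        """Copy of this config with ``noise_sd`` set to reach ``snr``."""
        weakest = self.effective_cb_peak
        if self.rp1_rate > 0:
            weakest = min(weakest, self.effective_rp1_peak)
        return dataclasses.replace(self, noise_sd=weakest / snr)

    @classmethod
    def for_condition(cls, condition: str, **overrides) -> "SimulationConfig":
        """Config preset for an osmolarity condition (low/control/high)."""
        if condition not in CONDITION_MULTIPLIERS:
            raise ValueError(f"unknown condition {condition!r}")
        kw = dict(
            condition_label=condition,
            osmolarity_multiplier=CONDITION_MULTIPLIERS[condition],
            elongated_width_px=CONDITION_ELONGATED_WIDTHS[condition],
        )
        kw.update(overrides)
        return cls(**kw)


@dataclass
class GroundTruthEvents:
    """True event times and classes emitted by the simulator.

    ``pulse_times`` are the times of the transient *peaks* (what a peak
    detector reports); CB pulse times lie inside exactly one burst
    window, RP1 times lie outside all of them.
    """

    burst_windows: list[tuple[float, float]]
    pulse_times: np.ndarray
    pulse_classes: np.ndarray  # "CB" or "RP1", parallel to pulse_times
    duration: float

    @property
    def cb_times(self) -> np.ndarray:
        return self.pulse_times[self.pulse_classes == "CB"]

    @property
    def rp1_times(self) -> np.ndarray:
        return self.pulse_times[self.pulse_classes == "RP1"]

    @property
    def burst_count(self) -> int:
        return len(self.burst_windows)


@dataclass
class GeometryTrajectory:
    """Per-frame body-column geometry with ground-truth cycle minima."""

    times: np.ndarray
    length_px: np.ndarray
    width_px: np.ndarray
    centroid: np.ndarray  # (n, 2) row/col, px
    cycle_minima_times: np.ndarray
    cycle_minima_widths: np.ndarray


def simulate_events(config: SimulationConfig) -> GroundTruthEvents:
    """Draw CB bursts and RP1 pulses for one recording.

    Burst onsets follow a homogeneous Poisson process at
    ``cb_burst_rate * osmolarity_multiplier``; onsets landing inside the
    refractory window of the preceding burst are shifted to its end so
    the Poisson count is preserved.  Each burst carries
    ``1 + Poisson(pulses_per_burst_mean)`` pulses spaced
    ``intra_burst_interval`` apart.  RP1 pulses are a jittered periodic
    process; any RP1 falling within ``rp1_exclusion_pad`` of a burst
    window is discarded (the RP1 circuit fires during elongation, not
    around contractions).
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    dur = config.duration
    ibi = config.intra_burst_interval

    rate_per_s = config.cb_burst_rate * config.osmolarity_multiplier / 3600.0
    n_bursts = rng.poisson(rate_per_s * dur)
    onsets = np.sort(rng.uniform(0.0, dur, n_bursts))
    burst_sizes = 1 + rng.poisson(config.pulses_per_burst_mean, n_bursts)

    burst_windows: list[tuple[float, float]] = []
    cb_times: list[float] = []
    pad = ibi / 2.0
    prev_end = -math.inf
    for onset, size in zip(onsets, burst_sizes):
        onset = max(onset, prev_end + config.min_interburst_interval)
        times = onset + ibi * np.arange(size)
        times = times[times < dur]
        if times.size == 0 or onset >= dur:
            continue
        window = (max(0.0, times[0] - pad), min(dur, times[-1] + pad))
        burst_windows.append(window)
        cb_times.extend(times.tolist())
        prev_end = window[1]

    rp1_times: list[float] = []
    if config.rp1_rate > 0:
        period = 3600.0 / config.rp1_rate
        t = rng.uniform(0.0, period)
        guard = config.rp1_exclusion_pad
        while t < dur:
            if t > 0 and not any(w0 - guard <= t <= w1 + guard
                                 for w0, w1 in burst_windows):
                rp1_times.append(t)
            t += period + rng.normal(0.0, config.rp1_jitter_frac * period)

    times = np.array(cb_times + rp1_times, dtype=float)
    classes = np.array(["CB"] * len(cb_times) + ["RP1"] * len(rp1_times))
    order = np.argsort(times, kind="stable")
    return GroundTruthEvents(
        burst_windows=burst_windows,
        pulse_times=times[order],
        pulse_classes=classes[order],
        duration=dur,
    )


def render_trace(events: GroundTruthEvents, config: SimulationConfig) -> FluorescenceTrace:
    """Render a raw fluorescence trace from ground-truth events.

    The trace is ``baseline * exp(-t/bleach_tau) * (1 + dF/F + noise)``
    where dF/F is the sum of difference-of-exponentials transients.  Each
    transient is placed so that its *peak* occurs at the event's pulse
    time, keeping detector output and ground truth on the same clock.
    """
    config.validate()
    if events.pulse_times.size and (
        events.pulse_times.min() < 0 or events.pulse_times.max() > events.duration
    ):
        raise ValueError("event times outside [0, duration]")

    n = int(round(config.duration * config.frame_rate))
    t = np.arange(n) / config.frame_rate
    dff = np.zeros(n)
    delay = _kernel_peak_delay(config.rise_tau, config.decay_tau)
    support = int(math.ceil(15.0 * config.decay_tau * config.frame_rate))
    for tp, cls in zip(events.pulse_times, events.pulse_classes):
        amp = config.cb_amplitude if cls == "CB" else config.rp1_amplitude
        onset = tp - delay
        i0 = max(0, int(math.ceil(onset * config.frame_rate)))
        i1 = min(n, i0 + support)
        if i0 >= i1:
            continue
        tt = t[i0:i1] - onset
        dff[i0:i1] += amp * (np.exp(-tt / config.decay_tau) - np.exp(-tt / config.rise_tau))

    bleach = np.exp(-t / config.bleach_tau) if math.isfinite(config.bleach_tau) else 1.0
    noise = 0.0
    if config.noise_sd > 0:
        noise = np.random.default_rng([config.seed, 2]).normal(0.0, config.noise_sd, n)
    values = config.baseline * bleach * (1.0 + dff + noise)
    return FluorescenceTrace(
        values=values,
        frame_rate=config.frame_rate,
        units="raw",
        condition=config.condition_label,
        tissue="neuron" if config.rp1_rate > 0 else "ectoderm",
    )


def simulate_geometry(config: SimulationConfig,
                      events: GroundTruthEvents) -> GeometryTrajectory:
    """Body-column geometry driven by the burst windows.

    During a burst window the column contracts (width relaxes quickly
    toward ``contracted_width_px``); between bursts it elongates slowly
    back toward ``elongated_width_px``.  Length is the exact mirror of
    width, so length minima coincide with width maxima.  The ground-truth
    end-of-elongation minima are the width minima of each
    inter-contraction interval (between a burst's offset and the next
    onset, plus the tail after the last burst).
    """
    config.validate()
    n = int(round(config.duration * config.frame_rate))
    t = np.arange(n) / config.frame_rate
    w_lo, w_hi = config.elongated_width_px, config.contracted_width_px
    width = np.empty(n)
    w = w_lo
    dt = 1.0 / config.frame_rate
    k_contract = 1.0 - math.exp(-dt / config.contraction_tau_s)
    k_elong = 1.0 - math.exp(-dt / config.elongation_tau_s)
    windows = events.burst_windows
    wi = 0
    for i, ti in enumerate(t):
        while wi < len(windows) and ti > windows[wi][1]:
            wi += 1
        in_burst = wi < len(windows) and windows[wi][0] <= ti <= windows[wi][1]
        if in_burst:
            w += (w_hi - w) * k_contract
        else:
            w += (w_lo - w) * k_elong
        width[i] = w

    frac = (width - w_lo) / (w_hi - w_lo)
    length = config.elongated_length_px - frac * (
        config.elongated_length_px - config.contracted_length_px
    )

    minima_t: list[float] = []
    minima_w: list[float] = []
    for j, (_, offset) in enumerate(windows):
        next_onset = windows[j + 1][0] if j + 1 < len(windows) else config.duration
        sel = np.flatnonzero((t > offset) & (t < next_onset))
        if sel.size == 0:
            continue
        k = sel[np.argmin(width[sel])]
        minima_t.append(t[k])
        minima_w.append(width[k])

    centroid = np.zeros((n, 2))
    return GeometryTrajectory(
        times=t,
        length_px=length,
        width_px=width,
        centroid=centroid,
        cycle_minima_times=np.asarray(minima_t),
        cycle_minima_widths=np.asarray(minima_w),
    )


def render_movie(
    traj: GeometryTrajectory,
    trace: FluorescenceTrace,
    frame_shape: tuple[int, int] = (256, 320),
    orientation: float = 0.0,
    gain: float = 10.0,
    shot_noise: bool = False,
    seed: int = 0,
) -> np.ndarray:
    """Rasterize the trajectory as a 16-bit movie stack.

    Each frame is a filled ellipse (major axis = body length, minor axis
    = body width) on a dark background whose interior intensity is
    ``gain`` times the trace value at that frame, optionally with Poisson
    shot noise.  The trace is resampled onto the trajectory's time base
    when the two differ.
    """
    from skimage.draw import ellipse as draw_ellipse

    h, w = frame_shape
    values = trace.values
    if len(values) != len(traj.times):
        values = np.interp(traj.times, trace.times, trace.values)

    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    half_len = traj.length_px.max() / 2.0
    half_wid = traj.width_px.max() / 2.0
    # extents of a rotated ellipse along the frame axes
    c, s = math.cos(orientation), math.sin(orientation)
    max_c = math.hypot(half_len * c, half_wid * s)
    max_r = math.hypot(half_len * s, half_wid * c)
    if cy - max_r < 0 or cy + max_r > h - 1 or cx - max_c < 0 or cx + max_c > w - 1:
        raise ValueError(
            f"ellipse (length {traj.length_px.max():.0f}, width "
            f"{traj.width_px.max():.0f} px) exceeds frame bounds {frame_shape}"
        )

    rng = np.random.default_rng([seed, 3]) if shot_noise else None
    stack = np.zeros((len(traj.times), h, w), dtype=np.uint16)
    for i in range(len(traj.times)):
        rr, cc = draw_ellipse(
            cy + traj.centroid[i, 0],
            cx + traj.centroid[i, 1],
            traj.width_px[i] / 2.0,
            traj.length_px[i] / 2.0,
            shape=(h, w),
            rotation=orientation,
        )
        frame = np.zeros((h, w))
        intensity = max(gain * values[i], 0.0)
        frame[rr, cc] = intensity
        if rng is not None:
            frame[rr, cc] = rng.poisson(frame[rr, cc])
        stack[i] = np.clip(np.round(frame), 0, 65535).astype(np.uint16)
    return stack


def save_ground_truth(path, events: GroundTruthEvents,
                      traj: GeometryTrajectory | None = None) -> None:
    """Write ground truth as a JSON sidecar."""
    payload = {
        "duration_s": events.duration,
        "burst_windows_s": [[a, b] for a, b in events.burst_windows],
        "pulse_times_s": events.pulse_times.tolist(),
        "pulse_classes": events.pulse_classes.tolist(),
    }
    if traj is not None:
        payload["cycle_minima_times_s"] = traj.cycle_minima_times.tolist()
        payload["cycle_minima_widths_px"] = traj.cycle_minima_widths.tolist()
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_ground_truth(path) -> GroundTruthEvents:
    with open(path) as fh:
        payload = json.load(fh)
    return GroundTruthEvents(
        burst_windows=[tuple(w) for w in payload["burst_windows_s"]],
        pulse_times=np.asarray(payload["pulse_times_s"], dtype=float),
        pulse_classes=np.asarray(payload["pulse_classes"]),
        duration=payload["duration_s"],
    )
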