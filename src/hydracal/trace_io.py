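"""Whole-body fluorescence trace extraction and tabular trace I/O.

The upstream measurement of this workflow is a single number per movie
frame: the whole-body fluorescence intensity.  This module reads
multi-page TIFF stacks, reduces them to a :class:`FluorescenceTrace`,
and round-trips traces through a small commented CSV format.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "FluorescenceTrace",
    "read_stack",
    "write_stack",
    "extract_whole_body_trace",
    "read_trace",
    "write_trace",
]

_UNIFORMITY_RTOL = 1e-6


@dataclass
class FluorescenceTrace:
    """Uniformly sampled whole-body fluorescence intensity series.

    ``values`` are raw intensity (a.u.) or dF/F depending on ``units``;
    frame ``i`` is at time ``i / frame_rate`` seconds.
    """

    values: np.ndarray
    frame_rate: float
    units: str = "raw"            # "raw" or "dff"
    condition: str = ""
    tissue: str = "neuron"        # neuron | ectoderm | endoderm
    source: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("trace needs at least 2 samples")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace values must be finite")
        if not (self.frame_rate > 0 and math.isfinite(self.frame_rate)):
            raise ValueError("frame_rate must be positive and finite")
        if self.units not in ("raw", "dff"):
            raise ValueError(f"units must be 'raw' or 'dff', got {self.units!r}")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) / self.frame_rate

    @property
    def duration(self) -> float:
        return self.values.size / self.frame_rate

    def __len__(self) -> int:
        return self.values.size


def read_stack(path) -> np.ndarray:
    """Read a single-channel multi-page TIFF as a (frames, h, w) array."""
    stack = tifffile.imread(str(path))
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3:
        raise ValueError(
            f"single-channel required: {path} has shape {stack.shape}"
        )
    if stack.shape[0] == 0:
        raise ValueError(f"zero frames in {path}")
    return stack


def write_stack(stack: np.ndarray, path) -> None:
    """Write a movie stack as a multi-page TIFF (16-bit for integer data)."""
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("expected (frames, h, w) array")
    tifffile.imwrite(str(path), stack)


def _otsu_foreground(frame: np.ndarray) -> np.ndarray:
    from skimage.filters import threshold_otsu

    if frame.max() == frame.min():
        return np.zeros(frame.shape, dtype=bool)
    return frame > threshold_otsu(frame)


def extract_whole_body_trace(
    stack: np.ndarray,
    frame_rate: float,
    mask_mode: str = "whole_frame",
    **metadata,
) -> FluorescenceTrace:
    """Mean fluorescence per frame, over the whole frame or an Otsu mask.

    ``whole_frame`` averages every pixel; ``otsu_mask`` averages only the
    per-frame foreground (the animal), which removes dilution by the dark
    background when the animal's footprint changes.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.shape[0] == 0:
        raise ValueError("expected non-empty (frames, h, w) stack")
    if mask_mode == "whole_frame":
        values = stack.reshape(stack.shape[0], -1).mean(axis=1)
    elif mask_mode == "otsu_mask":
        values = np.empty(stack.shape[0])
        for i, frame in enumerate(stack):
            mask = _otsu_foreground(frame)
            if not mask.any():
                raise ValueError(f"empty foreground mask in frame {i}")
            values[i] = frame[mask].mean()
    else:
        raise ValueError(f"unknown mask_mode {mask_mode!r}")
    return FluorescenceTrace(values=values, frame_rate=frame_rate,
                             units="raw", **metadata)


def write_trace(trace: FluorescenceTrace, path) -> None:
    """Write a trace as CSV with a commented metadata header.

    Values are written with 12 significant digits so a read/write round
    trip is lossless well beyond 1e-9 relative tolerance.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# hydracal trace v1\n")
        fh.write(f"# frame_rate_hz: {trace.frame_rate!r}\n")
        fh.write(f"# units: {trace.units}\n")
        fh.write(f"# condition: {trace.condition}\n")
        fh.write(f"# tissue: {trace.tissue}\n")
        fh.write("frame,time_s,intensity\n")
        for i, (t, v) in enumerate(zip(trace.times, trace.values)):
            fh.write(f"{i},{t:.10g},{v:.12g}\n")


def read_trace(path) -> FluorescenceTrace:
    """Read a trace CSV (columns frame, time_s, intensity) back."""
    path = Path(path)
    meta: dict[str, str] = {}
    header: list[str] | None = None
    frames: list[int] = []
    times: list[float] = []
    values: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("# ")
                if ":" in body:
                    key, _, val = body.partition(":")
                    meta[key.strip()] = val.strip()
                continue
            if header is None:
                header = [c.strip() for c in line.split(",")]
                missing = {"frame", "time_s", "intensity"} - set(header)
                if missing:
                    raise ValueError(f"missing columns {sorted(missing)} in {path}")
                idx = {c: header.index(c) for c in ("frame", "time_s", "intensity")}
                continue
            cells = line.split(",")
            frames.append(int(cells[idx["frame"]]))
            times.append(float(cells[idx["time_s"]]))
            values.append(float(cells[idx["intensity"]]))
    if header is None or len(values) < 2:
        raise ValueError(f"no trace data in {path}")

    times_arr = np.asarray(times)
    steps = np.diff(times_arr)
    if "frame_rate_hz" in meta:
        frame_rate = float(meta["frame_rate_hz"])
    else:
        frame_rate = 1.0 / np.median(steps)
    step = 1.0 / frame_rate
    if np.any(steps <= 0) or np.any(np.abs(steps - step) > _UNIFORMITY_RTOL * step):
        raise ValueError(f"non-uniform sampling in {path}")
    return FluorescenceTrace(
        values=np.asarray(values),
        frame_rate=frame_rate,
        units=meta.get("units", "raw"),
        condition=meta.get("condition", ""),
        tissue=meta.get("tissue", "neuron"),
        source=str(path),
    )
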