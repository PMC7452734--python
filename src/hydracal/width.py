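"""Body-column width morphometry by moment-based ellipse fitting.

Each movie frame is segmented (Otsu threshold, largest connected
component, hole filling) and the body column is summarized by its
moment-equivalent ellipse: the ellipse whose second central moments
match those of the foreground mask.  The minor axis is the body-column
width, the major axis its length.  Contraction--elongation cycles are
read off the width trace, and the per-cycle minima give the
end-of-elongation width.  An automated contraction counter on the
length channel stands in for manual scoring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_fill_holes
from scipy.signal import find_peaks

__all__ = [
    "EllipseFit",
    "WidthTrace",
    "CycleSet",
    "segment_body",
    "fit_ellipse",
    "compute_width_trace",
    "detect_cycles",
    "count_contractions",
]


@dataclass
class EllipseFit:
    """Moment-equivalent ellipse of a binary mask."""

    centroid: tuple[float, float]   # (row, col), px
    major_axis: float               # full axis length, px
    minor_axis: float               # full axis length, px
    orientation: float              # radians, major axis vs column axis
    area: float                     # px^2 (foreground pixel count)


@dataclass
class WidthTrace:
    """Per-frame body-column width/length with a validity mask."""

    times: np.ndarray
    width: np.ndarray       # minor axis, px
    length: np.ndarray      # major axis, px
    valid: np.ndarray       # bool per frame
    frame_rate: float

    def __len__(self) -> int:
        return self.times.size


@dataclass
class CycleSet:
    """Contraction-cycle width minima (end-of-elongation widths)."""

    minima_times: np.ndarray
    minima_widths: np.ndarray

    @property
    def mean_end_elongation_width(self) -> float:
        """Mean of per-cycle minimum widths; NaN when no cycle was found."""
        if self.minima_widths.size == 0:
            return math.nan
        return float(np.mean(self.minima_widths))


def segment_body(frame: np.ndarray) -> np.ndarray | None:
    """Binary body mask: Otsu threshold, largest component, filled holes.

    Returns None for frames with no usable foreground (blank frames),
    which callers flag invalid rather than failing.
    """
    from skimage.filters import threshold_otsu
    from skimage.measure import label

    frame = np.asarray(frame)
    if frame.ndim != 2:
        raise ValueError("expected a single-channel frame")
    if frame.max() == frame.min():
        return None
    mask = frame > threshold_otsu(frame)
    if not mask.any():
        return None
    labels = label(mask)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    return binary_fill_holes(labels == largest)


def fit_ellipse(mask: np.ndarray) -> EllipseFit:
    """Fit the moment-equivalent ellipse to a binary mask.

    Axis lengths are ``4 * sqrt(eigenvalue)`` of the covariance matrix of
    the foreground pixel coordinates -- the ellipse with the same second
    central moments as the mask.
    """
    coords = np.argwhere(np.asarray(mask, dtype=bool))
    if coords.shape[0] < 3:
        raise ValueError("mask too small for an ellipse fit")
    centroid = coords.mean(axis=0)
    cov = np.cov(coords.T, ddof=0)
    eigvals, eigvecs = np.linalg.eigh(cov)
    if eigvals[0] <= 0:
        raise ValueError("degenerate (collinear) mask")
    minor = 4.0 * math.sqrt(eigvals[0])
    major = 4.0 * math.sqrt(eigvals[1])
    vec = eigvecs[:, 1]
    orientation = math.atan2(vec[1], vec[0]) % math.pi
    return EllipseFit(
        centroid=(float(centroid[0]), float(centroid[1])),
        major_axis=major,
        minor_axis=minor,
        orientation=orientation,
        area=float(coords.shape[0]),
    )


def compute_width_trace(stack: np.ndarray, frame_rate: float,
                        max_invalid_frac: float = 0.2) -> WidthTrace:
    """Segment and fit every frame; width = minor axis, length = major.

    Isolated invalid frames (blank or degenerate) are linearly
    interpolated from their neighbours; runs of invalid frames are left
    invalid.  More than ``max_invalid_frac`` invalid frames is an error.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.shape[0] == 0:
        raise ValueError("expected non-empty (frames, h, w) stack")
    n = stack.shape[0]
    width = np.full(n, np.nan)
    length = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    for i, frame in enumerate(stack):
        mask = segment_body(frame)
        if mask is None:
            continue
        try:
            fit = fit_ellipse(mask)
        except ValueError:
            continue
        width[i] = fit.minor_axis
        length[i] = fit.major_axis
        valid[i] = True

    n_invalid = int((~valid).sum())
    if n_invalid > max_invalid_frac * n:
        raise ValueError(
            f"{n_invalid}/{n} frames invalid (> {max_invalid_frac:.0%})"
        )
    # interpolate isolated invalid frames only
    for i in np.flatnonzero(~valid):
        if 0 < i < n - 1 and valid[i - 1] and valid[i + 1]:
            width[i] = 0.5 * (width[i - 1] + width[i + 1])
            length[i] = 0.5 * (length[i - 1] + length[i + 1])
            valid[i] = True

    times = np.arange(n) / frame_rate
    return WidthTrace(times=times, width=width, length=length,
                      valid=valid, frame_rate=frame_rate)


def detect_cycles(wt: WidthTrace,
                  min_period: float = 60.0,
                  prominence: float | None = None) -> CycleSet:
    """Find per-cycle width minima (end-of-elongation widths).

    Minima are peaks of the negated width trace with at least the stated
    prominence (default 5% of the trace's range) separated by
    ``min_period`` seconds.  An empty result reports its mean as NaN,
    not zero.
    """
    w = wt.width.copy()
    if np.isnan(w).any():
        # fill remaining invalid frames by nearest valid value for peak
        # finding only; minima inside such runs are not trusted anyway
        idx = np.arange(w.size)
        good = ~np.isnan(w)
        if good.sum() < 2:
            return CycleSet(np.array([]), np.array([]))
        w = np.interp(idx, idx[good], w[good])
    if prominence is None:
        rng = float(w.max() - w.min())
        prominence = 0.05 * rng if rng > 0 else 1e-9
    distance = max(1, int(round(min_period * wt.frame_rate)))
    minima, _ = find_peaks(-w, prominence=prominence, distance=distance)
    return CycleSet(
        minima_times=wt.times[minima],
        minima_widths=w[minima],
    )


def count_contractions(wt: WidthTrace, shortening_fraction: float = 0.3) -> int:
    """Count length excursions below (1 - fraction) of the preceding maximum.

    A contraction is scored when the body length drops below
    ``(1 - shortening_fraction)`` times the running local maximum and
    later recovers above that threshold.
    """
    if not (0 < shortening_fraction < 1):
        raise ValueError("shortening_fraction must be in (0, 1)")
    length = wt.length[wt.valid]
    if length.size == 0:
        return 0
    count = 0
    ref_max = length[0]
    in_contraction = False
    for value in length[1:]:
        if not in_contraction:
            ref_max = max(ref_max, value)
            if value < (1.0 - shortening_fraction) * ref_max:
                in_contraction = True
        else:
            if value >= (1.0 - shortening_fraction) * ref_max:
                count += 1
                in_contraction = False
                ref_max = value
    return count
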