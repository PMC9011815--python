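"""Peak detection and ladder-based size calibration.

A ladder injection carries the lower-marker internal standard plus one
narrow peak per ladder transcript. Migration time is modelled as a straight
line in log10(size): with eight ladder points a line is the simplest
monotone model, and the fit residuals are kept so curvature on real
instruments remains visible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import trapezoid
from scipy.signal import find_peaks

from .errors import CalibrationError
from .integration import Baseline, effective_noise_sd, smooth_signal
from .synthetic import LadderSpec
from .traceio import Trace

#: Window (s) in which the earliest peak is taken to be the lower marker.
MARKER_WINDOW = (15.0, 22.0)


@dataclass
class Peak:
    """A detected electropherogram feature."""

    apex_time: float
    height: float
    left: float
    right: float
    area: float
    snr: float
    size_nt: float | None = None

    def __post_init__(self) -> None:
        if not (self.left < self.apex_time < self.right):
            raise ValueError("peak bounds must bracket the apex")
        if self.area < 0 or self.height <= 0:
            raise ValueError("peak area must be >= 0 and height > 0")


@dataclass
class SizeCalibration:
    """Fitted line ``time = intercept + slope * log10(size_nt)``.

    ``slope`` is seconds per decade of size and must be positive (larger
    species migrate later). ``size_range`` is the ladder's span; size
    estimates outside it are flagged as extrapolated.
    """

    intercept: float
    slope: float
    size_range: tuple[float, float]
    ladder_sizes: np.ndarray = field(default_factory=lambda: np.array([]))
    ladder_times: np.ndarray = field(default_factory=lambda: np.array([]))
    residuals: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise CalibrationError("calibration slope must be positive")

    def time_of(self, size_nt: float) -> float:
        """Migration time predicted for a species of the given size."""
        return float(self.intercept + self.slope * np.log10(size_nt))

    def size_at(self, time_s: float) -> float:
        """Inverse mapping: RNA size (nt) at a migration time."""
        return float(10.0 ** ((time_s - self.intercept) / self.slope))

    def extrapolates(self, time_s: float) -> bool:
        """True when ``size_at(time_s)`` falls outside the ladder's range."""
        size = self.size_at(time_s)
        lo, hi = self.size_range
        return not (lo <= size <= hi)

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "slope": self.slope,
            "size_range": list(self.size_range),
            "ladder_sizes": np.asarray(self.ladder_sizes).tolist(),
            "ladder_times": np.asarray(self.ladder_times).tolist(),
            "residuals": np.asarray(self.residuals).tolist(),
        }


def _apex_refine(t: np.ndarray, y: np.ndarray, i: int, noiseless: bool) -> float:
    """Sub-sample apex via parabolic interpolation through three points.

    For noiseless data the interpolation is done on log(signal), which is
    exact for a Gaussian peak; for noisy data a plain parabola on the
    smoothed signal is more stable.
    """
    if i == 0 or i == y.size - 1:
        return float(t[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    if noiseless and min(y0, y1, y2) > 0:
        y0, y1, y2 = np.log(y0), np.log(y1), np.log(y2)
    denom = y0 - 2.0 * y1 + y2
    if denom >= 0:
        return float(t[i])
    shift = 0.5 * (y0 - y2) / denom
    shift = float(np.clip(shift, -0.5, 0.5))
    dt = t[1] - t[0]
    return float(t[i] + shift * dt)


def detect_peaks(
    trace: Trace,
    baseline: Baseline,
    min_snr: float = 3.0,
    min_prominence: float = 0.02,
) -> list[Peak]:
    """Detect peaks on the baseline-corrected (and, if noisy, smoothed) signal.

    A peak is a local maximum with prominence at least ``min_prominence`` x
    the corrected-signal maximum and S/N (height over the baseline noise SD)
    at least ``min_snr``. Bounds are the nearest flanking local minima; the
    area is the trapezoidal integral of the clipped corrected signal between
    them. Peaks are returned sorted by apex time. A flat trace yields an
    empty list.
    """
    t = trace.time
    corrected = trace.signal - baseline.values
    noise_sd = effective_noise_sd(corrected, baseline.noise_sd)
    noiseless = noise_sd == 0
    sm = smooth_signal(corrected, noise_sd)
    top = float(sm.max(initial=0.0))
    if top <= 0:
        return []
    idx, _ = find_peaks(sm, prominence=min_prominence * top)
    clipped = np.clip(corrected, 0.0, None)
    peaks: list[Peak] = []
    for i in idx:
        height = float(sm[i])
        snr = float("inf") if noiseless else height / noise_sd
        if snr < min_snr or height <= 0:
            continue
        li = _walk_to_min(sm, int(i), -1)
        ri = _walk_to_min(sm, int(i), +1)
        if li >= i:
            li = max(i - 1, 0)
        if ri <= i:
            ri = min(i + 1, t.size - 1)
        area = float(trapezoid(clipped[li : ri + 1], t[li : ri + 1]))
        apex = _apex_refine(t, corrected if noiseless else sm, int(i), noiseless)
        peaks.append(
            Peak(apex_time=apex, height=height, left=float(t[li]),
                 right=float(t[ri]), area=area, snr=snr)
        )
    peaks.sort(key=lambda p: p.apex_time)
    return peaks


def _walk_to_min(y: np.ndarray, i: int, direction: int) -> int:
    """Walk from a local maximum until the signal stops decreasing."""
    j = i
    n = y.size
    while True:
        nxt = j + direction
        if nxt < 0 or nxt > n - 1:
            return j
        if y[nxt] > y[j]:
            return j
        j = nxt


def split_marker(
    peaks: list[Peak], marker_window: tuple[float, float] = MARKER_WINDOW
) -> tuple[Peak | None, list[Peak]]:
    """Identify the lower marker as the earliest peak inside the marker window."""
    in_window = [p for p in peaks if marker_window[0] <= p.apex_time <= marker_window[1]]
    if not in_window:
        return None, list(peaks)
    marker = min(in_window, key=lambda p: p.apex_time)
    return marker, [p for p in peaks if p is not marker]


def fit_ladder(
    peaks: list[Peak],
    ladder: LadderSpec,
    marker_window: tuple[float, float] = MARKER_WINDOW,
) -> SizeCalibration:
    """Least-squares fit of ladder apex times against log10(transcript size).

    The lower marker (earliest peak in the marker window) is excluded. If
    more peaks than ladder sizes are present, the largest-area ones are kept
    with a warning (robustness to noise spikes); if fewer, calibration fails
    listing the detected apex times.
    """
    _, analyte = split_marker(peaks, marker_window)
    sizes = np.asarray(ladder.transcript_sizes, float)
    n = sizes.size
    if len(analyte) < n:
        times = [round(p.apex_time, 3) for p in analyte]
        raise CalibrationError(
            f"expected {n} ladder peaks, found {len(analyte)} at times {times}"
        )
    if len(analyte) > n:
        warnings.warn(
            f"{len(analyte)} candidate ladder peaks for {n} sizes; keeping the "
            f"{n} largest by area",
            stacklevel=2,
        )
        analyte = sorted(analyte, key=lambda p: p.area, reverse=True)[:n]
        analyte.sort(key=lambda p: p.apex_time)

    x = np.log10(sizes)
    y = np.array([p.apex_time for p in analyte])
    slope, intercept = np.polyfit(x, y, 1)
    if slope <= 0:
        raise CalibrationError(f"fitted migration slope {slope:.3g} is not positive")
    residuals = y - (intercept + slope * x)
    for p, size in zip(analyte, sizes):
        p.size_nt = float(size)
    return SizeCalibration(
        intercept=float(intercept),
        slope=float(slope),
        size_range=(float(sizes.min()), float(sizes.max())),
        ladder_sizes=sizes,
        ladder_times=y,
        residuals=residuals,
    )


def size_at(cal: SizeCalibration, time_s: float) -> float:
    """Module-level convenience for :meth:`SizeCalibration.size_at`."""
    return cal.size_at(time_s)
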