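"""Emulated manual ciliary-beat counting.

The manual protocol a trained observer follows: pause the recording where
the cilia are closest to the maximal bend, mark that starting frame, count
ten complete beats (forward plus recovery stroke), note the frame where the
tenth beat completes, and convert with

    manual CBF (Hz) = (fps / frames elapsed for 10 full beats) * 10

Here the visual counting field is reduced to a scalar proxy — the mean
intensity over the region of interest per frame — and "maximal bend"
landmarks become the local maxima of that trace after light smoothing.  The
proxy is declared as such: it emulates the protocol's arithmetic and frame
quantization, not observer behavior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from .io import FrameStack
from .preprocess import RectROI
from .spectral import CBFEstimate

__all__ = [
    "BeatTrace",
    "LandmarkSet",
    "roi_mean_trace",
    "detect_beat_landmarks",
    "manual_cbf",
    "emulate_manual_count",
]


@dataclass
class BeatTrace:
    """ROI-mean intensity per frame — the 1-D signal a counter watches."""

    values: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("trace must be 1-D with at least 2 samples")
        if not self.fps > 0:
            raise ValueError(f"fps must be positive, got {self.fps}")


@dataclass
class LandmarkSet:
    """Frame indices of successive maximal-bend landmarks, plus detector settings."""

    frames: np.ndarray  # strictly increasing
    smoothing_width: int
    min_prominence: float
    smoothed: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        if self.frames.size and np.any(np.diff(self.frames) <= 0):
            raise ValueError("landmark frames must be strictly increasing")

    def __len__(self) -> int:
        return self.frames.size

    def to_tsv(self) -> str:
        lines = ["frame\tsmoothed_value"]
        for f in self.frames:
            v = self.smoothed[f] if self.smoothed is not None else float("nan")
            lines.append(f"{f}\t{v:.4f}")
        return "\n".join(lines) + "\n"


def roi_mean_trace(stack: FrameStack, roi: RectROI | None = None) -> BeatTrace:
    """Spatial mean over the ROI of every frame (full frame when roi is None)."""
    frames = stack.frames
    if roi is not None:
        roi.check_bounds(frames.shape[1], frames.shape[2])
        frames = frames[:, roi.y0 : roi.y0 + roi.height, roi.x0 : roi.x0 + roi.width]
    return BeatTrace(frames.mean(axis=(1, 2)), fps=stack.fps)


def detect_beat_landmarks(
    trace: BeatTrace,
    smoothing_width: int = 5,
    min_prominence: float | None = None,
) -> LandmarkSet:
    """Maximal-bend landmarks: local maxima of the smoothed trace.

    The trace is smoothed with a centered moving average of
    ``smoothing_width`` frames, then local maxima with at least
    ``min_prominence`` (default: 10% of the smoothed trace's peak-to-peak
    range) are returned in order.  Fewer than 2 landmarks is an error — the
    signal is too flat or too short to count beats on.
    """
    if trace.values.size < 3:
        raise ValueError("trace too short to detect beat landmarks")
    smoothed = uniform_filter1d(trace.values, size=max(1, smoothing_width), mode="nearest")
    ptp = float(np.ptp(smoothed))
    if min_prominence is None:
        min_prominence = 0.1 * ptp
    if ptp == 0.0:
        raise ValueError("insufficient landmarks: trace is constant")
    peaks, _ = find_peaks(smoothed, prominence=min_prominence if min_prominence > 0 else None)
    if peaks.size < 2:
        raise ValueError(f"insufficient landmarks: found {peaks.size}, need at least 2")
    return LandmarkSet(
        frames=peaks, smoothing_width=smoothing_width, min_prominence=float(min_prominence),
        smoothed=smoothed,
    )


def manual_cbf(fps: float, frames_elapsed: int, n_beats: int = 10) -> CBFEstimate:
    """Closed-form manual count: ``(fps / frames elapsed for n beats) * n_beats``.

    E.g. 500 frames elapsed over 10 beats at 500 fps -> 10.0 Hz.
    """
    if frames_elapsed < 1:
        raise ValueError("frames_elapsed must be at least 1")
    if n_beats < 1:
        raise ValueError("n_beats must be at least 1")
    return CBFEstimate(value_hz=fps / frames_elapsed * n_beats, method="manual")


def emulate_manual_count(
    trace: BeatTrace,
    n_beats: int = 10,
    *,
    smoothing_width: int = 5,
    min_prominence: float | None = None,
) -> CBFEstimate:
    """Run the full emulated protocol on a beat trace.

    The first detected landmark is the starting frame; ``frames_elapsed`` is
    the span from it to the ``n_beats``-th subsequent landmark, and the
    closed-form conversion yields the estimate.  For a perfectly periodic
    trace whose period is an integer number of frames the result is exact;
    otherwise landmark rounding bounds the error by roughly
    ``f^2 / (fps * n_beats)``.
    """
    landmarks = detect_beat_landmarks(trace, smoothing_width, min_prominence)
    if len(landmarks) < n_beats + 1:
        raise ValueError(
            f"insufficient landmarks: {len(landmarks)} found, "
            f"need {n_beats + 1} to count {n_beats} beats"
        )
    frames_elapsed = int(landmarks.frames[n_beats] - landmarks.frames[0])
    return manual_cbf(trace.fps, frames_elapsed, n_beats)
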