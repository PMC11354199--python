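"""Pre-processing chain for high-speed ciliary video.

The stages mirror the standard semi-automated workflow applied before any
frequency estimate: manual rotation of the field, cropping to a region of
interest over the ciliated edge, translation-only image stabilization
(whole-field drift of the cell cluster corrupts the power spectrum and must
be removed), cropping of the margins invalidated by registration, and
finally motion extraction by mean-image subtraction, which removes every
pixel's static background so only moving structures retain signal.

Fixed stage order: rotation -> ROI crop -> stabilization -> margin crop ->
motion extraction.

Registration is translation-only against a fixed reference frame (default:
the first), estimated by phase correlation — not consecutive-pairwise
chaining, which would accumulate drift in the estimate itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.registration import phase_cross_correlation
from skimage.transform import rotate as _sk_rotate

from .io import FrameStack

__all__ = ["RectROI", "ShiftTrace", "rotate_frames", "crop_roi", "stabilize", "subtract_mean_image"]


@dataclass(frozen=True)
class RectROI:
    """Axis-aligned rectangular region of interest, half-open pixel bounds.

    Covers pixels ``x0 <= x < x0 + width`` and ``y0 <= y < y0 + height``
    (0-based, x = column, y = row).
    """

    x0: int
    y0: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError(f"ROI must be at least 1x1, got {self.width}x{self.height}")

    def check_bounds(self, frame_height: int, frame_width: int) -> None:
        if (
            self.x0 < 0
            or self.y0 < 0
            or self.x0 + self.width > frame_width
            or self.y0 + self.height > frame_height
        ):
            raise ValueError(
                f"ROI {self} extends outside frame bounds {frame_height}x{frame_width}"
            )

    def compose(self, inner: "RectROI") -> "RectROI":
        """The single ROI equivalent to cropping ``self`` then ``inner``."""
        return RectROI(self.x0 + inner.x0, self.y0 + inner.y0, inner.width, inner.height)


@dataclass
class ShiftTrace:
    """Per-frame correction shifts estimated by stabilization.

    ``shifts[t] = (dx, dy)`` is the translation *applied* to frame ``t`` to
    register it onto the reference frame — the negative of the frame's
    estimated displacement.  The reference frame's entry is ``(0, 0)``.
    """

    shifts: np.ndarray  # (T, 2) as (dx, dy)
    reference: int = 0

    def __post_init__(self) -> None:
        self.shifts = np.asarray(self.shifts, dtype=float)
        if self.shifts.ndim != 2 or self.shifts.shape[1] != 2:
            raise ValueError(f"shifts must be (T, 2), got {self.shifts.shape}")
        if not np.allclose(self.shifts[self.reference], 0):
            raise ValueError("reference frame must carry a zero shift")

    def to_tsv(self) -> str:
        lines = ["frame\tdx\tdy"]
        lines += [f"{t}\t{dx:g}\t{dy:g}" for t, (dx, dy) in enumerate(self.shifts)]
        return "\n".join(lines) + "\n"


def rotate_frames(stack: FrameStack, angle: float) -> FrameStack:
    """Rotate every frame by ``angle`` degrees (counterclockwise) about the center.

    Multiples of 90 degrees are lossless index permutations; other angles use
    bilinear interpolation with zero fill and return float frames.
    """
    if not np.isfinite(angle):
        raise ValueError(f"angle must be finite, got {angle}")
    angle = angle % 360.0
    if angle == 0.0:
        return stack.with_frames(stack.frames.copy())
    if angle % 90.0 == 0.0:
        k = int(angle // 90)
        return stack.with_frames(np.rot90(stack.frames, k=k, axes=(1, 2)).copy())
    out = np.stack(
        [
            _sk_rotate(f.astype(float), angle, order=1, mode="constant", cval=0.0,
                       preserve_range=True)
            for f in stack.frames
        ]
    )
    return stack.with_frames(out)


def crop_roi(stack: FrameStack, roi: RectROI) -> FrameStack:
    """Crop every frame to ``roi`` (half-open bounds; errors if out of frame)."""
    _, h, w = stack.shape
    roi.check_bounds(h, w)
    return stack.with_frames(
        stack.frames[:, roi.y0 : roi.y0 + roi.height, roi.x0 : roi.x0 + roi.width].copy()
    )


def stabilize(
    stack: FrameStack,
    reference: int = 0,
    *,
    subpixel: bool = False,
    upsample_factor: int = 10,
) -> tuple[FrameStack, ShiftTrace]:
    """Register every frame onto a fixed reference frame by phase correlation.

    Each frame's translation relative to the reference is estimated from the
    phase-correlation peak (ties broken toward the lowest ``(dy, dx)``) and
    undone; the output is cropped to the maximal axis-aligned region valid in
    every registered frame, so no fill values enter the downstream spectra.
    With ``subpixel=False`` (default) shifts are integer and the correction
    is an exact index remap.

    Returns the stabilized stack and the :class:`ShiftTrace` of applied
    corrections.
    """
    frames = stack.frames.astype(float)
    n, h, w = frames.shape
    if not 0 <= reference < n:
        raise ValueError(f"reference index {reference} outside [0, {n})")
    ref = frames[reference]

    corrections = np.zeros((n, 2))  # (dx, dy) applied to register
    for t in range(n):
        if t == reference:
            continue
        shift, _, _ = phase_cross_correlation(
            ref, frames[t], upsample_factor=upsample_factor if subpixel else 1,
            normalization="phase",
        )
        dy, dx = shift  # shift that maps frame t onto the reference
        corrections[t] = (dx, dy)
    if not subpixel:
        corrections = np.round(corrections)

    # registered extent: frame t contributes rows [cy, h + cy) of the
    # reference grid after applying correction (cx, cy)
    cx, cy = corrections[:, 0], corrections[:, 1]
    x_lo = int(np.ceil(max(0.0, cx.max())))
    x_hi = int(np.floor(w + min(0.0, cx.min())))
    y_lo = int(np.ceil(max(0.0, cy.max())))
    y_hi = int(np.floor(h + min(0.0, cy.min())))
    if x_hi <= x_lo or y_hi <= y_lo:
        raise ValueError("drift too large: registered frames share no common overlap region")

    out = np.empty((n, y_hi - y_lo, x_hi - x_lo))
    for t in range(n):
        dx, dy = corrections[t]
        if subpixel and (dx != int(dx) or dy != int(dy)):
            from scipy.ndimage import shift as ndshift

            moved = ndshift(frames[t], (dy, dx), order=1, mode="nearest")
        else:
            moved = np.roll(frames[t], (int(dy), int(dx)), axis=(0, 1))
        out[t] = moved[y_lo:y_hi, x_lo:x_hi]

    if stack.frames.dtype.kind in "ui" and not subpixel:
        out = out.astype(stack.frames.dtype)
    return stack.with_frames(out), ShiftTrace(corrections, reference=reference)


def subtract_mean_image(stack: FrameStack) -> FrameStack:
    """Motion extraction: subtract each pixel's temporal mean image.

    Removes the static background entirely — a temporally constant stack maps
    to zero — while leaving all non-DC spectral content untouched.  Output is
    float (signed intensities).
    """
    frames = stack.frames.astype(float)
    return stack.with_frames(frames - frames.mean(axis=0, keepdims=True))
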