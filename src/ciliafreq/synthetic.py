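"""Synthetic high-speed-video benchmarks with known ground truth.

Patient recordings of beating cilia are rarely shareable, so every stage of
the analysis pipeline is exercised against synthetic ciliated-patch image
sequences instead.  The pixel model is the one the spectral estimators
assume: each ciliated region modulates light intensity sinusoidally at its
beat frequency, neighboring cilia beat with a spatial phase lag (the
metachronal wave, modeled as a linear phase ramp), the rest of the field is
a static background, and the sensor adds Gaussian noise and quantizes.
Optionally the whole field drifts — the failure mode image stabilization
exists to undo.

    I(x, y, t) = B(x, y)
               + sum_r M_r(x, y) * A_r * sin(2*pi*f_r*t/fps + phi_r(x, y))
               + eps,     eps ~ N(0, sigma^2) i.i.d.

followed by per-frame translation by the cumulative drift, then clipping and
quantization to the sensor bit depth.  Every draw is driven by a seed, so
identical configurations reproduce bit-identical stacks.

:func:`simulate_cohort` scales this up to a two-group study: each recording's
true beat frequency is drawn from its group's distribution (point mass,
normal, IQR-parameterized normal, or uniform — cohort summaries in this field
are reported as medians and IQRs, so the generator accepts exactly those),
with a truth table tying every recording to its subject, group and true CBF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .io import FrameStack

__all__ = [
    "Region",
    "SimConfig",
    "GroundTruth",
    "GroupSpec",
    "CohortRecording",
    "simulate_cilia_stack",
    "simulate_cohort",
    "quantize",
]

# IQR of a normal = 2 * Phi^-1(0.75) * sigma
_IQR_PER_SIGMA = 2.0 * norm.ppf(0.75)


@dataclass
class Region:
    """One ciliated patch: a mask plus its beat parameters.

    ``mask`` is an axis-aligned rectangle ``("rect", x0, y0, w, h)``, a disk
    ``("disk", cx, cy, r)``, or a boolean image of the full frame.  The
    metachronal wave is a linear phase ramp: wavelength in pixels along
    ``wave_direction`` (radians, 0 = +x).  ``wavelength_px=inf`` means all
    cilia in the patch beat in phase.
    """

    mask: tuple | np.ndarray
    cbf_hz: float
    amplitude: float = 20.0
    wavelength_px: float = np.inf
    wave_direction: float = 0.0
    phase0: float = 0.0

    def mask_array(self, height: int, width: int) -> np.ndarray:
        if isinstance(self.mask, np.ndarray):
            m = np.asarray(self.mask, dtype=bool)
            if m.shape != (height, width):
                raise ValueError(f"mask shape {m.shape} != frame shape {(height, width)}")
            return m
        kind = self.mask[0]
        if kind == "rect":
            _, x0, y0, w, h = self.mask
            if x0 < 0 or y0 < 0 or x0 + w > width or y0 + h > height:
                raise ValueError(f"rect mask {self.mask} out of frame bounds {(height, width)}")
            m = np.zeros((height, width), dtype=bool)
            m[y0 : y0 + h, x0 : x0 + w] = True
            return m
        if kind == "disk":
            _, cx, cy, r = self.mask
            if cx - r < 0 or cy - r < 0 or cx + r > width or cy + r > height:
                raise ValueError(f"disk mask {self.mask} out of frame bounds {(height, width)}")
            yy, xx = np.mgrid[0:height, 0:width]
            return (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2
        raise ValueError(f"unknown mask spec {self.mask!r}")

    def phase_map(self, height: int, width: int) -> np.ndarray:
        yy, xx = np.mgrid[0:height, 0:width]
        if not np.isfinite(self.wavelength_px):
            return np.full((height, width), self.phase0)
        proj = xx * np.cos(self.wave_direction) + yy * np.sin(self.wave_direction)
        return self.phase0 + 2.0 * np.pi * proj / self.wavelength_px


@dataclass
class SimConfig:
    """Parameters of one synthetic recording.

    Defaults emulate the acquisition envelope of a clinical high-speed
    recording (500 fps, 1000 analyzed frames) on a desk-scale 128x128 field;
    height/width scale up to full camera frames (637 x 880) unchanged.
    ``drift`` is either ``None``, a per-frame velocity ``(vx, vy)`` in px/frame
    accumulated over time, or an explicit ``(T, 2)`` array of cumulative
    ``(dx, dy)`` shifts with row 0 equal to ``(0, 0)``.
    """

    fps: float = 500.0
    n_frames: int = 1000
    height: int = 128
    width: int = 128
    regions: Sequence[Region] = field(default_factory=list)
    background: float | np.ndarray = 100.0
    noise_sigma: float = 0.0
    drift: tuple[float, float] | np.ndarray | None = None
    subpixel_drift: bool = False
    bit_depth: int = 8
    quantize_output: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        nyquist = self.fps / 2.0
        for r in self.regions:
            if not 0 <= r.cbf_hz < nyquist:
                raise ValueError(
                    f"region frequency {r.cbf_hz} Hz violates Nyquist limit {nyquist} Hz"
                )


@dataclass
class GroundTruth:
    """What the generator actually put into a stack.

    ``frequency_map`` is NaN outside the union of region masks; ``shifts`` is
    the ``(T, 2)`` cumulative ``(dx, dy)`` translation of each frame's content
    relative to frame 0 (``shifts[0] == (0, 0)``).
    """

    frequency_map: np.ndarray
    shifts: np.ndarray
    regions: pd.DataFrame  # columns: cbf_hz, amplitude, area_px


def quantize(values: np.ndarray, bit_depth: int) -> np.ndarray:
    """Round half away from zero, clip to [0, 2^bit_depth - 1], cast to uint."""
    limit = 2**bit_depth - 1
    rounded = np.sign(values) * np.floor(np.abs(values) + 0.5)
    clipped = np.clip(rounded, 0, limit)
    return clipped.astype(np.uint8 if bit_depth <= 8 else np.uint16)


def _cumulative_shifts(config: SimConfig) -> np.ndarray:
    t = np.arange(config.n_frames, dtype=float)
    if config.drift is None:
        shifts = np.zeros((config.n_frames, 2))
    elif isinstance(config.drift, np.ndarray) or (
        hasattr(config.drift, "__len__") and len(config.drift) == config.n_frames
    ):
        shifts = np.asarray(config.drift, dtype=float)
        if shifts.shape != (config.n_frames, 2):
            raise ValueError(f"explicit drift must be (n_frames, 2), got {shifts.shape}")
        if not np.allclose(shifts[0], 0):
            raise ValueError("cumulative drift must start at (0, 0)")
    else:
        vx, vy = config.drift
        shifts = np.column_stack([vx * t, vy * t])
    if not config.subpixel_drift:
        shifts = np.round(shifts)
    return shifts


def simulate_cilia_stack(config: SimConfig) -> tuple[FrameStack, GroundTruth]:
    """Render one synthetic recording and its ground truth.

    Drift is realized by rendering the scene on a canvas padded by the drift
    extent and sampling a window whose origin moves opposite to the content
    shift, so no fill values ever enter the frame.  Integer drift (the
    default) is therefore exactly invertible by integer re-shifting, which
    keeps stabilization recovery bit-exact.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    h, w, n = config.height, config.width, config.n_frames

    shifts = _cumulative_shifts(config)
    # canvas pads by the drift extent so the moving window stays inside
    pad_left = int(np.ceil(max(0, shifts[:, 0].max())))
    pad_right = int(np.ceil(max(0, -shifts[:, 0].min())))
    pad_top = int(np.ceil(max(0, shifts[:, 1].max())))
    pad_bottom = int(np.ceil(max(0, -shifts[:, 1].min())))
    ch, cw = h + pad_top + pad_bottom, w + pad_left + pad_right

    background = np.broadcast_to(np.asarray(config.background, dtype=float), (h, w))
    canvas_bg = np.zeros((ch, cw))
    canvas_bg[pad_top : pad_top + h, pad_left : pad_left + w] = background
    # extend the border so a drifting window never sees an empty margin
    if pad_top:
        canvas_bg[:pad_top] = canvas_bg[pad_top]
    if pad_bottom:
        canvas_bg[pad_top + h :] = canvas_bg[pad_top + h - 1]
    if pad_left:
        canvas_bg[:, :pad_left] = canvas_bg[:, [pad_left]]
    if pad_right:
        canvas_bg[:, pad_left + w :] = canvas_bg[:, [pad_left + w - 1]]

    freq_map = np.full((h, w), np.nan)
    region_rows = []
    masks, phases = [], []
    for r in config.regions:
        m = r.mask_array(h, w)
        masks.append(m)
        phases.append(r.phase_map(h, w))
        freq_map[m] = r.cbf_hz
        region_rows.append({"cbf_hz": r.cbf_hz, "amplitude": r.amplitude, "area_px": int(m.sum())})

    t = np.arange(n, dtype=float) / config.fps
    frames = np.empty((n, h, w))
    has_drift = np.any(shifts != 0)
    canvas = np.empty((ch, cw))
    for i in range(n):
        scene = np.zeros((h, w))
        for r, m, phi in zip(config.regions, masks, phases):
            scene[m] += r.amplitude * np.sin(2 * np.pi * r.cbf_hz * t[i] + phi[m])
        if has_drift:
            dx, dy = shifts[i]
            canvas[:] = canvas_bg
            canvas[pad_top : pad_top + h, pad_left : pad_left + w] += scene
            if config.subpixel_drift and (dx != int(dx) or dy != int(dy)):
                from scipy.ndimage import shift as ndshift

                moved = ndshift(canvas, (dy, dx), order=1, mode="nearest")
                frame = moved[pad_top : pad_top + h, pad_left : pad_left + w]
            else:
                # content moves by (+dx, +dy): sample the window offset the other way
                y0, x0 = pad_top - int(dy), pad_left - int(dx)
                frame = canvas[y0 : y0 + h, x0 : x0 + w].copy()
        else:
            frame = background + scene
        if config.noise_sigma > 0:
            frame = frame + rng.normal(0.0, config.noise_sigma, size=(h, w))
        frames[i] = frame

    if config.quantize_output:
        out = quantize(frames, config.bit_depth)
    else:
        out = frames
    stack = FrameStack(out, fps=config.fps, bit_depth=config.bit_depth)
    truth = GroundTruth(
        frequency_map=freq_map,
        shifts=shifts,
        regions=pd.DataFrame(region_rows, columns=["cbf_hz", "amplitude", "area_px"]),
    )
    return stack, truth


@dataclass
class GroupSpec:
    """One cohort arm of a simulated study.

    ``cbf_dist`` is ``("point", value)``, ``("normal", mean, sigma)``,
    ``("normal_iqr", median, iqr)`` (sigma = iqr / 1.349), or
    ``("uniform", lo, hi)``, all in Hz.
    """

    label: str
    n_subjects: int
    recordings_per_subject: int
    cbf_dist: tuple
    amplitude: float = 20.0
    noise_sigma: float = 0.0

    def draw_cbf(self, rng: np.random.Generator) -> float:
        kind = self.cbf_dist[0]
        if kind == "point":
            return float(self.cbf_dist[1])
        if kind == "normal":
            return float(rng.normal(self.cbf_dist[1], self.cbf_dist[2]))
        if kind == "normal_iqr":
            return float(rng.normal(self.cbf_dist[1], self.cbf_dist[2] / _IQR_PER_SIGMA))
        if kind == "uniform":
            return float(rng.uniform(self.cbf_dist[1], self.cbf_dist[2]))
        raise ValueError(f"unknown CBF distribution spec {self.cbf_dist!r}")


@dataclass
class CohortRecording:
    """One simulated recording: metadata plus either full frames or a fast-path trace."""

    subject: str
    group: str
    recording: str
    true_cbf_hz: float
    seed: int
    stack: FrameStack | None = None
    trace: np.ndarray | None = None  # ROI-mean intensity per frame (fast path)
    sim_config: "SimConfig | None" = None  # set in lazy mode; render on demand
    fps: float = 500.0

    def render(self) -> FrameStack:
        """The recording's frames, rendering them now if generated lazily."""
        if self.stack is None and self.sim_config is not None:
            self.stack, _ = simulate_cilia_stack(self.sim_config)
        if self.stack is None:
            raise ValueError(f"recording {self.recording} carries no frames")
        return self.stack


def simulate_cohort(
    groups: Sequence[GroupSpec],
    seed: int = 0,
    *,
    fps: float = 500.0,
    n_frames: int = 1000,
    frame_shape: tuple[int, int] = (64, 64),
    frames: bool | str = True,
    region_fraction: float = 0.5,
    wavelength_px: float = 40.0,
) -> tuple[list[CohortRecording], pd.DataFrame]:
    """Simulate a multi-group cohort of recordings with known per-recording CBF.

    Each recording's true CBF is drawn from its group's distribution; the
    recording is rendered by :func:`simulate_cilia_stack` with a centered
    ciliated rectangle covering ``region_fraction`` of the frame.  With
    ``frames=False`` only the ROI-mean trace is synthesized — enough for the
    manual-count path and orders of magnitude cheaper; with ``frames="lazy"``
    the recording carries its :class:`SimConfig` and renders on first use,
    so a large cohort never holds all frames in memory at once.

    A single study seed fans out to per-recording child seeds via
    ``numpy.random.SeedSequence.spawn``, so recordings are independently
    reproducible.

    Returns the recordings and a truth table ``(subject, group, recording,
    true_cbf_hz)``.
    """
    if not groups:
        raise ValueError("need at least one group")
    nyquist = fps / 2.0
    root = np.random.SeedSequence(seed)
    n_total = sum(g.n_subjects * g.recordings_per_subject for g in groups)
    children = root.spawn(n_total + 1)
    draw_rng = np.random.default_rng(children[0])

    h, w = frame_shape
    side_h = max(1, int(round(h * np.sqrt(region_fraction))))
    side_w = max(1, int(round(w * np.sqrt(region_fraction))))
    x0, y0 = (w - side_w) // 2, (h - side_h) // 2

    recordings: list[CohortRecording] = []
    rows = []
    k = 1
    for g in groups:
        if g.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for s in range(g.n_subjects):
            subject = f"{g.label}-S{s + 1:02d}"
            for r in range(g.recordings_per_subject):
                cbf = g.draw_cbf(draw_rng)
                if not 0 < cbf < nyquist:
                    raise ValueError(
                        f"drawn CBF {cbf:.2f} Hz outside (0, {nyquist}) — "
                        "distribution spec has support outside the Nyquist band"
                    )
                child_seed = int(children[k].generate_state(1)[0] % (2**31 - 1))
                k += 1
                rec_id = f"{subject}-R{r + 1:02d}"
                rec = CohortRecording(
                    subject=subject,
                    group=g.label,
                    recording=rec_id,
                    true_cbf_hz=cbf,
                    seed=child_seed,
                    fps=fps,
                )
                if frames:  # True or "lazy"
                    cfg = SimConfig(
                        fps=fps,
                        n_frames=n_frames,
                        height=h,
                        width=w,
                        regions=[
                            Region(
                                ("rect", x0, y0, side_w, side_h),
                                cbf_hz=cbf,
                                amplitude=g.amplitude,
                                wavelength_px=wavelength_px,
                            )
                        ],
                        noise_sigma=g.noise_sigma,
                        seed=child_seed,
                        quantize_output=False,
                    )
                    if frames == "lazy":
                        rec.sim_config = cfg
                    else:
                        rec.stack, _ = simulate_cilia_stack(cfg)
                else:
                    rng = np.random.default_rng(child_seed)
                    t = np.arange(n_frames) / fps
                    trace = 100.0 + g.amplitude * np.sin(2 * np.pi * cbf * t)
                    if g.noise_sigma > 0:
                        trace = trace + rng.normal(0, g.noise_sigma, size=n_frames)
                    rec.trace = trace
                recordings.append(rec)
                rows.append(
                    {
                        "subject": subject,
                        "group": g.label,
                        "recording": rec_id,
                        "true_cbf_hz": cbf,
                    }
                )
    truth = pd.DataFrame(rows, columns=["subject", "group", "recording", "true_cbf_hz"])
    return recordings, truth
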