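"""Reading and writing high-speed video image sequences.

Three on-disk dialects are supported, mirroring the interchange formats that
ciliary-analysis workflows actually touch:

* ``tiff`` — a single multipage TIFF stack (grayscale; 8/16-bit integer or
  32-bit float samples).
* ``png_seq`` — a directory of numbered PNG frames (``frame_000001.png`` ...),
  ordered by the numeric suffix regardless of directory listing order.
* ``raw`` — a headerless, frame-major, row-major, unsigned little-endian
  sample payload plus a plain-text ``key: value`` sidecar carrying the
  geometry and acquisition metadata the payload itself cannot express.

The in-memory currency is :class:`FrameStack`: an ordered ``(time, height,
width)`` intensity array with its acquisition frame rate attached.  Frame
rate is metadata the caller must supply for TIFF/PNG sources (high-speed
cameras rarely store it in portable tags); RAW sources carry it in the
sidecar.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile
from imageio.v3 import imread, imwrite

__all__ = [
    "FrameStack",
    "SidecarMeta",
    "read_sequence",
    "write_sequence",
    "SequenceIOError",
]

#: Rec. 601 luma weights used to collapse color inputs to grayscale.
_LUMA = np.array([0.299, 0.587, 0.114])

_DIALECTS = ("tiff", "png_seq", "raw")


class SequenceIOError(ValueError):
    """Raised for malformed sequences, metadata mismatches or unsupported dialects."""


@dataclass
class FrameStack:
    """An ordered grayscale image sequence with acquisition metadata.

    Parameters
    ----------
    frames
        ``(T, H, W)`` array of pixel intensities, ``T >= 2``.  Integer dtypes
        are preserved losslessly through I/O roundtrips; processing stages
        that produce signed or fractional intensities return float frames.
    fps
        Acquisition frame rate in Hz.  Sets the Nyquist limit ``fps/2`` and,
        together with the analyzed frame count ``N``, the spectral resolution
        ``fps/N``.
    bit_depth
        Quantization of the source samples in bits (8 or 16 for typical
        monochrome high-speed cameras).
    source_dialect
        Which on-disk dialect the stack came from, if any.
    """

    frames: np.ndarray
    fps: float
    bit_depth: int = 8
    source_dialect: str | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise SequenceIOError(
                f"frames must be (time, height, width), got shape {self.frames.shape}"
            )
        t, h, w = self.frames.shape
        if t < 2 or h < 1 or w < 1:
            raise SequenceIOError(f"need >= 2 frames of >= 1x1 px, got {self.frames.shape}")
        if not self.fps > 0:
            raise SequenceIOError(f"fps must be positive, got {self.fps}")
        if not np.all(np.isfinite(self.frames)):
            raise SequenceIOError("frames contain non-finite intensities")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    def with_frames(self, frames: np.ndarray) -> "FrameStack":
        """A copy of this stack carrying new pixel data, same metadata."""
        return replace(self, frames=frames)


@dataclass
class SidecarMeta:
    """Geometry + acquisition metadata for a headerless RAW payload."""

    width: int
    height: int
    bit_depth: int
    fps: float
    frame_count: int

    def __post_init__(self) -> None:
        for name in ("width", "height", "bit_depth", "frame_count"):
            v = getattr(self, name)
            if int(v) != v or v <= 0:
                raise SequenceIOError(f"sidecar field {name} must be a positive integer, got {v}")
            setattr(self, name, int(v))
        if not self.fps > 0:
            raise SequenceIOError(f"sidecar fps must be positive, got {self.fps}")

    @property
    def dtype(self) -> np.dtype:
        if self.bit_depth <= 8:
            return np.dtype("<u1")
        if self.bit_depth <= 16:
            return np.dtype("<u2")
        raise SequenceIOError(f"unsupported RAW bit depth {self.bit_depth}")

    def to_text(self) -> str:
        return (
            f"width: {self.width}\nheight: {self.height}\nbit_depth: {self.bit_depth}\n"
            f"fps: {self.fps}\nframe_count: {self.frame_count}\n"
        )

    @classmethod
    def from_text(cls, text: str) -> "SidecarMeta":
        fields: dict[str, float] = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition(":")
            fields[key.strip()] = float(value)
        try:
            return cls(
                width=int(fields["width"]),
                height=int(fields["height"]),
                bit_depth=int(fields["bit_depth"]),
                fps=fields["fps"],
                frame_count=int(fields["frame_count"]),
            )
        except KeyError as exc:  # pragma: no cover - message detail only
            raise SequenceIOError(f"sidecar missing field {exc}") from exc


def _to_gray(frame: np.ndarray) -> np.ndarray:
    """Collapse an (H, W[, C]) frame to grayscale with Rec. 601 luma weights."""
    if frame.ndim == 2:
        return frame
    if frame.ndim == 3 and frame.shape[-1] in (3, 4):
        return frame[..., :3].astype(float) @ _LUMA
    raise SequenceIOError(f"cannot interpret frame of shape {frame.shape} as an image")


def _infer_dialect(path: Path) -> str:
    if path.is_dir():
        return "png_seq"
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        return "tiff"
    if suffix == ".raw":
        return "raw"
    raise SequenceIOError(f"cannot infer sequence dialect from {path}")


def _png_frame_paths(directory: Path) -> list[Path]:
    """PNG frames ordered by the numeric suffix in their file name."""
    entries = []
    for p in directory.iterdir():
        if p.suffix.lower() != ".png":
            continue
        m = re.search(r"(\d+)(?=\.png$)", p.name, flags=re.IGNORECASE)
        if m is None:
            raise SequenceIOError(f"PNG frame {p.name} has no numeric suffix")
        entries.append((int(m.group(1)), p))
    if not entries:
        raise SequenceIOError(f"no PNG frames found in {directory}")
    entries.sort(key=lambda e: e[0])
    return [p for _, p in entries]


def read_sequence(
    path: str | Path,
    dialect: str | None = None,
    *,
    fps: float | None = None,
    meta: SidecarMeta | None = None,
    bit_depth: int | None = None,
) -> FrameStack:
    """Load an image sequence from disk into a :class:`FrameStack`.

    Parameters
    ----------
    path
        TIFF file, PNG-sequence directory, or ``.raw`` payload.
    dialect
        One of ``tiff``, ``png_seq``, ``raw``; inferred from ``path`` when
        omitted.
    fps
        Frame rate for TIFF/PNG sources (required there; the RAW sidecar
        overrides it).
    meta
        Sidecar metadata for RAW payloads; when omitted, a ``.meta`` file
        adjacent to the payload is read.
    bit_depth
        Override the inferred source quantization (TIFF/PNG only).

    Grayscale sources roundtrip bit-for-bit; color inputs are collapsed with
    Rec. 601 luma weights.
    """
    path = Path(path)
    if not path.exists():
        raise SequenceIOError(f"no such sequence: {path}")
    if dialect is None:
        dialect = _infer_dialect(path)
    if dialect not in _DIALECTS:
        raise SequenceIOError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")

    if dialect == "raw":
        if meta is None:
            sidecar = path.with_suffix(".meta")
            if not sidecar.exists():
                raise SequenceIOError(f"RAW payload {path} has no sidecar {sidecar.name}")
            meta = SidecarMeta.from_text(sidecar.read_text())
        payload = np.fromfile(path, dtype=meta.dtype)
        expected = meta.frame_count * meta.height * meta.width
        if payload.size != expected:
            raise SequenceIOError(
                "payload/metadata mismatch: "
                f"{payload.size} samples on disk vs {expected} expected from sidecar"
            )
        frames = payload.reshape(meta.frame_count, meta.height, meta.width)
        return FrameStack(frames, fps=meta.fps, bit_depth=meta.bit_depth, source_dialect="raw")

    if fps is None:
        raise SequenceIOError(f"fps must be supplied for {dialect} sources")

    if dialect == "tiff":
        frames = tifffile.imread(path)
        if frames.ndim == 2:
            frames = frames[None]
        if frames.ndim == 4:  # color pages
            frames = np.stack([_to_gray(f) for f in frames])
    else:  # png_seq
        loaded = [_to_gray(np.asarray(imread(p))) for p in _png_frame_paths(path)]
        shapes = {f.shape for f in loaded}
        if len(shapes) != 1:
            raise SequenceIOError(f"inconsistent frame shapes across PNG sequence: {shapes}")
        frames = np.stack(loaded)

    if bit_depth is None:
        bit_depth = frames.dtype.itemsize * 8 if frames.dtype.kind in "ui" else 32
    return FrameStack(frames, fps=fps, bit_depth=bit_depth, source_dialect=dialect)


def write_sequence(stack: FrameStack, path: str | Path, dialect: str | None = None) -> Path:
    """Write a :class:`FrameStack` to disk; ``read_sequence`` inverts it bit-exactly
    for integer stacks (and for float stacks stored as 32-bit float TIFF).

    RAW writes emit the ``.meta`` sidecar next to the payload.  Integer writes
    are checked against the declared ``bit_depth``.
    """
    path = Path(path)
    if dialect is None:
        dialect = _infer_dialect(path) if (path.suffix or path.is_dir()) else "png_seq"
    if dialect not in _DIALECTS:
        raise SequenceIOError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")

    frames = stack.frames
    integer = frames.dtype.kind in "ui"
    if integer:
        limit = 2**stack.bit_depth - 1
        if frames.max(initial=0) > limit or frames.min(initial=0) < 0:
            raise SequenceIOError(
                f"intensities outside [0, {limit}] exceed declared bit depth {stack.bit_depth}"
            )

    if dialect == "tiff":
        out = frames if integer else frames.astype(np.float32)
        tifffile.imwrite(path, out)
        return path

    if dialect == "raw":
        if not integer:
            raise SequenceIOError("RAW dialect stores unsigned integers; quantize first")
        meta = SidecarMeta(
            width=frames.shape[2],
            height=frames.shape[1],
            bit_depth=stack.bit_depth,
            fps=stack.fps,
            frame_count=frames.shape[0],
        )
        frames.astype(meta.dtype).tofile(path)
        path.with_suffix(".meta").write_text(meta.to_text())
        return path

    # png_seq
    if not integer:
        raise SequenceIOError("PNG dialect stores integers; quantize first")
    path.mkdir(parents=True, exist_ok=True)
    dtype = np.uint8 if stack.bit_depth <= 8 else np.uint16
    for i, frame in enumerate(frames):
        imwrite(path / f"frame_{i + 1:06d}.png", frame.astype(dtype))
    return path
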