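"""ROI color-dynamics extraction from movie frame stacks.

A chromatophore actuation movie is analyzed by fixing a small region of
interest (the study uses a 20 × 20 pixel square) and averaging each RGB
channel over the ROI in every frame (0.03 s per frame), yielding a
per-channel time series that traces the color sweep of the expanding or
relaxing organ.  Means are computed in float with no rounding; channel
order is fixed R, G, B regardless of file byte order; no background
subtraction or white balance is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_FRAME_INTERVAL_S = 0.03
DEFAULT_ROI_SIZE = 20


@dataclass(frozen=True)
class FrameStack:
    """T frames of H×W×3 channel intensities in [0, 255]."""

    frames: np.ndarray  # (T, H, W, 3) float
    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S

    def __post_init__(self) -> None:
        arr = np.asarray(self.frames, dtype=float)
        if arr.ndim != 4 or arr.shape[-1] != 3:
            raise ValueError("frames must have shape (T, H, W, 3)")
        if arr.shape[0] < 1:
            raise ValueError("frame stack must contain at least one frame")
        if self.frame_interval_s <= 0:
            raise ValueError("frame interval must be positive")
        object.__setattr__(self, "frames", arr)

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.frames.shape

    @classmethod
    def from_files(
        cls,
        directory: str | Path,
        frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S,
        rescale_16bit: bool = True,
    ) -> "FrameStack":
        """Load a lexicographically ordered PNG/TIFF frame sequence.

        16-bit inputs are rescaled to the 0–255 range when
        ``rescale_16bit`` is set; multi-page TIFFs expand into frames.
        """
        import imageio.v3 as iio

        paths = sorted(
            p
            for p in Path(directory).iterdir()
            if p.suffix.lower() in (".png", ".tif", ".tiff")
        )
        if not paths:
            raise FileNotFoundError(f"no PNG/TIFF frames in {directory}")
        frames = []
        for p in paths:
            img = np.asarray(iio.imread(p))
            if img.ndim == 4:  # multi-page
                frames.extend(img)
            else:
                frames.append(img)
        arr = np.stack([_normalize_frame(f, rescale_16bit) for f in frames])
        return cls(frames=arr, frame_interval_s=frame_interval_s)


def _normalize_frame(img: np.ndarray, rescale_16bit: bool) -> np.ndarray:
    if img.ndim == 2:
        img = np.repeat(img[..., None], 3, axis=-1)
    if img.shape[-1] == 4:  # drop alpha
        img = img[..., :3]
    img = img.astype(float)
    if rescale_16bit and img.max() > 255:
        img = img * (255.0 / 65535.0)
    return img


@dataclass(frozen=True)
class ROI:
    """A fixed pixel window: top-left (row, col) plus height and width."""

    row: int
    col: int
    height: int = DEFAULT_ROI_SIZE
    width: int = DEFAULT_ROI_SIZE

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("ROI height and width must be >= 1")
        if self.row < 0 or self.col < 0:
            raise ValueError("ROI origin must be non-negative")

    def check_bounds(self, frame_shape: tuple[int, int]) -> None:
        h, w = frame_shape
        if self.row + self.height > h or self.col + self.width > w:
            raise ValueError(
                f"ROI rows {self.row}:{self.row + self.height}, cols "
                f"{self.col}:{self.col + self.width} exceed frame {h}×{w}"
            )

    def slices(self) -> tuple[slice, slice]:
        return (
            slice(self.row, self.row + self.height),
            slice(self.col, self.col + self.width),
        )


@dataclass(frozen=True)
class ROITrace:
    """Per-frame mean R, G, B over the ROI, with a time axis in seconds."""

    time_s: np.ndarray
    r: np.ndarray
    g: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        n = self.time_s.size
        for name in ("r", "g", "b"):
            ch = getattr(self, name)
            if ch.size != n:
                raise ValueError("trace channels must match the time axis")

    def __len__(self) -> int:
        return self.time_s.size

    def as_array(self) -> np.ndarray:
        """Channels as a (T, 3) array in R, G, B order."""
        return np.stack([self.r, self.g, self.b], axis=-1)


def roi_mean_rgb(stack: FrameStack, roi: ROI) -> ROITrace:
    """Average each channel over the ROI in every frame.

    Time for frame ``t`` is ``t × frame_interval``.
    """
    roi.check_bounds(stack.frames.shape[1:3])
    rs, cs = roi.slices()
    means = stack.frames[:, rs, cs, :].mean(axis=(1, 2))
    t = np.arange(stack.frames.shape[0]) * stack.frame_interval_s
    return ROITrace(time_s=t, r=means[:, 0], g=means[:, 1], b=means[:, 2])


def dominant_channel_timeline(trace: ROITrace) -> list[str]:
    """Per-frame argmax channel label; ties resolve R > G > B."""
    if len(trace) == 0:
        raise ValueError("empty trace")
    arr = trace.as_array()
    labels = []
    names = ["R", "G", "B"]
    for row in arr:
        i = int(np.argmax(row))  # argmax returns the first max: R > G > B
        if np.sum(row == row.max()) > 1:
            logger.debug("channel tie at %s resolved to %s", row, names[i])
        labels.append(names[i])
    return labels


def trace_from_synthetic_movie(config, roi: ROI | None = None) -> ROITrace:
    """Render a synthetic expanding-disc movie and extract its ROI trace.

    End-to-end harness composing :func:`chromatophore.synthetic.make_movie`
    with :func:`roi_mean_rgb`; deterministic for a fixed config seed.
    """
    from chromatophore.synthetic import make_movie

    stack, _truth = make_movie(config)
    if roi is None:
        h, w = stack.frames.shape[1:3]
        size = min(DEFAULT_ROI_SIZE, h, w)
        roi = ROI(row=(h - size) // 2, col=(w - size) // 2, height=size, width=size)
    return roi_mean_rgb(stack, roi)
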