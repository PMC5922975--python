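"""Video container and file I/O.

The unit of storage is a :class:`VideoClip`: an ordered stack of grayscale
frames with a frame rate.  Multi-page TIFF is the primary (lossless) on-disk
format; AVI is supported where an imageio video backend is available, in
which case only the frame count (not pixel equality) is guaranteed across a
round trip.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile


class VideoReadError(RuntimeError):
    """Raised when a video file is missing, empty, or unreadable."""


@dataclass
class VideoClip:
    """Ordered grayscale frames plus acquisition metadata.

    frames : (T, H, W) uint8 array
    frame_rate_hz : nominal acquisition rate
    provenance : free-form origin record (generator spec, source path, ...)
    """

    frames: np.ndarray
    frame_rate_hz: float = 5.0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) stack")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def window(self, start: int, length: int) -> "VideoClip":
        """Contiguous sub-clip of ``length`` frames starting at ``start``."""
        if start + length > self.n_frames:
            raise ValueError("window extends past end of clip")
        return VideoClip(
            self.frames[start : start + length],
            self.frame_rate_hz,
            {**self.provenance, "window_start": start},
        )


def write_video(clip: VideoClip, path: str | Path) -> None:
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, clip.frames.astype(np.uint8))
    elif suffix == ".avi":
        import imageio.v2 as imageio

        try:
            writer = imageio.get_writer(path, fps=clip.frame_rate_hz)
        except Exception as exc:  # no video backend in this install
            raise VideoReadError(f"no AVI backend available: {exc}") from exc
        with writer:
            for frame in clip.frames:
                writer.append_data(frame.astype(np.uint8))
    else:
        raise ValueError(f"unsupported video format: {suffix!r}")


def read_video(path: str | Path, frame_rate_hz: float = 5.0) -> VideoClip:
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise VideoReadError(f"missing or empty video file: {path}")
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        try:
            frames = tifffile.imread(path)
        except Exception as exc:
            raise VideoReadError(f"unreadable TIFF: {path}: {exc}") from exc
        frames = np.asarray(frames)
        if frames.ndim == 2:
            frames = frames[None]
    elif suffix == ".avi":
        import imageio.v2 as imageio

        try:
            raw = imageio.mimread(path, memtest=False)
        except Exception as exc:
            raise VideoReadError(f"unreadable AVI: {path}: {exc}") from exc
        if not raw:
            raise VideoReadError(f"no frames in {path}")
        frames = np.stack([f[..., 0] if f.ndim == 3 else f for f in raw])
    else:
        raise ValueError(f"unsupported video format: {suffix!r}")
    if frames.shape[0] == 0:
        raise VideoReadError(f"no frames in {path}")
    return VideoClip(frames, frame_rate_hz, {"source": str(path)})
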