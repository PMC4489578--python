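"""Video input/output and the VideoVolume container.

All downstream stages operate on a ``VideoVolume``: a T x H x W stack of
grayscale intensities in [0, 1].  Frame rate is carried as metadata only;
every model parameter with a temporal unit is expressed in frames.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = ["VideoVolume", "load_sequence", "save_sequence", "clip_subsequence"]

_FRAME_EXTS = (".png", ".pgm", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff")

# Rec.601 luma weights
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class VideoVolume:
    """A grayscale image sequence I(x, t).

    Parameters
    ----------
    frames : ndarray, shape (T, H, W)
        Intensities in [0, 1], float.
    frame_rate : float, optional
        Frames per second; metadata only.
    id : str
        Free-form label (subject/action/condition) used by evaluation
        protocols to split data without leaking a subject across folds.
    """

    frames: np.ndarray
    frame_rate: float = 25.0
    id: str = ""

    def __post_init__(self) -> None:
        f = np.asarray(self.frames, dtype=np.float32)
        if f.ndim != 3:
            raise ValueError(f"frames must be T x H x W, got shape {f.shape}")
        if f.shape[0] < 2:
            raise ValueError("a video needs at least 2 frames")
        if float(f.min()) < -1e-6 or float(f.max()) > 1 + 1e-6:
            raise ValueError("intensities must lie in [0, 1]")
        self.frames = np.clip(f, 0.0, 1.0)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape  # type: ignore[return-value]

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def _to_gray(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim == 3:
        img = img[..., :3] @ _LUMA
    if np.issubdtype(img.dtype, np.integer):
        info = np.iinfo(img.dtype)
        img = img.astype(np.float32) / info.max
    return img.astype(np.float32)


def load_sequence(path: str | os.PathLike, as_gray: bool = True,
                  frame_rate: float = 25.0, id: str | None = None) -> VideoVolume:
    """Read a frame directory (or a video container) into a VideoVolume.

    A directory is read as lexicographically sorted image frames; any other
    path is handed to imageio's video reader.  Color input is converted to
    Rec.601 luminance and rescaled to [0, 1].
    """
    import imageio.v3 as iio

    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(str(p))
    if p.is_dir():
        files = sorted(f for f in p.iterdir() if f.suffix.lower() in _FRAME_EXTS)
        if not files:
            raise ValueError(f"no readable frames in {p}")
        frames = [_to_gray(iio.imread(f)) for f in files]
    else:
        frames = [_to_gray(fr) for fr in iio.imiter(p)]
        if not frames:
            raise ValueError(f"no readable frames in {p}")
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent frame sizes: {sorted(shapes)}")
    if not as_gray:
        raise NotImplementedError("only grayscale processing is supported")
    return VideoVolume(np.stack(frames), frame_rate=frame_rate, id=id or p.stem)


def save_sequence(video: VideoVolume, directory: str | os.PathLike,
                  fmt: str = "png") -> list[Path]:
    """Write a VideoVolume as 8-bit frames ``frame_0000.png`` ..."""
    import imageio.v3 as iio

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = []
    u8 = np.round(video.frames * 255).astype(np.uint8)
    for t in range(video.n_frames):
        fp = d / f"frame_{t:04d}.{fmt}"
        iio.imwrite(fp, u8[t])
        paths.append(fp)
    return paths


def clip_subsequence(video: VideoVolume, start: int, t_max: int) -> VideoVolume:
    """Contiguous t_max-frame window starting at ``start``; metadata kept."""
    if start < 0 or t_max < 2 or start + t_max > video.n_frames:
        raise ValueError(
            f"window [{start}, {start + t_max}) out of range for T={video.n_frames}")
    return replace(video, frames=video.frames[start:start + t_max])
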