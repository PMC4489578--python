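"""Field of attention (FA): adaptive square window with smooth pursuit.

The FA is a square of side L centered on the tracked object's mask.  At
initialization L is the mask's larger bounding-box side plus a margin
n1*r.  Afterwards L changes only in quanta of n2*r (when the box has
grown or shrunk by at least that much since the last update) and the
center jumps to the mask centroid only when it has drifted by at least
n3*r — smooth pursuit with a dead zone.  The constraint n2 + n3 < n1
keeps the mask inside the window between updates.  The tracked window is
finally cropped and resampled to a canonical square frame.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from skimage.transform import resize

from .video import VideoVolume

__all__ = ["AttentionField", "BoxObs", "init_field", "update_field",
           "track", "crop_resize", "largest_region_box"]

CANONICAL_SIDE = 120


@dataclass
class BoxObs:
    """One frame's mask observation: bounding box sides and centroid."""

    lx: float
    ly: float
    cx: float
    cy: float

    @property
    def side(self) -> float:
        return max(self.lx, self.ly)


@dataclass
class AttentionField:
    """Square attention window state.

    r is the granularity constant (pixels); n1, n2, n3 the margin, size
    and pursuit factors (defaults 7, 2, 2 with n2 + n3 < n1).
    """

    L: float
    xc: tuple[float, float]          # (cx, cy)
    t0: int = 0
    side0: float = 0.0               # bbox side at the last size update
    r: float = 4.0
    n1: int = 7
    n2: int = 2
    n3: int = 2
    canonical: int = CANONICAL_SIDE

    def __post_init__(self) -> None:
        if not self.n2 + self.n3 < self.n1:
            raise ValueError("require n2 + n3 < n1")


def largest_region_box(regions: list[np.ndarray]) -> BoxObs | None:
    """Bounding box + centroid of the largest region mask (None if empty)."""
    best = None
    for reg in regions:
        area = int(reg.sum())
        if area and (best is None or area > best[0]):
            best = (area, reg)
    if best is None:
        return None
    ys, xs = np.nonzero(best[1])
    return BoxObs(lx=float(xs.max() - xs.min() + 1),
                  ly=float(ys.max() - ys.min() + 1),
                  cx=float(xs.mean()), cy=float(ys.mean()))


def init_field(obs: BoxObs, r: float = 4.0, n1: int = 7, n2: int = 2,
               n3: int = 2, t: int = 0,
               canonical: int = CANONICAL_SIDE) -> AttentionField:
    """L = max(lx, ly) + n1*r, centered on the mask centroid."""
    return AttentionField(L=obs.side + n1 * r, xc=(obs.cx, obs.cy), t0=t,
                          side0=obs.side, r=r, n1=n1, n2=n2, n3=n3,
                          canonical=canonical)


def update_field(f: AttentionField, obs: BoxObs, t: int) -> AttentionField:
    """One tracking step.

    Size: L grows/shrinks by floor(d/(n2*r)) quanta of n2*r, where d is
    the bbox-side change since the last size update.  Center: jumps to
    the mask centroid when the drift reaches n3*r, else holds.
    """
    quantum = f.n2 * f.r
    steps = math.floor((obs.side - f.side0) / quantum)
    L, side0 = f.L, f.side0
    updated = False
    if steps != 0:
        L = f.L + steps * quantum
        side0 = f.side0 + steps * quantum
        updated = True
    drift = math.hypot(obs.cx - f.xc[0], obs.cy - f.xc[1])
    xc = f.xc
    if drift >= f.n3 * f.r:
        xc = (obs.cx, obs.cy)
        updated = True
    return replace(f, L=L, side0=side0, xc=xc, t0=t if updated else f.t0)


def track(observations: list[BoxObs | None], r: float = 4.0, n1: int = 7,
          n2: int = 2, n3: int = 2,
          canonical: int = CANONICAL_SIDE) -> list[AttentionField]:
    """Run the tracker over per-frame observations (None = no detection).

    Before the first detection, and on detection dropouts, the previous
    field is held; the trace always has one field per frame.
    """
    fields: list[AttentionField] = []
    f: AttentionField | None = None
    for t, obs in enumerate(observations):
        if obs is not None:
            f = init_field(obs, r, n1, n2, n3, t, canonical) if f is None \
                else update_field(f, obs, t)
        if f is not None:
            fields.append(f)
        else:
            fields.append(None)  # type: ignore[arg-type]
    # backfill frames before the first detection with the first field
    first = next((g for g in fields if g is not None), None)
    if first is None:
        raise ValueError("no detection in any frame; field undefined")
    return [g if g is not None else first for g in fields]


def crop_resize(video: VideoVolume, trace: list[AttentionField]) -> VideoVolume:
    """Per-frame L x L crop at the field center, bilinear-resampled to the
    canonical square.  Windows exiting the frame are clamped with edge
    padding."""
    if len(trace) != video.n_frames:
        raise ValueError("field trace must cover every frame")
    T, H, W = video.shape
    side = trace[0].canonical
    out = np.empty((T, side, side), dtype=np.float32)
    clipped = False
    for t, f in enumerate(trace):
        L = max(int(round(f.L)), 2)
        x0 = int(round(f.xc[0] - L / 2))
        y0 = int(round(f.xc[1] - L / 2))
        px0, py0 = max(0, -x0), max(0, -y0)
        px1, py1 = max(0, x0 + L - W), max(0, y0 + L - H)
        clipped |= bool(px0 or py0 or px1 or py1)
        patch = video.frames[t, max(y0, 0):y0 + L, max(x0, 0):x0 + L]
        if px0 or py0 or px1 or py1:
            patch = np.pad(patch, ((py0, py1), (px0, px1)), mode="edge")
        if patch.shape == (side, side):
            out[t] = patch
        else:
            out[t] = resize(patch, (side, side), order=1, anti_aliasing=L > side,
                            preserve_range=True)
    if clipped:
        warnings.warn("attention window exited the frame; edge-padded")
    return VideoVolume(np.clip(out, 0, 1), frame_rate=video.frame_rate,
                       id=video.id + "_fa")
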