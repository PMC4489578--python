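"""Synthetic video generator with ground truth.

Produces toy action scenes — a moving figure of controllable speed,
direction and periodicity over a static (optionally textured) background
with optional static high-contrast distractors — plus per-frame truth
masks and class labels, all reproducible from a seed.  This is the test
bed standing in for real benchmark footage: single actor, static camera,
grayscale.

Shapes are rendered with area sampling (4x supersampling, box average)
so sub-pixel positions and speeds are meaningful.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .video import VideoVolume

__all__ = [
    "ActorSpec", "SceneSpec", "generate", "drifting_grating",
    "translating_bar", "action_library",
]

_SS = 4  # supersampling factor


@dataclass
class ActorSpec:
    """One figure in the scene.

    shape: 'dot' | 'square' | 'bar' | 'limb' (two-bar hinged oscillator)
    motion: 'static' | 'translate' (bounces off frame walls) | 'oscillate'
    speed: pixels per frame (translation) ; for 'oscillate' the limb/bar
        swings with the given period instead.
    """

    shape: str = "square"
    size: float = 10.0
    x: float = 0.0            # initial center, (x=column, y=row)
    y: float = 0.0
    motion: str = "translate"
    speed: float = 2.0
    direction: float = 0.0    # radians; x increases rightward, y downward
    period: float = 16.0      # frames, oscillatory motions
    swing: float = math.pi / 4  # limb swing amplitude, radians
    intensity: float = 1.0
    bar_aspect: float = 0.25  # width/length for bars


@dataclass
class SceneSpec:
    """Scene geometry + photometry; deterministic given ``seed``."""

    height: int = 64
    width: int = 64
    n_frames: int = 40
    actors: list[ActorSpec] = field(default_factory=list)
    distractors: list[ActorSpec] = field(default_factory=list)
    background: str = "blank"      # 'blank' | 'texture' | 'grating'
    bg_level: float = 0.5
    bg_contrast: float = 0.15      # texture std / grating contrast
    bg_corr_len: float = 2.0       # texture spatial correlation, px
    bg_speed: float = 1.5          # grating drift (ppF); coherent clutter
    bg_lambda: float = 9.0         # grating wavelength, px
    noise_sigma: float = 0.0       # additive per-frame Gaussian noise
    seed: int = 0
    label: str = ""


def _coverage(shape: str, size: float, cx: float, cy: float, ang: float,
              H: int, W: int, bar_aspect: float = 0.25,
              limb_phase: float = 0.0, swing: float = math.pi / 4) -> np.ndarray:
    """Area-sampled occupancy of one shape on an H x W grid, values in [0,1]."""
    n = _SS
    ys = (np.arange(H * n) + 0.5) / n
    xs = (np.arange(W * n) + 0.5) / n
    X, Y = np.meshgrid(xs, ys)
    dx, dy = X - cx, Y - cy
    if shape == "dot":
        m = dx * dx + dy * dy <= (size / 2) ** 2
    elif shape == "square":
        h = size / 2
        m = (np.abs(dx) <= h) & (np.abs(dy) <= h)
    elif shape == "bar":
        c, s = math.cos(ang), math.sin(ang)
        u = c * dx + s * dy
        v = -s * dx + c * dy
        m = (np.abs(u) <= size / 2) & (np.abs(v) <= size * bar_aspect / 2)
    elif shape == "limb":
        # two bars hinged at (cx, cy), swinging in antiphase
        m = np.zeros_like(dx, dtype=bool)
        for sgn in (1.0, -1.0):
            a = ang + sgn * swing * math.sin(limb_phase)
            c, s = math.cos(a), math.sin(a)
            u = c * dx + s * dy
            v = -s * dx + c * dy
            m |= (u >= 0) & (u <= size) & (np.abs(v) <= size * bar_aspect / 2)
    else:
        raise ValueError(f"unknown shape {shape!r}")
    return m.astype(np.float32).reshape(H, n, W, n).mean(axis=(1, 3))


def _trajectory(a: ActorSpec, T: int, H: int, W: int) -> np.ndarray:
    """Per-frame (cx, cy); translation reflects off frame walls."""
    pos = np.zeros((T, 2))
    if a.motion == "static" or a.motion == "oscillate":
        pos[:] = (a.x, a.y)
        return pos
    if a.motion != "translate":
        raise ValueError(f"unknown motion {a.motion!r}")
    vx = a.speed * math.cos(a.direction)
    vy = a.speed * math.sin(a.direction)
    margin = a.size / 2 + 1
    x, y = a.x, a.y
    for t in range(T):
        pos[t] = (x, y)
        x += vx
        y += vy
        if x < margin or x > W - margin:
            vx = -vx
            x = min(max(x, margin), W - margin)
        if y < margin or y > H - margin:
            vy = -vy
            y = min(max(y, margin), H - margin)
    return pos


def generate(spec: SceneSpec) -> tuple[VideoVolume, np.ndarray, str]:
    """Render a scene.

    Returns
    -------
    video : VideoVolume
    masks : bool ndarray (T, H, W) — union of actor supports per frame
    label : str — the scene's class label
    """
    H, W, T = spec.height, spec.width, spec.n_frames
    rng = np.random.default_rng(spec.seed)
    if spec.background == "texture":
        bg = gaussian_filter(rng.standard_normal((H, W)), spec.bg_corr_len)
        bg = spec.bg_level + spec.bg_contrast * bg / max(bg.std(), 1e-9)
        bg = np.clip(bg, 0.0, 1.0).astype(np.float32)
        frames = np.repeat(bg[None], T, axis=0)
    elif spec.background == "blank":
        frames = np.full((T, H, W), spec.bg_level, dtype=np.float32)
    elif spec.background == "grating":
        # full-field coherent drift: the stimulus surround suppression
        # exists to reject; direction seeded per scene
        theta = float(rng.uniform(0, 2 * math.pi))
        frames = drifting_grating((T, H, W), spec.bg_speed, theta,
                                  spec.bg_lambda, spec.bg_contrast).frames.copy()
    else:
        raise ValueError(f"unknown background {spec.background!r}")
    masks = np.zeros((T, H, W), dtype=bool)

    for d in spec.distractors:
        cov = _coverage(d.shape, d.size, d.x, d.y, d.direction, H, W,
                        d.bar_aspect)
        frames = frames * (1 - cov) + d.intensity * cov

    for a in spec.actors:
        pos = _trajectory(a, T, H, W)
        for t in range(T):
            phase = 2 * math.pi * t / a.period if a.motion == "oscillate" else 0.0
            cov = _coverage(a.shape, a.size, pos[t, 0], pos[t, 1], a.direction,
                            H, W, a.bar_aspect, limb_phase=phase, swing=a.swing)
            frames[t] = frames[t] * (1 - cov) + a.intensity * cov
            masks[t] |= cov > 0.5

    if spec.noise_sigma > 0:
        frames = frames + rng.normal(0, spec.noise_sigma, frames.shape)
    frames = np.clip(frames, 0.0, 1.0).astype(np.float32)
    return VideoVolume(frames, id=spec.label or "scene"), masks, spec.label


def drifting_grating(size: tuple[int, int, int], v: float, theta: float,
                     lam: float, contrast: float = 1.0) -> VideoVolume:
    """Full-field sinusoidal grating drifting at velocity v along theta.

    I(x, t) = 0.5 + 0.5*contrast*cos(2*pi/lam * (x_par - v*t)) where x_par is
    the coordinate along theta, so the pattern shifts by v px per frame in
    the +theta direction.
    """
    if not 0.0 <= contrast <= 1.0:
        raise ValueError("contrast must be in [0, 1]")
    if lam <= 1:
        raise ValueError("wavelength must exceed 1 px")
    T, H, W = size
    y, x = np.mgrid[0:H, 0:W].astype(np.float32)
    xpar = x * math.cos(theta) + y * math.sin(theta)
    t = np.arange(T, dtype=np.float32)[:, None, None]
    frames = 0.5 + 0.5 * contrast * np.cos(
        2 * math.pi / lam * (xpar[None] - v * t))
    return VideoVolume(frames.astype(np.float32), id=f"grating_v{v}_th{theta:.2f}")


def translating_bar(size: tuple[int, int, int], v: float, theta: float,
                    length: float = 12.0, width: float = 3.0,
                    contrast: float = 1.0, bg: float = 0.5,
                    start: tuple[float, float] | None = None) -> tuple[VideoVolume, np.ndarray]:
    """A single bright bar (perpendicular to its motion) translating at
    velocity v along theta on a blank background; returns video + masks."""
    T, H, W = size
    if start is None:
        cx0 = W / 2 - v * math.cos(theta) * T / 2
        cy0 = H / 2 - v * math.sin(theta) * T / 2
    else:
        cx0, cy0 = start
    frames = np.full((T, H, W), bg, dtype=np.float32)
    masks = np.zeros((T, H, W), dtype=bool)
    inten = np.clip(bg + contrast * 0.5, 0, 1)
    for t in range(T):
        cx = cx0 + v * math.cos(theta) * t
        cy = cy0 + v * math.sin(theta) * t
        cov = _coverage("bar", length, cx, cy, theta + math.pi / 2, H, W,
                        bar_aspect=width / length)
        frames[t] = frames[t] * (1 - cov) + inten * cov
        masks[t] = cov > 0.5
    return VideoVolume(frames, id=f"bar_v{v}_th{theta:.2f}"), masks


def attention_benchmark_scene(seed: int) -> tuple[VideoVolume, np.ndarray, np.ndarray]:
    """Standard moving-object-detection scene with ground truth.

    One bright 40 px square translating at 2 ppF through the lower half of
    a 120 x 120 textured field, with two static high-contrast distractor
    squares (one bright, one dark) in the upper band.  Motion direction is
    drawn from the filter bank's represented directions (rightward or
    downward; the 4-orientation bank covers half the direction circle).
    Actor size is large relative to the receptive-field blur (sigma of the
    fast channel is about 7 px) so localization measures attention rather
    than filter resolution; the path stays inside the frame.

    Returns (video, per-frame actor truth masks, static distractor mask).
    """
    rng = np.random.default_rng(seed)
    H = W = 120
    T = 22
    d1 = ActorSpec(shape="square", size=16, x=float(rng.uniform(20, 32)),
                   y=float(rng.uniform(18, 28)), motion="static", intensity=1.0)
    d2 = ActorSpec(shape="square", size=16, x=float(rng.uniform(80, 92)),
                   y=float(rng.uniform(18, 28)), motion="static", intensity=0.0)
    direction = float(rng.choice([0.0, math.pi / 2]))
    if direction == 0.0:
        ax = W / 2 - 16 + float(rng.uniform(-6, 6))
        ay = 84 + float(rng.uniform(-4, 4))
    else:
        ax = W / 2 + float(rng.uniform(-12, 12))
        ay = 50 + float(rng.uniform(-4, 4))
    actor = ActorSpec(shape="square", size=40, x=ax, y=ay, motion="translate",
                      speed=2.0, direction=direction, intensity=1.0)
    spec = SceneSpec(height=H, width=W, n_frames=T, actors=[actor],
                     distractors=[d1, d2], background="texture",
                     bg_contrast=0.1, noise_sigma=0.005, seed=seed,
                     label="benchmark")
    video, truth, _ = generate(spec)
    dmask = (_coverage("square", 16, d1.x, d1.y, 0.0, H, W) > 0.5) \
        | (_coverage("square", 16, d2.x, d2.y, 0.0, H, W) > 0.5)
    return video, truth, dmask


# ---------------------------------------------------------------------------
# toy action library

_CLASSES = ("translate_slow", "translate_fast", "oscillate")


def action_library(n_per_class: int = 10, size: tuple[int, int, int] = (70, 64, 64),
                   background: str = "blank", noise_sigma: float = 0.01,
                   seed: int = 0) -> list[tuple[VideoVolume, np.ndarray, str]]:
    """A labeled library of toy 'actions': slow translation (1 ppF), fast
    translation (3 ppF) and an in-place two-limb oscillation.

    Each instance gets its own seed-derived geometry (start position,
    heading, oscillation period jitter) and acts as its own 'subject' for
    leave-one-out protocols.  Returns (video, truth masks, label) triples.
    """
    T, H, W = size
    out = []
    rng = np.random.default_rng(seed)
    for label in _CLASSES:
        for i in range(n_per_class):
            inst = int(rng.integers(0, 2**31 - 1))
            r = np.random.default_rng(inst)
            direction = float(r.choice([0, math.pi / 4, math.pi / 2,
                                        3 * math.pi / 4]))
            x = float(r.uniform(0.35, 0.65) * W)
            y = float(r.uniform(0.35, 0.65) * H)
            if label == "translate_slow":
                actor = ActorSpec(shape="square", size=10, x=x, y=y,
                                  motion="translate", speed=1.0,
                                  direction=direction, intensity=1.0)
            elif label == "translate_fast":
                actor = ActorSpec(shape="square", size=10, x=x, y=y,
                                  motion="translate", speed=3.0,
                                  direction=direction, intensity=1.0)
            else:
                actor = ActorSpec(shape="limb", size=14, x=x, y=y,
                                  motion="oscillate",
                                  period=float(r.uniform(12, 20)),
                                  direction=direction, intensity=1.0,
                                  bar_aspect=0.25)
            spec = SceneSpec(height=H, width=W, n_frames=T, actors=[actor],
                             background=background, noise_sigma=noise_sigma,
                             seed=inst, label=label)
            video, masks, _ = generate(spec)
            video.id = f"{label}_s{i}"
            out.append((video, masks, label))
    return out
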