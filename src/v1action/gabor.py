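"""Causal 3D spatiotemporal Gabor filters: V1 simple and complex cells.

A simple cell's receptive field is a space-time Gabor tuned to a preferred
speed v (pixels per frame, ppF) and direction theta.  Its envelope is
tilted along the motion direction through the (x_par + v*t) coupling; a
step function makes it causal (zero for t < 0), so the response at frame t
only ever uses the current and past frames.  Quadrature pairs (phases 0
and pi/2) are combined into phase-insensitive Gabor energy (complex
cells), a non-oriented channel is the mean energy over directions, and a
one-frame spatiotemporal correlation along the preferred displacement
disambiguates the raw energy.

Conventions: volumes are (T, H, W); x is the column axis (rightward), y
the row axis (downward); the channel labeled (v, theta) prefers motion at
velocity v*(cos theta, sin theta) in those coordinates.  The non-oriented
channel of speed v is keyed by theta=None.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.signal import fftconvolve

from .video import VideoVolume

__all__ = [
    "GaborParams", "BankSpec", "EnergyStack",
    "temporal_decay", "preferred_wavelength", "build_gabor_kernel",
    "gabor_energy", "bank_energy", "non_oriented_energy", "correlate_energy",
    "apply_kernel",
]

SIGMA_OVER_LAMBDA = 0.56


def temporal_decay(v: float) -> float:
    """Temporal decay tau (frames) as a linear function of preferred speed:
    tau = -0.13*v + 2.73.  Faster channels decay faster; the law only
    covers speeds below its root (~21 ppF)."""
    if v < 0:
        raise ValueError("speed must be nonnegative")
    tau = -0.13 * v + 2.73
    if tau <= 0:
        raise ValueError(f"speed {v} ppF is outside the linear tau law (tau <= 0)")
    return tau


def preferred_wavelength(v: float, lambda0: float = 4.0) -> float:
    """Preferred spatial wavelength lambda = lambda0 * sqrt(1 + v^2).

    Faster channels have coarser carriers and larger receptive fields
    (sigma = 0.56 * lambda)."""
    if v < 0 or lambda0 <= 0:
        raise ValueError("require v >= 0 and lambda0 > 0")
    return lambda0 * math.sqrt(1.0 + v * v)


@dataclass
class GaborParams:
    """Full parameter set of one spatiotemporal Gabor channel.

    tau, lam and sigma are derived from v unless given explicitly.
    ``u`` is the latency (frames) at which the temporal envelope peaks,
    as in measured V1 space-time receptive fields; None (the default)
    resolves to tau.  A peak at a positive latency lets the causal
    window hold most of a carrier period, so static patterns cancel
    instead of leaking into the motion channels; u = 0 degenerates to a
    half-Gaussian peaked at the current frame, whose spectral tail
    responds appreciably to temporal DC.
    """

    v: float
    theta: float = 0.0
    phi: float = 0.0
    lambda0: float = 4.0
    gamma: float = 0.5
    u: float | None = None
    s_support: float = 3.0     # spatial half-width in units of sigma
    t_support: int | None = None  # causal temporal length (frames)
    tau: float = field(init=False)
    lam: float = field(init=False)
    sigma: float = field(init=False)

    def __post_init__(self) -> None:
        self.tau = temporal_decay(self.v)
        self.lam = preferred_wavelength(self.v, self.lambda0)
        self.sigma = SIGMA_OVER_LAMBDA * self.lam
        if self.u is None:
            self.u = self.tau
        if self.t_support is None:
            self.t_support = int(math.ceil(self.u + 3 * self.tau))
        if self.t_support < 1:
            raise ValueError("t_support must cover at least one frame")


@dataclass
class BankSpec:
    """The filter bank: N_v speeds x N_theta directions (+ non-oriented).

    With ``calibrate`` (default) every channel's energy is divided by its
    response to a canonical probe — a unit-contrast bar moving at the
    channel's own preferred speed and direction — so that responses are
    comparable across speed channels.  Without it, slower channels have
    systematically higher broadband gain (their narrower receptive
    fields admit more of a compact stimulus's spectrum) and any
    across-channel comparison, from speed decoding to conspicuity
    fusion, is biased toward low speeds.
    """

    speeds: tuple[float, ...] = (1.0, 3.0)
    orientations: tuple[float, ...] = (0.0, math.pi / 4, math.pi / 2,
                                       3 * math.pi / 4)
    include_non_oriented: bool = True
    lambda0: float = 4.0
    gamma: float = 0.5
    u: float | None = None     # temporal-envelope latency; None = tau
    calibrate: bool = True

    def __post_init__(self) -> None:
        if len(self.speeds) == 0 or len(set(self.speeds)) != len(self.speeds):
            raise ValueError("speeds must be non-empty and distinct")
        if len(set(self.orientations)) != len(self.orientations):
            raise ValueError("orientations must be distinct")

    def channels(self) -> list[tuple[float, float | None]]:
        out: list[tuple[float, float | None]] = []
        for v in self.speeds:
            for th in self.orientations:
                out.append((v, th))
            if self.include_non_oriented:
                out.append((v, None))
        return out

    def params(self, v: float, theta: float | None) -> GaborParams:
        return GaborParams(v=v, theta=0.0 if theta is None else theta,
                           lambda0=self.lambda0, gamma=self.gamma, u=self.u)


@dataclass
class EnergyStack:
    """Per-channel nonnegative (T, H, W) response volumes at one stage.

    Channels are keyed (v, theta) with theta=None for the non-oriented
    channel.  Stages: 'raw_energy' (r-bar), 'correlated' (r-hat),
    'suppressed' (R), 'grouped' (O), 'feature' (F)."""

    channels: dict[tuple[float, float | None], np.ndarray]
    stage: str

    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    def speeds(self) -> tuple[float, ...]:
        return tuple(sorted({v for v, _ in self.channels}))

    def orientations(self, v: float) -> list[float]:
        return [th for vv, th in self.channels if vv == v and th is not None]

    def max_value(self) -> float:
        return max(float(c.max()) for c in self.channels.values())

    def map(self, fn, stage: str | None = None) -> "EnergyStack":
        return EnergyStack({k: fn(k, c) for k, c in self.channels.items()},
                           stage or self.stage)


def build_gabor_kernel(p: GaborParams) -> np.ndarray:
    """Sample the causal spatiotemporal Gabor on a (t, y, x) grid.

    The grid spans t in [0, t_support) and x, y in [-h, h] with
    h = ceil(s_support * sigma).  Zero for t < 0 by construction.
    """
    h = int(math.ceil(p.s_support * p.sigma))
    if 2 * h + 1 < p.lam:
        import warnings
        warnings.warn("kernel support smaller than one carrier period")
    xs = np.arange(-h, h + 1, dtype=np.float64)
    t = np.arange(p.t_support, dtype=np.float64)[:, None, None]
    X, Y = np.meshgrid(xs, xs)          # X: column offset, Y: row offset
    xb = X * math.cos(p.theta) + Y * math.sin(p.theta)
    yb = -X * math.sin(p.theta) + Y * math.cos(p.theta)
    arg = xb[None] + p.v * t
    tc = t - p.u
    env = np.exp(-arg**2 / (2 * p.sigma**2)
                 - p.gamma**2 * yb[None]**2 / (2 * p.sigma**2)
                 - tc**2 / (2 * p.tau**2))
    amp = p.gamma / ((2 * math.pi) ** 1.5 * p.sigma**2 * p.tau)
    return (amp * env * np.cos(2 * math.pi / p.lam * arg + p.phi)).astype(np.float32)


def apply_kernel(frames: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Causal filtering of a (T, H, W) volume with a (t, y, x) kernel.

    Spatial correlation (template matching with reflect padding) combined
    with causal temporal convolution (zero history before frame 0):
    out[t, y, x] = sum_{s, dy, dx} kernel[s, dy+h, dx+h] * in[t-s, y+dy, x+dx].
    Output matches the input shape; the first t_support-1 frames are the
    onset transient.
    """
    S, kh, kw = kernel.shape
    hy, hx = kh // 2, kw // 2
    core = np.pad(frames, ((0, 0), (hy, hy), (hx, hx)), mode="reflect")
    zeros = np.zeros((S - 1,) + core.shape[1:], dtype=core.dtype)
    pad = np.concatenate([zeros, core], axis=0)
    k = kernel[:, ::-1, ::-1]  # spatial flip => correlation in x, y
    return fftconvolve(pad, k, mode="valid").astype(np.float32)


def gabor_energy(video: VideoVolume | np.ndarray, p: GaborParams) -> np.ndarray:
    """Phase-insensitive motion energy r-bar of one (v, theta) channel.

    Each quadrature phase contributes the summed energy of a push-pull
    pair of half-wave-rectified simple cells (phases phi and phi + pi),
    i.e. the magnitude of the linear response; combining the {0, pi/2}
    pair in quadrature then yields a phase-invariant complex-cell energy.
    (Rectified single phases alone are silent for half the carrier cycle
    and cannot be phase-invariant.)
    """
    frames = video.frames if isinstance(video, VideoVolume) else video
    if frames.shape[0] <= p.t_support:
        raise ValueError("video shorter than the kernel's temporal support")
    r = []
    for phi in (0.0, math.pi / 2):
        kern = build_gabor_kernel(GaborParams(
            v=p.v, theta=p.theta, phi=phi, lambda0=p.lambda0, gamma=p.gamma,
            u=p.u, s_support=p.s_support, t_support=p.t_support))
        lin = apply_kernel(frames, kern)
        # |z| = |z|^+ + |-z|^+ : the push-pull pair of rectified cells
        r.append(np.abs(lin))
    return np.sqrt(r[0]**2 + r[1]**2)


@lru_cache(maxsize=64)
def channel_gain(v: float, lambda0: float = 4.0, gamma: float = 0.5,
                 u: float | None = None) -> float:
    """Gain of one speed channel to its canonical probe stimulus.

    The probe is a unit-contrast bar (12 x 3 px) crossing a blank 96 x 96
    field at the channel's preferred speed along theta = 0; the gain is
    the square root of the probe's correlated energy averaged over the
    true bar support at a post-transient frame.  Dividing r-bar by this
    gain equalizes channels so that each responds with unit correlated
    energy to its own preferred probe (orientation symmetry makes one
    probe direction sufficient).
    """
    from .synth import translating_bar

    p = GaborParams(v=v, theta=0.0, lambda0=lambda0, gamma=gamma, u=u)
    T = max(2 * p.t_support + 8, 24)
    t_eval = T - 8
    vid, masks = translating_bar((T, 96, 96), v, 0.0)
    rbar = gabor_energy(vid, p)
    dx = int(round(v))
    prev = _shift_back(rbar, dx, 0)
    rhat = prev[t_eval - 1] * rbar[t_eval]
    val = float(rhat[masks[t_eval]].mean())
    if val <= 0:
        raise RuntimeError(f"degenerate probe response for v={v}")
    return math.sqrt(val)


def non_oriented_energy(stack: EnergyStack, v: float) -> np.ndarray:
    """Non-oriented cell response: mean Gabor energy over all directions."""
    chans = [stack.channels[(vv, th)] for vv, th in stack.channels
             if vv == v and th is not None]
    if not chans:
        raise ValueError(f"no oriented channels at speed {v}")
    return np.mean(chans, axis=0)


def bank_energy(video: VideoVolume | np.ndarray, bank: BankSpec) -> EnergyStack:
    """Raw motion-energy stack r-bar for every bank channel."""
    channels: dict[tuple[float, float | None], np.ndarray] = {}
    for v in bank.speeds:
        gain = channel_gain(v, bank.lambda0, bank.gamma, bank.u) \
            if bank.calibrate else 1.0
        for th in bank.orientations:
            channels[(v, th)] = gabor_energy(video, bank.params(v, th)) / gain
    stack = EnergyStack(channels, "raw_energy")
    if bank.include_non_oriented:
        for v in bank.speeds:
            stack.channels[(v, None)] = non_oriented_energy(stack, v)
    return stack


def _shift_back(frames: np.ndarray, dx: int, dy: int) -> np.ndarray:
    """frames with each pixel taken from (x - dx, y - dy); zeros off-frame."""
    out = np.roll(frames, (dy, dx), axis=(1, 2))
    if dy > 0:
        out[:, :dy, :] = 0
    elif dy < 0:
        out[:, dy:, :] = 0
    if dx > 0:
        out[:, :, :dx] = 0
    elif dx < 0:
        out[:, :, dx:] = 0
    return out


def correlate_energy(stack: EnergyStack) -> EnergyStack:
    """Disambiguated motion energy r-hat: the product of the energy at
    frame t with the energy one frame earlier, displaced backward along
    the channel's preferred motion (no displacement for the non-oriented
    channel).  Frame 0 is backfilled from frame 1 so stack shapes stay
    uniform; it lies inside the documented onset transient.
    """
    out: dict[tuple[float, float | None], np.ndarray] = {}
    for (v, th), r in stack.channels.items():
        if th is None:
            prev = r
        else:
            dx = int(round(v * math.cos(th)))
            dy = int(round(v * math.sin(th)))
            prev = _shift_back(r, dx, dy)
        rh = np.empty_like(r)
        rh[1:] = prev[:-1] * r[1:]
        rh[0] = rh[1]
        out[(v, th)] = rh
    return EnergyStack(out, "correlated")
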