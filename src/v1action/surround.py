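"""Center-surround suppression of motion energy.

The surround weighting kernel is the half-wave-rectified difference of
two concentric Gaussian envelopes (inner scale sigma, outer scale
k*sigma, k > 1), L1-normalized: near zero inside the classical RF,
positive in an annulus around it, dissipating with distance.  The
oriented variant shares the Gabor's motion tilt; the non-oriented
variant is isotropic with a receptive field that grows over the causal
window (sigma' = sigma * (1 + 0.05 t)).  Suppressed energy is the
rectified difference between a channel's energy and alpha times its
surround-weighted average, which is strongest when the surround moves
coherently with the center — texture is inhibited, motion boundaries
survive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .gabor import BankSpec, EnergyStack, GaborParams, apply_kernel

__all__ = ["SurroundSpec", "surround_weight", "suppress"]

SIGMA_PRIME_RATE = 0.05   # growth of the non-oriented envelope per frame
SURROUND_EXTENT = 8.0     # kernel side in units of sigma (annulus support)


@dataclass
class SurroundSpec:
    """alpha: suppression strength; k_set: outer-scale factors (inner = 1)."""

    alpha: float = 1.0
    k_set: tuple[float, ...] = (2.0, 3.0, 4.0)

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be nonnegative")
        if any(k <= 1 for k in self.k_set):
            raise ValueError("surround scale factors must exceed 1")


def _gauss_env(p: GaborParams, scale: float, oriented: bool,
               h: int) -> np.ndarray:
    """Cosine-free causal Gaussian envelope on a (t, y, x) grid."""
    xs = np.arange(-h, h + 1, dtype=np.float64)
    t = np.arange(p.t_support, dtype=np.float64)[:, None, None]
    X, Y = np.meshgrid(xs, xs)
    tc = t - p.u
    temporal = np.exp(-tc**2 / (2 * p.tau**2)) / (math.sqrt(2 * math.pi) * p.tau)
    if oriented:
        xb = X * math.cos(p.theta) + Y * math.sin(p.theta)
        yb = -X * math.sin(p.theta) + Y * math.cos(p.theta)
        ks = scale * p.sigma
        spatial = (p.gamma / (2 * math.pi * ks**2)
                   * np.exp(-((xb[None] + p.v * t)**2 + p.gamma**2 * yb[None]**2)
                            / (2 * ks**2)))
    else:
        r2 = (X**2 + Y**2)[None]
        sp = scale * (p.sigma + SIGMA_PRIME_RATE * p.sigma * t)  # sigma'(t)
        spatial = np.exp(-r2 / (2 * sp**2)) / (2 * math.pi * sp**2)
    return spatial * temporal


def surround_weight(p: GaborParams, k: float, oriented: bool,
                    allow_zero: bool = False) -> np.ndarray:
    """L1-normalized annular weighting kernel |G_k - G_1|^+ on (t, y, x).

    Spatial side is SURROUND_EXTENT * sigma; temporal support matches the
    channel's Gabor.  With allow_zero, k == 1 yields an all-zero kernel
    (used by the grouping stage where the contrast law can demand a
    degenerate extent) instead of raising.
    """
    h = int(math.ceil(SURROUND_EXTENT * p.sigma / 2))
    if k == 1:
        if allow_zero:
            return np.zeros((p.t_support, 2 * h + 1, 2 * h + 1), dtype=np.float32)
        raise ValueError("outer scale k must exceed 1")
    w = np.maximum(_gauss_env(p, k, oriented, h) - _gauss_env(p, 1.0, oriented, h),
                   0.0)
    norm = w.sum()
    if norm <= 0:
        raise ValueError("degenerate all-zero surround difference")
    return (w / norm).astype(np.float32)


def suppress(stack: EnergyStack, spec: SurroundSpec, bank: BankSpec,
             k: float) -> EnergyStack:
    """Surround-suppressed energy R^(k) = |r - alpha * (r (*) w^(k))|^+
    channel by channel (r is the correlated stack)."""
    out: dict[tuple[float, float | None], np.ndarray] = {}
    for (v, th), r in stack.channels.items():
        p = bank.params(v, th)
        w = surround_weight(p, k, oriented=th is not None)
        out[(v, th)] = np.maximum(r - spec.alpha * apply_kernel(r, w), 0.0)
    return EnergyStack(out, "suppressed")
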