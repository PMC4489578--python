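"""Leaky integrate-and-fire spike coding of attended motion energy.

A uniform lattice of LIF neurons tiles the canonical attention window,
one lattice (sub-layer) per (speed, orientation) channel.  Each neuron's
input current is an amplified local maximum of the surround-suppressed
energy over its receptive-field patch; membrane dynamics follow
du/dt = g_L(V_L - u) + I(t) with a spike and reset at threshold.
Potentials are normalized (reset 0, threshold 1); the physiological
-70 mV resting level maps to the reset.  Spike trains are summarized by
mean firing rates in a glide window, cumulative mean rates per neuron,
per-sub-layer mean motion maps, and their concatenation — the action
code H_I.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import maximum_filter

from .gabor import BankSpec, EnergyStack

__all__ = ["LIFParams", "NeuronGrid", "input_current", "integrate_fire",
           "integrate_fire_counts", "spike_counts", "mean_rate",
           "encode_action", "SpikeEncoder"]


@dataclass
class LIFParams:
    """Normalized LIF parameters.

    g_L: leak conductance (1/frame); u0: threshold; u_reset: reset (= the
    leak/resting potential); K_exc: input amplification; dt: Euler step
    as a fraction of a frame."""

    g_L: float = 0.1
    u0: float = 1.0
    u_reset: float = 0.0
    K_exc: float = 5.0
    dt: float = 0.1

    def __post_init__(self) -> None:
        if self.u0 <= self.u_reset:
            raise ValueError("threshold must exceed reset")
        if self.g_L <= 0:
            raise ValueError("leak conductance must be positive")
        if not 0 < self.dt <= 1:
            raise ValueError("integration step must be in (0, 1] frames")

    def isi_closed_form(self, I: float) -> float:
        """Inter-spike interval under constant drive (frames); inf when
        subthreshold.  Solves the linear membrane ODE exactly."""
        # V_L coincides with the reset, so the drive toward threshold is
        # I - g_L (u0 - u_reset)
        den = I - self.g_L * (self.u0 - self.u_reset)
        if den <= 0 or I <= 0:
            return math.inf
        return math.log(I / den) / self.g_L


@dataclass
class NeuronGrid:
    """n_side x n_side RF centers uniformly tiling a side x side frame."""

    n_side: int = 40
    side: int = 120

    @property
    def n_cells(self) -> int:
        return self.n_side * self.n_side

    def positions(self) -> np.ndarray:
        """(N, 2) integer (row, col) RF centers."""
        step = self.side / self.n_side
        coords = np.clip(np.round((np.arange(self.n_side) + 0.5) * step - 0.5),
                         0, self.side - 1).astype(int)
        rr, cc = np.meshgrid(coords, coords, indexing="ij")
        return np.stack([rr.ravel(), cc.ravel()], axis=1)


def input_current(volume: np.ndarray, grid: NeuronGrid, K_exc: float,
                  patch: int) -> np.ndarray:
    """(T, N) currents: K_exc times the local maximum of the energy over
    each neuron's patch x patch receptive field (clamped at the frame
    border)."""
    patch = max(int(patch), 1)
    pooled = maximum_filter(volume, size=(1, patch, patch), mode="nearest")
    pos = grid.positions()
    return K_exc * pooled[:, pos[:, 0], pos[:, 1]]


def integrate_fire(I: np.ndarray, p: LIFParams) -> list[np.ndarray]:
    """Forward-Euler LIF integration of (T, N) frame-held currents.

    Returns per-neuron arrays of spike times in frame units; the current
    is held constant within each frame.  Deterministic.
    """
    I = np.asarray(I, dtype=np.float64)
    if I.ndim == 1:
        I = I[:, None]
    T, N = I.shape
    nsub = int(round(1.0 / p.dt))
    u = np.full(N, p.u_reset)
    times: list[list[float]] = [[] for _ in range(N)]
    for t in range(T):
        drive = I[t]
        for s in range(nsub):
            u += p.dt * (p.g_L * (p.u_reset - u) + drive)
            fired = u >= p.u0
            if fired.any():
                tt = t + (s + 1) * p.dt
                for idx in np.nonzero(fired)[0]:
                    times[idx].append(tt)
                u[fired] = p.u_reset
    return [np.array(tt) for tt in times]


def integrate_fire_counts(I: np.ndarray, p: LIFParams) -> np.ndarray:
    """Same dynamics as :func:`integrate_fire` but accumulates per-frame
    spike counts directly ((T, N) output); the fast path for encoding."""
    I = np.asarray(I, dtype=np.float64)
    if I.ndim == 1:
        I = I[:, None]
    T, N = I.shape
    nsub = int(round(1.0 / p.dt))
    u = np.full(N, p.u_reset)
    counts = np.zeros((T, N), dtype=np.float32)
    for t in range(T):
        drive = I[t]
        row = counts[t]
        for _ in range(nsub):
            u += p.dt * (p.g_L * (p.u_reset - u) + drive)
            fired = u >= p.u0
            if fired.any():
                row[fired] += 1.0
                u[fired] = p.u_reset
    return counts


def spike_counts(trains: list[np.ndarray], T: int) -> np.ndarray:
    """(T, N) spike counts; a spike at time s falls in frame ceil(s)-1,
    i.e. frame t collects spikes in (t, t+1]."""
    counts = np.zeros((T, len(trains)), dtype=np.float32)
    for i, tt in enumerate(trains):
        if tt.size:
            frames = np.clip(np.ceil(tt).astype(int) - 1, 0, T - 1)
            np.add.at(counts[:, i], frames, 1.0)
    return counts


def mean_rate(counts: np.ndarray, dt_win: int) -> np.ndarray:
    """Glide-window mean firing rate: spikes in (t - dt_win, t] / dt_win,
    per frame and neuron (windows truncated at the sequence start)."""
    if dt_win < 1:
        raise ValueError("glide window must span at least one frame")
    c = np.cumsum(counts, axis=0)
    out = np.empty_like(c)
    out[:dt_win] = c[:dt_win]
    out[dt_win:] = c[dt_win:] - c[:-dt_win]
    return out / dt_win


def encode_action(rates_by_channel: dict[tuple[float, float | None], np.ndarray],
                  t_max: int) -> np.ndarray:
    """Cumulative mean rates per neuron, concatenated over sub-layers in a
    fixed channel order: the action code H_I."""
    maps = []
    for key in sorted(rates_by_channel,
                      key=lambda k: (k[0], math.inf if k[1] is None else k[1])):
        r = rates_by_channel[key]
        if r.shape[0] != t_max:
            raise ValueError("rate series length differs from t_max")
        maps.append(r.mean(axis=0))
    return np.concatenate(maps)


@dataclass
class SpikeEncoder:
    """Drives every sub-layer's LIF lattice from a suppressed energy stack
    and emits the action code.

    The stack is max-normalized across all channels (per video) before
    current injection, so K_exc sets the drive range regardless of
    stimulus contrast while the relative channel structure — the actual
    speed/orientation signature — is preserved.
    """

    bank: BankSpec
    grid: NeuronGrid = None  # type: ignore[assignment]
    lif: LIFParams = None    # type: ignore[assignment]
    dt_win: int = 3
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.grid is None:
            self.grid = NeuronGrid()
        if self.lif is None:
            self.lif = LIFParams()

    @property
    def n_features(self) -> int:
        return len(self.bank.channels()) * self.grid.n_cells

    def encode(self, stack: EnergyStack) -> np.ndarray:
        T = stack.shape()[0]
        scale = 1.0
        if self.normalize:
            mx = stack.max_value()
            scale = 1.0 / mx if mx > 0 else 1.0
        rates: dict[tuple[float, float | None], np.ndarray] = {}
        for (v, th), vol in stack.channels.items():
            sigma = self.bank.params(v, th).sigma
            patch = max(int(round(2 * sigma)), 1)
            I = input_current(vol * scale, self.grid, self.lif.K_exc, patch)
            counts = integrate_fire_counts(I, self.lif)
            rates[(v, th)] = mean_rate(counts, self.dt_win)
        return encode_action(rates, T)
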