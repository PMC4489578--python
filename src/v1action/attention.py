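"""Perceptual grouping, saliency, and moving-object mask extraction.

Suppressed motion energy is scattered; facilitative (butterfly-like)
interactions between neurons regroup it into object-level structure.  The
facilitative weight of a channel is its energy blurred with the annular
surround kernel rotated 90 degrees and dilated by a contrast-dependent
extent n: low-contrast locations recruit a wider surround
(n = floor(exp(zeta * (1 - R_norm))), non-increasing in contrast).
Grouped channels are fused across surround scales into feature maps,
split at 1 ppF into spatial (slow) and motion (fast) conspicuity maps,
promoted with the classic single-peak normalization, and summed into a
saliency map.  An adaptive sliding-window threshold turns saliency into
binary masks whose interaction (spatial AND motion evidence) keeps the
moving object and discards static high-contrast distractors.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import (binary_closing, binary_fill_holes, binary_opening,
                           maximum_filter)
from skimage.morphology import disk
from skimage.measure import label as cc_label

from .gabor import BankSpec, EnergyStack
from .gabor import GaborParams, apply_kernel
from .surround import SurroundSpec, surround_weight, suppress

__all__ = [
    "GroupingSpec", "SaliencyProducts", "MaskChain",
    "facilitative_weight", "group", "feature_maps", "conspicuity",
    "normalize_map", "saliency", "extract_mask", "combine_masks",
    "compute_saliency", "moving_object_masks",
]


@dataclass
class GroupingSpec:
    """zeta: contrast sensitivity of the grouping extent (<= 2);
    speed_split: channels at speeds <= split are 'spatial', faster ones
    'motion'; k_th and win control adaptive mask thresholding."""

    zeta: float = 1.6
    speed_split: float = 1.0
    k_th: float = 2.0
    win: int | None = None        # sliding-window side; default 2*sigma(v=1)
    morph_radius: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.zeta <= 2:
            raise ValueError("zeta must lie in (0, 2]")


@dataclass
class SaliencyProducts:
    """Conspicuity and saliency volumes, all (T, H, W), nonnegative.

    F/Fo: spatial intensity/orientation; M/Mo: motion intensity/
    orientation; S = S1 + S2 with S1 the spatial and S2 the motion map.
    """

    F: np.ndarray
    Fo: np.ndarray
    M: np.ndarray
    Mo: np.ndarray
    S: np.ndarray = field(init=False)
    S1: np.ndarray = field(init=False)
    S2: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        nFo = normalize_map(self.Fo)
        nF = normalize_map(self.F)
        nMo = normalize_map(self.Mo)
        nM = normalize_map(self.M)
        self.S1 = nFo + nF
        self.S2 = nMo + nM
        self.S = self.S1 + self.S2


@dataclass
class MaskChain:
    """Region sets along the mask-combination chain for one frame."""

    bm1: list[np.ndarray]
    bm2: list[np.ndarray]
    bm3: list[np.ndarray]
    bm4: list[np.ndarray]
    bm: list[np.ndarray]

    def final_mask(self) -> np.ndarray:
        if not self.bm:
            raise ValueError("empty final region set")
        return np.any(self.bm, axis=0)


def grouping_extent(r_norm: np.ndarray, zeta: float) -> np.ndarray:
    """Contrast-dependent grouping extent n = floor(exp(zeta*(1-R))),
    clamped >= 1; R normalized to [0, 1]."""
    return np.maximum(np.floor(np.exp(zeta * (1.0 - r_norm))), 1.0).astype(np.int64)


def facilitative_weight(stackR: EnergyStack, g: GroupingSpec,
                        bank: BankSpec) -> EnergyStack:
    """Per-channel facilitative weight h = R (*) w^(n), the grouping
    kernel being the surround weight rotated by pi/2 with outer scale n.

    n varies per location; the convolution is evaluated at each distinct
    extent and selected pointwise.  n = 1 contributes no facilitation.
    """
    out: dict[tuple[float, float | None], np.ndarray] = {}
    for (v, th), R in stackR.channels.items():
        mx = float(R.max())
        rn = R / mx if mx > 0 else R
        nmap = grouping_extent(rn, g.zeta)
        p = bank.params(v, th)
        if th is not None:
            p = GaborParams(v=v, theta=th + math.pi / 2, lambda0=bank.lambda0,
                            gamma=bank.gamma, u=bank.u)
        h = np.zeros_like(R)
        for n in np.unique(nmap):
            if n == 1:
                continue  # degenerate annulus: no facilitation
            w = surround_weight(p, float(n), oriented=th is not None,
                                allow_zero=True)
            conv = apply_kernel(R, w)
            sel = nmap == n
            h[sel] = conv[sel]
        out[(v, th)] = h
    return EnergyStack(out, "facilitative")


def group(stackR: EnergyStack, h: EnergyStack) -> EnergyStack:
    """Grouped subbands O = R + kappa*h.

    kappa is, per frame, the channel's spatial maximum of h divided by
    the maximum over sibling subbands (over theta for oriented channels,
    over v for non-oriented ones)."""
    hmax = {key: vol.max(axis=(1, 2)) for key, vol in h.channels.items()}
    out: dict[tuple[float, float | None], np.ndarray] = {}
    for (v, th), R in stackR.channels.items():
        if th is not None:
            sib = [hmax[k] for k in h.channels if k[0] == v and k[1] is not None]
        else:
            sib = [hmax[k] for k in h.channels if k[1] is None]
        denom = np.maximum.reduce(sib)
        with np.errstate(invalid="ignore", divide="ignore"):
            kappa = np.where(denom > 0, hmax[(v, th)] / np.maximum(denom, 1e-30), 0.0)
        out[(v, th)] = R + kappa[:, None, None] * h.channels[(v, th)]
    return EnergyStack(out, "grouped")


def feature_maps(grouped_by_k: dict[float, EnergyStack]) -> EnergyStack:
    """Across-scale addition: F_{v,(theta)} = sum_k O^(k), pointwise."""
    if not grouped_by_k:
        raise ValueError("no surround scales provided")
    keys = next(iter(grouped_by_k.values())).channels.keys()
    out = {key: np.sum([g.channels[key] for g in grouped_by_k.values()], axis=0)
           for key in keys}
    return EnergyStack(out, "feature")


def conspicuity(features: EnergyStack, speed_split: float = 1.0) -> SaliencyProducts:
    """Fuse feature maps into the four conspicuity maps, split by speed:
    slow channels (v <= split) carry spatial structure, fast ones motion."""
    shape = features.shape()
    F = np.zeros(shape, dtype=np.float32)
    M = np.zeros(shape, dtype=np.float32)
    Fo = np.zeros(shape, dtype=np.float32)
    Mo = np.zeros(shape, dtype=np.float32)
    seen_slow = seen_fast = False
    for (v, th), vol in features.channels.items():
        slow = v <= speed_split
        seen_slow |= slow
        seen_fast |= not slow
        if th is None:
            (F if slow else M)[:] += vol
        else:
            (Fo if slow else Mo)[:] += vol
    if not seen_slow or not seen_fast:
        warnings.warn("one side of the speed split has no channels; "
                      "its conspicuity maps are zero")
    return SaliencyProducts(F=F, Fo=Fo, M=M, Mo=Mo)


def normalize_map(m: np.ndarray, peak_size: int = 5) -> np.ndarray:
    """Itti-style promotion, frame by frame: rescale to [0, 1], then weight
    by (1 - mean of the other local maxima)^2 — a map with one dominant
    peak is promoted, one with many equal peaks is crushed.  Zero maps
    stay zero."""
    m = np.asarray(m, dtype=np.float32)
    single = m.ndim == 2
    vol = m[None] if single else m
    out = np.zeros_like(vol)
    for t in range(vol.shape[0]):
        f = vol[t]
        mx = float(f.max())
        if mx <= 0:
            continue
        f = f / mx
        peaks = (f == maximum_filter(f, size=peak_size)) & (f > 0.05)
        vals = f[peaks]
        if vals.size <= 1:
            mbar = 0.0
        else:
            mbar = (float(vals.sum()) - 1.0) / (vals.size - 1)
        out[t] = f * (1.0 - mbar) ** 2
    return out[0] if single else out


def saliency(sp: SaliencyProducts) -> np.ndarray:
    """The saliency map S = N(Fo) + N(F) + N(Mo) + N(M)."""
    return sp.S


def extract_mask(m: np.ndarray, win: int, k_th: float = 1.0,
                 stride: int | None = None,
                 morph_radius: int = 3) -> list[np.ndarray]:
    """Adaptive-threshold region extraction from one H x W map.

    A win x win window slides over the map (stride win//2); its summed
    saliency is the window's salient degree.  The threshold is k_th times
    the mean salient degree (the frequency-histogram mean); windows above
    it form the ROI, cleaned by morphological closing then opening and
    split into connected regions."""
    if win < 1:
        raise ValueError("window side must be >= 1")
    H, W = m.shape
    stride = stride or max(win // 2, 1)
    ys = list(range(0, max(H - win, 0) + 1, stride))
    xs = list(range(0, max(W - win, 0) + 1, stride))
    degrees = np.array([[m[y:y + win, x:x + win].sum() for x in xs] for y in ys])
    if degrees.size == 0 or degrees.max() <= 0:
        return []
    th = k_th * degrees.mean()
    roi = np.zeros((H, W), dtype=bool)
    for i, y in enumerate(ys):
        for j, x in enumerate(xs):
            if degrees[i, j] > th:
                roi[y:y + win, x:x + win] = True
    if morph_radius > 0:
        se = disk(morph_radius)
        roi = binary_opening(binary_closing(roi, structure=se), structure=se)
        # energy concentrates on object boundaries; fill enclosed interiors
        roi = binary_fill_holes(roi)
    lab = cc_label(roi)
    return [lab == i for i in range(1, lab.max() + 1)]


def combine_masks(bm1: list[np.ndarray], bm2: list[np.ndarray],
                  bm4: list[np.ndarray]) -> MaskChain:
    """Interact the mask chain.

    A saliency region (BM1) intersecting spatial-structure regions (BM2)
    is completed by union with them (BM3); a completed region survives to
    the final BM only if it also intersects motion evidence (BM4) —
    static high-contrast objects drop out."""
    bm3: list[np.ndarray] = []
    for r1 in bm1:
        hits = [r2 for r2 in bm2 if np.any(r1 & r2)]
        if hits:
            bm3.append(np.any([r1] + hits, axis=0))
    bm = [r3 for r3 in bm3 if any(np.any(r3 & r4) for r4 in bm4)]
    return MaskChain(bm1=bm1, bm2=bm2, bm3=bm3, bm4=bm4, bm=bm)


# ---------------------------------------------------------------------------
# high-level drivers

def default_window(bank: BankSpec) -> int:
    """Sliding-window side: twice the RF sigma of the slowest channel."""
    v0 = min(bank.speeds)
    return max(int(round(2 * bank.params(v0, None).sigma)), 2)


def compute_saliency(correlated: EnergyStack, bank: BankSpec,
                     sspec: SurroundSpec, gspec: GroupingSpec
                     ) -> tuple[SaliencyProducts, dict[float, EnergyStack]]:
    """Suppress, group and fuse at every surround scale; returns the
    saliency products and the per-scale suppressed stacks."""
    suppressed = {k: suppress(correlated, sspec, bank, k) for k in sspec.k_set}
    grouped = {}
    for k, stackR in suppressed.items():
        h = facilitative_weight(stackR, gspec, bank)
        grouped[k] = group(stackR, h)
    feats = feature_maps(grouped)
    return conspicuity(feats, gspec.speed_split), suppressed


def moving_object_masks(sp: SaliencyProducts, bank: BankSpec,
                        gspec: GroupingSpec) -> list[MaskChain]:
    """Per-frame mask chains: BM1 from S, BM2 from S1, BM4 from S2."""
    win = gspec.win or default_window(bank)
    chains = []
    for t in range(sp.S.shape[0]):
        bm1 = extract_mask(sp.S[t], win, gspec.k_th, morph_radius=gspec.morph_radius)
        bm2 = extract_mask(sp.S1[t], win, gspec.k_th, morph_radius=gspec.morph_radius)
        bm4 = extract_mask(sp.S2[t], win, gspec.k_th, morph_radius=gspec.morph_radius)
        chains.append(combine_masks(bm1, bm2, bm4))
    return chains
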