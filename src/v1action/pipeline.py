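"""End-to-end orchestration: perceive -> suppress -> attend -> track ->
spike-encode -> classify.

The attention stage and FA tracking run on the raw video; the energies
feeding the spike encoder are recomputed on the canonical FA crop, so
the code always describes the actor at a normalized scale.  The
``use_surround`` switch reproduces the classical-RF ablation (the
correlated energy drives the neurons directly); ``fa_mode`` switches
between the adaptive tracked window and a fixed full-frame window.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .attention import (GroupingSpec, compute_saliency, moving_object_masks)
from .classify import ClassifyResult, EvalProtocol, fit_predict
from .foa import AttentionField, BoxObs, crop_resize, largest_region_box, track
from .gabor import BankSpec, EnergyStack, bank_energy, correlate_energy
from .spiking import LIFParams, NeuronGrid, SpikeEncoder
from .surround import SurroundSpec, suppress
from .video import VideoVolume, clip_subsequence

__all__ = ["PipelineConfig", "encode_video", "encode_library", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything the pipeline needs; defaults are the model's standard
    operating point (speeds 1 and 3 ppF, 4 orientations + non-oriented,
    surround scales {2,3,4} with k = 4 feeding the encoder, zeta = 1.6,
    glide window 3, t_max = 60, 40 x 40 neurons on a 120 px window)."""

    bank: BankSpec = field(default_factory=BankSpec)
    surround: SurroundSpec = field(default_factory=SurroundSpec)
    grouping: GroupingSpec = field(default_factory=GroupingSpec)
    lif: LIFParams = field(default_factory=LIFParams)
    k_encode: float = 4.0
    t_max: int = 60
    dt_win: int = 3
    fa_mode: str = "adaptive"     # 'adaptive' | 'fixed'
    use_surround: bool = True
    canonical: int = 120
    grid_side: int = 40
    fa_r: float = 4.0
    fa_n: tuple[int, int, int] = (7, 2, 2)

    def encoder(self) -> SpikeEncoder:
        return SpikeEncoder(bank=self.bank,
                            grid=NeuronGrid(self.grid_side, self.canonical),
                            lif=self.lif, dt_win=self.dt_win)


def attend_and_crop(video: VideoVolume, cfg: PipelineConfig) -> VideoVolume:
    """Locate the moving object, track the FA, return the canonical crop."""
    raw = bank_energy(video, cfg.bank)
    corr = correlate_energy(raw)
    sp, _ = compute_saliency(corr, cfg.bank, cfg.surround, cfg.grouping)
    chains = moving_object_masks(sp, cfg.bank, cfg.grouping)
    obs: list[BoxObs | None] = [largest_region_box(ch.bm) for ch in chains]
    if all(o is None for o in obs):
        # nothing salient detected: fall back to the full frame
        return _full_frame_crop(video, cfg)
    n1, n2, n3 = cfg.fa_n
    trace = track(obs, r=cfg.fa_r, n1=n1, n2=n2, n3=n3,
                  canonical=cfg.canonical)
    return crop_resize(video, trace)


def _full_frame_crop(video: VideoVolume, cfg: PipelineConfig) -> VideoVolume:
    T, H, W = video.shape
    n1, n2, n3 = cfg.fa_n
    f = AttentionField(L=max(H, W), xc=(W / 2, H / 2), r=cfg.fa_r,
                       n1=n1, n2=n2, n3=n3, canonical=cfg.canonical)
    return crop_resize(video, [f] * T)


def encode_video(video: VideoVolume, cfg: PipelineConfig) -> np.ndarray:
    """Full pipeline for one sequence: returns the action code H_I."""
    if video.n_frames > cfg.t_max:
        video = clip_subsequence(video, 0, cfg.t_max)
    if cfg.fa_mode == "adaptive":
        fa = attend_and_crop(video, cfg)
    elif cfg.fa_mode == "fixed":
        fa = _full_frame_crop(video, cfg)
    else:
        raise ValueError(f"unknown fa_mode {cfg.fa_mode!r}")
    raw = bank_energy(fa, cfg.bank)
    corr = correlate_energy(raw)
    if cfg.use_surround:
        stack = suppress(corr, cfg.surround, cfg.bank, cfg.k_encode)
    else:
        stack = corr
    return cfg.encoder().encode(stack)


def encode_library(library, cfg: PipelineConfig, verbose: bool = False):
    """Encode (video, masks, label) triples; each video id is its subject.

    Returns (X, labels, subjects)."""
    X, labels, subjects = [], [], []
    for i, (video, _masks, label) in enumerate(library):
        X.append(encode_video(video, cfg))
        labels.append(label)
        subjects.append(video.id or f"seq{i}")
        if verbose:
            print(f"encoded {video.id} ({i + 1}/{len(library)})")
    return np.stack(X), labels, subjects


def run_pipeline(library, cfg: PipelineConfig | None = None,
                 protocol: EvalProtocol | None = None,
                 verbose: bool = False) -> ClassifyResult:
    """Encode a labeled library and evaluate the SVM under a protocol."""
    cfg = cfg or PipelineConfig()
    X, labels, subjects = encode_library(library, cfg, verbose=verbose)
    return fit_predict(X, labels, subjects, protocol or EvalProtocol())
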