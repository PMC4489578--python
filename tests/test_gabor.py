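import math

import numpy as np
import pytest

from v1action import synth
from v1action.gabor import (BankSpec, EnergyStack, GaborParams, apply_kernel,
                            bank_energy, build_gabor_kernel, correlate_energy,
                            gabor_energy, non_oriented_energy,
                            preferred_wavelength, temporal_decay)


class TestTemporalDecay:
    def test_reference_values(self):
        assert temporal_decay(0.0) == pytest.approx(2.73)
        assert temporal_decay(1.0) == pytest.approx(2.60)

    def test_rejects_speed_beyond_linear_law(self):
        with pytest.raises(ValueError):
            temporal_decay(21.1)
        with pytest.raises(ValueError):
            temporal_decay(-1.0)


class TestPreferredWavelength:
    def test_zero_speed_gives_base_period(self):
        assert preferred_wavelength(0.0, 4.0) == pytest.approx(4.0)

    def test_direct_value(self):
        assert preferred_wavelength(1.0, 4.0) == pytest.approx(4 * math.sqrt(2))

    def test_monotone_in_speed(self):
        lams = [preferred_wavelength(v) for v in np.linspace(0, 5, 20)]
        assert np.all(np.diff(lams) > 0)


class TestKernel:
    def test_v0_slices_are_2d_gabors(self):
        """At v=0 the kernel is space-time separable: every temporal slice
        is the same 2-D Gabor up to the (positive) temporal envelope."""
        p = GaborParams(v=0.0, theta=math.pi / 4, phi=0.3)
        k = build_gabor_kernel(p)
        ref = k[0] / np.abs(k[0]).max()
        for t in range(1, k.shape[0]):
            sl = k[t] / np.abs(k[t]).max()
            assert np.allclose(sl, ref, atol=1e-6)

    def test_space_time_ridge_slope(self):
        """The envelope crest tracks x = -v*t: motion tilt in space-time."""
        p = GaborParams(v=2.0, theta=0.0, phi=0.0)
        k = build_gabor_kernel(p)
        h = k.shape[2] // 2
        env = np.abs(k).sum(axis=1)          # collapse y
        xs = np.arange(-h, h + 1)
        crests = [xs[np.argmax(env[t])] for t in range(k.shape[0])]
        slope = np.polyfit(np.arange(k.shape[0]), crests, 1)[0]
        assert slope == pytest.approx(-p.v, abs=0.35)

    def test_support_and_latency(self):
        p = GaborParams(v=1.0)
        assert p.t_support == math.ceil(p.u + 3 * p.tau)
        assert p.sigma == pytest.approx(0.56 * p.lam)


class TestEnergy:
    def test_blank_video_silent(self, slow_params):
        """A constant field only drives the tiny DC residual of the
        truncated carrier; the steady response matches that residual."""
        vid = np.full((20, 32, 32), 0.5, dtype=np.float32)
        r = gabor_energy(vid, slow_params)
        dc = []
        for phi in (0.0, math.pi / 2):
            k = build_gabor_kernel(GaborParams(v=1.0, theta=0.0, phi=phi))
            dc.append(0.5 * abs(k.sum()))
        expected = math.hypot(*dc)
        assert expected < 1e-3
        steady = r[slow_params.t_support:, 16, 16]
        assert np.allclose(steady, expected, rtol=0.25)

    def test_quadrature_phase_invariance_small(self, slow_params):
        g = synth.drifting_grating((30, 40, 40), 1.0, 0.0, slow_params.lam, 1.0)
        r = gabor_energy(g, slow_params)[slow_params.t_support:, 20, 20]
        assert r.std() / r.mean() < 0.05

    def test_direction_selectivity(self, slow_params):
        pref = synth.drifting_grating((30, 40, 40), 1.0, 0.0, slow_params.lam)
        anti = synth.drifting_grating((30, 40, 40), 1.0, math.pi, slow_params.lam)
        rp = gabor_energy(pref, slow_params)[slow_params.t_support:, 20, 20]
        ra = gabor_energy(anti, slow_params)[slow_params.t_support:, 20, 20]
        assert ra.mean() < rp.mean()

    def test_video_must_exceed_temporal_support(self, slow_params):
        with pytest.raises(ValueError):
            gabor_energy(np.zeros((4, 16, 16), dtype=np.float32), slow_params)


def test_non_oriented_is_mean_over_orientations():
    shape = (3, 4, 4)
    chans = {(1.0, th): np.full(shape, c, dtype=np.float32)
             for th, c in zip((0.0, 0.5, 1.0, 1.5), (1, 2, 3, 4))}
    stack = EnergyStack(chans, "raw_energy")
    assert np.allclose(non_oriented_energy(stack, 1.0), 2.5)
    with pytest.raises(ValueError):
        non_oriented_energy(stack, 2.0)


class TestCorrelate:
    def test_static_zero_speed_squares(self):
        """v=0 channel on a static scene: no displacement, so the
        correlation is the energy squared from frame 1 on."""
        rng = np.random.default_rng(0)
        frame = rng.random((8, 8)).astype(np.float32)
        r = np.repeat(frame[None], 5, axis=0)
        stack = EnergyStack({(0.0, 0.0): r}, "raw_energy")
        rhat = correlate_energy(stack).channels[(0.0, 0.0)]
        assert np.allclose(rhat[1:], r[1:] ** 2)
        assert np.allclose(rhat[0], rhat[1])

    def test_nonnegative_and_shape(self, raw_bank):
        vid, _ = synth.translating_bar((16, 40, 40), 1.0, 0.0)
        rhat = correlate_energy(bank_energy(vid, raw_bank))
        for vol in rhat.channels.values():
            assert vol.shape == (16, 40, 40)
            assert (vol >= 0).all()


def test_causality_truncation_equivalence(raw_bank):
    """Energies at frame t computed from frames [0..t] equal those from
    the full video: the pipeline never looks ahead."""
    vid, _ = synth.translating_bar((18, 32, 32), 1.0, 0.0)
    full = correlate_energy(bank_energy(vid, raw_bank))
    t = 14
    from v1action.video import VideoVolume, clip_subsequence
    trunc_vid = clip_subsequence(vid, 0, t + 1)
    trunc = correlate_energy(bank_energy(trunc_vid, raw_bank))
    for key in full.channels:
        assert np.allclose(full.channels[key][t], trunc.channels[key][t],
                           atol=1e-6)


def test_bank_spec_validation():
    with pytest.raises(ValueError):
        BankSpec(speeds=())
    with pytest.raises(ValueError):
        BankSpec(speeds=(1.0, 1.0))
    with pytest.raises(ValueError):
        BankSpec(orientations=(0.0, 0.0))
    bank = BankSpec()
    assert len(bank.channels()) == 10
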