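import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import disk_mask, square_mask
from micronuclei.clsa import (
    ClsaConfig,
    RegionTooSmall,
    detect_micronucleus,
    haar_highpass,
    layer_window,
    screen_peaks,
    short_window_energy,
    trace_signature,
)
from micronuclei.io_images import split_channels
from micronuclei.pipeline import clsa_call_for_component
from micronuclei.quantize import foreground_mask, quantize_channel
from micronuclei.regions import label_components
from micronuclei.synthetic import single_nucleus_scene


def _circdiff(a, b):
    return abs(math.remainder(a - b, 2 * math.pi))


def _call_on_scene(rgb, seed, cfg=ClsaConfig()):
    nucleus, _ = split_channels(rgb)
    q = quantize_channel(nucleus, 15, seed)
    fg = label_components(foreground_mask(q))
    cid = int(np.argmax(fg.areas()[1:])) + 1
    return clsa_call_for_component(q, fg.component(cid), cid, cfg)


class TestSignature:
    def test_digital_disk_is_constant_within_a_pixel(self):
        sig = trace_signature(disk_mask(radius=20))
        assert sig.length >= 8
        assert sig.values.max() - sig.values.min() <= 2.0  # +-1 px digitization
        assert sig.values.max() == pytest.approx(20.0, abs=1.0)

    def test_square_max_min_ratio_is_sqrt2(self):
        sig = trace_signature(square_mask(side=21))
        assert sig.values.max() / sig.values.min() == pytest.approx(math.sqrt(2), abs=0.08)

    def test_multi_component_mask_rejected(self):
        m = np.zeros((16, 16), bool)
        m[2:5, 2:5] = True
        m[10:13, 10:13] = True
        with pytest.raises(ValueError):
            trace_signature(m)

    def test_tiny_region_raises_skip_signal(self):
        m = np.zeros((8, 8), bool)
        m[3, 3] = True
        with pytest.raises(RegionTooSmall):
            trace_signature(m)

    def test_angles_cover_the_circle(self):
        sig = trace_signature(disk_mask(radius=15))
        assert sig.angles.min() >= -math.pi and sig.angles.max() <= math.pi
        assert sig.angles[0] < sig.angles[-1]  # monotone angular grid


class TestEnergy:
    def test_constant_signature_gives_zero_highpass_and_energy(self):
        psi = haar_highpass(np.full(64, 17.0))
        assert (psi == 0).all()
        e = short_window_energy(psi)
        assert (e.delta == 0).all() and e.mean_abs == 0.0

    def test_alternating_signature_highpass_magnitude(self):
        psi = haar_highpass(np.array([0.0, 2.0] * 16))
        assert (np.abs(psi) == 1.0).all()

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000), L=st.integers(12, 512))
    def test_telescoping_identity_and_zero_sum(self, seed, L):
        """The literal 10-term windowed sum telescopes to psi(m+11)-psi(m+1)."""
        s = np.random.default_rng(seed).uniform(0, 50, L)
        psi = haar_highpass(s)
        assert abs(psi.sum()) < 1e-8  # zero-sum kernel over a circle
        e = short_window_energy(psi)
        expected = np.roll(psi, -11) - np.roll(psi, -1)
        np.testing.assert_allclose(e.delta, expected, atol=1e-9)
        assert abs(e.delta.sum()) < 1e-7

    def test_curve_shorter_than_window_raises_skip(self):
        with pytest.raises(RegionTooSmall):
            short_window_energy(np.zeros(10))


class TestScreening:
    def test_flat_energy_has_no_ru_and_no_peaks(self):
        e = short_window_energy(np.zeros(32))
        regions, peaks = screen_peaks(e, mu=4.0)
        assert regions.ru == () and peaks == []

    def test_single_spike_yields_exactly_one_passing_peak(self, rng):
        """A 2*mu spike over a sub-threshold noise floor passes alone."""
        mu = 4.0
        L = 128
        s = 30.0 + rng.uniform(-0.3, 0.3, L)
        s[60:64] += 12.0  # sharp protrusion
        psi = haar_highpass(s)
        e = short_window_energy(psi)
        assert np.abs(e.delta).max() > mu
        regions, peaks = screen_peaks(e, mu, angles=np.linspace(-np.pi, np.pi, L))
        assert len(peaks) >= 1
        idx = {p.index for p in peaks}
        # every passing peak localizes near the planted spike (delta responds
        # within the 10-sample window around the jump)
        assert all(45 <= i <= 70 for i in idx)

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_ru_rd_partition_the_curve(self, seed):
        s = np.random.default_rng(seed).uniform(0, 40, 64)
        e = short_window_energy(haar_highpass(s))
        regions, _ = screen_peaks(e, mu=4.0)
        covered = np.zeros(64, dtype=int)
        for start, length in regions.ru + regions.rd:
            for t in range(length):
                covered[(start + t) % 64] += 1
        assert (covered == 1).all()


class TestLayerWindow:
    @pytest.mark.parametrize("k,expected", [(15, (4, 12)), (10, (3, 8)), (20, (5, 16))])
    def test_middle_layers_rule(self, k, expected):
        assert layer_window(k) == expected

    def test_tiny_k_rejected(self):
        with pytest.raises(ValueError):
            layer_window(3)


class TestDetection:
    def test_perfect_disk_across_all_layers_is_negative(self):
        layers = {lv: disk_mask((96, 96), (48, 48), 30) for lv in range(4, 13)}
        call = detect_micronucleus(1, layers, ClsaConfig())
        assert not call.positive

    def test_single_layer_spike_is_texture_not_micronucleus(self):
        rgb, _ = single_nucleus_scene("texture_spike", seed=5)
        assert not _call_on_scene(rgb, 5).positive

    def test_planted_micronucleus_found_at_planted_angle(self):
        angle = 0.8
        rgb, truth = single_nucleus_scene("micronucleus", seed=4, bump_angle=angle)
        call = _call_on_scene(rgb, 4)
        assert call.positive
        assert len(call.supporting_layers) >= 3
        assert _circdiff(call.angular_position, angle) <= math.radians(20)

    def test_rotation_equivariance(self):
        rgb, truth = single_nucleus_scene("micronucleus", seed=4, bump_angle=0.8)
        call = _call_on_scene(rgb, 4)
        rgb90 = np.rot90(rgb).copy()
        call90 = _call_on_scene(rgb90, 4)
        assert call.positive and call90.positive
        shift = _circdiff(call90.angular_position, call.angular_position)
        assert shift == pytest.approx(math.pi / 2, abs=math.radians(20))

    def test_scale_robustness(self):
        """Doubling the nucleus preserves the call: delta scales with radius."""
        for radius, shape in ((30, (160, 160)), (60, (320, 320))):
            rgb, _ = single_nucleus_scene(
                "micronucleus", seed=6, shape=shape, radius=radius, bump_angle=2.0
            )
            assert _call_on_scene(rgb, 6).positive, f"radius {radius}"

    def test_edge_connected_layers_are_excluded(self):
        """A layer mask touching the image border contributes no peaks."""
        m = disk_mask((40, 80), (20, 20), 19)
        m[:, 0] = True  # weld the region to the border
        layers = {lv: m for lv in range(4, 13)}
        call = detect_micronucleus(1, layers, ClsaConfig())
        assert not call.positive and call.supporting_layers == ()

    def test_border_bump_not_analyzed_in_pipeline(self):
        """Nuclei clipped by the border land in B and never reach the analysis."""
        from micronuclei.pipeline import PipelineConfig, run_pipeline
        from micronuclei.detector import DetectorConfig
        from micronuclei.synthetic import NucleusSpec, SceneSpec, generate_scene

        spec = SceneSpec(
            shape=(256, 256),
            nuclei=(NucleusSpec((10, 128), border_clip=True),),
            seed=3,
        )
        rgb, _ = generate_scene(spec)
        res = run_pipeline(rgb, PipelineConfig(detector=DetectorConfig(mode="blob", min_area=300)))
        assert res.calls == ()
        assert res.report.normal == 0 and res.report.micronuclei == 0
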