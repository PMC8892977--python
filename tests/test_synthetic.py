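"""Simulated focus rendering, base cells and the augmented training set."""

import numpy as np
import pytest

from fociquant.io_gating import GH2AX, GatingConfig, apply_gate, \
    compute_gating_features
from fociquant.synthetic import (
    SpotParams,
    SyntheticCellSpec,
    amplitude_for_sigma,
    build_training_set,
    inject_spots,
    make_base_cell,
    render_spot,
    target_heatmap,
    write_fixture_stack,
)


class TestRenderSpot:
    @pytest.mark.parametrize("sigma", [0.75, 1.0, 1.5, 2.25])
    def test_flux_equals_integrated_amplitude(self, sigma):
        # analytic: the unbounded integral of the Gaussian is A = 3 sigma^3
        A = float(amplitude_for_sigma(sigma))
        img = render_spot(SpotParams(32, 32, sigma, A), 64)
        assert abs(img.sum() - A) / A < 0.005

    def test_zero_amplitude_renders_nothing(self):
        img = render_spot(SpotParams(10, 10, 1.0, 0.0), 32)
        assert not img.any()

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            SpotParams(10, 10, 0.0, 1.0)

    def test_peak_at_center(self):
        img = render_spot(SpotParams(20, 12, 1.5, 10.0), 64)
        assert np.unravel_index(np.argmax(img), img.shape) == (12, 20)


class TestMakeBaseCell:
    def test_noise_free_cell_is_smooth_profile(self):
        spec = SyntheticCellSpec(noise_sd=0.0, rng_seed=0)
        rec = make_base_cell(spec)
        gh = rec.channels[GH2AX]
        # the continuum peak sits between pixels on an even grid
        assert gh.max() == pytest.approx(spec.background_level, rel=0.01)
        assert gh.min() >= 0.0

    def test_seed_reproducibility(self):
        a = make_base_cell(SyntheticCellSpec(rng_seed=5))
        b = make_base_cell(SyntheticCellSpec(rng_seed=5))
        for ch in a.channels:
            np.testing.assert_array_equal(a.channels[ch], b.channels[ch])

    def test_default_cell_passes_default_gate(self):
        rec = make_base_cell(SyntheticCellSpec(rng_seed=123))
        assert apply_gate(compute_gating_features(rec), GatingConfig())


class TestInjectSpots:
    def test_zero_count_is_identity(self):
        base = np.full((64, 64), 5.0)
        out, truth = inject_spots(base, (0, 0), rng=np.random.default_rng(0))
        np.testing.assert_array_equal(out, base)
        assert truth == []

    def test_flux_additivity(self):
        base = np.zeros((64, 64))
        out, truth = inject_spots(base, (3, 3), rng=np.random.default_rng(1))
        expected = sum(s.A for s in truth)
        assert abs(out.sum() - expected) / expected < 0.005

    def test_amplitude_law_and_sampling_bounds(self):
        rng = np.random.default_rng(2)
        base = np.zeros((32, 32))
        sigmas, amps, counts = [], [], []
        for _ in range(300):
            _, truth = inject_spots(base, rng=rng)
            counts.append(len(truth))
            sigmas += [s.sigma for s in truth]
            amps += [s.A for s in truth]
        sigmas, amps = np.array(sigmas), np.array(amps)
        assert sigmas.min() >= 0.75 and sigmas.max() <= 2.25
        assert min(counts) >= 0 and max(counts) <= 10
        np.testing.assert_allclose(amps, 3.0 * sigmas**3, rtol=1e-12)

    def test_mean_spot_count_matches_uniform_law(self):
        # counts ~ uniform{0..10}: mean 5, var 10
        rng = np.random.default_rng(3)
        base = np.zeros((16, 16))
        n = 10_000
        counts = np.array(
            [len(inject_spots(base, rng=rng)[1]) for _ in range(n)]
        )
        se = np.sqrt(10.0 / n)
        assert abs(counts.mean() - 5.0) < 3 * se

    def test_min_separation_enforced(self):
        rng = np.random.default_rng(4)
        base = np.zeros((64, 64))
        for _ in range(20):
            _, truth = inject_spots(base, (5, 10), rng=rng, min_separation=6)
            pts = np.array([[s.y0, s.x0] for s in truth])
            for i in range(len(pts)):
                for j in range(i + 1, len(pts)):
                    assert np.linalg.norm(pts[i] - pts[j]) >= 6.0


class TestBuildTrainingSet:
    def test_cardinality(self, base_cells_20):
        pairs = build_training_set(base_cells_20[:2], pairs_per_base=3,
                                   rng_seed=0)
        assert len(pairs) == 6

    def test_single_pair_contract(self, base_cells_20):
        pairs = build_training_set(base_cells_20[:1], pairs_per_base=1,
                                   rng_seed=0)
        assert len(pairs) == 1
        p = pairs[0]
        assert p.input_image.shape == (64, 64)
        assert p.target_heatmap.shape == (64, 64)
        assert 0 <= len(p.truth) <= 10
        assert p.input_image.min() >= 0 and p.input_image.max() <= 1
        assert (p.target_heatmap >= 0).all()

    def test_seed_determinism(self, base_cells_20):
        a = build_training_set(base_cells_20[:3], 2, rng_seed=11)
        b = build_training_set(base_cells_20[:3], 2, rng_seed=11)
        for pa, pb in zip(a, b):
            assert [
                (s.x0, s.y0, s.sigma, s.A) for s in pa.truth
            ] == [(s.x0, s.y0, s.sigma, s.A) for s in pb.truth]
            np.testing.assert_array_equal(pa.input_image, pb.input_image)

    def test_empty_base_list_rejected(self):
        with pytest.raises(ValueError):
            build_training_set([], 8)


class TestTargetHeatmap:
    def test_unit_peak_height(self):
        hm = target_heatmap([SpotParams(20, 30, 1.5, 10.0)], 64)
        assert hm.max() == pytest.approx(1.0, abs=1e-6)
        assert np.unravel_index(np.argmax(hm), hm.shape) == (30, 20)


class TestWriteFixtureStack:
    @pytest.mark.parametrize("n", [1, 4, 10])
    def test_roundtrip_identity(self, n, tmp_path, base_cells_20):
        from fociquant.io_gating import read_stack
        from fociquant.synthetic import fixture_channel_map

        recs = base_cells_20[:n]
        path = write_fixture_stack(recs, tmp_path / f"s{n}.tif")
        back = read_stack(path, fixture_channel_map(recs))
        assert len(back) == n
        for a, b in zip(recs, back):
            for ch in a.channels:
                np.testing.assert_array_equal(
                    np.asarray(a.channels[ch], np.float32), b.channels[ch]
                )
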