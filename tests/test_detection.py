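"""Candidate masking, Gaussian fitting, thresholds and per-cell metrics."""

import math

import numpy as np
import pytest

from fociquant.detection import (
    DetectionConfig,
    Focus,
    call_foci,
    candidate_mask,
    compute_cell_metrics,
    fit_candidates,
    fit_gaussian_patch,
    photometric_refit,
    score_confidence,
    select_foci,
)
from fociquant.io_gating import GH2AX
from fociquant.synthetic import SpotParams, render_spot, target_heatmap


class TestCandidateMask:
    def test_constant_heatmap_yields_nothing(self):
        assert candidate_mask(np.full((64, 64), 3.0)) == []
        assert candidate_mask(np.zeros((64, 64))) == []

    def test_single_bump_single_candidate(self):
        hm = render_spot(SpotParams(20, 30, 1.5, 10.0), 64)
        cands = candidate_mask(hm)
        assert cands == [(30, 20)]

    def test_two_separated_bumps(self):
        hm = (
            render_spot(SpotParams(15, 15, 1.5, 10.0), 64)
            + render_spot(SpotParams(35, 15, 1.5, 10.0), 64)
        )
        assert sorted(candidate_mask(hm)) == [(15, 15), (15, 35)]

    def test_close_pair_above_min_distance_both_found(self):
        hm = target_heatmap(
            [SpotParams(30, 30, 2.25, 1.0), SpotParams(36, 30, 2.25, 1.0)], 64
        )
        assert len(candidate_mask(hm)) == 2


class TestFitGaussianPatch:
    def test_recovers_noiseless_spot(self):
        spot = SpotParams(7.3, 7.6, 1.2, 20.0)
        img = render_spot(spot, 15)
        fit = fit_gaussian_patch(img, (8, 7), patch_size=9)
        assert abs(fit.sigma - 1.2) < 0.05
        assert abs(fit.A - 20.0) / 20.0 < 0.02
        assert fit.r2 > 0.999
        assert abs(fit.x0 - 7.3) < 0.05 and abs(fit.y0 - 7.6) < 0.05

    def test_offset_invariance(self):
        spot = SpotParams(7.0, 7.0, 1.4, 30.0)
        img = render_spot(spot, 15)
        f0 = fit_gaussian_patch(img, (7, 7), 9)
        f1 = fit_gaussian_patch(img + 10.0, (7, 7), 9)
        assert abs(f1.sigma - f0.sigma) / f0.sigma < 0.02
        assert abs(f1.A - f0.A) / f0.A < 0.02

    def test_pure_noise_rarely_passes_r2_gate(self):
        rng = np.random.default_rng(0)
        n = 1000
        fails = 0
        for _ in range(n):
            patch = rng.normal(0.0, 1.0, size=(9, 9))
            fit = fit_gaussian_patch(patch, (4, 4), 9)
            if fit.r2 >= 0.85:
                fails += 1
        assert fails / n < 0.05

    def test_flat_patch_returns_sentinel(self):
        fit = fit_gaussian_patch(np.full((9, 9), 2.0), (4, 4), 9)
        assert fit.r2 == -math.inf


class TestPhotometry:
    def test_amplitude_recovered_at_frozen_geometry(self):
        spot = SpotParams(30.0, 28.0, 1.5, 250.0)
        img = render_spot(spot, 64) + 40.0
        amp = photometric_refit(img, 30.0, 28.0, 1.5, (28, 30), 9)
        assert abs(amp - 250.0) / 250.0 < 0.01


class TestScoreConfidence:
    def test_zero_amplitude_zero_confidence(self):
        assert score_confidence(0.0, 0.99, 0.1) == 0.0

    def test_clean_bright_fit_is_far_above_threshold(self):
        assert score_confidence(100.0, 1.0, 1e-12) > 1e4

    def test_monotone_in_amplitude(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            a = rng.uniform(1, 500)
            r2 = rng.uniform(0, 1)
            rms = rng.uniform(1e-3, 10)
            assert score_confidence(2 * a, r2, rms) > \
                score_confidence(a, r2, rms)


class TestCallFoci:
    def test_zero_heatmap_no_foci(self):
        assert call_foci(np.zeros((64, 64)), np.zeros((64, 64))) == []

    def test_three_bright_spots_all_counted(self):
        truth = [
            SpotParams(15, 15, 1.2, 400.0),
            SpotParams(40, 20, 1.8, 600.0),
            SpotParams(25, 45, 1.0, 300.0),
        ]
        img = np.full((64, 64), 50.0)
        for s in truth:
            img = img + render_spot(s, 64)
        hm = target_heatmap(truth, 64)
        foci = call_foci(hm, img)
        assert len(foci) == 3
        assert all(f.counted for f in foci)

    def test_dim_focus_kept_but_not_counted(self):
        truth = [SpotParams(32, 32, 1.0, 50.0)]  # below 100 counts
        img = np.full((64, 64), 20.0) + render_spot(truth[0], 64)
        foci = call_foci(target_heatmap(truth, 64), img)
        assert len(foci) == 1
        assert not foci[0].counted
        metrics = compute_cell_metrics(foci, img)
        assert metrics.n_foci == 0
        assert metrics.focus_intensity == pytest.approx(
            foci[0].amplitude, rel=1e-12
        )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            call_foci(np.zeros((64, 64)), np.zeros((32, 32)))

    def test_threshold_monotonicity_suite(self, eval_cells_64):
        """Raising any of r2/confidence/intensity thresholds never
        increases the counted focus number (1,000 randomized instances
        over fitted candidates from oracle-heatmap cells)."""
        cells, _, heatmaps = eval_cells_64
        base_cfg = DetectionConfig()
        cand_lists = [
            fit_candidates(hm, cell.channels[GH2AX], base_cfg)
            for cell, hm in zip(cells[:10], heatmaps[:10])
        ]
        rng = np.random.default_rng(17)
        for _ in range(100):
            cands = cand_lists[int(rng.integers(len(cand_lists)))]
            lo = DetectionConfig(
                r2_threshold=rng.uniform(0, 1),
                confidence_threshold=rng.uniform(0, 500),
                intensity_threshold=rng.uniform(0, 500),
            )
            hi = DetectionConfig(
                r2_threshold=min(lo.r2_threshold + rng.uniform(0, 0.5), 1.0),
                confidence_threshold=lo.confidence_threshold
                + rng.uniform(0, 500),
                intensity_threshold=lo.intensity_threshold
                + rng.uniform(0, 500),
            )
            n_lo = sum(f.counted for f in select_foci(cands, lo))
            n_hi = sum(f.counted for f in select_foci(cands, hi))
            assert n_hi <= n_lo
            # single-threshold variations, 9 more instances per round
            for field in ("r2_threshold", "confidence_threshold",
                          "intensity_threshold"):
                for delta in (0.0, 0.1, 1.0):
                    import dataclasses as dc

                    mid = dc.replace(
                        lo, **{field: getattr(lo, field) + delta}
                    )
                    assert sum(
                        f.counted for f in select_foci(cands, mid)
                    ) <= n_lo


class TestCellMetrics:
    def test_empty_focus_list(self):
        img = np.full((10, 10), 2.0)
        m = compute_cell_metrics([], img)
        assert m.n_foci == 0
        assert m.focus_intensity == 0.0
        assert m.cell_intensity == pytest.approx(200.0)

    def test_counted_and_uncounted_arithmetic(self):
        mk = lambda A, counted: Focus(0, 0, 1.0, A, 0.99, 1e4, counted)
        foci = [mk(150.0, True), mk(200.0, True), mk(50.0, False)]
        m = compute_cell_metrics(foci, np.zeros((5, 5)))
        assert m.n_foci == 2
        assert m.focus_intensity == pytest.approx(400.0)

    def test_zero_image_all_zero(self):
        m = compute_cell_metrics([], np.zeros((64, 64)))
        assert (m.n_foci, m.focus_intensity, m.cell_intensity) == (0, 0.0, 0.0)


class TestOracleCountRecovery:
    def test_well_separated_spots_recovered_exactly(self, eval_cells_64):
        """With truth heatmaps standing in for the network, every
        well-separated spot (>= 6 px) is called, and no extras."""
        cells, truths, heatmaps = eval_cells_64
        for cell, truth, hm in zip(cells, truths, heatmaps):
            foci = call_foci(hm, cell.channels[GH2AX])
            assert sum(f.counted for f in foci) == len(truth)

    def test_merged_pair_never_overcounts(self):
        rng = np.random.default_rng(23)
        base = np.full((64, 64), 100.0)
        for _ in range(10):
            x = rng.uniform(25, 35)
            y = rng.uniform(25, 35)
            truth = [
                SpotParams(x, y, 1.5, 400.0),
                SpotParams(x + 1.2, y, 1.5, 400.0),  # < 2 px apart
            ]
            img = base + sum(render_spot(s, 64) for s in truth)
            foci = call_foci(target_heatmap(truth, 64), img)
            assert sum(f.counted for f in foci) <= 2


class TestDetectionConfig:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            DetectionConfig(patch_size=8)
        with pytest.raises(ValueError):
            DetectionConfig(mask_percentile=0)
        with pytest.raises(ValueError):
            DetectionConfig(r2_threshold=-1)
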