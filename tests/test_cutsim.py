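"""Poisson-binomial cut-count model: loading, exact DP, simulation."""

import numpy as np
import pytest

from fociquant.cutsim import (
    CutDistribution,
    EditingPanel,
    exact_distribution,
    load_panel,
    simulate_cells,
    summarize,
)
from fociquant.panels import REFERENCE_PANELS, reference_panel


def enumeration_pmf(ps):
    """Independent oracle: brute force over all 2^n site outcomes."""
    ps = np.asarray(ps, dtype=np.float64)
    n = ps.size
    idx = np.arange(2**n, dtype=np.uint64)
    pmf = np.zeros(n + 1)
    prob = np.ones(2**n)
    k = np.zeros(2**n, dtype=np.int64)
    for i, p in enumerate(ps):
        hit = (idx >> np.uint64(i)) & np.uint64(1) == 1
        prob *= np.where(hit, p, 1.0 - p)
        k += hit
    np.add.at(pmf, k, prob)
    return pmf


def _panel(ps, name="test"):
    return EditingPanel(name, tuple((f"s{i}", p) for i, p in enumerate(ps)))


class TestLoadPanel:
    def test_percent_to_fraction(self, tmp_path):
        f = tmp_path / "p.csv"
        f.write_text("site_id,efficiency_percent\non,94.8\not1,0.2\n")
        panel = load_panel(f)
        np.testing.assert_allclose(panel.probabilities, [0.948, 0.002])
        assert panel.n_sites == 2

    def test_cutoff_drops_low_rows(self, tmp_path):
        f = tmp_path / "p.csv"
        f.write_text("site_id,efficiency_percent\non,94.8\nx,0.04\n")
        panel = load_panel(f, cutoff_percent=0.05)
        assert [s for s, _ in panel.sites] == ["on"]

    def test_empty_csv_rejected(self, tmp_path):
        f = tmp_path / "p.csv"
        f.write_text("site_id,efficiency_percent\n")
        with pytest.raises(ValueError):
            load_panel(f)

    def test_out_of_range_row_named(self, tmp_path):
        f = tmp_path / "p.csv"
        f.write_text("site_id,efficiency_percent\nbad_site,120\n")
        with pytest.raises(ValueError, match="bad_site"):
            load_panel(f)


class TestExactDistribution:
    def test_single_site(self):
        d = exact_distribution(_panel([0.948]))
        np.testing.assert_allclose(d.pmf, [0.052, 0.948], atol=1e-15)
        assert d.mean == pytest.approx(0.948)

    def test_two_fair_sites_binomial(self):
        d = exact_distribution(_panel([0.5, 0.5]))
        np.testing.assert_allclose(d.pmf, [0.25, 0.5, 0.25], atol=1e-15)

    @pytest.mark.parametrize("n_sites", [1, 5, 12, 20])
    def test_matches_enumeration_oracle(self, n_sites):
        rng = np.random.default_rng(n_sites)
        ps = rng.random(n_sites)
        d = exact_distribution(_panel(ps))
        np.testing.assert_allclose(d.pmf, enumeration_pmf(ps), atol=1e-12)

    def test_mean_identity(self):
        rng = np.random.default_rng(8)
        ps = rng.random(60) * 0.9
        d = exact_distribution(_panel(ps))
        assert d.mean == pytest.approx(float(ps.sum()), abs=1e-12)
        k = np.arange(d.pmf.size)
        assert float(k @ d.pmf) == pytest.approx(d.mean, abs=1e-9)

    def test_pmf_normalized(self):
        rng = np.random.default_rng(9)
        d = exact_distribution(_panel(rng.random(40)))
        assert abs(d.pmf.sum() - 1.0) < 1e-12


class TestSimulateCells:
    def test_all_zero_probabilities(self):
        d = simulate_cells(_panel([0.0, 0.0, 0.0]), 1000, rng_seed=0)
        assert d.pmf[0] == 1.0

    def test_all_certain_sites(self):
        d = simulate_cells(_panel([1.0] * 5), 1000, rng_seed=0)
        assert d.pmf[5] == 1.0

    def test_clt_mean_agreement(self):
        rng = np.random.default_rng(10)
        ps = rng.random(30)
        n = 100_000
        d = simulate_cells(_panel(ps), n, rng_seed=1)
        var = float((ps * (1 - ps)).sum())
        se = np.sqrt(var / n)
        assert abs(d.mean - ps.sum()) < 3 * se

    def test_seed_reproducibility(self):
        p = _panel([0.3, 0.7, 0.1])
        a = simulate_cells(p, 5000, rng_seed=4)
        b = simulate_cells(p, 5000, rng_seed=4)
        np.testing.assert_array_equal(a.pmf, b.pmf)


class TestSummarize:
    def test_single_site_p_ge_1(self):
        row = summarize(exact_distribution(_panel([0.948]))).iloc[0]
        assert row["p_ge_1_cut"] == pytest.approx(0.948)

    def test_zero_panel(self):
        row = summarize(exact_distribution(_panel([0.0]))).iloc[0]
        assert row["p_zero_cuts"] == 1.0

    def test_consistency_with_pmf(self):
        rng = np.random.default_rng(11)
        d = exact_distribution(_panel(rng.random(15)))
        row = summarize(d).iloc[0]
        assert row["p_ge_2_cuts"] == pytest.approx(float(d.pmf[2:].sum()))
        k = np.arange(d.pmf.size)
        assert row["variance"] == pytest.approx(
            float((k - d.mean) ** 2 @ d.pmf)
        )


class TestReferencePanels:
    def test_reconstructed_panels_match_summary_figures(self):
        for name, figs in REFERENCE_PANELS.items():
            panel = reference_panel(name)
            assert panel.n_sites == figs["n_sites"]
            total = panel.probabilities.sum() * 100
            assert total == pytest.approx(figs["total_percent"], abs=1e-9)
            assert panel.probabilities[0] * 100 == pytest.approx(
                figs["on_target_percent"]
            )
            # every site clears the reporting cutoff
            assert (panel.probabilities * 100 >= 0.05 - 1e-12).all()

    def test_invariant_checks(self):
        with pytest.raises(ValueError):
            EditingPanel("bad", (("s", 1.2),))
        with pytest.raises(ValueError):
            CutDistribution(pmf=np.array([0.5, 0.4]), mean=0.4)
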