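"""Generator contracts: determinism, noise-free exactness, planted errors."""

import numpy as np
import pandas as pd
import pytest

from benthotrend import detection_eval as de
from benthotrend import synthetic_data as sd
from benthotrend._geo import pairwise_km


class TestSpecValidation:
    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError, match="base_rate"):
            sd.TaxonSpec("x", 50, 10, -1.0)

    def test_recall_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="recall"):
            sd.TaxonSpec("x", 50, 10, 1.0, recall=1.2)

    def test_contradictory_depth_range_rejected(self):
        with pytest.raises(ValueError, match="depth range"):
            sd.TransectSpec("T", 2000, 100, 50.0, 40.0)

    def test_nonpositive_frames_per_metre_rejected(self):
        with pytest.raises(ValueError, match="frames_per_m"):
            sd.TransectSpec("T", 2000, 100, 10.0, 50.0, 0.0)

    def test_benchmark_error_counts_exceeding_truth_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            sd.simulate_detection_benchmark(5, 2, {"n_fn": 4, "n_swap": 2})

    def test_raster_cell_size_rejected(self):
        with pytest.raises(ValueError, match="cell size"):
            sd.RasterSpec(cell_deg=0.0)


class TestSimulateSurvey:
    def config(self, **kw):
        defaults = dict(
            taxa=[sd.TaxonSpec("a", 50, 10, 1.0)],
            transects=[sd.TransectSpec("T0", 2000, 100, 20.0, 80.0, 4.0),
                       sd.TransectSpec("T1", 2010, 200, 20.0, 80.0, 4.0)],
            seed=1,
        )
        defaults.update(kw)
        return sd.SimulationConfig(**defaults)

    def test_zero_rate_no_detections_but_depths_emitted(self):
        cfg = self.config(taxa=[sd.TaxonSpec("a", 50, 10, 0.0)])
        det, depths, _ = sd.simulate_survey(cfg)
        assert len(det) == 0
        assert len(depths) > 0

    def test_fixed_seed_bitwise_identical(self):
        cfg = self.config()
        a = sd.simulate_survey(cfg)
        b = sd.simulate_survey(cfg)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_expected_mode_reproduces_analytic_rates_exactly(self):
        cfg = self.config()
        det, _, _ = sd.simulate_survey(cfg, mode="expected")
        taxon = cfg.taxa[0]
        cov = sd.transect_covariates(cfg.transects)
        for i, tr in enumerate(cfg.transects):
            depths = sd.frame_depths_true(tr)
            lam = sd.expected_rate(
                taxon, depths, cov.loc[i, "year_s"], cov.loc[i, "day_s"], cov.loc[i, "day2_s"]
            )
            got = det[det["transect_id"] == tr.transect_id].set_index("frame")["count"]
            assert np.allclose(got.to_numpy(), lam[got.index.to_numpy()])

    def test_expected_mode_confidence_is_one(self):
        det, _, _ = sd.simulate_survey(self.config(), mode="expected")
        assert (det["confidence"] == 1.0).all()

    def test_truth_quantiles_are_normal_quantiles(self):
        cfg = self.config(taxa=[sd.TaxonSpec("a", 70, 10, 1.0)])
        _, _, truth = sd.simulate_survey(cfg)
        q16, q50, q84 = truth.depth_quantiles["a"]
        assert q50 == pytest.approx(70.0)
        assert q16 == pytest.approx(70 - 9.9446, abs=1e-3)
        assert q84 == pytest.approx(70 + 9.9446, abs=1e-3)

    def test_recall_thins_detections(self):
        full = self.config(taxa=[sd.TaxonSpec("a", 50, 15, 3.0, recall=1.0)])
        half = self.config(taxa=[sd.TaxonSpec("a", 50, 15, 3.0, recall=0.5)])
        d_full, _, _ = sd.simulate_survey(full)
        d_half, _, _ = sd.simulate_survey(half)
        assert d_half["count"].sum() < 0.65 * d_full["count"].sum()

    def test_confusion_moves_counts_to_target(self):
        cfg = self.config(
            taxa=[
                sd.TaxonSpec("a", 50, 15, 3.0, confusion={"b": 0.3}),
                sd.TaxonSpec("b", 50, 15, 0.0),
            ]
        )
        det, _, _ = sd.simulate_survey(cfg)
        counts = det.groupby("taxon")["count"].sum()
        assert counts.get("b", 0) > 0
        assert counts["b"] / (counts["a"] + counts["b"]) == pytest.approx(0.3, abs=0.05)

    def test_depth_readings_have_dropouts_and_misreads(self):
        cfg = self.config(depth_reading=sd.DepthReadingSpec(10, 0.2, 0.1))
        _, depths, _ = sd.simulate_survey(cfg)
        n_expected = sum(len(np.arange(0, t.n_frames, 10)) + 1 for t in cfg.transects)
        assert len(depths) < n_expected  # dropouts occurred
        assert (depths["depth_m"] == 999.0).any()  # misreads planted

    def test_truth_json_round_trip(self, tmp_path):
        _, _, truth = sd.simulate_survey(self.config())
        p = tmp_path / "truth.json"
        truth.to_json(p)
        back = sd.TruthParameters.from_json(p)
        assert back.depth_quantiles == truth.depth_quantiles
        assert back.trend_coefficients == truth.trend_coefficients


class TestDetectionBenchmark:
    def test_zero_errors_predictions_equal_truths(self):
        truths, preds = sd.simulate_detection_benchmark(10, 3, seed=0)
        assert (preds["confidence"] == 1.0).all()
        pd.testing.assert_frame_equal(preds.drop(columns="confidence"), truths)

    def test_planted_fp_precision_across_threshold(self):
        truths, preds = sd.simulate_detection_benchmark(
            8, 1, {"n_fp": 2, "fp_confidence": 0.3}, seed=1
        )
        for thr, expected in [(0.5, 1.0), (0.2, 0.8)]:
            m = de.match_predictions(preds[preds["confidence"] >= thr], truths)
            _, p, _ = de.roc_metrics(m.tp, m.fp, m.fn)
            assert p == pytest.approx(expected)

    def test_planted_fn_and_swap_counts(self):
        truths, preds = sd.simulate_detection_benchmark(
            20, 4, {"n_fn": 3, "n_swap": 2}, seed=2
        )
        m = de.match_predictions(preds, truths)
        assert m.tp == 15 and m.fp == 2 and m.fn == 5

    def test_seed_determinism(self):
        a = sd.simulate_detection_benchmark(15, 3, {"n_fp": 2, "n_fn": 1}, seed=9)
        b = sd.simulate_detection_benchmark(15, 3, {"n_fp": 2, "n_fn": 1}, seed=9)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])


class TestGlobalOccurrences:
    def test_sd_zero_no_contaminants_median_equals_nearest_cell_temperature(self):
        cfg = sd.SimulationConfig(niches=[sd.NicheSpec("s", 10.0, 0.0, 50)], seed=2)
        occs, raster, truth = sd.simulate_global_occurrences(cfg)
        temps = raster.lookup(occs["decimalLatitude"], occs["decimalLongitude"])
        assert np.allclose(temps, temps[0])  # all in equal-temperature cells
        assert truth.niche_medians["s"] == pytest.approx(10.0, abs=0.1)

    def test_contaminant_labels_partition_output(self):
        cfg = sd.SimulationConfig(
            niches=[sd.NicheSpec("s", 9.0, 1.0, 60, 3, 4, 2, (5,))], seed=4
        )
        occs, _, _ = sd.simulate_global_occurrences(cfg)
        counts = occs["contaminant"].value_counts()
        assert counts["clean"] == 60
        assert counts["uncertainty"] == 3
        assert counts["cell_range"] == 4
        assert counts["isolated"] == 2
        assert counts["cluster_0"] == 5

    def test_clean_points_pairwise_beyond_thinning_radius(self):
        cfg = sd.SimulationConfig(niches=[sd.NicheSpec("s", 8.0, 1.0, 120)], seed=5)
        occs, _, _ = sd.simulate_global_occurrences(cfg)
        clean = occs[occs["contaminant"] == "clean"]
        d = pairwise_km(clean["decimalLatitude"], clean["decimalLongitude"])
        np.fill_diagonal(d, np.inf)
        assert d.min() > 1.0

    def test_determinism(self):
        cfg = sd.SimulationConfig(niches=[sd.NicheSpec("s", 9.0, 1.0, 40, 2, 2, 1, (4,))], seed=6)
        a = sd.simulate_global_occurrences(cfg)[0]
        b = sd.simulate_global_occurrences(cfg)[0]
        pd.testing.assert_frame_equal(a, b)

    def test_too_many_isolated_rejected(self):
        with pytest.raises(ValueError, match="isolated"):
            sd.NicheSpec("s", 9.0, 1.0, 40, n_isolated=4)


def test_linear_abundance_planted_coefficients_recoverable():
    from benthotrend import trend_model as tm

    rng = np.random.default_rng(0)
    rec = pd.DataFrame(
        {
            "year": rng.integers(1997, 2024, 400),
            "day_of_year": rng.integers(1, 366, 400),
            "depth_m": rng.integers(7, 105, 400),
        }
    )
    design = tm.build_design_matrix(rec)
    beta = {"const": 0.0, "year_s": 0.3, "day_s": -0.1}
    y = sd.simulate_linear_abundance(design.X, beta, sigma=0.2, rng=rng)
    fit = tm.fit_abundance_trend(design, y, scale_response=False)
    assert fit.params["year_s"] == pytest.approx(0.3, abs=3 * fit.bse["year_s"])
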