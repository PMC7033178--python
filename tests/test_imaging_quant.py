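"""Single-mRNA calibration, cytosolic counting, escape ratio, uptake metrics."""

import numpy as np
import pandas as pd
import pytest

from nanotraffic import imaging_quant as iq
from nanotraffic import synthdata
from nanotraffic._utils import ValidationError


def table(rows):
    return pd.DataFrame(rows, columns=["cell_id", "channel", "object_id",
                                       "intensity", "area"])


def standards(intensities):
    return [("std", "electroporation_standard", f"s{i}", v, 4.0)
            for i, v in enumerate(intensities)]


class TestCalibration:
    def test_constant_standards(self):
        cal = iq.calibrate_single_mrna(table(standards([100.0] * 30)))
        assert cal.unit_intensity == 100.0
        assert cal.spread == 0.0

    def test_lognormal_standards_within_five_percent(self, rng):
        vals = 100.0 * np.exp(rng.normal(0, np.sqrt(np.log1p(0.2 ** 2)), 500))
        cal = iq.calibrate_single_mrna(table(standards(vals)))
        assert cal.unit_intensity == pytest.approx(100.0, rel=0.05)

    def test_median_robust_to_outlier(self):
        vals = [100.0] * 99 + [1000.0]
        cal = iq.calibrate_single_mrna(table(standards(vals)))
        assert cal.unit_intensity == 100.0

    def test_too_few_standards_rejected(self):
        with pytest.raises(ValidationError):
            iq.calibrate_single_mrna(table(standards([100.0] * 5)))


class TestCounting:
    def setup_method(self):
        self.cal = iq.SingleMoleculeCalibration(unit_intensity=100.0, spread=5.0,
                                                n_objects=100)

    def test_unit_intensity_objects_are_cytosolic(self):
        rows = [("c1", "fish", f"o{i}", 100.0, 4.0) for i in range(10)]
        counts = iq.count_cytosolic(table(rows), self.cal)
        assert counts["c1"] == 10

    def test_bright_clusters_are_entrapped(self):
        rows = [("c1", "fish", f"o{i}", 500.0, 9.0) for i in range(10)]
        counts = iq.count_cytosolic(table(rows), self.cal)
        assert counts["c1"] == 0

    def test_gain_invariance_of_classification(self):
        rng = np.random.default_rng(1)
        inten = rng.uniform(20.0, 400.0, 50)
        rows = [("c1", "fish", f"o{i}", v, 4.0) for i, v in enumerate(inten)]
        base = iq.count_cytosolic(table(rows), self.cal)["c1"]
        gain = 7.3
        rows_g = [("c1", "fish", f"o{i}", v * gain, 4.0) for i, v in enumerate(inten)]
        cal_g = iq.SingleMoleculeCalibration(100.0 * gain, 5.0 * gain, 100)
        assert iq.count_cytosolic(table(rows_g), cal_g)["c1"] == base

    def test_lnp_count_from_intensity_sum(self):
        rows = [("c1", "lnp", "o1", 350.0, 4.0)]
        counts = iq.count_lnp(table(rows), lnp_unit_intensity=50.0)
        assert counts["c1"] == 7

    def test_cells_without_lnp_objects_count_zero(self):
        rows = [("c1", "lnp", "o1", 100.0, 4.0), ("c2", "fish", "o2", 90.0, 4.0)]
        counts = iq.count_lnp(table(rows), 50.0)
        assert counts["c2"] == 0

    def test_nonpositive_unit_rejected(self):
        with pytest.raises(ValidationError):
            iq.count_lnp(table([("c1", "lnp", "o1", 1.0, 4.0)]), 0.0)

    def test_simulated_counts_recovered_within_ten_percent(self):
        cfg = synthdata.SpotFieldSim(n_cells=60, seed=7)
        objects, truth = synthdata.simulate_spot_field(cfg)
        cal = iq.calibrate_single_mrna(objects)
        cyt = iq.count_cytosolic(objects, cal)
        got = cyt.loc[truth.cell_id].to_numpy(float).mean()
        want = truth.n_cytosolic_mrna.mean()
        assert got == pytest.approx(want, rel=0.10)


class TestEscapeRatio:
    def test_simple_ratio(self):
        cyt = pd.Series({"c1": 10}, name="cyt")
        lnp = pd.Series({"c1": 5})
        res = iq.escape_ratio(cyt, lnp)
        assert res.mean_ratio == pytest.approx(2.0)

    def test_zero_cytosolic_everywhere(self):
        cells = [f"c{i}" for i in range(5)]
        res = iq.escape_ratio(pd.Series(0, index=cells), pd.Series(10, index=cells))
        assert res.mean_ratio == 0.0

    def test_zero_lnp_cells_excluded_and_counted(self):
        cyt = pd.Series({"c1": 10, "c2": 4})
        lnp = pd.Series({"c1": 5, "c2": 0})
        res = iq.escape_ratio(cyt, lnp)
        assert res.n_cells == 1
        assert res.n_excluded_zero_lnp == 1
        assert res.mean_ratio == pytest.approx(2.0)

    def test_scale_free_per_cell(self):
        cyt = pd.Series({"c1": 10, "c2": 20})
        lnp = pd.Series({"c1": 5, "c2": 10})
        res = iq.escape_ratio(cyt, lnp)
        assert res.per_cell.escape_ratio.tolist() == [2.0, 2.0]

    def test_disjoint_cells_rejected(self):
        with pytest.raises(ValidationError):
            iq.escape_ratio(pd.Series({"a": 1}), pd.Series({"b": 1}))

    def test_cohort_ordering_follows_escape_probability(self):
        means = []
        for frac, seed in ((2.0, 1), (6.0, 2)):
            cfg = synthdata.SpotFieldSim(n_cells=40, n_cytosolic_mrna=frac, seed=seed)
            objects, truth = synthdata.simulate_spot_field(cfg)
            cal = iq.calibrate_single_mrna(objects)
            cyt = iq.count_cytosolic(objects, cal)
            lnp = iq.count_lnp(objects, cfg.lnp_unit_intensity)
            means.append(iq.escape_ratio(cyt.loc[truth.cell_id],
                                         lnp.loc[truth.cell_id]).mean_ratio)
        assert means[1] > means[0]

    def test_full_pipeline_cohort_mean_within_fifteen_percent(self):
        ratios = []
        for seed in range(10):
            cfg = synthdata.SpotFieldSim(n_cells=40, seed=seed)
            objects, truth = synthdata.simulate_spot_field(cfg)
            cal = iq.calibrate_single_mrna(objects)
            cyt = iq.count_cytosolic(objects, cal)
            lnp = iq.count_lnp(objects, cfg.lnp_unit_intensity)
            ratios.append(iq.escape_ratio(cyt.loc[truth.cell_id],
                                          lnp.loc[truth.cell_id]).mean_ratio)
        expected = synthdata.SpotFieldSim().n_cytosolic_mrna / synthdata.SpotFieldSim().n_lnp
        assert np.mean(ratios) == pytest.approx(expected, rel=0.15)


class TestUptake:
    def test_perinuclear_intensity_per_nucleus(self):
        rows = [("c1", "lnp", "o1", 300.0, 4.0)] + \
               [("c1", "nuclei", f"n{i}", 1.0, 100.0) for i in range(3)]
        assert iq.perinuclear_uptake(table(rows)) == pytest.approx(100.0)

    def test_doubling_nuclei_halves_metric(self):
        rows = [("c1", "lnp", "o1", 300.0, 4.0)] + \
               [("c1", "nuclei", f"n{i}", 1.0, 100.0) for i in range(3)]
        rows2 = rows + [("c1", "nuclei", f"m{i}", 1.0, 100.0) for i in range(3)]
        assert iq.perinuclear_uptake(table(rows2)) == pytest.approx(
            iq.perinuclear_uptake(table(rows)) / 2.0)

    def test_zero_nuclei_rejected(self):
        with pytest.raises(ValidationError):
            iq.perinuclear_uptake(table([("c1", "lnp", "o1", 1.0, 4.0)]))

    def test_dose_ladder_is_monotone(self, rng):
        metrics = []
        for dose in (1.0, 4.0, 16.0):
            rows = [("c1", "lnp", f"o{i}", dose * 10.0 + rng.normal(0, 0.1), 4.0)
                    for i in range(20)]
            rows += [("c1", "nuclei", f"n{i}", 1.0, 100.0) for i in range(5)]
            metrics.append(iq.perinuclear_uptake(table(rows)))
        assert metrics[0] < metrics[1] < metrics[2]

    def test_linear_uptake_constant_rate(self):
        t = np.arange(0.0, 10.0)
        rate = iq.uptake_rate(t, 2.0 * t + 1.0, smooth_window=1)
        np.testing.assert_allclose(rate, 2.0, rtol=1e-12)

    def test_constant_series_zero_rate(self):
        t = np.arange(0.0, 8.0)
        np.testing.assert_allclose(iq.uptake_rate(t, np.full_like(t, 5.0)), 0.0)

    def test_saturating_curve_matches_analytic_derivative(self):
        # closed-form oracle: d/dt A(1 - e^{-kt}) = A k e^{-kt}
        A, k = 100.0, 0.2
        t = np.arange(0.0, 25.0)
        rate = iq.uptake_rate(t, A * (1.0 - np.exp(-k * t)), smooth_window=1)
        analytic = A * k * np.exp(-k * t)
        np.testing.assert_allclose(rate[1:-1], analytic[1:-1], rtol=0.05)

    def test_duplicate_time_points_rejected(self):
        with pytest.raises(ValidationError):
            iq.uptake_rate(np.array([0.0, 1.0, 1.0, 2.0]), np.arange(4.0))
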