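"""Statistics: binning, power-law fits, survival curves, regression."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats as sps

from microwet import scene as sc
from microwet import stats as st


def records(rows, cols=("droplet_area_um2", "cell_area_um2",
                        "live_area_um2", "dead_area_um2", "repeat")):
    return pd.DataFrame(rows, columns=cols)


class TestBinSpec:
    def test_validation(self):
        with pytest.raises(ValueError):
            st.BinSpec([1.0])
        with pytest.raises(ValueError):
            st.BinSpec([1.0, 1.0, 2.0])

    def test_log_spaced_and_centers(self):
        b = st.BinSpec.log_spaced(1.0, 100.0, 2)
        assert b.edges == pytest.approx([1.0, 10.0, 100.0])
        assert b.centers == pytest.approx([np.sqrt(10), np.sqrt(1000)])

    def test_index_closed_last_bin_and_outside(self):
        b = st.BinSpec.log_spaced(1.0, 100.0, 2)
        assert list(b.index(np.array([0.5, 1.0, 9.0, 100.0, 101.0]))) == [-1, 0, 0, 1, -1]


class TestSizeDistribution:
    def test_single_bin_density(self):
        df = records([(50.0, 0, 0, 0, "a")] * 100)
        out = st.size_distribution(df, 10.0, st.BinSpec([10.0, 100.0]))
        assert out.count_per_mm2.iloc[0] == pytest.approx(10.0)

    def test_two_fields_mean_and_sem(self):
        rows = [(50.0, 0, 0, 0, "f1")] * 10 + [(50.0, 0, 0, 0, "f2")] * 20
        out = st.size_distribution(records(rows), 1.0, st.BinSpec([10.0, 100.0]))
        assert out["count_per_mm2"].iloc[0] == pytest.approx(15.0)
        assert out["sem"].iloc[0] == pytest.approx(5.0)

    def test_no_droplets_all_zero(self):
        out = st.size_distribution(records([]), 1.0, st.BinSpec([10.0, 100.0]))
        assert (out.count_per_mm2 == 0).all()

    def test_matches_ground_truth_histogram(self, small_scene):
        dtab, _ = sc.scene_tables(small_scene)
        bins = st.BinSpec.log_spaced(10.0, 300.0, 5)
        out = st.size_distribution(dtab, 2.0, bins)
        oracle, _ = np.histogram(small_scene.droplet_areas(), bins=bins.edges)
        assert np.allclose(out.count_per_mm2 * 2.0, oracle)


class TestFitPowerLaw:
    def test_hill_closed_form(self):
        """Untruncated MLE reduces to the Hill estimator."""
        fit = st.fit_power_law([10, 20, 40, 80], method="truncated_mle", xmin=10.0)
        assert fit.gamma == pytest.approx(-1.96, abs=0.005)

    def test_truncated_mle_matches_grid_search_oracle(self):
        """Optimizer agrees with an independent brute-force likelihood scan."""
        rng = np.random.default_rng(5)
        x = sc.sample_truncated_power_law(2000, -1.5, 10.0, 1e4, rng)
        fit = st.fit_power_law(x, method="truncated_mle", xmin=10.0, xmax=1e4)

        def loglik(g):
            g1 = g + 1.0
            if abs(g1) < 1e-9:
                logc = -np.log(np.log(1e4 / 10.0))
            else:
                logc = np.log(abs(g1)) - np.log(abs(1e4**g1 - 10.0**g1))
            return len(x) * logc + g * np.log(x).sum()

        grid = np.linspace(-3.0, -0.5, 5001)
        oracle = grid[np.argmax([loglik(g) for g in grid])]
        assert fit.gamma == pytest.approx(oracle, abs=1e-3)

    def test_mle_recovery_and_stderr(self):
        rng = np.random.default_rng(7)
        x = sc.sample_truncated_power_law(10_000, -1.2, 10.0, 1e4, rng)
        fit = st.fit_power_law(x, method="truncated_mle", xmin=10.0, xmax=1e4)
        assert -1.3 <= fit.gamma <= -1.1
        assert 0 < fit.stderr < 0.1

    def test_logbin_ls_recovers_exponent(self):
        rng = np.random.default_rng(8)
        x = sc.sample_truncated_power_law(20_000, -1.2, 10.0, 1e4, rng)
        fit = st.fit_power_law(x, method="logbin_ls", xmin=10.0, xmax=1e4)
        assert fit.gamma == pytest.approx(-1.2, abs=0.15)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(st.FitError):
            st.fit_power_law([50.0], xmin=10.0)
        with pytest.raises(st.FitError):
            st.fit_power_law([50.0] * 10, method="truncated_mle", xmin=10.0)


class TestBinnedMeanCurve:
    def test_single_bin_mean_and_sem(self):
        out = st.binned_mean_curve([5.0, 5.0], [2.0, 4.0], st.BinSpec([1.0, 10.0]))
        assert out.mean[0] == pytest.approx(3.0)
        assert out.sem[0] == pytest.approx(1.0)

    def test_constant_y_zero_sem(self):
        bins = st.BinSpec.log_spaced(1.0, 1000.0, 3)
        out = st.binned_mean_curve([2.0, 20.0, 200.0, 3.0], [7.0] * 4, bins)
        occupied = out.n > 0
        assert np.all(out.sem[occupied] == 0)

    def test_empty_bins_flagged_not_dropped(self):
        bins = st.BinSpec.log_spaced(1.0, 1000.0, 3)
        out = st.binned_mean_curve([2.0], [1.0], bins)
        assert len(out.mean) == 3
        assert out.n[1] == 0 and np.isnan(out.mean[1])

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            st.binned_mean_curve([1.0, 2.0], [1.0], st.BinSpec([1.0, 10.0]))

    def test_monotone_coupling_recovered(self):
        """Generator couples droplet size to cell area ⇒ rising binned curve."""
        spec = dataclasses.replace(sc.SceneSpec(), field_width_um=665.6,
                                   field_height_um=665.6, n_aggregates=50, seed=13)
        dtab, _ = sc.scene_tables(sc.sample_scene(spec))
        d = dtab[dtab.cell_area_um2 > 0]
        bins = st.BinSpec.log_spaced(1.0, 1e4, 8)
        out = st.binned_mean_curve(d.cell_area_um2, d.droplet_area_um2, bins)
        m = out.mean[out.n >= 3]
        assert len(m) >= 3
        assert np.all(np.diff(m) > 0)


class TestSurvivalVsDropletSize:
    def test_single_all_live_droplet(self):
        df = records([(50.0, 5.0, 5.0, 0.0, "a")])
        out = st.survival_vs_droplet_size(df, st.BinSpec([10.0, 100.0]))
        assert out.mean[0] == pytest.approx(1.0)

    def test_mixed_bin_mean_and_sem(self):
        df = records([(50.0, 4.0, 0.0, 4.0, "a"), (60.0, 4.0, 4.0, 0.0, "a")])
        out = st.survival_vs_droplet_size(df, st.BinSpec([10.0, 100.0]))
        assert out.mean[0] == pytest.approx(0.5)
        assert out.sem[0] == pytest.approx(0.5)

    def test_no_cells_warns_empty_curve(self):
        df = records([(50.0, 0.0, 0.0, 0.0, "a")])
        with pytest.warns(UserWarning):
            out = st.survival_vs_droplet_size(df, st.BinSpec([10.0, 100.0]))
        assert np.isnan(out.mean).all()

    def test_scale_invariance(self):
        """Rescaling all areas and bin edges by a constant leaves the curve."""
        rng = np.random.default_rng(3)
        a = rng.uniform(10, 1e4, 200)
        live = rng.uniform(0, 5, 200)
        dead = rng.uniform(0, 5, 200)
        df = records(list(zip(a, live + dead, live, dead, ["x"] * 200)))
        bins = st.BinSpec.log_spaced(10.0, 1e4, 6)
        base = st.survival_vs_droplet_size(df, bins)
        c = 7.3
        df2 = df.copy()
        for col in ("droplet_area_um2", "cell_area_um2", "live_area_um2", "dead_area_um2"):
            df2[col] *= c
        scaled = st.survival_vs_droplet_size(df2, st.BinSpec(bins.edges * c))
        assert np.allclose(base.mean, scaled.mean, equal_nan=True)
        assert np.array_equal(base.n, scaled.n)

    def test_recovers_generator_logistic(self):
        """Binned survival tracks the generator's logistic in droplet size."""
        droplet_rows = []
        for seed in range(3):
            spec = dataclasses.replace(sc.SceneSpec(), field_width_um=665.6,
                                       field_height_um=665.6, n_aggregates=40,
                                       seed=100 + seed)
            dtab, _ = sc.scene_tables(sc.sample_scene(spec), field_id=str(seed))
            droplet_rows.append(dtab)
        df = pd.concat(droplet_rows, ignore_index=True)
        bins = st.BinSpec.log_spaced(10.0, 1e4, 6)
        curve = st.survival_vs_droplet_size(df, bins, pooled=True)
        spec0 = sc.SceneSpec()
        for b in range(bins.n_bins):
            sel = df[(bins.index(df.droplet_area_um2.to_numpy()) == b)
                     & (df.cell_area_um2 > 0)]
            n_cells = sel.cell_area_um2.sum() / sc.CELL_FOOTPRINT_UM2
            if n_cells < 30:
                continue
            expected = float(np.average(
                sc.survival_probability(sel.droplet_area_um2.to_numpy(), spec0),
                weights=sel.cell_area_um2,
            ))
            ci = 3.3 * np.sqrt(expected * (1 - expected) / n_cells)
            assert abs(curve.mean[b] - expected) <= ci + 0.02


class TestPopulationSummaries:
    def test_population_by_size_conservation(self, small_scene):
        dtab, _ = sc.scene_tables(small_scene)
        bins = st.BinSpec.log_spaced(1.0, 1e3, 6)
        out = st.population_by_droplet_size(dtab, bins)
        total = out.live_area_per_mm2.sum() + out.dead_area_per_mm2.sum()
        assert total == pytest.approx(dtab.cell_area_um2.sum())

    def test_all_cells_single_bin(self):
        df = records([(50.0, 10.0, 6.0, 4.0, "a")])
        out = st.population_by_droplet_size(df, st.BinSpec.log_spaced(10.0, 100.0, 1))
        assert out.live_area_per_mm2.iloc[0] == pytest.approx(6.0)
        assert out.dead_area_per_mm2.iloc[0] == pytest.approx(4.0)

    def test_population_above_size_extremes(self):
        df = records([(50.0, 10.0, 5.0, 5.0, "a"), (500.0, 2.0, 1.0, 1.0, "a")])
        out = st.population_above_size(df, thresholds=np.array([10.0, 1e4]))
        assert out.fraction_above.iloc[0] == pytest.approx(1.0)
        assert out.fraction_above.iloc[1] == pytest.approx(0.0)
        assert (np.diff(st.population_above_size(df).fraction_above) <= 1e-12).all()

    def test_population_above_size_zero_cells_raises(self):
        with pytest.raises(ValueError):
            st.population_above_size(records([(50.0, 0.0, 0.0, 0.0, "a")]))

    def test_aggregated_population_dominates_solitary(self):
        """Larger aggregates put more of the population into large droplets."""
        base = dict(field_width_um=665.6, field_height_um=665.6,
                    n_aggregates=40, seed=17)
        agg_spec = dataclasses.replace(sc.SceneSpec(), aggregate_area_params=(1.8, 0.5), **base)
        sol_spec = dataclasses.replace(sc.SceneSpec(), aggregate_area_params=(0.0, 0.1), **base)
        agg_tab, _ = sc.scene_tables(sc.sample_scene(agg_spec))
        sol_tab, _ = sc.scene_tables(sc.sample_scene(sol_spec))
        thr = np.logspace(1.5, 3.5, 20)
        fa = st.population_above_size(agg_tab, thr).fraction_above
        fs = st.population_above_size(sol_tab, thr).fraction_above
        assert (fa >= fs).all() and fa.iloc[-1] > fs.iloc[-1]


class TestSurvival2D:
    def test_single_record(self):
        atab = pd.DataFrame([{
            "aggregate_id": 1, "repeat": "a", "aggregate_area_um2": 5.0,
            "host_droplet_id": 1, "droplet_area_um2": 50.0,
            "live_area_um2": 4.0, "dead_area_um2": 1.0, "survival_rate": 0.8,
        }])
        g = st.survival_2d(atab, st.BinSpec([10.0, 100.0, 1000.0]),
                           st.BinSpec([1.0, 10.0]))
        assert g["mean"][0, 0] == pytest.approx(0.8)
        assert g["n"].sum() == 1 and np.isnan(g["mean"][0, 1])

    def test_empty_input(self):
        atab = pd.DataFrame(columns=["aggregate_id", "repeat", "aggregate_area_um2",
                                     "host_droplet_id", "droplet_area_um2",
                                     "live_area_um2", "dead_area_um2", "survival_rate"])
        g = st.survival_2d(atab, st.BinSpec([10.0, 100.0]), st.BinSpec([1.0, 10.0]))
        assert g["n"].sum() == 0

    def test_rows_flat_when_survival_depends_only_on_droplet(self):
        """Fixing the droplet bin, survival does not vary with aggregate size."""
        spec = dataclasses.replace(sc.SceneSpec(), field_width_um=975.0,
                                   field_height_um=975.0, n_aggregates=80,
                                   coupling_noise_sd=1.0, seed=23)
        _, atab = sc.scene_tables(sc.sample_scene(spec))
        dbins = st.BinSpec.log_spaced(10.0, 1e4, 6)
        abins = st.BinSpec.log_spaced(0.5, 2e3, 4)
        g = st.survival_2d(atab, dbins, abins)
        spec0 = sc.SceneSpec()
        for c in range(dbins.n_bins):
            col_mean = g["mean"][:, c]
            col_n = g["n"][:, c]
            ok = col_n >= 5
            if ok.sum() < 2:
                continue
            expected = sc.survival_probability(np.array([dbins.centers[c]]), spec0)[0]
            for m, n in zip(col_mean[ok], col_n[ok]):
                assert abs(m - expected) <= 3.5 * np.sqrt(0.25 / n) + 0.25


class TestFitContribution:
    @staticmethod
    def synth_records(n, seed, droplet_effect=True):
        """Objects with power-law droplet areas, noisy aggregate coupling and
        survival depending only on droplet size (or constant)."""
        rng = np.random.default_rng(seed)
        spec = sc.SceneSpec()
        d_area = sc.sample_truncated_power_law(n, -1.2, 10.0, 1e4, rng)
        a_area = np.maximum(0.2 * d_area * np.exp(rng.normal(0, 1.0, n)), 1.0)
        a_area = np.minimum(a_area, d_area)
        p = sc.survival_probability(d_area, spec) if droplet_effect \
            else np.full(n, 0.4)
        n_cells = np.maximum(1, np.round(a_area / sc.CELL_FOOTPRINT_UM2)).astype(int)
        live = rng.binomial(n_cells, p)
        return pd.DataFrame({
            "aggregate_id": np.arange(n), "repeat": "0",
            "aggregate_area_um2": a_area, "host_droplet_id": np.arange(n),
            "droplet_area_um2": d_area,
            "live_area_um2": live * 1.0,
            "dead_area_um2": (n_cells - live) * 1.0,
            "survival_rate": live / n_cells,
        })

    def test_droplet_size_dominates_when_it_drives_survival(self):
        atab = self.synth_records(5000, seed=31)
        model = st.fit_contribution(atab)
        assert not model.separated
        assert model.droplet_dominates
        assert abs(model.beta_aggregate) <= 1.96 * model.se_aggregate + 0.05

    def test_constant_survival_null_coefficients(self):
        atab = self.synth_records(3000, seed=37, droplet_effect=False)
        model = st.fit_contribution(atab)
        assert abs(model.beta_droplet) <= 2.6 * model.se_droplet + 0.02
        assert abs(model.beta_aggregate) <= 2.6 * model.se_aggregate + 0.02

    def test_degenerate_predictors_raise(self):
        atab = self.synth_records(100, seed=1)
        atab["droplet_area_um2"] = 100.0
        with pytest.raises(st.FitError):
            st.fit_contribution(atab)


class TestOverallSurvival:
    def test_all_live(self):
        assert st.overall_survival(records([(50.0, 5.0, 5.0, 0.0, "a")])) == 1.0

    def test_pooled_ratio(self):
        df = records([(50.0, 100.0, 20.0, 80.0, "a")])
        assert st.overall_survival(df) == pytest.approx(0.2)

    def test_zero_denominator_raises(self):
        with pytest.raises(ValueError):
            st.overall_survival(records([(50.0, 0.0, 0.0, 0.0, "a")]))
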