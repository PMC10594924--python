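"""Reading, missingness screening, EM imputation and reliability."""

import io

import numpy as np
import pandas as pd
import pytest

import ptsdcfa as pc
from ptsdcfa import dataprep as dp
from ptsdcfa.dataprep import Schema

from conftest import exact_moments_sample


def _csv(text: str) -> io.StringIO:
    return io.StringIO(text.strip() + "\n")


def _small_schema():
    return Schema(groups={"PCL": ("PCL1", "PCL2"), "K10": ("K10_1",)},
                  ranges={"PCL": (0, 4), "K10": (1, 5)})


class TestReadDataset:
    def test_missing_tokens_become_mask(self):
        ds = dp.read_dataset(
            _csv("PCL1,PCL2,K10_1\n1,,3\n2,NA,4\n0,.,5"),
            schema=_small_schema())
        assert ds.n == 3
        assert ds.mask["PCL2"].all()
        assert not ds.mask["PCL1"].any()

    def test_out_of_range_names_cell(self):
        with pytest.raises(ValueError, match=r"PCL1.*row 1"):
            dp.read_dataset(_csv("PCL1,PCL2,K10_1\n1,2,3\n7,2,3"),
                            schema=_small_schema())

    def test_non_numeric_cell_reported(self):
        with pytest.raises(ValueError, match="PCL2"):
            dp.read_dataset(_csv("PCL1,PCL2,K10_1\n1,x,3\n1,2,3"),
                            schema=_small_schema())

    def test_missing_header_column(self):
        with pytest.raises(ValueError, match="K10_1"):
            dp.read_dataset(_csv("PCL1,PCL2\n1,2\n1,2"),
                            schema=_small_schema())

    def test_generator_round_trip(self, tmp_path, paper_dataset):
        ds, _ = paper_dataset
        path = tmp_path / "sim.csv"
        dp.write_dataset(ds, path)
        back = dp.read_dataset(path)
        assert back.n == 641
        pd.testing.assert_frame_equal(back.values, ds.values)


class TestMissingnessSummary:
    def test_complete_data_tallies(self):
        ds = dp.read_dataset(_csv("PCL1,PCL2,K10_1\n1,2,3\n0,1,2"),
                             schema=_small_schema())
        summary = dp.missingness_summary(ds)
        assert summary.per_count["PCL"] == {0: 2}
        assert summary.mcar["PCL"] is None
        assert summary.overall_missing_fraction == 0.0

    def test_counting_missing_items(self):
        ds = dp.read_dataset(
            _csv("PCL1,PCL2,K10_1\n,,3\n1,2,4\n0,1,5"),
            schema=_small_schema())
        summary = dp.missingness_summary(ds)
        assert summary.per_count["PCL"][2] == 1
        assert summary.per_count["PCL"][0] == 2

    def test_all_missing_variable_rejected(self):
        ds = dp.DataSet.__new__(dp.DataSet)
        ds.values = pd.DataFrame({"PCL1": [np.nan, np.nan],
                                  "PCL2": [1.0, 2.0], "K10_1": [3.0, 4.0]})
        ds.schema = _small_schema()
        with pytest.raises(ValueError, match="PCL1"):
            dp.missingness_summary(ds)

    def test_little_test_calibration_under_mcar(self):
        """Under true MCAR on normal data the test rejects at ~alpha."""
        rng = np.random.default_rng(31)
        p, n, reps, alpha = 5, 400, 250, 0.05
        cov = 0.4 + 0.6 * np.eye(p)
        rejections = 0
        for _ in range(reps):
            x = rng.multivariate_normal(np.zeros(p), cov, size=n)
            x[rng.random(x.shape) < 0.10] = np.nan
            res = dp.little_mcar_test(x)
            rejections += res.p_value < alpha
        assert 0.02 <= rejections / reps <= 0.09


class TestEMImpute:
    def test_complete_data_unchanged(self, continuous_dataset):
        ds, _ = continuous_dataset
        out = dp.em_impute(ds)
        pd.testing.assert_frame_equal(out.values, ds.values)

    def test_em_moments_match_sample_on_complete_data(self):
        x = exact_moments_sample([1.0, -1.0], [[2.0, 0.3], [0.3, 1.0]],
                                 n=200, seed=5)
        mu, sigma, _ = dp.em_mvn(x)
        assert np.allclose(mu, [1.0, -1.0], atol=1e-8)
        assert np.allclose(sigma, np.array([[2.0, 0.3], [0.3, 1.0]]) * 199 / 200,
                           atol=1e-8)

    def test_bivariate_conditional_mean(self):
        """With moments mu=0, Sigma=[[1,.5],[.5,1]], a missing x2 given
        x1=2 imputes to 0.5*2 = 1."""
        x = exact_moments_sample([0.0, 0.0], [[1.0, 0.5], [0.5, 1.0]],
                                 n=2000, seed=6)
        x = np.vstack([x, [2.0, np.nan]])
        ds = dp.DataSet.__new__(dp.DataSet)
        ds.values = pd.DataFrame(x, columns=["PCL1", "PCL2"])
        ds.schema = Schema(groups={"G": ("PCL1", "PCL2")},
                           ranges={"G": (-np.inf, np.inf)})
        out = dp.em_impute(ds)
        assert out.values.iloc[-1, 1] == pytest.approx(1.0, abs=0.05)
        # observed cells untouched
        assert np.array_equal(out.values.to_numpy()[:-1], x[:-1])

    def test_observed_cells_never_altered(self, paper_dataset):
        ds, _ = paper_dataset
        out = dp.em_impute(ds)
        obs = ~ds.mask.to_numpy()
        assert np.array_equal(out.values.to_numpy()[obs],
                              ds.values.to_numpy()[obs])
        assert out.complete

    def test_em_beats_listwise_deletion(self):
        """EM covariance is closer (Frobenius) to the complete-data
        covariance than the listwise estimate under 15% MCAR."""
        from dataclasses import replace
        from ptsdcfa import simulate as sim

        cols = [f"PCL{i}" for i in range(1, 9)]
        wins = 0
        reps = 20
        for r in range(reps):
            cfg = replace(sim.preset("continuous", seed=9000 + r))
            ds, _ = sim.generate(cfg)
            x = ds.values[cols].to_numpy()
            rng = np.random.default_rng(100 + r)
            xm = x.copy()
            xm[rng.random(x.shape) < 0.15] = np.nan
            complete_cov = np.cov(x, rowvar=False, bias=True)
            _, em_cov, _ = dp.em_mvn(xm)
            listwise = xm[~np.isnan(xm).any(axis=1)]
            lw_cov = np.cov(listwise, rowvar=False, bias=True)
            wins += (np.linalg.norm(em_cov - complete_cov)
                     < np.linalg.norm(lw_cov - complete_cov))
        assert wins >= 0.9 * reps

    def test_warns_above_30_percent_missing(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((200, 3))
        x[rng.random(200) < 0.5, 0] = np.nan
        ds = dp.DataSet.__new__(dp.DataSet)
        ds.values = pd.DataFrame(x, columns=["a", "b", "c"])
        ds.schema = Schema(groups={"G": ("a", "b", "c")},
                           ranges={"G": (-np.inf, np.inf)})
        with pytest.warns(UserWarning, match="30%"):
            dp.em_impute(ds)


class TestReliabilityAndDescriptives:
    def test_alpha_parallel_items_spearman_brown(self):
        """k=10 parallel items with pairwise correlation 0.5:
        alpha = 10*0.5 / (1 + 9*0.5) ~ 0.909."""
        k = 10
        cov = np.full((k, k), 0.5)
        np.fill_diagonal(cov, 1.0)
        x = exact_moments_sample(np.zeros(k), cov, n=500, seed=7)
        ds = dp.DataSet.__new__(dp.DataSet)
        ds.values = pd.DataFrame(x, columns=[f"i{j}" for j in range(k)])
        ds.schema = Schema(groups={"G": tuple(ds.values.columns)},
                           ranges={"G": (-np.inf, np.inf)})
        alpha = dp.cronbach_alpha(ds, ds.values.columns)
        assert alpha == pytest.approx(10 * 0.5 / (1 + 9 * 0.5), abs=1e-9)

    def test_alpha_boundary_cases(self):
        x = exact_moments_sample([0, 0], np.eye(2), n=100, seed=8)
        ds = dp.DataSet.__new__(dp.DataSet)
        ds.values = pd.DataFrame(
            {"a": x[:, 0], "b": x[:, 0], "c": x[:, 1]})
        ds.schema = Schema(groups={"G": ("a", "b", "c")},
                           ranges={"G": (-np.inf, np.inf)})
        assert dp.cronbach_alpha(ds, ["a", "b"]) == pytest.approx(1.0)
        assert dp.cronbach_alpha(ds, ["a", "c"]) == pytest.approx(0.0, abs=1e-12)
        # relabeling invariance
        assert dp.cronbach_alpha(ds, ["c", "a"]) == pytest.approx(
            dp.cronbach_alpha(ds, ["a", "c"]))

    def test_alpha_improves_without_noise_item(self):
        k = 5
        cov = np.full((k, k), 0.5)
        np.fill_diagonal(cov, 1.0)
        x = exact_moments_sample(np.zeros(k), cov, n=300, seed=9)
        noise = exact_moments_sample([0.0], [[1.0]], n=300, seed=10)
        ds = dp.DataSet.__new__(dp.DataSet)
        ds.values = pd.DataFrame(
            np.column_stack([x, noise]),
            columns=[f"i{j}" for j in range(k)] + ["noise"])
        ds.schema = Schema(groups={"G": tuple(ds.values.columns)},
                           ranges={"G": (-np.inf, np.inf)})
        with_noise = dp.cronbach_alpha(ds, ds.values.columns)
        without = dp.cronbach_alpha(ds, [f"i{j}" for j in range(k)])
        assert without > with_noise

    def test_scale_descriptives_arithmetic(self):
        ds = dp.DataSet.__new__(dp.DataSet)
        ds.values = pd.DataFrame({"a": [4.0, 20.0], "b": [6.0, 10.0]})
        ds.schema = Schema(groups={"G": ("a", "b")}, ranges={"G": (0, 30)})
        desc = dp.scale_descriptives(ds, ["a", "b"])
        assert desc["mean"] == pytest.approx(20.0)
        assert desc["sd"] == pytest.approx(np.sqrt(200.0))
        assert (desc["min"], desc["max"]) == (10.0, 30.0)

    def test_simulated_pcl_total_near_reference_mean(self, paper_imputed):
        """The default Likert thresholds put the PCL total near the
        reference sample mean of 26."""
        ds, _ = paper_imputed
        desc = dp.scale_descriptives(ds, [f"PCL{i}" for i in range(1, 21)])
        assert 24.0 <= desc["mean"] <= 28.0
        alpha = dp.cronbach_alpha(ds, [f"PCL{i}" for i in range(1, 21)])
        assert alpha > 0.85
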