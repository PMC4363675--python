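"""Local and granularity-hybrid calibration workflows."""

import json

import numpy as np
import pandas as pd
import pytest

import granupls as g

GRID = g.WavenumberGrid(start=10000.0, stop=4000.0, step=30.0)


def make_data(seed, n_samples=18, effect=None, noise=0.004):
    cfg = g.SimulationConfig(
        grid=GRID, n_samples=n_samples, seed=seed, noise_sd=noise,
        granularity_effect=effect or g.GranularityEffect())
    return g.generate_dataset(cfg)


CFG = g.ExperimentConfig(pipelines=("RAW", "MSC"), n_cal=12, max_lv=5)


@pytest.fixture(scope="module")
def data():
    return make_data(seed=7)


@pytest.fixture(scope="module")
def local_report(data):
    return g.run_local_models(data, CFG)


@pytest.fixture(scope="module")
def gh_report(data):
    return g.run_gh_model(data, CFG)


class TestLocalModels:
    def test_one_row_per_class_with_expected_columns(self, local_report):
        t = local_report.table
        assert sorted(t["mesh"]) == [40, 65, 80, 100]
        assert list(t.columns) == ["mesh", "pipeline", "LVs", "RMSECV",
                                   "R_CV", "RMSEP", "R_P", "RPD"]

    def test_rpd_identity_every_row(self, local_report):
        for mesh, row in local_report.table.set_index("mesh").iterrows():
            y = local_report.predictions[f"mesh{mesh}"]["reference"]
            assert row["RPD"] == pytest.approx(
                np.std(y, ddof=1) / row["RMSEP"], abs=1e-4)

    def test_cross_matrix_diagonal_is_matched_granularity(self, local_report):
        cross = local_report.extras["cross_rmsep"]
        # a model predicts its own granularity better than the average
        # mismatched one
        for mesh in cross.index:
            own = cross.loc[mesh, mesh]
            others = cross.loc[mesh].drop(mesh).mean()
            assert own < others

    def test_noisiest_class_has_worst_own_model(self):
        """Extra noise injected into the coarsest class surfaces as the
        largest own-validation RMSEP for that class's local model."""
        wins = 0
        for seed in range(5):
            ds = make_data(seed=100 + seed)
            rng = np.random.default_rng(seed)
            noisy = ds.intensities.copy()
            rows = ds.mesh == 40
            noisy[rows] += rng.normal(0, 0.05, size=noisy[rows].shape)
            ds = g.SpectraSet(ds.grid, noisy, ds.concentrations, ds.mesh,
                              ds.sample_ids, ds.replicate)
            t = g.run_local_models(ds, CFG).table.set_index("mesh")
            wins += t.loc[40, "RMSEP"] == t["RMSEP"].max()
        assert wins >= 4

    def test_class_too_small_is_skipped(self, data):
        cfg = g.ExperimentConfig(pipelines=("RAW",), n_cal=50, max_lv=3)
        rep = g.run_local_models(data, cfg)
        assert rep.table.empty


class TestGHModel:
    def test_pooled_calibration_count(self, gh_report):
        assert gh_report.extras["n_cal_pooled"] == 4 * CFG.n_cal

    def test_per_class_validation_columns(self, gh_report):
        t = gh_report.table
        for mesh in (40, 65, 80, 100):
            assert {f"RMSEP_{mesh}", f"R_P_{mesh}", f"RPD_{mesh}"} <= set(t.columns)

    def test_best_pipeline_has_minimum_press(self, gh_report):
        ok = gh_report.table[gh_report.table["status"] == "ok"]
        best_row = ok.loc[ok["min_press"].idxmin()]
        assert best_row["pipeline"] == gh_report.best_pipeline
        assert bool(best_row["best"])

    def test_rpd_identity_every_cell(self, gh_report):
        for _, row in gh_report.table.iterrows():
            if row["status"] != "ok":
                continue
            for mesh in (40, 65, 80, 100):
                y = gh_report.predictions[f"{row['pipeline']}|mesh{mesh}"]["reference"]
                assert row[f"RPD_{mesh}"] == pytest.approx(
                    np.std(y, ddof=1) / row[f"RMSEP_{mesh}"], abs=1e-4)

    def test_effect_off_gh_matches_locals(self):
        """With the granularity effect switched off the pooled model adds
        no information: GH and local mean RMSEPs are comparable."""
        ds = make_data(seed=21, effect=g.GranularityEffect(0.0, 0.0))
        res = g.gh_vs_local_mean_rmsep(ds, CFG, pipeline="RAW")
        for mesh, lm in res["local_mean_rmsep"].items():
            assert res["gh_mean_rmsep"] < 3 * lm
            assert lm < 3 * res["gh_mean_rmsep"]

    def test_effect_on_gh_beats_locals(self, data):
        res = g.gh_vs_local_mean_rmsep(data, CFG, pipeline="RAW")
        assert all(res["gh_mean_rmsep"] <= lm
                   for lm in res["local_mean_rmsep"].values())


class TestGridSearch:
    def test_single_pipeline_single_row(self, data):
        avg = g.average_replicates(data)
        cfg = g.ExperimentConfig(pipelines=("RAW",), n_cal=12, max_lv=4)
        rep = g.grid_search_preprocessing(
            avg.intensities, avg.concentrations, avg.grid, cfg)
        assert len(rep.table) == 1
        assert rep.best_pipeline == "RAW"

    def test_duplicates_deduplicated(self, data):
        avg = g.average_replicates(data)
        cfg = g.ExperimentConfig(pipelines=("RAW", "raw", "MSC"), n_cal=12,
                                 max_lv=4)
        rep = g.grid_search_preprocessing(
            avg.intensities, avg.concentrations, avg.grid, cfg)
        assert list(rep.table["pipeline"]).count("RAW") == 1

    def test_failed_pipeline_recorded_not_fatal(self):
        cfg = g.ExperimentConfig(pipelines=("SNV", "RAW"), max_lv=2)
        X = np.tile(np.full(GRID.n_points, 0.4), (8, 1))
        X[:, 0] += np.arange(8) * 0.01  # constant rows except one channel
        X[0] = 0.4  # exactly constant spectrum: SNV must fail
        y = np.linspace(2, 5, 8)
        rep = g.grid_search_preprocessing(X, y, GRID, cfg)
        status = rep.table.set_index("pipeline")["status"]
        assert status["SNV"].startswith("failed")
        assert status["RAW"] == "ok"

    def test_scatter_correction_ranks_above_raw_under_strong_scatter(self):
        """Strong multiplicative granularity scatter favours MSC by PRESS."""
        wins = 0
        for seed in range(5):
            ds = make_data(seed=300 + seed,
                           effect=g.GranularityEffect(0.4, 0.02))
            avg = g.average_replicates(ds)
            cfg = g.ExperimentConfig(pipelines=("RAW", "MSC"), max_lv=5)
            rep = g.grid_search_preprocessing(
                avg.intensities, avg.concentrations, avg.grid, cfg)
            wins += rep.best_pipeline == "MSC"
        assert wins >= 4


class TestRender:
    def test_round_trip_and_recomputable_rpd(self, gh_report, tmp_path):
        files = g.render_report(gh_report, tmp_path, prefix="gh")
        table = pd.read_csv(tmp_path / "gh_table.csv")
        orig = gh_report.table.reset_index(drop=True)
        for col in ("RMSECV", "RMSEP_65", "RPD_65"):
            assert np.allclose(table[col], orig[col].astype(float), rtol=1e-10)
        # RPD recomputable from RMSEP and validation SD
        y = pd.read_csv([f for f in files if "mesh65" in str(f)][0])
        sd = np.std(gh_report.predictions[
            f"{orig.iloc[0]['pipeline']}|mesh65"]["reference"], ddof=1)
        assert table.iloc[0]["RPD_65"] == pytest.approx(
            sd / table.iloc[0]["RMSEP_65"], rel=1e-9)

    def test_empty_report_valid_files(self, tmp_path):
        empty = g.EvaluationReport(kind="local", table=pd.DataFrame(
            columns=["mesh", "RMSEP"]))
        g.render_report(empty, tmp_path, prefix="empty")
        assert pd.read_csv(tmp_path / "empty_table.csv").empty
        doc = json.loads((tmp_path / "empty_table.json").read_text())
        assert doc["rows"] == []

    def test_end_to_end_determinism(self, tmp_path):
        """Identical config + seed produce byte-identical report files."""
        outs = []
        for run in ("r1", "r2"):
            ds = make_data(seed=5)
            rep = g.run_gh_model(ds, CFG)
            g.render_report(rep, tmp_path / run, prefix="gh")
            outs.append((tmp_path / run / "gh_table.csv").read_bytes())
        assert outs[0] == outs[1]
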