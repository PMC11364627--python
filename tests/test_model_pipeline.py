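import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

import resptypes as rt
from resptypes.cli import main as cli_main
from resptypes.pipeline import (
    PipelineConfig,
    run_pipeline,
    simulate_files,
    stage_cluster,
)


@pytest.fixture(scope="module")
def sim_dir(tmp_path_factory):
    """Synthetic 3-type, 6-country population written to disk with indices."""
    outdir = tmp_path_factory.mktemp("sim")
    profiles = rt.load_fixture("table2").loc[[3, 6, 7]]
    rng = np.random.default_rng(2024)
    countries = [f"C{i:02d}" for i in range(6)]
    fps = {c: rng.dirichlet(np.ones(3) * 5) for c in countries}
    npc = {c: 80 for c in countries}
    cfg = rt.GeneratorConfig(profiles=profiles, country_fingerprints=fps,
                             n_per_country=npc, missing_rate=0.02, seed=777)
    artefacts = simulate_files(cfg, outdir, index_targets={"CO2": (1, 0.9),
                                                           "EPI": (2, -0.7),
                                                           "GBI": (3, 0.0),
                                                           "NIS": (1, 0.5),
                                                           "LPI": (2, 0.3)})
    return outdir, cfg, artefacts


def _config(sim_dir_path, outdir, **kw):
    defaults = dict(
        responses=str(sim_dir_path / "responses.csv"),
        indices=str(sim_dir_path / "indices.csv"),
        outdir=str(outdir), k=3, min_country_n=25, seed=11,
    )
    defaults.update(kw)
    return PipelineConfig(**defaults)


class TestSimulateFiles:
    def test_artifact_shapes(self, sim_dir):
        outdir, cfg, artefacts = sim_dir
        resp = rt.read_responses(artefacts["responses"])
        assert len(resp) == 480
        truth = pd.read_csv(artefacts["truth_labels"])
        assert set(truth["label"]) == {3, 6, 7}
        idx = rt.read_index_table(artefacts["indices"])
        assert idx.shape == (6, 5)

    def test_survey_sized_population(self, tmp_path):
        t1 = rt.load_fixture("table1")
        rng = np.random.default_rng(0)
        cfg = rt.GeneratorConfig(
            country_fingerprints={c: rng.dirichlet(np.ones(8)) for c in t1.index},
            n_per_country={c: int(t1.loc[c, "n"]) for c in t1.index},
            missing_rate=0.02, seed=31,
        )
        arts = simulate_files(cfg, tmp_path)
        resp = rt.read_responses(arts["responses"])
        assert len(resp) == 4441
        assert resp["country"].nunique() == 37


class TestModel:
    def test_fit_summary_and_save(self, sim_dir, tmp_path):
        outdir, cfg, artefacts = sim_dir
        model = rt.ResponseTypeModel.from_csv(artefacts["responses"], seed=5)
        res = model.fit(k=3)
        assert res.k == 3 and res.gap is None
        assert sorted(np.unique(res.labels)) == [1, 2, 3]
        assert res.profiles["size"].sum() == 480
        # deterministic numbering: descending discrimination
        assert (res.profiles["discrimination_mean"].diff().dropna() <= 0).all()
        text = res.summary()
        assert "response types (k): 3" in text
        paths = res.save(tmp_path / "fit")
        assert paths["profiles"].exists() and paths["tree"].exists()

    def test_profile_recovery_of_distinct_types(self, sim_dir):
        """Types 3, 6, 7 are mutually distant; a k=3 fit recovers their means."""
        outdir, cfg, artefacts = sim_dir
        model = rt.ResponseTypeModel.from_csv(artefacts["responses"], seed=5)
        res = model.fit(k=3)
        mapping, dists = res.match_to(cfg.profiles.assign(size=1))
        assert sorted(mapping.values()) == [3, 6, 7]
        prof = res.profiles.rename(index=mapping)
        assert prof.loc[7, "invasive_species_mean"] == pytest.approx(1.33, abs=0.25)
        assert prof.loc[3, "discrimination_mean"] == pytest.approx(-0.33, abs=0.3)

    def test_small_country_excluded_with_warning(self, sim_dir):
        outdir, cfg, artefacts = sim_dir
        data = rt.read_responses(artefacts["responses"])
        tiny = data.iloc[:10].copy()
        tiny["country"] = "TIN"
        data = pd.concat([data, tiny], ignore_index=True)
        model = rt.ResponseTypeModel(data, seed=5)
        with pytest.warns(UserWarning, match="TIN"):
            res = model.fit(k=3)
        assert "TIN" not in res.fingerprints.index
        assert len(res.labels) == len(data)  # clustering used every record

    def test_correlate_from_results(self, sim_dir):
        outdir, cfg, artefacts = sim_dir
        model = rt.ResponseTypeModel.from_csv(artefacts["responses"], seed=5)
        res = model.fit(k=3)
        cells = res.correlate(rt.read_index_table(artefacts["indices"]))
        assert len(cells) == 3 * 5
        # CO2 was built as a strong monotone companion of the type-1 component
        mapping, _ = res.match_to(cfg.profiles.assign(size=1))
        inv = {v: k for k, v in mapping.items()}
        cell = cells[(cells.type_id == inv[3]) & (cells["index"] == "CO2")].iloc[0]
        assert cell.r > 0.3


class TestPipeline:
    def test_end_to_end_artifacts_and_log(self, sim_dir, tmp_path):
        outdir, cfg, artefacts = sim_dir
        config = _config(outdir, tmp_path / "run")
        arts = run_pipeline(config)
        for key in ("features", "labels", "profiles", "fingerprints",
                    "distances", "tree", "associations", "log"):
            assert Path(arts[key]).exists(), key
        log = json.loads(Path(arts["log"]).read_text())
        stages = [line["stage"] for line in log]
        assert stages == ["config", "preprocess", "cluster", "fingerprint",
                          "correlate"]
        fps = rt.io.read_fingerprints(arts["fingerprints"])
        np.testing.assert_allclose(fps.sum(axis=1), 1.0, atol=1e-9)

    def test_determinism_byte_identical(self, sim_dir, tmp_path):
        outdir, cfg, artefacts = sim_dir
        arts1 = run_pipeline(_config(outdir, tmp_path / "a"))
        arts2 = run_pipeline(_config(outdir, tmp_path / "b"))
        for key in ("features", "labels", "profiles", "fingerprints", "tree"):
            b1 = Path(arts1[key]).read_bytes()
            b2 = Path(arts2[key]).read_bytes()
            assert b1 == b2, key

    def test_stage_resumable(self, sim_dir, tmp_path):
        """Re-running the clustering stage from written intermediates is a no-op."""
        outdir, cfg, artefacts = sim_dir
        config = _config(outdir, tmp_path / "run")
        arts = run_pipeline(config)
        before = Path(arts["labels"]).read_bytes()
        stage_cluster(config)
        assert Path(arts["labels"]).read_bytes() == before

    def test_small_country_logged(self, sim_dir, tmp_path):
        outdir, cfg, artefacts = sim_dir
        data = rt.read_responses(artefacts["responses"])
        tiny = data.iloc[:10].copy()
        tiny["country"] = "TIN"
        resp_path = tmp_path / "responses.csv"
        rt.io.write_responses(pd.concat([data, tiny], ignore_index=True), resp_path)
        config = _config(outdir, tmp_path / "run", responses=str(resp_path))
        arts = run_pipeline(config)
        fps = rt.io.read_fingerprints(arts["fingerprints"])
        assert "TIN" not in fps.index
        labels = pd.read_csv(arts["labels"])
        assert (labels["country"] == "TIN").sum() == 10
        log = json.loads(Path(arts["log"]).read_text())
        fp_line = next(l for l in log if l["stage"] == "fingerprint")
        assert fp_line["excluded_below_min_n"] == ["TIN"]

    def test_failure_names_stage(self, tmp_path):
        bad = tmp_path / "missing.csv"
        config = PipelineConfig(responses=str(bad), outdir=str(tmp_path / "o"),
                                k=2, seed=0)
        with pytest.raises(RuntimeError, match="preprocess"):
            run_pipeline(config)


class TestCli:
    def test_simulate_and_run_all(self, tmp_path):
        runner = CliRunner()
        sim = tmp_path / "sim"
        r = runner.invoke(cli_main, ["simulate", "--outdir", str(sim),
                                     "--n", "300", "--seed", "3"])
        assert r.exit_code == 0, r.output
        assert (sim / "responses.csv").exists()
        out = tmp_path / "run"
        r = runner.invoke(cli_main, [
            "run-all", "--responses", str(sim / "responses.csv"),
            "--outdir", str(out), "--k", "3", "--min-country-n", "1",
            "--seed", "4",
        ])
        assert r.exit_code == 0, r.output
        assert (out / "profiles.csv").exists()
        assert len(pd.read_csv(out / "profiles.csv")) == 3

    def test_config_file_with_cli_override(self, sim_dir, tmp_path):
        outdir, cfg, artefacts = sim_dir
        cfg_path = tmp_path / "cfg.yaml"
        cfg_path.write_text(
            "responses: {r}\noutdir: {o}\nk: 3\nmin_country_n: 25\nseed: 11\n".format(
                r=artefacts["responses"], o=tmp_path / "from_yaml"
            )
        )
        runner = CliRunner()
        r = runner.invoke(cli_main, ["run-all", "--config", str(cfg_path),
                                     "--k", "2"])
        assert r.exit_code == 0, r.output
        assert len(pd.read_csv(tmp_path / "from_yaml" / "profiles.csv")) == 2
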