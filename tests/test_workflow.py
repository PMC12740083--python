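"""End-to-end runs from a config file, figures, and the CLI."""

import json

import numpy as np
import pytest
import yaml
from click.testing import CliRunner

import stratashift as ss
from stratashift.cli import main as cli_main
from stratashift.errors import ConfigurationError


@pytest.fixture()
def run_setup(tmp_path):
    """Two synthetic datasets (one null, one ancient-biased) on disk."""
    base = ss.SyntheticConfig(universe_size=3000, n_deg=250, seed=21)
    bundle = ss.make_bundle(base, name="null_set")
    bundle.write(tmp_path / "null")
    cfg = {
        "gene_ages": str(tmp_path / "null" / "universe.tsv"),
        "outdir": str(tmp_path / "results"),
        "datasets": [
            {"name": "null_set", "path": str(tmp_path / "null" / "degs.tsv")},
            {"name": "ancient_set", "path": str(tmp_path / "ancient_degs.tsv")},
        ],
    }
    # the biased set must come from the same universe to be fully mapped
    deg2 = ss.sample_deg_set(
        bundle.gene_ages, ss.SyntheticConfig(universe_size=3000, n_deg=250, beta=0.6, seed=22)
    )
    deg2.records[["gene", "direction", "effect"]].rename(columns={"effect": "logfc"}).to_csv(
        tmp_path / "ancient_degs.tsv", sep="\t", index=False
    )
    cfg_path = tmp_path / "run.yaml"
    cfg_path.write_text(yaml.safe_dump(cfg))
    return cfg_path, tmp_path


class TestRunAnalysis:
    def test_two_datasets_complete(self, run_setup):
        cfg_path, tmp_path = run_setup
        result = ss.run_analysis(ss.RunConfig.from_yaml(cfg_path))
        assert set(result.enrichment) == {"null_set", "ancient_set"}
        assert set(result.manifest["datasets"]) == {"null_set", "ancient_set"}
        assert all(d["status"] == "ok" for d in result.manifest["datasets"].values())
        outdir = tmp_path / "results"
        for name in ("null_set", "ancient_set"):
            for scope in ("combined", "up", "down"):
                assert (outdir / name / f"enrichment_{scope}.tsv").exists()
            assert (outdir / name / "age_shift.tsv").exists()
            assert (outdir / name / "enrichment.svg").exists()
        assert (outdir / "age_shift_summary.tsv").exists()
        assert (outdir / "heterogeneity.tsv").exists()
        assert (outdir / "manifest.json").exists()
        # the biased dataset shifts ancient; the null one is mild
        assert result.age_shifts["ancient_set"].mean_shift < result.age_shifts["null_set"].mean_shift

    def test_unreadable_dataset_isolated(self, run_setup):
        cfg_path, tmp_path = run_setup
        cfg = yaml.safe_load(cfg_path.read_text())
        cfg["datasets"].append({"name": "ghost", "path": str(tmp_path / "missing.tsv")})
        cfg_path.write_text(yaml.safe_dump(cfg))
        result = ss.run_analysis(ss.RunConfig.from_yaml(cfg_path))
        assert result.manifest["datasets"]["ghost"]["status"] == "failed"
        assert result.manifest["datasets"]["null_set"]["status"] == "ok"

    def test_deterministic_outputs(self, run_setup, tmp_path):
        cfg_path, base = run_setup
        cfg = yaml.safe_load(cfg_path.read_text())
        outs = []
        for run in ("r1", "r2"):
            cfg["outdir"] = str(tmp_path / run)
            p = tmp_path / f"{run}.yaml"
            p.write_text(yaml.safe_dump(cfg))
            ss.run_analysis(ss.RunConfig.from_yaml(p))
            outs.append(tmp_path / run)
        for rel in (
            "age_shift_summary.tsv",
            "heterogeneity.tsv",
            "manifest.json",
            "null_set/enrichment_combined.tsv",
        ):
            assert (outs[0] / rel).read_bytes() == (outs[1] / rel).read_bytes()

    def test_duplicate_dataset_names_rejected(self, run_setup):
        cfg_path, _ = run_setup
        cfg = yaml.safe_load(cfg_path.read_text())
        cfg["datasets"].append(dict(cfg["datasets"][0]))
        cfg_path.write_text(yaml.safe_dump(cfg))
        with pytest.raises(ConfigurationError):
            ss.RunConfig.from_yaml(cfg_path)

    def test_summary_tsv_regenerates_from_serialized_tables(self, run_setup):
        cfg_path, tmp_path = run_setup
        result = ss.run_analysis(ss.RunConfig.from_yaml(cfg_path))
        for name, tables in result.enrichment.items():
            path = tmp_path / "results" / name / "enrichment_combined.tsv"
            back = ss.EnrichmentResults.from_tsv(path, dataset=name)
            assert np.allclose(
                back.table["q_over"], tables["combined"].table["q_over"], atol=1e-12
            )
            assert (back.table["flag"] == tables["combined"].table["flag"]).all()


class TestBarChart:
    def test_flag_passthrough_and_file_written(self, tmp_path, small_bundle, small_universe):
        parts = small_bundle.deg_set.partition()
        up = ss.StratumEnrichment(parts["up"], small_universe, scope="up").fit()
        down = ss.StratumEnrichment(parts["down"], small_universe, scope="down").fit()
        flags = ["over"] + ["none"] * 18
        out = ss.plotting.render_barchart(
            up, down, small_universe, flags=flags, path=tmp_path / "fig.svg"
        )
        assert out.exists() and out.stat().st_size > 0

    def test_empty_down_series_still_renders(self, tmp_path, small_universe):
        import pandas as pd

        rec = pd.DataFrame(
            {"gene": ["A", "B"], "direction": "up", "effect": 1.0, "rank": [1, 2]}
        )
        deg = ss.DEGSet(name="t", records=rec, n_unmapped=0, intersected=True)
        up = ss.StratumEnrichment(deg, small_universe, scope="up").fit()
        down_table = up.table.copy()
        down_table["k"] = 0
        down_table["n"] = 0
        down = ss.EnrichmentResults(dataset="t", scope="down", alpha=0.05, table=down_table)
        out = ss.plotting.render_barchart(up, down, small_universe, path=tmp_path / "f.svg")
        assert out.exists()


class TestCli:
    def test_simulate_then_analyze(self, tmp_path):
        runner = CliRunner()
        sim = runner.invoke(
            cli_main,
            ["simulate", "--out", str(tmp_path / "bundle"), "--universe-size", "2000",
             "--n-deg", "150", "--beta", "0.5", "--seed", "4"],
        )
        assert sim.exit_code == 0, sim.output
        cfg = {
            "gene_ages": str(tmp_path / "bundle" / "universe.tsv"),
            "outdir": str(tmp_path / "out"),
            "datasets": [{"name": "sim", "path": str(tmp_path / "bundle" / "degs.tsv")}],
        }
        cfg_path = tmp_path / "cfg.yaml"
        cfg_path.write_text(yaml.safe_dump(cfg))
        run = runner.invoke(cli_main, ["analyze", str(cfg_path)])
        assert run.exit_code == 0, run.output
        assert "analyzed 1 dataset(s)" in run.output
        assert "mean age shift" in run.output

    def test_calibrate_null_report(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "cal.json"
        res = runner.invoke(
            cli_main,
            ["calibrate", "--out", str(out), "--replicates", "20", "--universe-size", "2000",
             "--n-deg", "100", "--seed", "1"],
        )
        assert res.exit_code == 0, res.output
        payload = json.loads(out.read_text())
        assert payload["mode"] == "null"
        assert len(payload["per_stratum"]) == 19

    def test_plot_subcommand(self, tmp_path, small_bundle, small_universe):
        parts = small_bundle.deg_set.partition()
        paths = {}
        for scope, subset in (("up", parts["up"]), ("down", parts["down"]),
                              ("combined", small_bundle.deg_set)):
            res = ss.StratumEnrichment(subset, small_universe, scope=scope).fit()
            paths[scope] = tmp_path / f"{scope}.tsv"
            res.to_tsv(paths[scope])
        runner = CliRunner()
        out = tmp_path / "fig.svg"
        res = runner.invoke(
            cli_main,
            ["plot", "--up", str(paths["up"]), "--down", str(paths["down"]),
             "--combined", str(paths["combined"]), "-o", str(out)],
        )
        assert res.exit_code == 0, res.output
        assert out.exists()
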