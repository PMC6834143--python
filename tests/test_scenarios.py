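import json

import numpy as np
import pandas as pd
import pytest
import yaml
from click.testing import CliRunner

import polyadmix as pa
from polyadmix.cli import main as cli_main


def tiny_cfg(**kw):
    base = dict(
        name="tiny", fraction_diff=1.0, prevalence_pop1=0.01, admixture=1.0,
        crossover_mean=36.0, generations=2, size=400, replicates=2, seed=5,
        mapping_samples=100_000, mapping_reps=2,
    )
    base.update(kw)
    return pa.ScenarioConfig(**base)


class TestConfig:
    def test_builtins_cover_the_five_experiment_families(self):
        scen = pa.builtin_scenarios()
        assert len(scen) >= 5
        assert any(c.fraction_diff is not None for c in scen.values())
        assert any(c.delta_prs is not None for c in scen.values())
        assert any(c.preset is not None for c in scen.values())
        assert any(c.therapy and c.therapy.mode == "single_shot" for c in scen.values())
        assert any(c.therapy and c.therapy.mode == "maintenance" for c in scen.values())

    def test_every_builtin_validates(self):
        for cfg in pa.builtin_scenarios().values():
            cfg.validate()

    def test_presets_carry_published_prevalences(self):
        assert pa.DISEASE_PRESETS["DD"].heritability == 0.80
        assert (pa.DISEASE_PRESETS["DD"].prevalence_high, pa.DISEASE_PRESETS["DD"].prevalence_low) == (0.25, 0.0025)
        assert pa.DISEASE_PRESETS["RA"].heritability == 0.60
        assert (pa.DISEASE_PRESETS["RA"].prevalence_high, pa.DISEASE_PRESETS["RA"].prevalence_low) == (0.030, 0.0030)
        assert pa.DISEASE_PRESETS["LE"].heritability == 0.44
        assert (pa.DISEASE_PRESETS["LE"].prevalence_high, pa.DISEASE_PRESETS["LE"].prevalence_low) == (0.0035, 0.0010)

    def test_conflicting_architecture_variants_rejected(self):
        with pytest.raises(pa.ConfigurationError, match="at most one"):
            tiny_cfg(fraction_diff=0.5, delta_prs=1.0).validate()

    def test_invalid_values_listed_in_error(self):
        cfg = tiny_cfg(fraction_diff=None)
        cfg.admixture = 1.5
        cfg.heritability = 2.0
        with pytest.raises(pa.ConfigurationError) as exc:
            cfg.validate()
        assert "admixture" in str(exc.value) and "heritability" in str(exc.value)

    def test_yaml_round_trip(self, tmp_path):
        doc = {
            "scenario": "from_yaml",
            "architecture": {"heritability": 0.6, "fraction_diff": 0.33},
            "populations": {"size": 500, "prevalence_pop1": 0.02},
            "evolution": {"admixture": 0.5, "generations": 3, "crossover_mean": 36},
            "therapy": {"mode": "single_shot", "target_prs": -1.0, "coverage": 0.5},
            "run": {"replicates": 2, "seed": 9},
        }
        path = tmp_path / "cfg.yaml"
        path.write_text(yaml.safe_dump(doc))
        cfg = pa.load_config(path)
        assert cfg.name == "from_yaml"
        assert cfg.heritability == 0.6 and cfg.fraction_diff == 0.33
        assert cfg.therapy.coverage == 0.5
        assert cfg.admixture == 0.5 and cfg.seed == 9

    def test_unknown_yaml_keys_rejected(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text(yaml.safe_dump({"architecture": {"heritabillity": 0.5}}))
        with pytest.raises(pa.ConfigurationError, match="heritabillity"):
            pa.load_config(path)


class TestRunScenario:
    def test_zero_generations_emits_initialization_only(self):
        res = pa.run_scenario(tiny_cfg(generations=0))
        assert set(res.stats.generation) == {0}
        assert set(res.stats["pop"]) == {"1", "2", "combined"}

    def test_same_seed_reproduces_outputs_bit_identically(self, tmp_path):
        a = pa.run_scenario(tiny_cfg(out_dir=str(tmp_path / "a")))
        b = pa.run_scenario(tiny_cfg(out_dir=str(tmp_path / "b")))
        assert (tmp_path / "a" / "stats.csv").read_bytes() == (tmp_path / "b" / "stats.csv").read_bytes()
        assert (tmp_path / "a" / "mapping.csv").read_bytes() == (tmp_path / "b" / "mapping.csv").read_bytes()

    def test_outputs_written_with_manifest(self, tmp_path):
        out = tmp_path / "run"
        res = pa.run_scenario(tiny_cfg(out_dir=str(out)))
        for name in ("stats.csv", "aggregate.csv", "mapping.csv", "architecture.csv", "manifest.json"):
            assert (out / name).exists()
        manifest = json.loads((out / "manifest.json").read_text())
        assert manifest["master_seed"] == 5
        assert manifest["architecture"]["n_loci"] == res.arch.n_loci

    def test_replicate_sd_matches_sample_sd(self):
        res = pa.run_scenario(tiny_cfg(replicates=3))
        g = res.stats[(res.stats.generation == 2) & (res.stats["pop"] == "combined")]
        agg = res.aggregate
        row = agg[(agg.generation == 2) & (agg["pop"] == "combined")].iloc[0]
        assert row["mean_prs_sd"] == pytest.approx(g["mean_prs"].std(ddof=1))

    def test_therapy_scenario_writes_edit_counts(self, tmp_path):
        cfg = tiny_cfg(
            fraction_diff=None, generations=2, out_dir=str(tmp_path / "t"),
            therapy=pa.TherapyPlan(mode="single_shot", target_delta_prs=-1.0),
        )
        res = pa.run_scenario(cfg)
        assert res.edits is not None
        assert set(res.edits.generation) == {1}  # single shot acts once
        assert (tmp_path / "t" / "edits.csv").exists()
        # pop 1 mean PRS dropped by at least the target at generation 1
        s = res.stats
        g0 = s[(s.generation == 0) & (s["pop"] == "1")]["mean_prs"].mean()
        g1 = s[(s.generation == 1) & (s["pop"] == "1")]["mean_prs"].mean()
        assert g0 - g1 > 1.0

    def test_maintenance_therapy_holds_level(self):
        cfg = tiny_cfg(
            fraction_diff=None, generations=4, size=800, admixture=0.0,
            therapy=pa.TherapyPlan(mode="maintenance", target_delta_prs=-1.5),
        )
        res = pa.run_scenario(cfg)
        level = res.arch.expected_mean_prs(1) - 1.5
        s = res.stats
        late = s[(s.generation >= 2) & (s["pop"] == "1")]["mean_prs"]
        assert np.allclose(late, level, atol=0.15)
        assert set(res.edits.generation) == {1, 2, 3, 4}  # top-ups every generation


class TestCli:
    def test_scenarios_listing(self):
        out = CliRunner().invoke(cli_main, ["scenarios"])
        assert out.exit_code == 0
        assert "equal_liability_diff100" in out.output
        assert "preset_ra" in out.output

    def test_simulate_from_yaml(self, tmp_path):
        doc = {
            "scenario": "cli_smoke",
            "architecture": {"fraction_diff": 1.0},
            "populations": {"size": 300, "prevalence_pop1": 0.01},
            "evolution": {"admixture": 1.0, "generations": 1},
            "run": {"replicates": 1, "seed": 3, "mapping_samples": 50_000, "mapping_reps": 2},
        }
        cfg_path = tmp_path / "cfg.yaml"
        cfg_path.write_text(yaml.safe_dump(doc))
        out_dir = tmp_path / "out"
        res = CliRunner().invoke(
            cli_main,
            ["simulate", "--config", str(cfg_path), "--out", str(out_dir)],
        )
        assert res.exit_code == 0, res.output
        assert (out_dir / "stats.csv").exists()
        assert "cli_smoke" in res.output

    def test_mapping_build(self, tmp_path):
        out_path = tmp_path / "map.csv"
        res = CliRunner().invoke(
            cli_main,
            ["mapping", "build", "--heritability", "0.5", "--prevalence", "0.01",
             "--samples", "100000", "--reps", "2", "--out", str(out_path)],
        )
        assert res.exit_code == 0, res.output
        table = pa.load_mapping(out_path)
        assert table.prevalence == 0.01
        assert np.all(np.diff(table.band_prob) >= -1e-12)

    def test_simulate_requires_exactly_one_source(self):
        res = CliRunner().invoke(cli_main, ["simulate"])
        assert res.exit_code != 0
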