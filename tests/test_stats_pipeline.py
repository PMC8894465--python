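import json

import networkx as nx
import numpy as np
import pytest

from commarch import pipeline, stats
from commarch.synthetic_networks import ModularSpec, generate_modular


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        r, p = stats.pearson(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p < 1e-6

    def test_perfect_inverse(self):
        x = np.arange(10.0)
        r, _ = stats.pearson(x, -x)
        assert r == pytest.approx(-1.0)

    def test_four_point_fixture_against_direct_formula(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        y = np.array([0.0, 1.0, 0.0, 1.0])
        r, _ = stats.pearson(x, y)
        direct = np.sum((x - x.mean()) * (y - y.mean())) / (
            np.sqrt(np.sum((x - x.mean()) ** 2)) * np.sqrt(np.sum((y - y.mean()) ** 2))
        )
        assert r == pytest.approx(direct, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            stats.pearson([1, 1, 1], [1, 2, 3])


class TestWelch:
    def test_hand_computed_3v3(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([2.0, 4.0, 9.0])
        t, p = stats.welch_t(a, b)
        sa2, sb2 = a.var(ddof=1) / 3, b.var(ddof=1) / 3
        expected_t = (a.mean() - b.mean()) / np.sqrt(sa2 + sb2)
        assert t == pytest.approx(expected_t, abs=1e-12)
        assert 0 < p <= 1

    def test_identical_distributions_t_near_zero(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        t, p = stats.welch_t(a, a.copy())
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError):
            stats.welch_t([1.0, 1.0], [1.0, 1.0])


class TestCompareGroups:
    def test_architecture_contrast_directions(self):
        # moderately segregated, overlap-rich networks vs strongly segregated ones
        moderate = [
            generate_modular(ModularSpec(N=60, M=4, p_in=0.45, p_out=0.10, seed=s))
            for s in range(6)
        ]
        segregated = [
            generate_modular(ModularSpec(N=60, M=4, p_in=0.95, p_out=0.02, seed=10 + s))
            for s in range(6)
        ]
        comp = stats.compare_groups(moderate, segregated, seed=3, n_null=5, louvain_runs=3)
        assert comp.segregation_a.mean() < comp.segregation_b.mean()
        assert comp.overlap_a.mean() > comp.overlap_b.mean()
        assert 0 < comp.p_segregation <= 1 and 0 < comp.p_overlap <= 1

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            stats.compare_groups([], [nx.complete_graph(4)])


class TestPipeline:
    def _tiny_config(self, tmp_path, seed=0):
        return {
            "seed": seed,
            "outdir": str(tmp_path / "out"),
            "stages": ["sweep"],
            "sweep": {
                "N": 20, "M": 4,
                "p_in_start": 0.6, "p_in_stop": 0.8, "p_in_step": 0.2,
                "p_out_start": 0.05, "p_out_stop": 0.15, "p_out_step": 0.1,
                "replicates": 2,
            },
        }

    def test_empty_stage_list_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            pipeline.run_pipeline({"stages": [], "outdir": str(tmp_path)})

    def test_unknown_stage_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            pipeline.run_pipeline({"stages": ["bogus"], "outdir": str(tmp_path)})

    def test_deterministic_outputs(self, tmp_path):
        cfg = self._tiny_config(tmp_path)
        pipeline.run_pipeline(cfg)
        first = (tmp_path / "out" / "sweep.tsv").read_bytes()
        summary1 = (tmp_path / "out" / "summary.json").read_bytes()
        pipeline.run_pipeline(cfg)
        assert (tmp_path / "out" / "sweep.tsv").read_bytes() == first
        assert (tmp_path / "out" / "summary.json").read_bytes() == summary1

    def test_summary_structure(self, tmp_path):
        cfg = self._tiny_config(tmp_path, seed=4)
        summary = pipeline.run_pipeline(cfg)
        on_disk = json.loads((tmp_path / "out" / "summary.json").read_text())
        assert on_disk == summary
        assert summary["stages"]["sweep"]["n_cells"] == 4
        assert "config_hash" in summary


class TestCLI:
    def test_segregate_and_overlap_roundtrip(self, tmp_path, bowtie):
        from click.testing import CliRunner

        from commarch.cli import main
        from commarch.graph_core import write_edge_list

        p = tmp_path / "bowtie.edges"
        write_edge_list(bowtie, p)
        runner = CliRunner()
        res = runner.invoke(main, ["segregate", str(p), "--seed", "1"])
        assert res.exit_code == 0, res.output
        out = json.loads(res.output)
        assert out["Q"] == pytest.approx(5 / 14, abs=1e-9)
        res = runner.invoke(main, ["overlap", str(p), "--nulls", "2", "--seed", "1"])
        assert res.exit_code == 0, res.output
        out = json.loads(res.output)
        assert out["overlap_score"] == pytest.approx(4 / 3, abs=1e-9)
        assert out["n_communities"] == 3
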