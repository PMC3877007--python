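import filecmp

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from chemopanel.cli import main
from chemopanel.interface import PipelineConfig, run_pipeline
from chemopanel.interface import io as cio
from chemopanel.profile_clustering import PotencyMatrix
from chemopanel.synth import PlateDesign, gen_plate_experiment


@pytest.fixture
def small_config() -> PipelineConfig:
    return PipelineConfig(
        seed=11,
        groups={"g1": ["A", "B"], "g2": ["C", "D"]},
        n_cell_lines=6,
        n_experiments=1,
        n_genes=40,
        n_terms=8,
    )


class TestPotencyTableIO:
    def test_round_trip_preserves_flags(self, tmp_path):
        values = pd.DataFrame(
            [[0.5, 30.0, np.nan], [1.25, 2.5, 10.0]],
            index=["cpdA", "cpdB"], columns=["l1", "l2", "l3"],
        )
        censored = pd.DataFrame(
            [[False, True, False], [False, False, True]],
            index=values.index, columns=values.columns,
        )
        pm = PotencyMatrix(values=values, censored=censored)
        path = tmp_path / "potency.tsv"
        cio.write_potency_table(pm, path, header_comment="round trip")
        back = cio.read_potency_table(path)
        pd.testing.assert_frame_equal(back.values, pm.values)
        pd.testing.assert_frame_equal(back.censored, pm.censored)

    def test_cell_parsing(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text("compound\tl1\tl2\ncpd\t0.5\t>30\n")
        pm = cio.read_potency_table(path)
        assert pm.values.at["cpd", "l1"] == pytest.approx(0.5)
        assert pm.values.at["cpd", "l2"] == pytest.approx(30.0)
        assert bool(pm.censored.at["cpd", "l2"])

    def test_malformed_cell_reports_coordinates(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text("compound\tl1\ncpd\toops\n")
        with pytest.raises(ValueError, match="row 2, column 2"):
            cio.read_potency_table(path)


class TestPlateCSVIO:
    def test_round_trip(self, tmp_path):
        design = PlateDesign(noise_cv=0.1)
        plates = [
            gen_plate_experiment(1.0, 1.2, design, seed=1, compound="A", cell_line="l1"),
            gen_plate_experiment(2.0, 0.9, design, seed=2, compound="B", cell_line="l2"),
        ]
        path = tmp_path / "plates.csv"
        cio.write_plate_csv(plates, path)
        back = cio.read_plate_csv(path)
        assert len(back) == 2
        by_cpd = {p.compound: p for p in back}
        for orig in plates:
            got = by_cpd[orig.compound]
            np.testing.assert_allclose(got.concentrations, orig.concentrations, rtol=1e-5)
            np.testing.assert_allclose(got.signals, orig.signals, rtol=1e-5)
            np.testing.assert_allclose(got.control_signals, orig.control_signals, rtol=1e-5)


class TestExpressionAnnotationIO:
    def test_expression_round_trip(self, tmp_path):
        em = pd.DataFrame(
            [[100.0, 200.0], [5000.0, 4000.0]],
            index=["g1", "g2"], columns=["l1", "l2"],
        )
        em.index.name = "gene"
        path = tmp_path / "expr.tsv"
        cio.write_expression_table(em, path, header_comment="x")
        back = cio.read_expression_table(path)
        pd.testing.assert_frame_equal(back, em)

    def test_annotation_round_trip(self, tmp_path):
        ann = {"g1": {"t1", "t2"}, "g2": set(), "g3": {"t1"}}
        path = tmp_path / "ann.tsv"
        cio.write_annotation_table(ann, path)
        back = cio.read_annotation_table(path)
        # genes without terms produce no rows
        assert back == {"g1": {"t1", "t2"}, "g3": {"t1"}}


class TestConfig:
    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError, match="unknown config keys"):
            PipelineConfig.from_dict({"bogus": 1})

    def test_hash_stable_and_sensitive(self):
        c1 = PipelineConfig()
        c2 = PipelineConfig()
        c3 = PipelineConfig(seed=99)
        assert c1.config_hash() == c2.config_hash()
        assert c1.config_hash() != c3.config_hash()

    def test_yaml_round_trip(self, tmp_path):
        import yaml

        path = tmp_path / "cfg.yaml"
        path.write_text(yaml.safe_dump({"seed": 5, "n_cell_lines": 7}))
        cfg = PipelineConfig.from_yaml(path)
        assert cfg.seed == 5
        assert cfg.n_cell_lines == 7

    def test_go_requires_expression(self):
        with pytest.raises(ValueError):
            PipelineConfig(run_expression=False, run_go=True)


class TestPipeline:
    def test_deterministic_byte_identical(self, tmp_path, small_config):
        out1, out2 = tmp_path / "run1", tmp_path / "run2"
        run_pipeline(small_config, out1)
        run_pipeline(small_config, out2)
        names = sorted(p.name for p in out1.iterdir())
        assert names == sorted(p.name for p in out2.iterdir())
        for name in names:
            assert filecmp.cmp(out1 / name, out2 / name, shallow=False), name

    def test_stage_toggle_leaves_others_unchanged(self, tmp_path, small_config):
        full = tmp_path / "full"
        run_pipeline(small_config, full)
        reduced_cfg = PipelineConfig.from_dict(
            {**small_config.to_dict(), "run_expression": False, "run_go": False}
        )
        reduced = tmp_path / "reduced"
        run_pipeline(reduced_cfg, reduced)
        assert not list(reduced.glob("assoc_*.tsv"))
        assert not list(reduced.glob("go_*.tsv"))
        assert filecmp.cmp(full / "potency.tsv", reduced / "potency.tsv", shallow=False)
        assert filecmp.cmp(full / "ci_table.tsv", reduced / "ci_table.tsv", shallow=False)

    def test_one_association_table_per_compound(self, tmp_path, small_config):
        out = tmp_path / "out"
        meta = run_pipeline(small_config, out)
        assocs = sorted(p.name for p in out.glob("assoc_*.tsv"))
        assert assocs == [f"assoc_{c}.tsv" for c in small_config.compounds]
        assert set(meta["stages"]["expression"]["hits_per_compound"]) == set(
            small_config.compounds
        )

    def test_outputs_carry_header_metadata(self, tmp_path, small_config):
        out = tmp_path / "out"
        run_pipeline(small_config, out)
        head = (out / "potency.tsv").read_text().splitlines()[0]
        assert head.startswith("# chemopanel")
        assert small_config.config_hash() in head


class TestCLI:
    def test_pkconvert_scalar(self):
        result = CliRunner().invoke(main, ["pkconvert", "--ng-per-ml", "1000", "--mw", "500"])
        assert result.exit_code == 0
        assert result.output.strip() == "2"

    def test_fit_and_cluster(self, tmp_path):
        design = PlateDesign(noise_cv=0.05)
        plates = []
        for i, cpd in enumerate(["A", "B", "C"]):
            for j, line in enumerate(["l1", "l2", "l3"]):
                plates.append(
                    gen_plate_experiment(
                        0.5 * (i + 1), 1.0, design, seed=10 * i + j,
                        compound=cpd, cell_line=line,
                    )
                )
        plate_path = tmp_path / "plates.csv"
        cio.write_plate_csv(plates, plate_path)
        potency_path = tmp_path / "potency.tsv"
        r = CliRunner().invoke(
            main, ["fit", "--plates", str(plate_path), "--out", str(potency_path)]
        )
        assert r.exit_code == 0, r.output
        pm = cio.read_potency_table(potency_path)
        assert pm.values.shape == (3, 3)
        r = CliRunner().invoke(
            main, ["cluster", "--potency", str(potency_path), "--out-dir", str(tmp_path)]
        )
        assert r.exit_code == 0, r.output
        assert (tmp_path / "potency_tree.nwk").exists()

    def test_run_all(self, tmp_path):
        import yaml

        cfg_path = tmp_path / "cfg.yaml"
        cfg_path.write_text(
            yaml.safe_dump(
                {
                    "groups": {"g1": ["A", "B"]},
                    "n_cell_lines": 6,
                    "n_experiments": 1,
                    "n_genes": 20,
                    "n_terms": 5,
                }
            )
        )
        out = tmp_path / "out"
        r = CliRunner().invoke(
            main,
            ["run-all", "--config", str(cfg_path), "--seed", "2", "--out", str(out)],
        )
        assert r.exit_code == 0, r.output
        assert (out / "run_metadata.json").exists()
        assert (out / "potency.tsv").exists()
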