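import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from hwdi import _schema as S
from hwdi.imputation import ImputationSpec
from hwdi.interface import (
    PipelineConfig,
    SchemaError,
    compare_fixture,
    load_table2_fixture,
    read_microdata,
    run_pipeline,
    write_microdata,
)
from hwdi.interface.cli import main as cli_main
from hwdi.synthetic_data import GeneratorConfig, MissingnessSpec, generate_population

from conftest import BALANCED_INCOME, BALANCED_MARGINS, balanced_config


class TestMicrodataIO:
    def test_round_trip(self, tmp_path):
        df = generate_population(balanced_config(n_per_state=50))
        path = tmp_path / "micro.csv"
        write_microdata(df, path, seed=0)
        back = read_microdata(path)
        pd.testing.assert_frame_equal(back, df, check_dtype=False, atol=1e-9)

    def test_round_trip_preserves_missing(self, tmp_path):
        df = generate_population(balanced_config(n_per_state=50))
        df.loc[3, S.BMI] = np.nan
        path = tmp_path / "micro.csv"
        write_microdata(df, path)
        back = read_microdata(path)
        assert np.isnan(back.loc[3, S.BMI])
        assert len(back) == len(df)

    def test_unparseable_cell_becomes_missing_with_tally(self, tmp_path, caplog):
        df = generate_population(balanced_config(n_per_state=5, states=("Texas",)))
        path = tmp_path / "micro.csv"
        write_microdata(df, path)
        text = path.read_text().replace(f"{df.loc[0, S.BMI]}", "banana", 1)
        path.write_text(text)
        with caplog.at_level("WARNING", logger="hwdi.interface.io"):
            back = read_microdata(path)
        assert np.isnan(back.loc[0, S.BMI])
        assert back.attrs["coercion_tally"] == {S.BMI: 1}
        assert len(back) == len(df)

    def test_out_of_range_cell_becomes_missing(self, tmp_path):
        df = generate_population(balanced_config(n_per_state=5, states=("Texas",)))
        df.loc[0, S.INCOME] = 9.0  # outside 1..8
        path = tmp_path / "micro.csv"
        write_microdata(df, path)
        back = read_microdata(path)
        assert np.isnan(back.loc[0, S.INCOME])

    def test_missing_state_column_schema_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("age_category,sex\n1,1\n")
        with pytest.raises(SchemaError, match="state"):
            read_microdata(path)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.raises(SchemaError):
            read_microdata(path)

    def test_case_insensitive_header(self, tmp_path):
        df = generate_population(balanced_config(n_per_state=3, states=("Texas",)))
        path = tmp_path / "micro.csv"
        write_microdata(df, path)
        path.write_text(path.read_text().replace("state,", "STATE,", 1))
        assert len(read_microdata(path)) == 3


class TestFixture:
    def test_shape_and_bijections(self, fixture_table):
        assert len(fixture_table) == 49
        for col in ("rhwdi_rank", "hwdi_rank"):
            assert sorted(fixture_table[col]) == list(range(1, 50))
        assert "Michigan" not in set(fixture_table["state"])
        assert "South Dakota" not in set(fixture_table["state"])

    def test_compare_fixture_headline_counts(self):
        rep = compare_fixture()
        assert rep.counts["diff_ge_5"] == 38
        assert rep.top_diffs[0][0] == "South Carolina"

    def test_equal_rank_columns_degenerate(self, fixture_table):
        f = fixture_table.copy()
        f["hwdi_rank"] = f["rhwdi_rank"]
        rep = compare_fixture(f)
        assert rep.rho == pytest.approx(1.0)
        assert rep.kappa == pytest.approx(1.0)
        assert (rep.diffs == 0).all()


def small_pipeline_config(tmp_dir=None, **kw):
    # Near-uniform margins keep every income-by-race cell occupied at small n.
    gen = balanced_config(
        n_per_state=kw.pop("n_per_state", 800),
        covariate_margins={
            S.AGE: (0.2, 0.2, 0.2, 0.2, 0.2),
            S.SEX: (0.5, 0.5),
            S.RACE: (0.25, 0.15, 0.15, 0.15, 0.15, 0.15),
            S.EDUCATION: (0.25, 0.25, 0.25, 0.25),
        },
        income_category_probs=(0.12, 0.12, 0.12, 0.12, 0.12, 0.12, 0.12, 0.16),
        seed=0,
    )
    return PipelineConfig(
        generator=gen,
        missingness=kw.pop("missingness", None),
        imputation=kw.pop("imputation", ImputationSpec(m_datasets=2, cycles_per_dataset=2)),
        output_dir=str(tmp_dir) if tmp_dir else None,
        seed=kw.pop("seed", 0),
        **kw,
    )


class TestRunPipeline:
    def test_rhwdi_sign_matches_generator_construction(self, guidelines):
        # Gradient +2/0/0 inflates low-income BMI -> positive RHWDI everywhere;
        # oracle: indices computed directly from generator group means.
        cfg = small_pipeline_config(n_per_state=1500)
        res = run_pipeline(cfg)
        comp = res.index_table[res.index_table["computable"]]
        assert len(comp) == 5
        assert (comp["rhwdi"] > 0).all()

    def test_determinism_byte_identical_outputs(self, tmp_path):
        out1, out2 = tmp_path / "a", tmp_path / "b"
        run_pipeline(small_pipeline_config(out1, missingness=MissingnessSpec(rates={S.BMI: 0.2})))
        run_pipeline(small_pipeline_config(out2, missingness=MissingnessSpec(rates={S.BMI: 0.2})))

        def data_lines(p):
            return [l for l in p.read_text().splitlines() if not l.startswith("#")]

        # Headers carry the config hash (which covers output_dir); the data
        # rows must be byte-identical.
        assert data_lines(out1 / "index_table.csv") == data_lines(out2 / "index_table.csv")

    def test_m1_no_missing_equals_no_imputation_run(self):
        res1 = run_pipeline(small_pipeline_config(imputation=ImputationSpec(m_datasets=1)))
        res20 = run_pipeline(small_pipeline_config(imputation=ImputationSpec(m_datasets=20)))
        # No missing data: imputation is a no-op regardless of m.
        pd.testing.assert_frame_equal(res1.index_table, res20.index_table)

    def test_stage_accounting_balances(self):
        cfg = small_pipeline_config(missingness=MissingnessSpec(rates={S.BMI: 0.1}))
        res = run_pipeline(cfg)
        c = res.stage_counts
        assert c["excluded"] + c["retained"] == c["input_records"]
        assert c["eligible_states"] + c["ineligible_states"] == len(res.eligibility)
        assert res.exclusion_tally.total == c["input_records"]

    def test_concordance_skipped_below_three_states(self):
        cfg = small_pipeline_config()
        cfg.generator = balanced_config(states=("Texas", "Ohio"), n_per_state=400)
        res = run_pipeline(cfg)
        assert res.report is None

    def test_report_produced_for_five_states(self):
        res = run_pipeline(small_pipeline_config())
        assert res.report is not None
        assert res.report.n_states == 5

    def test_stage_error_names_stage(self, tmp_path):
        cfg = small_pipeline_config()
        cfg.input_path = str(tmp_path / "nope.csv")
        with pytest.raises(FileNotFoundError):
            run_pipeline(cfg)


class TestConfig:
    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text(
            """
seed: 3
generator:
  states: [Texas, Ohio]
  n_per_state: 10
imputation:
  m_datasets: 2
missingness:
  rates: {bmi: 0.1}
"""
        )
        cfg = PipelineConfig.from_yaml(path)
        assert cfg.seed == 3
        assert cfg.generator.states == ("Texas", "Ohio")
        assert cfg.generator.seed == 3  # master seed propagated
        assert cfg.missingness.seed == 4
        assert cfg.imputation.seed == 5
        assert cfg.imputation.m_datasets == 2

    def test_config_hash_stable(self):
        assert small_pipeline_config().config_hash() == small_pipeline_config().config_hash()


class TestCli:
    def test_simulate_then_pipeline(self, tmp_path):
        runner = CliRunner()
        micro = tmp_path / "micro.csv"
        r = runner.invoke(
            cli_main,
            ["simulate", "--out", str(micro), "--states", "Texas,Ohio", "--n-per-state", "30", "--seed", "1"],
        )
        assert r.exit_code == 0, r.output
        assert micro.exists()
        back = read_microdata(micro)
        assert len(back) == 60

    def test_compare_indices_defaults_to_fixture(self):
        r = CliRunner().invoke(cli_main, ["compare-indices"])
        assert r.exit_code == 0, r.output
        assert "diff_ge_5: 38" in r.output
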