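"""Report tables, end-to-end pipeline, and the command-line interface."""

import pytest
from click.testing import CliRunner

import egonet.metrics as m
from egonet.cli import main as cli_main
from egonet.model import StudyCollection
from egonet.reporting import (
    build_report,
    run_report,
    tabulate_descriptives,
    tabulate_ei,
    tabulate_homophily,
    tabulate_network_metrics,
    tabulate_relationships,
)
from egonet.synth import GeneratorConfig

from conftest import complete_network, make_network


def collection_with_ego_ages(n_over_30: int, k: int = 20) -> StudyCollection:
    """k single-alter networks; the first n_over_30 egos are 30 or older."""
    nets = []
    for i in range(k):
        age_group = ">=30" if i < n_over_30 else "<30"
        nets.append(
            make_network(
                1, [], label=f"N{i}", ego_overrides={"age_group": age_group}
            )
        )
    return StudyCollection(networks=nets)


class TestDescriptives:
    def test_ego_age_percentage(self):
        df = tabulate_descriptives(collection_with_ego_ages(15))
        row = df[(df.attribute == "age_group") & (df.level == ">=30")].iloc[0]
        assert row.ego_n == 15 and row.ego_pct == 75.0

    def test_percentages_recomputable_from_counts(self, small_collection):
        df = tabulate_descriptives(small_collection)
        n_egos = len(small_collection.egos)
        sub = df[df.attribute == "ethnicity"]
        for _, row in sub.iterrows():
            assert row.ego_pct == m.round1(100.0 * row.ego_n / n_egos)

    def test_empty_collection_gives_empty_tables(self):
        empty = StudyCollection(networks=[])
        assert tabulate_descriptives(empty).ego_n.sum() == 0
        assert len(tabulate_relationships(empty)) > 0  # rows exist, all zero
        assert tabulate_relationships(empty).total_n.sum() == 0

    def test_relationship_table_site_split(self):
        nets = []
        for i, (site, rel) in enumerate(
            [("A", "relative_or_close_friend"), ("B", "neighbour_or_acquaintance")]
        ):
            net = make_network(2, [], label=f"N{i}",
                               alter_overrides={"a1": {"relationship": rel},
                                                "a2": {"relationship": rel}})
            nets.append(type(net)(net.label, site, net.ego, net.alters, net.ties))
        df = tabulate_relationships(StudyCollection(networks=nets))
        visits = df[(df.attribute == "relationship")
                    & (df.level == "relative_or_close_friend")].iloc[0]
        assert visits.site_a_n == 2 and visits.site_b_n == 0
        assert visits.total_pct == 50.0


class TestMetricTables:
    def test_complete_network_row_renders_expected_values(self):
        df = tabulate_network_metrics(StudyCollection(networks=[complete_network(10)]))
        row = df.iloc[0]
        assert row.density == 1.0
        assert row.ego_nbetweenness == 0.0 and row.average_nbetweenness == 0.0

    def test_ei_table_prints_dash_for_undefined_cells(self):
        net = make_network(2, [("ego", "a1")])  # everyone Hausa -> Others empty
        df = tabulate_ei(StudyCollection(networks=[net]))
        assert df.iloc[0]["ethnicity:Others"] == "–"
        assert df.iloc[0]["ethnicity:Hausa"] == "-1.000"

    def test_homophily_table_columns_consistent(self, small_collection):
        df = tabulate_homophily(small_collection)
        for _, row in df.iterrows():
            assert row.total_n == row.ego_n + row.alter_n


class TestRunReport:
    def test_synthetic_defaults_write_all_outputs(self, tmp_path):
        cfg = GeneratorConfig(seed=8, k_egos=20)
        run_report(tmp_path, config=cfg)
        assert len(list((tmp_path / "sociograms").glob("*.graphml"))) == 20
        for name in ("descriptives", "network_metrics", "ei_indices", "homophily"):
            assert (tmp_path / f"{name}.csv").exists()
        assert "seed: 8" in (tmp_path / "run_log.txt").read_text()

    def test_rerun_is_byte_identical(self, tmp_path):
        for sub in ("one", "two"):
            run_report(tmp_path / sub, config=GeneratorConfig(seed=9, k_egos=3))
        for name in ("network_metrics", "ei_indices", "homophily", "roster"):
            assert (tmp_path / "one" / f"{name}.csv").read_bytes() == (
                tmp_path / "two" / f"{name}.csv"
            ).read_bytes()

    def test_requires_exactly_one_source(self, tmp_path):
        with pytest.raises(ValueError, match="exactly one"):
            run_report(tmp_path)


class TestCLI:
    def test_simulate_then_analyze(self, tmp_path):
        runner = CliRunner()
        data = tmp_path / "data"
        r = runner.invoke(
            cli_main, ["simulate", "--seed", "3", "--out", str(data)]
        )
        assert r.exit_code == 0, r.output
        out = tmp_path / "out"
        r = runner.invoke(
            cli_main,
            ["analyze", "--roster", str(data / "roster.csv"),
             "--ties", str(data / "ties.csv"), "--out", str(out),
             "--format", "dot"],
        )
        assert r.exit_code == 0, r.output
        assert len(list((out / "sociograms").glob("*.dot"))) == 20

    def test_missing_ties_file_exits_nonzero_naming_path(self, tmp_path):
        runner = CliRunner()
        data = tmp_path / "data"
        runner.invoke(cli_main, ["simulate", "--seed", "3", "--out", str(data)])
        r = runner.invoke(
            cli_main,
            ["analyze", "--roster", str(data / "roster.csv"),
             "--ties", str(data / "gone.csv"), "--out", str(tmp_path / "o")],
        )
        assert r.exit_code != 0
        assert "gone.csv" in r.output

    def test_single_sociogram_subcommand(self, tmp_path):
        runner = CliRunner()
        data = tmp_path / "data"
        runner.invoke(cli_main, ["simulate", "--seed", "4", "--out", str(data)])
        out = tmp_path / "SNA-B.graphml"
        r = runner.invoke(
            cli_main,
            ["sociogram", "--roster", str(data / "roster.csv"),
             "--ties", str(data / "ties.csv"), "--network", "SNA-B",
             "--out", str(out)],
        )
        assert r.exit_code == 0, r.output
        assert out.exists()

    def test_report_end_to_end(self, tmp_path):
        runner = CliRunner()
        r = runner.invoke(
            cli_main, ["report", "--seed", "6", "--out", str(tmp_path / "rep")]
        )
        assert r.exit_code == 0, r.output
        assert (tmp_path / "rep" / "config.yaml").exists()
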