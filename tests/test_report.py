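"""Cohort summaries, the pipeline driver and the CLI surface."""

import json

import pytest
import yaml
from click.testing import CliRunner

from repstab.ce_sizing import SizingModel
from repstab.classifier import (
    SomaticLabel,
    SomaticOutcome,
    TransmissionLabel,
    TransmissionOutcome,
    classify_sample,
)
from repstab.cli import main as cli_main
from repstab.report import (
    PipelineError,
    run_pipeline,
    summarize_somatic,
    summarize_transmissions,
)
from repstab.synthetic_data import (
    SpeciesSpec,
    TraceSimParams,
    cohort_from_counts,
    simulate_cohort,
    simulate_pedigree,
    simulate_trace,
    write_pedigree_tsv,
)


def _allele(label, length=None):
    return SomaticOutcome(SomaticLabel(label), repeat_length=length)


def _cohort(expanded=0, retained=0, contracted=0, large_deletion=0):
    samples = []
    samples += [[_allele("expanded", 130)]] * expanded
    samples += [[_allele("retained", 96)]] * retained
    samples += [[_allele("contracted", 60)]] * contracted
    samples += [[_allele("large_deletion")]] * large_deletion
    return samples


class TestSummarizeSomatic:
    def test_ratio_from_unrounded_frequencies(self):
        """183/218 expanded/contracted alleles give the 0.84 ratio."""
        s = summarize_somatic(_cohort(183, 427, 218, 185))
        assert s.exp_over_cont == 0.84
        assert s.cont_over_ret == 0.51
        assert s.n_alleles == 1013

    def test_ratio_na_when_denominator_empty(self):
        s = summarize_somatic(_cohort(expanded=5, retained=10))
        assert s.exp_over_cont is None
        assert s.cont_over_ret == 0.0

    def test_per_allele_frequencies_sum_to_100(self):
        s = summarize_somatic(_cohort(7, 90, 9, 1))
        assert abs(sum(s.freq.values()) - 100.0) <= 0.1 + 1e-9

    def test_ratio_consistency_chain(self):
        """exp/cont times cont/ret equals exp/ret within rounding tolerance."""
        s = summarize_somatic(_cohort(46, 107, 55, 46))
        assert s.exp_over_cont * s.cont_over_ret == pytest.approx(
            s.exp_over_ret, abs=0.02
        )

    def test_max_repeat_length_ignores_deletions(self):
        samples = _cohort(expanded=1, large_deletion=3)
        assert summarize_somatic(samples).max_repeat_length == 130

    def test_indicator_mode_counts_samples_once_per_category(self):
        mosaic = [
            [_allele("retained", 96), _allele("expanded", 130), _allele("expanded", 150)],
            [_allele("retained", 95)],
        ]
        s = summarize_somatic(mosaic, mode="per_sample_indicator")
        assert s.counts == {
            "large_deletion": 0, "contracted": 0, "retained": 2, "expanded": 1,
        }
        assert s.freq["retained"] == 100.0  # denominator is samples
        assert sum(s.freq.values()) > 100.0 or s.freq["expanded"] == 50.0

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            summarize_somatic([])


def _transmission(label, fold=1.0):
    return TransmissionOutcome(TransmissionLabel(label), fold)


class TestSummarizeTransmissions:
    def test_single_category_offspring(self):
        per_offspring = (
            [[_transmission("retention")]] * 85
            + [[_transmission("contraction", 0.4)]] * 5
            + [[_transmission("expansion", 1.8)]] * 1
        )
        s = summarize_transmissions(per_offspring)
        assert s.percentages == {"retention": 93.4, "contraction": 5.5, "expansion": 1.1}

    def test_mosaic_indicator_counts_exceed_total(self):
        per_offspring = (
            [[_transmission("retention")]] * 33
            + [[_transmission("retention"), _transmission("contraction", 0.3)]] * 4
            + [[_transmission("retention"), _transmission("expansion", 2.0)]] * 5
            + [[_transmission("contraction", 0.3)]]
            + [[_transmission("expansion", 2.0)]]
        )
        s = summarize_transmissions(per_offspring)
        assert s.counts == {"retention": 42, "contraction": 5, "expansion": 6}
        assert sum(s.counts.values()) > s.n_offspring

    def test_single_offspring_retention(self):
        s = summarize_transmissions([[_transmission("retention")]])
        assert s.percentages["retention"] == 100.0

    def test_duplicate_category_within_offspring_counts_once(self):
        s = summarize_transmissions(
            [[_transmission("expansion", 1.6), _transmission("expansion", 2.0)]]
        )
        assert s.counts["expansion"] == 1


@pytest.fixture()
def ce_project(tmp_path):
    """A small on-disk CE project: traces simulated from a known cohort."""
    model = SizingModel()
    probs = {"expanded": 0.2, "retained": 0.5, "contracted": 0.2, "large_deletion": 0.1}
    calls = simulate_cohort(96, probs, n=40, seed=53)
    rows = []
    for i, call in enumerate(calls):
        name = f"s{i:03d}.csv"
        if call.large_deletion_flag:
            (tmp_path / name).write_text("size_bp,intensity\n")
        else:
            species = [SpeciesSpec(l, max(r, 1e-6)) for l, r in call.species]
            trace = simulate_trace(species, model, TraceSimParams(noise_sd=0))
            trace.to_csv(tmp_path / name)
        rows.append(f"sample_{i:03d}\t{name}")
    (tmp_path / "samples.tsv").write_text(
        "sample_id\tpeak_table\n" + "\n".join(rows) + "\n"
    )
    config = {
        "locus": "c9orf72",
        "bands": {"expanded_min": 105, "retained_min": 90, "retained_max": 104,
                  "parental_length": 96},
        "mode": "per_allele",
        "ce": {"samples": "samples.tsv"},
        "outdir": str(tmp_path / "out"),
    }
    config_path = tmp_path / "config.yaml"
    config_path.write_text(yaml.safe_dump(config))
    return config_path, calls


class TestPipeline:
    def test_end_to_end_recovers_direct_classification(self, ce_project):
        config_path, calls = ce_project
        report = run_pipeline(config_path)
        direct = summarize_somatic([classify_sample(c) for c in calls])
        assert report["somatic"]["counts"] == direct.counts
        assert report["somatic"]["expansion_contraction_ratio"] == direct.exp_over_cont

    def test_rerun_is_byte_identical(self, ce_project, tmp_path):
        config_path, _ = ce_project
        run_pipeline(config_path, outdir=tmp_path / "a")
        run_pipeline(config_path, outdir=tmp_path / "b")
        assert (tmp_path / "a/report.json").read_bytes() == (
            tmp_path / "b/report.json"
        ).read_bytes()

    def test_missing_input_names_the_file(self, tmp_path):
        cfg = tmp_path / "c.yaml"
        cfg.write_text(yaml.safe_dump({"ce": {"samples": "nope.tsv"}}))
        with pytest.raises(PipelineError, match="nope.tsv"):
            run_pipeline(cfg, outdir=tmp_path / "out")

    def test_empty_metadata_rejected(self, tmp_path):
        (tmp_path / "samples.tsv").write_text("sample_id\tpeak_table\n")
        cfg = tmp_path / "c.yaml"
        cfg.write_text(yaml.safe_dump({"ce": {"samples": "samples.tsv"}}))
        with pytest.raises(PipelineError, match="no samples"):
            run_pipeline(cfg, outdir=tmp_path / "out")

    def test_transmission_branch(self, tmp_path):
        table = simulate_pedigree(
            400, {"retention": 0.8, "contraction": 0.15, "expansion": 0.05},
            60, seed=59,
        )
        write_pedigree_tsv(table, tmp_path / "ped.tsv")
        cfg = tmp_path / "c.yaml"
        cfg.write_text(yaml.safe_dump({"transmissions": {"table": "ped.tsv"}}))
        report = run_pipeline(cfg, outdir=tmp_path / "out")
        assert report["transmissions"]["n_offspring"] == 60
        expected = table.groupby("offspring_id").true_category.unique()
        n_ret = sum("retention" in cats for cats in expected)
        assert report["transmissions"]["counts"]["retention"] == n_ret


class TestCli:
    def test_call_ce_reports_species(self, tmp_path):
        trace = simulate_trace(
            [SpeciesSpec(96, 0.7), SpeciesSpec(150, 0.3)],
            SizingModel(),
            TraceSimParams(noise_sd=0),
        )
        trace.to_csv(tmp_path / "trace.csv")
        result = CliRunner().invoke(
            cli_main, ["call-ce", "--peaks", str(tmp_path / "trace.csv")]
        )
        assert result.exit_code == 0, result.output
        payload = json.loads(result.output)
        assert payload["primary_length"] == 96
        assert sorted(s["repeat_length"] for s in payload["species"]) == [96, 150]

    def test_pipeline_command_fails_cleanly_on_missing_config(self, tmp_path):
        result = CliRunner().invoke(
            cli_main, ["pipeline", "--config", str(tmp_path / "absent.yaml")]
        )
        assert result.exit_code != 0

    def test_classify_then_report_round_trip(self, tmp_path):
        cohort = cohort_from_counts(
            {"expanded": 4, "retained": 10, "contracted": 5, "large_deletion": 1},
            seed=61,
        )
        lines = ["sample_id\tspecies_lengths\tparental_length"]
        for i, call in enumerate(cohort):
            lengths = ",".join(str(x) for x in call.lengths)
            lines.append(f"s{i:03d}\t{lengths}\t96")
        (tmp_path / "cohort.tsv").write_text("\n".join(lines) + "\n")
        runner = CliRunner()
        classified = tmp_path / "classified.tsv"
        r1 = runner.invoke(
            cli_main,
            ["classify", "--input", str(tmp_path / "cohort.tsv"),
             "--out", str(classified)],
        )
        assert r1.exit_code == 0, r1.output
        r2 = runner.invoke(cli_main, ["report", "--input", str(classified)])
        assert r2.exit_code == 0, r2.output
        assert "Expansion/contraction ratio\t0.8" in r2.output
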