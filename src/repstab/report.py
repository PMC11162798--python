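"""Cohort summaries of classified repeat-instability outcomes, and the pipeline driver.

Somatic cohorts are summarized as outcome frequencies (percent, 1 decimal),
expansion/contraction-type ratios (2 decimals, computed from unrounded
frequencies, NA when the denominator category is empty) and the maximum
repeat length. Two counting modes exist because mosaic samples carry several
alleles:

* ``per_allele`` - the denominator is the total allele count (a
  large-deletion sample contributes one allele); frequencies sum to 100%.
* ``per_sample_indicator`` - the denominator is the sample count and a
  sample counts once per category it contains; frequencies can exceed 100%
  in mosaic cohorts.

Transmission cohorts are summarized per mouse with indicator semantics: a
mosaic offspring with species in several fold categories counts in each, so
category counts may exceed the number of offspring.

All rounding is half-up (ties away from zero).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import pandas as pd
import yaml

from ._util import round_half_up
from .ce_sizing import (
    AlleleCall,
    Electropherogram,
    SizingModel,
    call_alleles,
    load_locus,
)
from .classifier import (
    SomaticLabel,
    SomaticOutcome,
    SubcloneBands,
    TransmissionLabel,
    TransmissionOutcome,
    classify_sample,
    classify_transmission,
)
from .read_counter import AnchorSpec, anchors_from_fasta, count_readset, modal_repeat_length, read_fastx

__all__ = [
    "CohortSummary",
    "TransmissionSummary",
    "PipelineError",
    "summarize_somatic",
    "summarize_transmissions",
    "run_pipeline",
]

logger = logging.getLogger("repstab")

_SOMATIC_ORDER = [
    SomaticLabel.LARGE_DELETION,
    SomaticLabel.CONTRACTED,
    SomaticLabel.RETAINED,
    SomaticLabel.EXPANDED,
]
_TRANSMISSION_ORDER = [
    TransmissionLabel.RETENTION,
    TransmissionLabel.CONTRACTION,
    TransmissionLabel.EXPANSION,
]


class PipelineError(RuntimeError):
    """Fatal pipeline configuration or input error."""


@dataclass
class CohortSummary:
    """Table-style somatic cohort summary."""

    n_samples: int
    n_alleles: int
    mode: str
    counts: dict[str, int]
    freq: dict[str, float]  # percent, 1 decimal
    exp_over_cont: Optional[float]
    exp_over_ret: Optional[float]
    cont_over_ret: Optional[float]
    max_repeat_length: Optional[int]

    def to_dict(self) -> dict:
        return {
            "n_samples": self.n_samples,
            "n_alleles": self.n_alleles,
            "mode": self.mode,
            "counts": self.counts,
            "freq_percent": self.freq,
            "expansion_contraction_ratio": self.exp_over_cont,
            "expansion_retention_ratio": self.exp_over_ret,
            "contraction_retention_ratio": self.cont_over_ret,
            "max_repeat_length": self.max_repeat_length,
        }

    def to_text(self) -> str:
        na = "NA"
        lines = [
            f"# of samples analyzed\t{self.n_samples}",
            f"# of alleles (mode={self.mode})\t{self.n_alleles}",
        ]
        for label in _SOMATIC_ORDER:
            name = label.value.replace("_", " ").capitalize()
            lines.append(f"{name} (%)\t{self.freq[label.value]}")
        for name, value in [
            ("Expansion/contraction ratio", self.exp_over_cont),
            ("Expansion/retention ratio", self.exp_over_ret),
            ("Contraction/retention ratio", self.cont_over_ret),
        ]:
            lines.append(f"{name}\t{na if value is None else value}")
        lines.append(
            f"Max repeat length\t{na if self.max_repeat_length is None else self.max_repeat_length}"
        )
        return "\n".join(lines)


@dataclass
class TransmissionSummary:
    """Per-mouse indicator summary of intergenerational outcomes."""

    n_offspring: int
    counts: dict[str, int]
    percentages: dict[str, float]  # percent, 1 decimal

    def to_dict(self) -> dict:
        return {
            "n_offspring": self.n_offspring,
            "counts": self.counts,
            "percentages": self.percentages,
        }

    def to_text(self) -> str:
        lines = [f"# of offspring analyzed\t{self.n_offspring}"]
        for label in _TRANSMISSION_ORDER:
            lines.append(
                f"{label.value.capitalize()}\t{self.counts[label.value]} "
                f"({self.percentages[label.value]}%)"
            )
        return "\n".join(lines)


def _ratio(numerator: int, denominator: int) -> Optional[float]:
    # from unrounded frequencies: counts share the denominator, so the
    # frequency ratio equals the count ratio
    if denominator == 0:
        return None
    return round_half_up(numerator / denominator, 2)


def summarize_somatic(
    outcomes_per_sample: Sequence[Sequence[SomaticOutcome]],
    mode: str = "per_allele",
) -> CohortSummary:
    """Summarize somatic outcomes of a cohort.

    ``outcomes_per_sample`` holds one outcome list per sample (one entry per
    repeat species; a large-deletion sample has a single large-deletion
    outcome). Ratios are computed from unrounded frequencies and are NA
    (``None``) when the denominator category is empty.
    """
    if not outcomes_per_sample:
        raise ValueError("cohort must contain at least one sample")
    if mode not in {"per_allele", "per_sample_indicator"}:
        raise ValueError(f"unknown mode {mode!r}")
    if any(len(sample) == 0 for sample in outcomes_per_sample):
        raise ValueError("every sample must carry at least one outcome")

    n_samples = len(outcomes_per_sample)
    n_alleles = sum(len(sample) for sample in outcomes_per_sample)
    counts = {label: 0 for label in _SOMATIC_ORDER}
    if mode == "per_allele":
        denominator = n_alleles
        for sample in outcomes_per_sample:
            for outcome in sample:
                counts[outcome.label] += 1
    else:
        denominator = n_samples
        for sample in outcomes_per_sample:
            for label in {outcome.label for outcome in sample}:
                counts[label] += 1

    freq = {
        label.value: round_half_up(100.0 * counts[label] / denominator, 1)
        for label in _SOMATIC_ORDER
    }
    lengths = [
        outcome.repeat_length
        for sample in outcomes_per_sample
        for outcome in sample
        if outcome.repeat_length is not None
    ]
    return CohortSummary(
        n_samples=n_samples,
        n_alleles=n_alleles,
        mode=mode,
        counts={label.value: counts[label] for label in _SOMATIC_ORDER},
        freq=freq,
        exp_over_cont=_ratio(counts[SomaticLabel.EXPANDED], counts[SomaticLabel.CONTRACTED]),
        exp_over_ret=_ratio(counts[SomaticLabel.EXPANDED], counts[SomaticLabel.RETAINED]),
        cont_over_ret=_ratio(counts[SomaticLabel.CONTRACTED], counts[SomaticLabel.RETAINED]),
        max_repeat_length=max(lengths) if lengths else None,
    )


def summarize_transmissions(
    per_offspring_outcomes: Sequence[Sequence[TransmissionOutcome]],
    n_offspring: Optional[int] = None,
) -> TransmissionSummary:
    """Per-mouse indicator summary: each offspring counts once per category present.

    Category counts (and percentages over ``n_offspring``) may sum to more
    than the number of offspring when mosaic mice span several categories.
    """
    if n_offspring is None:
        n_offspring = len(per_offspring_outcomes)
    if n_offspring < 1:
        raise ValueError(f"n_offspring must be >= 1, got {n_offspring}")
    if len(per_offspring_outcomes) != n_offspring:
        raise ValueError(
            f"{len(per_offspring_outcomes)} offspring outcome lists for n_offspring={n_offspring}"
        )
    counts = {label: 0 for label in _TRANSMISSION_ORDER}
    for outcomes in per_offspring_outcomes:
        if not outcomes:
            raise ValueError("every offspring must carry at least one outcome")
        for label in {outcome.label for outcome in outcomes}:
            counts[label] += 1
    percentages = {
        label.value: round_half_up(100.0 * counts[label] / n_offspring, 1)
        for label in _TRANSMISSION_ORDER
    }
    return TransmissionSummary(
        n_offspring=n_offspring,
        counts={label.value: counts[label] for label in _TRANSMISSION_ORDER},
        percentages=percentages,
    )


# ---------------------------------------------------------------------------
# pipeline driver


def _load_bands(raw: Optional[Mapping]) -> SubcloneBands:
    if raw is None:
        return SubcloneBands()
    return SubcloneBands(
        expanded_min=int(raw["expanded_min"]),
        retained_min=int(raw["retained_min"]),
        retained_max=int(raw["retained_max"]),
        parental_length=int(raw.get("parental_length", raw["retained_min"] + 6)),
    )


def _load_model(raw: Union[str, Mapping, None], base: Path) -> SizingModel:
    if raw is None:
        return SizingModel()
    if isinstance(raw, str):
        path = base / raw
        return load_locus(path if path.exists() else raw)
    return SizingModel(
        unit_bp=int(raw["unit_bp"]),
        flank_bp=float(raw["flank_bp"]),
        migration_factor=float(raw.get("migration_factor", 1.0)),
        name=str(raw.get("name", "custom")),
    )


def _require(path: Path) -> Path:
    if not path.exists():
        raise PipelineError(f"missing input file: {path}")
    return path


def _parse_species_lengths(value) -> list[int]:
    if pd.isna(value) or str(value).strip() == "":
        return []
    return [int(x) for x in str(value).split(",") if str(x).strip() != ""]


def _ce_branch(cfg: Mapping, base: Path, model: SizingModel, bands: SubcloneBands, mode: str, warnings: list[str]):
    meta = pd.read_csv(_require(base / cfg["samples"]), sep="\t", dtype=str)
    if "sample_id" not in meta.columns:
        raise PipelineError(f"{cfg['samples']}: missing sample_id column")
    if meta.empty:
        raise PipelineError(f"{cfg['samples']}: no samples listed")
    outcomes_per_sample = []
    calls = {}
    for row in meta.itertuples():
        try:
            if "peak_table" in meta.columns and isinstance(row.peak_table, str):
                trace = Electropherogram.from_csv(
                    _require(base / row.peak_table),
                    sample_id=row.sample_id,
                    size_window=model.default_window(),
                )
                call = call_alleles(trace, model)
            elif "species_lengths" in meta.columns:
                lengths = _parse_species_lengths(row.species_lengths)
                if lengths:
                    k = len(lengths)
                    call = AlleleCall(
                        species=[(length, 1.0 - i / (k + 1)) for i, length in enumerate(lengths)]
                    )
                else:
                    call = AlleleCall(large_deletion_flag=True)
            else:
                raise ValueError("row has neither peak_table nor species_lengths")
        except PipelineError:
            raise
        except Exception as exc:  # malformed row: warn, skip, count
            warnings.append(f"sample {row.sample_id}: skipped ({exc})")
            logger.warning("sample %s skipped: %s", row.sample_id, exc)
            continue
        calls[row.sample_id] = call
        outcomes_per_sample.append(classify_sample(call, bands))
    if not outcomes_per_sample:
        raise PipelineError("no usable CE samples after row filtering")
    summary = summarize_somatic(outcomes_per_sample, mode=mode)
    per_sample = pd.DataFrame(
        [
            {
                "sample_id": sid,
                "species_lengths": ",".join(str(x) for x in call.lengths),
                "primary_length": call.primary_length,
                "large_deletion": call.large_deletion_flag,
            }
            for sid, call in calls.items()
        ]
    )
    return summary, per_sample


def _reads_branch(cfg: Mapping, base: Path, warnings: list[str]):
    records = read_fastx(_require(base / cfg["fastq"]))
    if "anchors_fasta" in cfg:
        anchors = anchors_from_fasta(
            _require(base / cfg["anchors_fasta"]),
            min_norm_score=float(cfg.get("min_norm_score", 0.6)),
        )
    else:
        anchors = AnchorSpec(
            prefix_seq=cfg["prefix_seq"],
            suffix_seq=cfg["suffix_seq"],
            min_norm_score=float(cfg.get("min_norm_score", 0.6)),
        )
    unit_seq = cfg.get("unit_seq", "GGGGCC")
    table = count_readset(records, anchors, unit_seq)
    result = modal_repeat_length(
        records,
        anchors,
        unit_seq,
        bin_width=int(cfg.get("bin_width", 1)),
        secondary_frac=float(cfg.get("secondary_frac", 0.5)),
    )
    if result.n_reads_used == 0:
        warnings.append("read counting: no usable reads")
    return result, table


def _transmission_branch(cfg: Mapping, base: Path, warnings: list[str]):
    table = pd.read_csv(_require(base / cfg["table"]), sep="\t")
    required = {"offspring_id", "parental_length", "offspring_length"}
    if missing := required - set(table.columns):
        raise PipelineError(f"{cfg['table']}: missing columns {sorted(missing)}")
    if table.empty:
        raise PipelineError(f"{cfg['table']}: no transmissions listed")
    per_offspring: dict[str, list[TransmissionOutcome]] = {}
    rows = []
    for row in table.itertuples():
        try:
            outcome = classify_transmission(
                float(row.parental_length), float(row.offspring_length)
            )
        except Exception as exc:
            warnings.append(f"offspring {row.offspring_id}: skipped ({exc})")
            logger.warning("offspring %s skipped: %s", row.offspring_id, exc)
            continue
        per_offspring.setdefault(str(row.offspring_id), []).append(outcome)
        rows.append(
            {
                "offspring_id": row.offspring_id,
                "parental_length": row.parental_length,
                "offspring_length": row.offspring_length,
                "label": outcome.label.value,
                "fold": round_half_up(outcome.fold_change, 2),
            }
        )
    if not per_offspring:
        raise PipelineError("no usable transmissions after row filtering")
    summary = summarize_transmissions(list(per_offspring.values()))
    return summary, pd.DataFrame(rows)


def run_pipeline(
    config: Union[str, Path, Mapping],
    outdir: Optional[Union[str, Path]] = None,
) -> dict:
    """Execute the configured analysis end to end and write the report bundle.

    The YAML config names input peak tables and/or read sets plus metadata;
    relative paths resolve against the config file's directory. Emits
    ``report.json`` (machine-readable, deterministically serialized),
    per-branch TSVs and a plain-text ``summary.txt``; every threshold in use
    is logged. Raises :class:`PipelineError` for missing inputs; malformed
    rows are warned about, skipped and counted in the report.
    """
    if isinstance(config, (str, Path)):
        config_path = Path(config)
        if not config_path.exists():
            raise PipelineError(f"missing config file: {config_path}")
        cfg = yaml.safe_load(config_path.read_text()) or {}
        base = config_path.parent
    else:
        cfg = dict(config)
        base = Path(cfg.get("basedir", "."))
    if not any(key in cfg for key in ("ce", "reads", "transmissions")):
        raise PipelineError("config must define at least one of: ce, reads, transmissions")

    outdir = Path(outdir or cfg.get("outdir", "repstab_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    model = _load_model(cfg.get("locus"), base)
    bands = _load_bands(cfg.get("bands"))
    mode = str(cfg.get("mode", "per_allele")).replace("-", "_")
    if mode == "per_sample":
        mode = "per_sample_indicator"
    logger.info(
        "thresholds: background/species fraction 0.20, bands %s, sizing %s, mode %s",
        bands,
        model,
        mode,
    )

    warnings: list[str] = []
    report: dict = {"config_mode": mode, "warnings": warnings}
    text_blocks = []

    if "ce" in cfg:
        summary, per_sample = _ce_branch(cfg["ce"], base, model, bands, mode, warnings)
        report["somatic"] = summary.to_dict()
        per_sample.to_csv(outdir / "allele_calls.tsv", sep="\t", index=False)
        text_blocks.append("== Somatic repeat instability ==\n" + summary.to_text())
    if "reads" in cfg:
        result, table = _reads_branch(cfg["reads"], base, warnings)
        report["read_counting"] = result.to_dict()
        table.to_csv(outdir / "read_counts.tsv", sep="\t", index=False)
        text_blocks.append(
            "== Read-based repeat counting ==\n"
            f"modal repeat length\t{result.modal_length}\n"
            f"reads used/discarded\t{result.n_reads_used}/{result.n_reads_discarded}\n"
            f"modes\t{','.join(str(m) for m in result.modes)}"
        )
    if "transmissions" in cfg:
        summary, per_row = _transmission_branch(cfg["transmissions"], base, warnings)
        report["transmissions"] = summary.to_dict()
        per_row.to_csv(outdir / "transmission_calls.tsv", sep="\t", index=False)
        text_blocks.append(
            "== Intergenerational repeat instability ==\n" + summary.to_text()
        )

    report["n_warnings"] = len(warnings)
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    (outdir / "summary.txt").write_text("\n\n".join(text_blocks) + "\n")
    return report
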