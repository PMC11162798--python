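"""Synthetic inputs for the repeat-instability pipeline.

Generates every input the downstream stages consume, with the structure the
analysis assumes:

* electropherograms - per-species gene-specific peaks with +/-1-unit stutter
  shoulders, a repeat-primed ladder descending one unit at a time from the
  largest gene-specific product with geometrically decaying intensity,
  additive Gaussian intensity noise and a baseline floor;
* read sets - a fixed-unit repeat tract between flanking sequences, with
  substitution errors at a configurable per-base rate (no indels);
* subclone cohorts with prescribed somatic-outcome proportions and optional
  mosaicism (2-5 species per mosaic sample);
* parent -> offspring transmission tables with prescribed category
  proportions, offspring lengths drawn inside the fold band of their
  category.

All generators are deterministic under a fixed seed; independent operations
derive child seeds from one top-level seed via
:func:`repstab._util.child_seeds`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .ce_sizing import AlleleCall, Electropherogram, Peak, SizingModel
from .classifier import (
    SomaticLabel,
    SubcloneBands,
    TransmissionLabel,
    bands_from_parental,
)

__all__ = [
    "SpeciesSpec",
    "TraceSimParams",
    "ReadSimParams",
    "G4C2_UNIT",
    "synthetic_flanks",
    "simulate_trace",
    "simulate_reads",
    "simulate_cohort",
    "cohort_from_counts",
    "simulate_pedigree",
    "write_fastq",
    "write_cohort_tsv",
    "write_pedigree_tsv",
]

G4C2_UNIT = "GGGGCC"

#: maximum number of distinct repeat species observed in one mosaic sample
MAX_MOSAIC_SPECIES = 5

_DNA = "ACGT"


@dataclass(frozen=True)
class SpeciesSpec:
    """One repeat species: integer copy number plus relative abundance."""

    repeat_length: int
    relative_abundance: float = 1.0

    def __post_init__(self) -> None:
        if self.repeat_length < 0:
            raise ValueError(f"repeat_length must be >= 0, got {self.repeat_length}")
        if not (0 < self.relative_abundance <= 1):
            raise ValueError(
                f"relative_abundance must be in (0, 1], got {self.relative_abundance}"
            )


def _normalize(species: Sequence[SpeciesSpec]) -> list[SpeciesSpec]:
    if not species:
        raise ValueError("species list must be non-empty")
    total = sum(s.relative_abundance for s in species)
    if not math.isfinite(total) or total <= 0:
        raise ValueError("species abundances must sum to a positive finite value")
    return [
        SpeciesSpec(s.repeat_length, s.relative_abundance / total) for s in species
    ]


@dataclass(frozen=True)
class TraceSimParams:
    """Electropherogram simulator knobs.

    ``ladder_decay`` (default 0.85) makes roughly ten repeat-primed rungs
    exceed the 20% background threshold below the top peak; ``stutter_prob``
    (default 0.05) puts symmetric +/-1-unit shoulders on every gene-specific
    peak. ``amplitude`` is the fluorescence scale of a unit-abundance peak.
    """

    stutter_prob: float = 0.05
    ladder_decay: float = 0.85
    noise_sd: float = 0.0
    baseline: float = 0.0
    amplitude: float = 10000.0
    include_ladder: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("stutter_prob", "ladder_decay", "noise_sd", "baseline", "amplitude"):
            value = getattr(self, name)
            if not math.isfinite(value):
                raise ValueError(f"{name} must be finite, got {value!r}")
        if not (0 < self.ladder_decay < 1):
            raise ValueError(f"ladder_decay must be in (0, 1), got {self.ladder_decay}")
        if not (0 <= self.stutter_prob < 1):
            raise ValueError(f"stutter_prob must be in [0, 1), got {self.stutter_prob}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.amplitude <= 0:
            raise ValueError(f"amplitude must be positive, got {self.amplitude}")


@dataclass(frozen=True)
class ReadSimParams:
    """Read simulator knobs (substitution errors only, no indels).

    ``rc_fraction`` optionally emits a fraction of reads reverse-complemented,
    as strand-agnostic long-read sequencing would.
    """

    n_reads: int
    length_distribution: Sequence[SpeciesSpec] = (SpeciesSpec(96, 1.0),)
    per_base_error: float = 0.0
    flank_len: int = 150
    rc_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads < 1:
            raise ValueError(f"n_reads must be >= 1, got {self.n_reads}")
        if not (0 <= self.per_base_error < 0.25):
            raise ValueError(
                f"per_base_error must be in [0, 0.25), got {self.per_base_error}"
            )
        if self.flank_len < 1:
            raise ValueError(f"flank_len must be >= 1, got {self.flank_len}")
        if not (0 <= self.rc_fraction <= 1):
            raise ValueError(f"rc_fraction must be in [0, 1], got {self.rc_fraction}")


def synthetic_flanks(flank_len: int = 150, seed: int = 714025) -> tuple[str, str]:
    """Deterministic synthetic prefix/suffix flanking sequences.

    The real flanking sequences of the assayed locus are not redistributed
    here; these are fixed random stand-ins with the correct length. Repeat
    counting is flank-sequence-agnostic, so any non-repetitive flank works.
    """
    rng = np.random.default_rng(seed)
    prefix = "".join(rng.choice(list(_DNA), size=flank_len))
    suffix = "".join(rng.choice(list(_DNA), size=flank_len))
    return prefix, suffix


def simulate_trace(
    species: Sequence[SpeciesSpec],
    model: SizingModel = SizingModel(),
    params: TraceSimParams = TraceSimParams(),
    sample_id: str = "sim",
) -> Electropherogram:
    """Simulate the peak table of a repeat-primed PCR CE run.

    Each species contributes a gene-specific peak at
    ``(unit_bp * L + flank_bp) * migration_factor`` with intensity
    proportional to its abundance, flanked by +/-1-unit stutter shoulders at
    ``stutter_prob`` of the main intensity. A repeat-primed ladder descends
    one unit at a time from the largest gene-specific product with intensity
    decaying by ``ladder_decay`` per rung. Gaussian noise (``noise_sd``) is
    added per peak and intensities are floored at ``baseline``.
    """
    species = _normalize(species)
    rng = np.random.default_rng(params.seed)

    # accumulate intensity on the integer copy-number grid: gene-specific
    # peaks, stutter shoulders and ladder rungs all sit on the same grid
    grid: dict[int, float] = {}

    def add(length: int, intensity: float) -> None:
        if length >= 0 and intensity > 0:
            grid[length] = grid.get(length, 0.0) + intensity

    for sp in species:
        main = params.amplitude * sp.relative_abundance
        add(sp.repeat_length, main)
        if params.stutter_prob > 0:
            add(sp.repeat_length - 1, main * params.stutter_prob)
            add(sp.repeat_length + 1, main * params.stutter_prob)

    if params.include_ladder:
        largest = max(species, key=lambda s: s.repeat_length)
        top = params.amplitude * largest.relative_abundance
        floor = max(params.baseline, 1e-3 * params.amplitude)
        for k in range(1, largest.repeat_length + 1):
            rung = top * params.ladder_decay**k
            if rung < floor:
                break
            add(largest.repeat_length - k, rung)

    peaks = []
    for length in sorted(grid):
        intensity = grid[length]
        if params.noise_sd > 0:
            intensity += rng.normal(0.0, params.noise_sd)
        intensity = max(intensity, params.baseline, 0.0)
        if intensity > 0:
            peaks.append(Peak(model.repeat_length_to_size(length), intensity))
    return Electropherogram(
        peaks=peaks, sample_id=sample_id, size_window=model.default_window()
    )


def _mutate(rng: np.random.Generator, seq: str, per_base_error: float) -> str:
    if per_base_error <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(arr.size) < per_base_error)[0]
    for i in hits:
        base = arr[i].decode()
        choices = [b for b in _DNA if b != base]
        arr[i] = rng.choice(choices).encode()
    return arr.tobytes().decode()


def simulate_reads(
    params: ReadSimParams,
    unit_seq: str = G4C2_UNIT,
    prefix_seq: Optional[str] = None,
    suffix_seq: Optional[str] = None,
) -> list[SeqRecord]:
    """Simulate reads spanning a repeat tract: ``prefix + L*unit + suffix``.

    ``L`` is drawn per read from ``length_distribution``; substitution
    errors are applied at ``per_base_error`` per base. Qualities are a
    constant Phred score matching the error rate (a stated simplification).
    The true copy number and orientation are recorded in each record id
    (``read_0001_L96_fwd``) so closed-loop tests can recover the template.
    """
    unit_seq = unit_seq.upper()
    if not unit_seq or set(unit_seq) - set(_DNA):
        raise ValueError(f"unit_seq must be non-empty A/C/G/T, got {unit_seq!r}")
    if prefix_seq is None or suffix_seq is None:
        prefix_default, suffix_default = synthetic_flanks(params.flank_len)
        prefix_seq = prefix_seq or prefix_default
        suffix_seq = suffix_seq or suffix_default
    if len(prefix_seq) < params.flank_len or len(suffix_seq) < params.flank_len:
        raise ValueError(
            f"flanks must be at least flank_len={params.flank_len} bp long"
        )
    dist = _normalize(list(params.length_distribution))
    lengths = np.array([s.repeat_length for s in dist])
    probs = np.array([s.relative_abundance for s in dist])
    rng = np.random.default_rng(params.seed)

    if params.per_base_error > 0:
        phred = min(40, int(round(-10 * math.log10(params.per_base_error))))
    else:
        phred = 40

    records = []
    for i in range(params.n_reads):
        L = int(rng.choice(lengths, p=probs))
        seq = _mutate(rng, prefix_seq + unit_seq * L + suffix_seq, params.per_base_error)
        orient = "fwd"
        if params.rc_fraction > 0 and rng.random() < params.rc_fraction:
            seq = str(Seq(seq).reverse_complement())
            orient = "rev"
        rec = SeqRecord(
            Seq(seq),
            id=f"read_{i:04d}_L{L}_{orient}",
            description=f"true_length={L} orientation={orient}",
        )
        rec.letter_annotations["phred_quality"] = [phred] * len(seq)
        records.append(rec)
    return records


_OUTCOME_KEYS = {label.value: label for label in SomaticLabel}
_CATEGORY_KEYS = {label.value: label for label in TransmissionLabel}


def _check_probs(probs: Mapping, keys: Mapping[str, object], what: str) -> dict:
    out = {}
    for key, p in probs.items():
        name = key.value if isinstance(key, (SomaticLabel, TransmissionLabel)) else str(key)
        if name not in keys:
            raise ValueError(f"unknown {what} {key!r}; expected one of {sorted(keys)}")
        if p < 0:
            raise ValueError(f"{what} probability must be >= 0, got {key}={p}")
        out[keys[name]] = float(p)
    total = sum(out.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"{what} probabilities must sum to 1, got {total!r}")
    return out


def _somatic_length_range(
    label: SomaticLabel, bands: SubcloneBands
) -> tuple[int, int]:
    """Inclusive copy-number range used to draw lengths of a given outcome."""
    if label is SomaticLabel.RETAINED:
        return bands.retained_min, bands.retained_max
    if label is SomaticLabel.CONTRACTED:
        lo = max(1, bands.parental_length // 4)
        hi = bands.retained_min - 1
        return min(lo, hi), hi
    if label is SomaticLabel.EXPANDED:
        lo = bands.expanded_min
        return lo, max(lo + 40, int(2.6 * bands.parental_length))
    raise ValueError(f"no length range for {label}")


def _draw_call(
    rng: np.random.Generator,
    label: SomaticLabel,
    bands: SubcloneBands,
    mosaic_rate: float,
) -> AlleleCall:
    if label is SomaticLabel.LARGE_DELETION:
        return AlleleCall(large_deletion_flag=True)
    lo, hi = _somatic_length_range(label, bands)
    k = 1
    if mosaic_rate > 0 and rng.random() < mosaic_rate:
        k = int(rng.integers(2, MAX_MOSAIC_SPECIES + 1))
    k = min(k, hi - lo + 1)
    lengths = rng.choice(np.arange(lo, hi + 1), size=k, replace=False)
    weights = np.sort(rng.dirichlet(np.ones(k)))[::-1]
    rel = weights / weights[0]
    species = [(int(length), float(r)) for length, r in zip(lengths, rel)]
    return AlleleCall(species=species)


def simulate_cohort(
    parental_length: int,
    outcome_probs: Mapping,
    mosaic_rate: float = 0.0,
    n: int = 100,
    seed: int = 0,
    bands: Optional[SubcloneBands] = None,
) -> list[AlleleCall]:
    """Simulate a subclone cohort with prescribed somatic-outcome proportions.

    Each sample's outcome is drawn from ``outcome_probs``; its species are
    then drawn inside the copy-number band of that outcome, so classifying
    the cohort reproduces the requested labels exactly. Mosaic samples
    (probability ``mosaic_rate``) carry 2-5 species, all within the same
    band. ``bands`` defaults to the relative bands of ``parental_length``
    (identical to the absolute 96-copy bands when the parent is 96).
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not (0 <= mosaic_rate <= 1):
        raise ValueError(f"mosaic_rate must be in [0, 1], got {mosaic_rate}")
    probs = _check_probs(outcome_probs, _OUTCOME_KEYS, "outcome")
    bands = bands or bands_from_parental(parental_length)
    rng = np.random.default_rng(seed)
    labels = list(probs)
    p = np.array([probs[label] for label in labels])
    draws = rng.choice(len(labels), size=n, p=p)
    return [_draw_call(rng, labels[i], bands, mosaic_rate) for i in draws]


def cohort_from_counts(
    counts: Mapping,
    bands: SubcloneBands = SubcloneBands(),
    seed: int = 0,
) -> list[AlleleCall]:
    """Deterministic cohort with exact per-outcome allele counts (no mosaicism).

    Used to rebuild cohorts whose category frequencies are known exactly
    (e.g. from a published summary table); each allele's length is drawn
    within its outcome band, which classification is invariant to.
    """
    rng = np.random.default_rng(seed)
    calls = []
    for key, count in counts.items():
        name = key.value if isinstance(key, SomaticLabel) else str(key)
        label = _OUTCOME_KEYS[name]
        if count < 0:
            raise ValueError(f"count for {name} must be >= 0, got {count}")
        for _ in range(int(count)):
            calls.append(_draw_call(rng, label, bands, mosaic_rate=0.0))
    if not calls:
        raise ValueError("cohort counts must include at least one allele")
    return calls


def _transmission_length_range(
    label: TransmissionLabel, parental_length: int
) -> tuple[int, int]:
    """Inclusive offspring-length range whose folds fall in the category band."""
    if label is TransmissionLabel.RETENTION:
        return math.floor(0.5 * parental_length) + 1, math.ceil(1.5 * parental_length) - 1
    if label is TransmissionLabel.CONTRACTION:
        return max(1, math.floor(0.25 * parental_length)), math.floor(0.5 * parental_length)
    return math.ceil(1.5 * parental_length), max(
        math.ceil(1.5 * parental_length), 2 * parental_length
    )


def simulate_pedigree(
    parental_length: int,
    category_probs: Mapping,
    n_offspring: int,
    seed: int = 0,
    mosaic_rate: float = 0.0,
) -> pd.DataFrame:
    """Simulate a parent -> offspring transmission table.

    Returns one row per offspring repeat species with columns
    ``offspring_id, species_index, parental_length, offspring_length,
    true_category``. Each offspring's primary species falls in the fold band
    of its drawn category; mosaic offspring (probability ``mosaic_rate``)
    carry up to 5 species whose categories are drawn independently, so a
    single mouse can contribute several categories, as indicator-style
    summaries expect.
    """
    if parental_length < 2:
        raise ValueError(f"parental_length must be >= 2, got {parental_length}")
    if n_offspring < 1:
        raise ValueError(f"n_offspring must be >= 1, got {n_offspring}")
    if not (0 <= mosaic_rate <= 1):
        raise ValueError(f"mosaic_rate must be in [0, 1], got {mosaic_rate}")
    probs = _check_probs(category_probs, _CATEGORY_KEYS, "category")
    rng = np.random.default_rng(seed)
    labels = list(probs)
    p = np.array([probs[label] for label in labels])

    rows = []
    for i in range(n_offspring):
        k = 1
        if mosaic_rate > 0 and rng.random() < mosaic_rate:
            k = int(rng.integers(2, MAX_MOSAIC_SPECIES + 1))
        cats = [labels[j] for j in rng.choice(len(labels), size=k, p=p)]
        for j, cat in enumerate(cats):
            lo, hi = _transmission_length_range(cat, parental_length)
            length = int(rng.integers(lo, hi + 1))
            rows.append(
                {
                    "offspring_id": f"off_{i:04d}",
                    "species_index": j,
                    "parental_length": parental_length,
                    "offspring_length": length,
                    "true_category": cat.value,
                }
            )
    return pd.DataFrame(rows)


def write_fastq(records: Sequence[SeqRecord], path: Union[str, Path]) -> None:
    SeqIO.write(records, str(path), "fastq")


def write_cohort_tsv(
    calls: Sequence[AlleleCall],
    path: Union[str, Path],
    parental_length: Optional[int] = None,
) -> None:
    """Write a cohort as TSV: sample_id, species_lengths (comma-joined), parental_length.

    Large-deletion samples carry an empty species list.
    """
    rows = []
    for i, call in enumerate(calls):
        rows.append(
            {
                "sample_id": f"sample_{i:04d}",
                "species_lengths": ",".join(str(length) for length in call.lengths),
                "parental_length": "" if parental_length is None else parental_length,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_pedigree_tsv(table: pd.DataFrame, path: Union[str, Path]) -> None:
    table.to_csv(path, sep="\t", index=False)
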