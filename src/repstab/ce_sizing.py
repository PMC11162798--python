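"""Repeat-length calling from capillary-electrophoresis (CE) fragment tables.

Repeat-primed PCR of an STR locus yields a gene-specific (GS) amplicon whose
size encodes the repeat copy number, plus a one-unit-spaced repeat-primed
ladder. Fragment-analysis software reduces a CE run to a peak table of
(fragment size in bp, fluorescence intensity). This module converts such peak
tables into integer repeat-length calls.

Because GC-rich amplicons migrate anomalously relative to the size standard,
observed sizes are first divided by an empirical migration factor (0.95 for
the C9orf72 G4C2 assay) before subtracting the non-repeat amplicon length
(175 bp) and dividing by the unit length (6 bp)::

    repeat_length = round((size_bp / migration_factor - flank_bp) / unit_bp)

For samples whose absolute sizing is unreliable (3' breaks), the same formula
is applied to the size *difference* between the GS product and the smallest
repeat-primed product.

Signal below 20% of the highest peak is treated as background. Samples may be
mosaic: every GS peak above that fraction is called as an independent repeat
species, and the most abundant species is the sample's repeat length. A
sample with no GS product at all (lost priming site) is flagged as a large
deletion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import NamedTuple, Optional, Sequence, Union

import pandas as pd
import yaml

from ._util import round_half_away_int

__all__ = [
    "Peak",
    "Electropherogram",
    "SizingModel",
    "AlleleCall",
    "MinorPeakCount",
    "SizingError",
    "EmptyWindowError",
    "load_locus",
    "repeat_length_to_size",
    "size_to_repeat_length",
    "offset_to_repeat_length",
    "find_highest_peak",
    "count_minor_peaks",
    "call_alleles",
]

#: signal below this fraction of the highest peak is background
BACKGROUND_FRAC = 0.20


class SizingError(ValueError):
    """A fragment size is inconsistent with the sizing model."""


class EmptyWindowError(ValueError):
    """No peak falls inside the analysis window (large-deletion signal)."""


class Peak(NamedTuple):
    size_bp: float
    intensity: float


@dataclass(frozen=True)
class SizingModel:
    """Locus constants mapping repeat copies to migrated fragment size.

    Defaults are the C9orf72 G4C2 assay constants: 6 bp unit, 175 bp of
    non-repeat amplicon, migration factor 0.95.
    """

    unit_bp: int = 6
    flank_bp: float = 175.0
    migration_factor: float = 0.95
    name: str = "C9orf72-G4C2"

    def __post_init__(self) -> None:
        if self.unit_bp < 1:
            raise ValueError(f"unit_bp must be >= 1, got {self.unit_bp}")
        if self.flank_bp < 0:
            raise ValueError(f"flank_bp must be >= 0, got {self.flank_bp}")
        if not (0 < self.migration_factor <= 1):
            raise ValueError(
                f"migration_factor must be in (0, 1], got {self.migration_factor}"
            )

    def repeat_length_to_size(self, repeat_length: int) -> float:
        """Migrated fragment size (bp) of the GS product for ``repeat_length`` copies."""
        if repeat_length < 0:
            raise ValueError(f"repeat_length must be >= 0, got {repeat_length}")
        return (self.unit_bp * repeat_length + self.flank_bp) * self.migration_factor

    def default_window(self, max_copies: int = 1000) -> tuple[float, float]:
        """Analysis window covering 0..max_copies, padded by half a migrated unit."""
        half_unit = 0.5 * self.unit_bp * self.migration_factor
        return (
            self.repeat_length_to_size(0) - half_unit,
            self.repeat_length_to_size(max_copies) + half_unit,
        )

    def calibrated(self, known_length: int, observed_size_bp: float) -> "SizingModel":
        """Per-run migration-factor calibration from a sample of known length."""
        expected = self.unit_bp * known_length + self.flank_bp
        if expected <= 0 or observed_size_bp <= 0:
            raise ValueError("calibration requires positive sizes")
        return SizingModel(
            unit_bp=self.unit_bp,
            flank_bp=self.flank_bp,
            migration_factor=observed_size_bp / expected,
            name=self.name,
        )


@dataclass
class Electropherogram:
    """Peak table of one CE run, with sizes strictly ascending."""

    peaks: list[Peak]
    sample_id: str = ""
    size_window: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        self.peaks = [Peak(float(s), float(i)) for s, i in self.peaks]
        sizes = [p.size_bp for p in self.peaks]
        if any(s <= 0 for s in sizes):
            raise ValueError("peak sizes must be positive")
        if any(p.intensity < 0 for p in self.peaks):
            raise ValueError("peak intensities must be non-negative")
        if any(b <= a for a, b in zip(sizes, sizes[1:])):
            raise ValueError("peak sizes must be strictly increasing")
        if self.size_window is not None:
            lo, hi = self.size_window
            if not lo < hi:
                raise ValueError(f"empty size window {self.size_window}")

    def windowed(self, window: Optional[tuple[float, float]] = None) -> list[Peak]:
        window = window or self.size_window
        if window is None:
            return list(self.peaks)
        lo, hi = window
        return [p for p in self.peaks if lo <= p.size_bp <= hi]

    def to_csv(self, path: Union[str, Path]) -> None:
        pd.DataFrame(self.peaks, columns=["size_bp", "intensity"]).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(
        cls,
        path: Union[str, Path],
        sample_id: str = "",
        size_window: Optional[tuple[float, float]] = None,
    ) -> "Electropherogram":
        df = pd.read_csv(path)
        missing = {"size_bp", "intensity"} - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        df = df.sort_values("size_bp")
        peaks = [Peak(r.size_bp, r.intensity) for r in df.itertuples()]
        return cls(peaks=peaks, sample_id=sample_id or str(path), size_window=size_window)


@dataclass
class AlleleCall:
    """Repeat species of one sample.

    ``species`` holds (repeat_length, relative_intensity) pairs sorted by
    descending intensity; the most abundant species (relative intensity 1.0)
    is the sample's ``primary_length``. ``large_deletion_flag`` marks samples
    with no gene-specific product in the analysis window.
    """

    species: list[tuple[int, float]] = field(default_factory=list)
    primary_length: Optional[int] = None
    large_deletion_flag: bool = False

    def __post_init__(self) -> None:
        if self.large_deletion_flag:
            if self.species or self.primary_length is not None:
                raise ValueError("large-deletion call carries no species")
            return
        if not self.species:
            raise ValueError("non-deletion call requires at least one species")
        if any(not (0 < rel <= 1) for _, rel in self.species):
            raise ValueError("relative intensities must be in (0, 1]")
        top = max(self.species, key=lambda s: (s[1], s[0]))
        if self.primary_length is None:
            self.primary_length = top[0]
        elif self.primary_length != top[0]:
            raise ValueError("primary_length must be the most intense species")

    @property
    def lengths(self) -> list[int]:
        return [length for length, _ in self.species]


class MinorPeakCount(NamedTuple):
    n_smaller: int
    n_larger: int


def repeat_length_to_size(repeat_length: int, model: SizingModel) -> float:
    """Forward sizing: migrated GS-product size for a given copy number."""
    return model.repeat_length_to_size(repeat_length)


def size_to_repeat_length(size_bp: float, model: SizingModel) -> int:
    """Invert the CE sizing formula to integer repeat copies.

    ``round((size_bp / migration_factor - flank_bp) / unit_bp)``, ties away
    from zero. Sizes implying negative copies are rejected as sub-flank
    artifacts.
    """
    if size_bp <= 0:
        raise SizingError(f"fragment size must be positive, got {size_bp}")
    copies = (size_bp / model.migration_factor - model.flank_bp) / model.unit_bp
    length = round_half_away_int(copies)
    if length < 0:
        raise SizingError(
            f"size {size_bp} bp implies {copies:.2f} copies: sub-flank artifact peak"
        )
    return length


def offset_to_repeat_length(
    gene_specific_bp: float, smallest_rp_bp: float, model: SizingModel
) -> int:
    """Repeat length from the GS-product vs smallest repeat-primed product offset.

    Used where absolute sizing is unreliable; the size difference replaces
    the absolute GS size in the sizing formula.
    """
    diff = gene_specific_bp - smallest_rp_bp
    if diff <= 0:
        raise SizingError(
            "gene-specific product must be larger than the smallest "
            f"repeat-primed product (difference {diff} bp)"
        )
    return size_to_repeat_length(diff, model)


def find_highest_peak(trace: Electropherogram, window: Optional[tuple[float, float]] = None) -> Peak:
    """Maximum-intensity peak inside the analysis window.

    Equal-intensity ties resolve toward the larger fragment (conservative
    toward expansion calls).
    """
    peaks = trace.windowed(window)
    if not peaks:
        raise EmptyWindowError(
            f"sample {trace.sample_id!r}: no peak inside the analysis window"
        )
    return max(peaks, key=lambda p: (p.intensity, p.size_bp))


def count_minor_peaks(
    trace: Electropherogram,
    background_frac: float = BACKGROUND_FRAC,
    window: Optional[tuple[float, float]] = None,
) -> MinorPeakCount:
    """Count above-background peaks on each side of the highest peak.

    A peak is above background when its intensity is >= ``background_frac``
    of the highest peak (signal strictly below the fraction is background,
    so exactly 20% counts as signal). The highest peak itself is excluded.
    Invariant under rescaling all intensities by a positive constant.
    """
    top = find_highest_peak(trace, window)
    threshold = background_frac * top.intensity
    smaller = larger = 0
    for p in trace.windowed(window):
        if p == top or p.intensity < threshold:
            continue
        if p.size_bp < top.size_bp:
            smaller += 1
        elif p.size_bp > top.size_bp:
            larger += 1
    return MinorPeakCount(n_smaller=smaller, n_larger=larger)


def call_alleles(
    trace: Electropherogram,
    model: SizingModel,
    species_frac: float = BACKGROUND_FRAC,
    window: Optional[tuple[float, float]] = None,
) -> AlleleCall:
    """Call every repeat species in a (possibly mosaic) sample.

    Gene-specific peaks are above-background peaks (>= ``species_frac`` of
    the highest) that are also local intensity maxima over their one-unit
    neighbourhood: repeat-primed ladder rungs and stutter shoulders always
    sit next to a stronger peak one unit away and are thereby rejected,
    while a genuine species peak dominates its neighbours. Species whose
    sizes round to the same integer copy number are merged. A trace with no
    gene-specific peak in the window yields a large-deletion call.

    A minor species closer to the primary peak than the visible extent of
    the repeat-primed ladder must exceed the local ladder intensity to be
    called -- the same resolution limit CE itself has.
    """
    window = window or trace.size_window or model.default_window()
    peaks = trace.windowed(window)
    if not peaks:
        return AlleleCall(large_deletion_flag=True)
    top_intensity = max(p.intensity for p in peaks)
    if top_intensity <= 0:
        return AlleleCall(large_deletion_flag=True)
    threshold = species_frac * top_intensity
    neighbourhood = 1.5 * model.unit_bp * model.migration_factor

    def dominates(p: Peak) -> bool:
        for q in peaks:
            if q is p or abs(q.size_bp - p.size_bp) > neighbourhood:
                continue
            if q.intensity > p.intensity:
                return False
            if q.intensity == p.intensity and q.size_bp > p.size_bp:
                return False
        return True

    merged: dict[int, float] = {}
    for p in peaks:
        if p.intensity < threshold or not dominates(p):
            continue
        try:
            length = size_to_repeat_length(p.size_bp, model)
        except SizingError:
            continue  # sub-flank artifact inside a permissive window
        merged[length] = merged.get(length, 0.0) + p.intensity
    if not merged:
        return AlleleCall(large_deletion_flag=True)
    best = max(merged.values())
    species = sorted(
        ((length, inten / best) for length, inten in merged.items()),
        key=lambda s: (-s[1], -s[0]),
    )
    return AlleleCall(species=[(length, rel) for length, rel in species])


def load_locus(name_or_path: Union[str, Path]) -> SizingModel:
    """Load a locus sizing model from a shipped name (e.g. ``"c9orf72"``) or a YAML path.

    Shipped files live in ``repstab/loci/``; templates for assays whose
    non-repeat amplicon length is not published (TCF4 CTG, FXN GAA) carry a
    null ``flank_bp`` and are rejected until the user fills it in.
    """
    path = Path(name_or_path)
    if path.suffix in {".yaml", ".yml"} and path.exists():
        raw = yaml.safe_load(path.read_text())
    else:
        ref = resources.files("repstab").joinpath(f"loci/{name_or_path}.yaml")
        if not ref.is_file():
            raise FileNotFoundError(f"unknown locus {name_or_path!r}")
        raw = yaml.safe_load(ref.read_text())
    if raw.get("flank_bp") is None:
        raise ValueError(
            f"locus {raw.get('name', name_or_path)!r}: flank_bp is required "
            "configuration (not published for this assay)"
        )
    return SizingModel(
        unit_bp=int(raw["unit_bp"]),
        flank_bp=float(raw["flank_bp"]),
        migration_factor=float(raw.get("migration_factor", 1.0)),
        name=str(raw.get("name", name_or_path)),
    )
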