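"""Classification of somatic and intergenerational repeat-length changes.

Somatic outcomes (subclones or tissues relative to a parental line) use
absolute copy-number bands. For a 96-copy parental G4C2 allele: 105 copies
and above is *expanded* (the parental length plus roughly ten additional
copies), 90-104 copies is *retained*, below 90 copies is *contracted*, and a
sample with no gene-specific product (lost priming site) is a *large
deletion*. Mosaic samples contribute one outcome per repeat species - every
species counts as an independent allele.

Intergenerational outcomes (parent -> offspring transmissions) use the
offspring/parent fold change: 1.5-fold or more is *expansion*, 0.5-fold or
less is *contraction*, anything in between is *retention*. The bounds are
inclusive.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Sequence, Union

from ._util import round_half_up
from .ce_sizing import AlleleCall

__all__ = [
    "SomaticLabel",
    "TransmissionLabel",
    "SubcloneBands",
    "SomaticOutcome",
    "TransmissionOutcome",
    "bands_from_parental",
    "classify_allele",
    "classify_sample",
    "classify_transmission",
    "fold_range",
]

EXPANSION_FOLD = 1.5  # offspring/parent fold at or above which a transmission is an expansion
CONTRACTION_FOLD = 0.5  # fold at or below which it is a contraction


class SomaticLabel(str, enum.Enum):
    EXPANDED = "expanded"
    RETAINED = "retained"
    CONTRACTED = "contracted"
    LARGE_DELETION = "large_deletion"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class TransmissionLabel(str, enum.Enum):
    EXPANSION = "expansion"
    RETENTION = "retention"
    CONTRACTION = "contraction"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class SubcloneBands:
    """Absolute copy-number bands for somatic classification.

    Defaults are the 96-copy-parent G4C2 bands (expanded >= 105, retained
    90-104, contracted < 90). The bands must tile the non-negative integers:
    ``expanded_min`` is required to be ``retained_max + 1`` so that every
    length falls in exactly one band.
    """

    expanded_min: int = 105
    retained_min: int = 90
    retained_max: int = 104
    parental_length: int = 96

    def __post_init__(self) -> None:
        if not (0 <= self.retained_min <= self.retained_max < self.expanded_min):
            raise ValueError(
                f"require 0 <= retained_min <= retained_max < expanded_min, got {self}"
            )
        if self.expanded_min != self.retained_max + 1:
            raise ValueError(
                "bands must partition the integers: expanded_min must equal "
                f"retained_max + 1, got {self.expanded_min} vs {self.retained_max + 1}"
            )
        if not (self.retained_min <= self.parental_length <= self.retained_max):
            raise ValueError(
                f"parental length {self.parental_length} outside the retained band"
            )


def bands_from_parental(parental_length: int) -> SubcloneBands:
    """Relative-band helper: parental -6 / +8, mirroring the 96 -> 90/104 bands.

    Offered as a convenience for parental lengths whose absolute bands are
    not established; it is never applied implicitly by the classifier.
    """
    if parental_length < 7:
        raise ValueError(f"parental length {parental_length} too small for relative bands")
    return SubcloneBands(
        expanded_min=parental_length + 9,
        retained_min=parental_length - 6,
        retained_max=parental_length + 8,
        parental_length=parental_length,
    )


@dataclass(frozen=True)
class SomaticOutcome:
    label: SomaticLabel
    repeat_length: Optional[int] = None

    def __post_init__(self) -> None:
        if (self.label is SomaticLabel.LARGE_DELETION) != (self.repeat_length is None):
            raise ValueError("repeat_length is absent exactly for large deletions")


@dataclass(frozen=True)
class TransmissionOutcome:
    label: TransmissionLabel
    fold_change: float


def classify_allele(
    length: Optional[int], bands: SubcloneBands = SubcloneBands()
) -> SomaticOutcome:
    """Band membership of one allele; ``None`` marks a large deletion."""
    if length is None:
        return SomaticOutcome(SomaticLabel.LARGE_DELETION)
    if length < 0:
        raise ValueError(f"repeat length must be non-negative, got {length}")
    if length >= bands.expanded_min:
        label = SomaticLabel.EXPANDED
    elif length >= bands.retained_min:
        label = SomaticLabel.RETAINED
    else:
        label = SomaticLabel.CONTRACTED
    return SomaticOutcome(label, repeat_length=int(length))


def classify_sample(
    call: AlleleCall, bands: SubcloneBands = SubcloneBands()
) -> list[SomaticOutcome]:
    """One outcome per repeat species; a large-deletion sample yields one outcome."""
    if call.large_deletion_flag:
        return [SomaticOutcome(SomaticLabel.LARGE_DELETION)]
    return [classify_allele(length, bands) for length in call.lengths]


def classify_transmission(
    parental_length: Union[int, float], offspring_length: Union[int, float]
) -> TransmissionOutcome:
    """Classify one parent -> offspring transmission by fold change.

    Expansion at fold >= 1.5, contraction at fold <= 0.5 (both inclusive),
    retention in between.
    """
    if parental_length <= 0:
        raise ValueError(f"parental length must be positive, got {parental_length}")
    if offspring_length < 0:
        raise ValueError(f"offspring length must be non-negative, got {offspring_length}")
    fold = offspring_length / parental_length
    if fold >= EXPANSION_FOLD:
        label = TransmissionLabel.EXPANSION
    elif fold <= CONTRACTION_FOLD:
        label = TransmissionLabel.CONTRACTION
    else:
        label = TransmissionLabel.RETENTION
    return TransmissionOutcome(label, fold_change=fold)


def fold_range(
    parental_length: Union[int, float], offspring_lengths: Sequence[Union[int, float]]
) -> tuple[float, float]:
    """(min, max) offspring/parent fold change, each rounded to 2 decimals."""
    if parental_length <= 0:
        raise ValueError(f"parental length must be positive, got {parental_length}")
    if len(offspring_lengths) == 0:
        raise ValueError("offspring length list must be non-empty")
    folds = [length / parental_length for length in offspring_lengths]
    return round_half_up(min(folds), 2), round_half_up(max(folds), 2)
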