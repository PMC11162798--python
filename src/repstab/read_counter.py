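"""Anchored repeat counting in sequence reads.

Sequence-space analog of signal-level tandem-repeat genotypers for long
reads: the 150 bp immediately upstream (prefix) and downstream (suffix) of
the repeat tract are located in each read by local alignment, the repeat
copy number is the anchored span divided by the unit length, and the
cohort-level call is the modal per-read count.

Anchor alignment is Smith-Waterman with match +1, mismatch -1, gap open -2,
gap extend -1 (via :class:`Bio.Align.PairwiseAligner`). Each anchor must
reach a normalized score (score / anchor length) of at least
``min_norm_score`` (default 0.6); both read orientations are tried and
reverse-complement hits are reported in read-forward coordinates (0-based,
half-open). Span-based counting tolerates substitution errors inside a pure
repeat; indels bias the count and are outside the simulator's error model.
"""

from __future__ import annotations

import gzip
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd
from Bio import Align, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._util import round_half_away_int

__all__ = [
    "AnchorSpec",
    "RepeatCountResult",
    "locate_anchors",
    "count_repeats",
    "modal_repeat_length",
    "count_readset",
    "read_fastx",
    "anchors_from_fasta",
]

DEFAULT_MIN_NORM_SCORE = 0.6


@dataclass(frozen=True)
class AnchorSpec:
    """Prefix/suffix anchor sequences plus the per-anchor score threshold.

    ``min_norm_score`` is the local-alignment score divided by the anchor
    length; with unit match scores it is an identity-equivalent fraction.
    """

    prefix_seq: str
    suffix_seq: str
    min_norm_score: float = DEFAULT_MIN_NORM_SCORE

    def __post_init__(self) -> None:
        if not self.prefix_seq or not self.suffix_seq:
            raise ValueError("anchor sequences must be non-empty")
        if self.min_norm_score < 0:
            raise ValueError(f"min_norm_score must be >= 0, got {self.min_norm_score}")


@dataclass
class RepeatCountResult:
    """Per-read repeat counts and their modal summary for one read set."""

    per_read_counts: list[int]
    n_reads_used: int
    n_reads_discarded: int
    modal_length: Optional[int]
    modes: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_reads_used": self.n_reads_used,
            "n_reads_discarded": self.n_reads_discarded,
            "modal_length": self.modal_length,
            "modes": self.modes,
            "count_histogram": dict(sorted(Counter(self.per_read_counts).items())),
        }


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1
    return aligner


_ALIGNER = _aligner()


def _best_hit(read: str, anchor: str) -> tuple[float, int, int]:
    """(normalized score, start, end) of the best local hit of ``anchor`` in ``read``."""
    alignments = _ALIGNER.align(read, anchor)
    aln = alignments[0]
    blocks = aln.aligned[0]
    return alignments.score / len(anchor), int(blocks[0][0]), int(blocks[-1][1])


def locate_anchors(
    read: str, anchors: AnchorSpec
) -> Optional[tuple[int, int]]:
    """Locate both anchors in a read; ``None`` when the read is unusable.

    Returns ``(prefix_end, suffix_start)`` in read-forward coordinates
    (0-based, half-open repeat span). Both orientations are tried; the
    orientation with the higher combined anchor score wins (forward on
    ties). A read fails when either anchor misses its normalized score
    threshold or the anchors are out of order.
    """
    if not read:
        raise ValueError("read must be non-empty")
    read = str(read).upper()
    candidates = []
    for orientation, seq in (("fwd", read), ("rev", str(Seq(read).reverse_complement()))):
        p_score, _, p_end = _best_hit(seq, anchors.prefix_seq)
        s_score, s_start, _ = _best_hit(seq, anchors.suffix_seq)
        if p_score < anchors.min_norm_score or s_score < anchors.min_norm_score:
            continue
        if p_end > s_start:
            continue
        if orientation == "rev":
            span = (len(read) - s_start, len(read) - p_end)
        else:
            span = (p_end, s_start)
        candidates.append((p_score + s_score, orientation == "fwd", span))
    if not candidates:
        return None
    candidates.sort(key=lambda c: (c[0], c[1]), reverse=True)
    return candidates[0][2]


def count_repeats(
    read: str, span: tuple[int, int], unit_seq: str
) -> int:
    """Repeat copies in an anchored span: span length / unit length, rounded.

    Rounds to the nearest integer, ties away from zero (a 3 bp span of a
    6 bp unit counts as 1 copy).
    """
    start, end = span
    if not unit_seq:
        raise ValueError("unit_seq must be non-empty")
    if not (0 <= start <= end <= len(read)):
        raise ValueError(f"invalid span {span} for read of length {len(read)}")
    return round_half_away_int((end - start) / len(unit_seq))


def count_readset(
    readset: Iterable[Union[SeqRecord, tuple[str, str], str]],
    anchors: AnchorSpec,
    unit_seq: str,
) -> pd.DataFrame:
    """Per-read anchor location and repeat count.

    Accepts SeqRecords, ``(id, sequence)`` pairs or bare sequences; returns
    a DataFrame with columns ``read_id, used, count``.
    """
    rows = []
    for i, item in enumerate(readset):
        if isinstance(item, SeqRecord):
            read_id, seq = item.id, str(item.seq)
        elif isinstance(item, tuple):
            read_id, seq = item
        else:
            read_id, seq = f"read_{i:04d}", str(item)
        span = locate_anchors(seq, anchors)
        if span is None:
            rows.append({"read_id": read_id, "used": False, "count": pd.NA})
        else:
            rows.append(
                {
                    "read_id": read_id,
                    "used": True,
                    "count": count_repeats(seq, span, unit_seq),
                }
            )
    return pd.DataFrame(rows, columns=["read_id", "used", "count"])


def modal_repeat_length(
    readset: Iterable[Union[SeqRecord, tuple[str, str], str]],
    anchors: AnchorSpec,
    unit_seq: str,
    bin_width: int = 1,
    secondary_frac: float = 0.5,
) -> RepeatCountResult:
    """Most frequently called repeat length across a read set.

    Per-read counts are binned at ``bin_width`` copies; the modal length is
    the most frequent count in the most populated bin, ties broken toward
    the smaller length (conservative against expansion calls). ``modes``
    additionally reports one representative per bin whose occupancy is at
    least ``secondary_frac`` of the top bin, so mosaic read sets surface
    their secondary species. Zero usable reads yield an explicit empty
    result rather than an error.
    """
    if bin_width < 1:
        raise ValueError(f"bin_width must be >= 1, got {bin_width}")
    if not (0 < secondary_frac <= 1):
        raise ValueError(f"secondary_frac must be in (0, 1], got {secondary_frac}")
    table = count_readset(readset, anchors, unit_seq)
    counts = [int(c) for c in table.loc[table["used"], "count"]]
    n_discarded = int((~table["used"]).sum())
    if not counts:
        return RepeatCountResult(
            per_read_counts=[],
            n_reads_used=0,
            n_reads_discarded=n_discarded,
            modal_length=None,
        )
    bins = Counter(c // bin_width for c in counts)
    top_occupancy = max(bins.values())

    def representative(bin_index: int) -> int:
        members = Counter(c for c in counts if c // bin_width == bin_index)
        best = max(members.values())
        return min(c for c, k in members.items() if k == best)

    qualifying = sorted(
        b for b, k in bins.items() if k >= secondary_frac * top_occupancy
    )
    modal_bin = min(b for b, k in bins.items() if k == top_occupancy)
    return RepeatCountResult(
        per_read_counts=counts,
        n_reads_used=len(counts),
        n_reads_discarded=n_discarded,
        modal_length=representative(modal_bin),
        modes=[representative(b) for b in qualifying],
    )


def read_fastx(path: Union[str, Path]) -> list[SeqRecord]:
    """Read FASTA/FASTQ, gzip-aware, format inferred from the extension."""
    path = Path(path)
    suffixes = [s.lower() for s in path.suffixes]
    opener = gzip.open if suffixes and suffixes[-1] == ".gz" else open
    stem = suffixes[-2] if suffixes and suffixes[-1] == ".gz" else (
        suffixes[-1] if suffixes else ""
    )
    fmt = "fastq" if stem in {".fastq", ".fq"} else "fasta"
    with opener(path, "rt") as handle:
        return list(SeqIO.parse(handle, fmt))


def anchors_from_fasta(
    path: Union[str, Path], min_norm_score: float = DEFAULT_MIN_NORM_SCORE
) -> AnchorSpec:
    """Build an AnchorSpec from a 2-record FASTA (prefix first, suffix second)."""
    records = read_fastx(path)
    if len(records) != 2:
        raise ValueError(f"{path}: expected exactly 2 records, found {len(records)}")
    return AnchorSpec(
        prefix_seq=str(records[0].seq).upper(),
        suffix_seq=str(records[1].seq).upper(),
        min_norm_score=min_norm_score,
    )


def result_to_files(
    result: RepeatCountResult,
    table: Optional[pd.DataFrame],
    tsv_path: Optional[Union[str, Path]] = None,
    json_path: Optional[Union[str, Path]] = None,
) -> None:
    """Write the per-read TSV and/or the JSON summary of a counting run."""
    if tsv_path is not None and table is not None:
        table.to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        Path(json_path).write_text(json.dumps(result.to_dict(), indent=2, sort_keys=True))
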