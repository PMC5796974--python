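"""Interval algebra over cistromes.

A cistrome — the genome-wide binding-site set of a transcription factor under
one condition — is held as an :class:`IntervalSet` of 0-based half-open
intervals (BED convention, strand ignored). The module provides BED3 I/O,
merging, the symmetric Venn partition of two cistromes counted on the merged
union, and quantification of binding-site remodeling (retained / lost /
gained sites, percent inhibition) between a pre- and post-treatment cistrome.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Union

from .errors import BedParseError, DataError

PathLike = Union[str, Path]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic region [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise DataError("chromosome name must be non-empty")
        if self.start < 0:
            raise DataError(f"negative start coordinate: {self.start}")
        if self.start >= self.end:
            raise DataError(
                f"start must precede end: got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >= 1 bp."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class IntervalSet:
    """An ordered, possibly overlapping collection of intervals with a label."""

    intervals: list[GenomicInterval] = field(default_factory=list)
    label: str = ""

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return sorted(self.intervals) == sorted(other.intervals)

    def sorted(self) -> "IntervalSet":
        return IntervalSet(sorted(self.intervals), self.label)

    def total_span(self) -> int:
        """Number of covered base pairs (after merging)."""
        return sum(iv.length for iv in merge(self))


@dataclass
class OverlapSummary:
    """Venn partition of two cistromes, counted on merged union intervals."""

    n_common: int
    n_unique_a: int
    n_unique_b: int
    common: list[GenomicInterval]
    unique_a: list[GenomicInterval]
    unique_b: list[GenomicInterval]

    def as_dict(self) -> dict:
        return {
            "n_common": self.n_common,
            "n_unique_a": self.n_unique_a,
            "n_unique_b": self.n_unique_b,
        }


@dataclass
class RemodelingSummary:
    """Retained / lost / gained site counts between two cistromes.

    ``percent_inhibition`` is 100 * (1 - (n_retained + n_gained) / n_pre):
    positive when the post cistrome shrank, negative when binding expanded,
    zero under pure redistribution (equal loss and gain). ``None`` when the
    pre cistrome is empty (undefined).
    """

    n_pre: int
    n_retained: int
    n_lost: int
    n_gained: int
    percent_inhibition: Optional[float]

    def as_dict(self) -> dict:
        return {
            "n_pre": self.n_pre,
            "n_retained": self.n_retained,
            "n_lost": self.n_lost,
            "n_gained": self.n_gained,
            "percent_inhibition": self.percent_inhibition,
        }


def read_bed(path: PathLike, label: str = "") -> IntervalSet:
    """Read a BED file (3+ whitespace-delimited columns; extras ignored).

    Raises :class:`BedParseError` naming the 1-based line number on malformed
    coordinates.
    """
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise BedParseError(
                    f"expected >= 3 columns, got {len(fields)}", lineno
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise BedParseError(
                    f"non-integer coordinates {fields[1]!r}, {fields[2]!r}",
                    lineno,
                ) from None
            if start < 0:
                raise BedParseError(f"negative start {start}", lineno)
            if start >= end:
                raise BedParseError(
                    f"start {start} not before end {end}", lineno
                )
            intervals.append(GenomicInterval(chrom, start, end))
    if not label:
        label = Path(path).stem
    return IntervalSet(intervals, label)


def write_bed(interval_set: IntervalSet, path: PathLike) -> None:
    """Write BED3, sorted by (chrom, start, end)."""
    with open(path, "w") as fh:
        fh.write(format_bed(interval_set))


def format_bed(interval_set: IntervalSet) -> str:
    buf = io.StringIO()
    for iv in sorted(interval_set.intervals):
        buf.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
    return buf.getvalue()


def merge(interval_set: Union[IntervalSet, Iterable[GenomicInterval]]) -> IntervalSet:
    """Merge overlapping or book-ended intervals into a disjoint sorted set.

    Output intervals are pairwise disjoint with >= 1 bp gaps; the set of
    covered bases is preserved (adjacent intervals sharing a boundary are
    fused, matching BEDtools ``merge`` defaults).
    """
    ivs = list(interval_set)
    label = interval_set.label if isinstance(interval_set, IntervalSet) else ""
    if not ivs:
        return IntervalSet([], label)
    ivs.sort()
    merged = [ivs[0]]
    for iv in ivs[1:]:
        last = merged[-1]
        if iv.chrom == last.chrom and iv.start <= last.end:
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(iv)
    return IntervalSet(merged, label)


def _any_overlap(query: GenomicInterval, merged_sorted: list[GenomicInterval]) -> bool:
    # binary search over a merged, sorted interval list
    import bisect

    idx = bisect.bisect_left(
        merged_sorted, (query.chrom, query.end, 0), key=lambda iv: (iv.chrom, iv.start, iv.end)
    )
    # candidates: the interval starting before query.end on the same chrom
    for j in (idx - 1, idx):
        if 0 <= j < len(merged_sorted) and merged_sorted[j].overlaps(query):
            return True
    return False


def intersect(a: IntervalSet, b: IntervalSet) -> OverlapSummary:
    """Venn partition of two cistromes on the merged union.

    Each interval of merge(a + b) is classified common (overlaps >= 1 bp of
    both inputs), unique-A, or unique-B. The partition is exhaustive and
    exclusive and symmetric under swapping a and b.
    """
    union = merge(IntervalSet(list(a) + list(b)))
    merged_a = merge(a).intervals
    merged_b = merge(b).intervals
    common, unique_a, unique_b = [], [], []
    for iv in union:
        in_a = _any_overlap(iv, merged_a)
        in_b = _any_overlap(iv, merged_b)
        if in_a and in_b:
            common.append(iv)
        elif in_a:
            unique_a.append(iv)
        else:
            unique_b.append(iv)
    return OverlapSummary(
        n_common=len(common),
        n_unique_a=len(unique_a),
        n_unique_b=len(unique_b),
        common=common,
        unique_a=unique_a,
        unique_b=unique_b,
    )


def remodel(pre: IntervalSet, post: IntervalSet) -> RemodelingSummary:
    """Quantify binding-site remodeling from ``pre`` to ``post``.

    A pre site is retained iff it overlaps >= 1 bp of any post site; post
    sites overlapping no pre site are gained. Percent inhibition follows the
    :class:`RemodelingSummary` formula and is ``None`` for an empty pre set.
    """
    merged_pre = merge(pre).intervals
    merged_post = merge(post).intervals
    n_pre = len(merged_pre)
    n_retained = sum(1 for iv in merged_pre if _any_overlap(iv, merged_post))
    n_lost = n_pre - n_retained
    n_gained = sum(1 for iv in merged_post if not _any_overlap(iv, merged_pre))
    if n_pre > 0:
        pct = 100.0 * (1.0 - (n_retained + n_gained) / n_pre)
    else:
        pct = None
    return RemodelingSummary(n_pre, n_retained, n_lost, n_gained, pct)
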