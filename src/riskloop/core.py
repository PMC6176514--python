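"""Core genomic-interval types and interval algebra.

All coordinates are 0-based half-open (BED native). File readers convert
1-based conventions (SNP tables, GTF) on input; everything downstream uses a
single convention so there is no off-by-one drift between pipeline stages.

"Overlap" throughout the package means >= 1 bp of shared sequence on the same
chromosome; no minimum-overlap fraction is applied anywhere. Chromosome names
are compared verbatim unless a caller normalizes them first.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

from intervaltree import IntervalTree

STRANDS = ("+", "-", ".")

__all__ = [
    "GenomicInterval",
    "Peak",
    "LoopRecord",
    "SNPRecord",
    "MotifSite",
    "overlaps",
    "filter_overlapping",
    "window_around",
    "merge_intervals",
    "covered_bases",
    "IntervalIndex",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def mid(self) -> int:
        """Integer midpoint (floor), used for anchor distances and spans."""
        return (self.start + self.end) // 2

    def contains(self, chrom: str, pos0: int) -> bool:
        return self.chrom == chrom and self.start <= pos0 < self.end


@dataclass(frozen=True)
class Peak:
    """A scored interval call (ChIP-seq / DNase peak) tagged with its provenance.

    ``summit_offset`` is the distance of the point-source summit from
    ``interval.start`` (narrowPeak column 10); ``None`` when the caller did not
    report one, in which case :attr:`summit_pos0` falls back to the midpoint.
    """

    interval: GenomicInterval
    name: str = "."
    score: float = 0.0
    summit_offset: Optional[int] = None
    mark: str = ""
    cell_line: str = ""
    replicate: str = ""

    def __post_init__(self) -> None:
        if self.summit_offset is not None:
            if not 0 <= self.summit_offset < self.interval.length:
                raise ValueError(
                    f"summit_offset {self.summit_offset} outside peak of length "
                    f"{self.interval.length} ({self.name})"
                )

    @property
    def summit_pos0(self) -> int:
        if self.summit_offset is not None:
            return self.interval.start + self.summit_offset
        return self.interval.mid

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass(frozen=True)
class LoopRecord:
    """A chromatin loop: two anchor intervals plus dataset provenance and q-value.

    Anchors are canonically ordered (anchor1.start < anchor2.start) for
    intra-chromosomal loops. Inter-chromosomal records are representable so
    that :func:`riskloop.loops.filter_loops` can reject and count them, but
    they have no span.
    """

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    dataset: str = ""
    q_value: float = 0.0
    name: str = "."

    def __post_init__(self) -> None:
        if not 0.0 <= self.q_value <= 1.0:
            raise ValueError(f"q_value must be in [0, 1], got {self.q_value}")
        if self.is_intra and self.anchor2.start < self.anchor1.start:
            # canonicalize in place (frozen dataclass: go through __dict__)
            a1, a2 = self.anchor2, self.anchor1
            object.__setattr__(self, "anchor1", a1)
            object.__setattr__(self, "anchor2", a2)

    @property
    def is_intra(self) -> bool:
        return self.anchor1.chrom == self.anchor2.chrom

    @property
    def span_bp(self) -> Optional[int]:
        """Anchor midpoint-to-midpoint distance; None for inter-chromosomal."""
        if not self.is_intra:
            return None
        return self.anchor2.mid - self.anchor1.mid


@dataclass(frozen=True)
class SNPRecord:
    """A single-nucleotide variant as a 0-based point position."""

    rsid: str
    chrom: str
    pos0: int

    def __post_init__(self) -> None:
        if self.pos0 < 0:
            raise ValueError(f"pos0 must be >= 0, got {self.pos0} for {self.rsid}")

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.pos0, self.pos0 + 1)


@dataclass(frozen=True)
class MotifSite:
    """An oriented CTCF motif match; strand is never '.'."""

    interval: GenomicInterval
    score: float = 0.0
    name: str = "."

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError("MotifSite requires a stranded interval (+/-)")

    @property
    def strand(self) -> str:
        return self.interval.strand


IntervalLike = Union[GenomicInterval, Peak, SNPRecord, MotifSite]


def _interval_of(rec: IntervalLike) -> GenomicInterval:
    if isinstance(rec, GenomicInterval):
        return rec
    return rec.interval


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff a and b share >= 1 bp (same chromosome, half-open semantics)."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def window_around(point_chrom: str, point_pos0: int, flank: int) -> GenomicInterval:
    """Symmetric window around a point, closed on the point.

    Returns ``[max(0, pos0 - flank), pos0 + flank + 1)`` so that a position at
    exactly ``flank`` bp from the point is still inside. Clipped at the
    chromosome start.
    """
    if flank <= 0:
        raise ValueError(f"flank must be > 0, got {flank}")
    return GenomicInterval(point_chrom, max(0, point_pos0 - flank), point_pos0 + flank + 1)


class IntervalIndex:
    """Chromosome-partitioned interval tree over arbitrary interval-like records."""

    def __init__(self, records: Iterable[IntervalLike] = ()):
        self._trees: dict[str, IntervalTree] = {}
        for rec in records:
            self.add(rec)

    def add(self, rec: IntervalLike) -> None:
        iv = _interval_of(rec)
        self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, rec)

    def overlapping(self, chrom: str, start: int, end: int) -> list:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [hit.data for hit in tree.overlap(start, end)]

    def at(self, chrom: str, pos0: int) -> list:
        return self.overlapping(chrom, pos0, pos0 + 1)

    def any_overlap(self, chrom: str, start: int, end: int) -> bool:
        tree = self._trees.get(chrom)
        return tree is not None and bool(tree.overlap(start, end))

    def __len__(self) -> int:
        return sum(len(t) for t in self._trees.values())


def _check_sorted(records: Sequence[IntervalLike], label: str) -> None:
    prev = None
    for i, rec in enumerate(records):
        iv = _interval_of(rec)
        key = (iv.chrom, iv.start)
        if prev is not None and key < prev:
            raise ValueError(
                f"{label} not sorted by (chrom, start): record {i} "
                f"({iv.chrom}:{iv.start}-{iv.end}) is out of order"
            )
        prev = key


def filter_overlapping(
    query: Sequence[IntervalLike],
    reference: Sequence[Union[GenomicInterval, Peak]],
    keep_full_query: bool = True,
    streaming: bool = False,
):
    """Keep query records that overlap (>= 1 bp) at least one reference interval.

    With ``keep_full_query`` (the default, bedtools ``-wa -u`` semantics) the
    original query records are returned unmodified, each at most once, in input
    order — this preserves summit offsets needed by downstream summit-window
    steps. With ``keep_full_query=False`` the clipped intersection with each
    overlapping reference interval is returned instead (one plain interval per
    overlapping pair).

    ``streaming`` switches to a sorted sweep that requires both inputs sorted
    by (chrom, start) and raises naming the first out-of-order record.
    """
    ref_ivs = [_interval_of(r) for r in reference]
    if streaming:
        _check_sorted(query, "query")
        _check_sorted(ref_ivs, "reference")
    index = IntervalIndex(ref_ivs)
    if keep_full_query:
        out = []
        for rec in query:
            iv = _interval_of(rec)
            if index.any_overlap(iv.chrom, iv.start, iv.end):
                out.append(rec)
        return out
    clipped: list[GenomicInterval] = []
    for rec in query:
        iv = _interval_of(rec)
        hits = sorted(
            index.overlapping(iv.chrom, iv.start, iv.end),
            key=lambda r: (r.start, r.end),
        )
        for ref in hits:
            clipped.append(
                GenomicInterval(iv.chrom, max(iv.start, ref.start), min(iv.end, ref.end))
            )
    return clipped


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping or abutting intervals per chromosome (strand ignored)."""
    by_key = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in by_key:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            if iv.end > merged[-1].end:
                merged[-1] = GenomicInterval(iv.chrom, merged[-1].start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def covered_bases(target: GenomicInterval, intervals: Iterable[GenomicInterval]) -> int:
    """Base pairs of ``target`` covered by the union of ``intervals``."""
    total = 0
    for iv in merge_intervals(
        ivc for ivc in intervals if ivc.chrom == target.chrom
    ):
        lo = max(target.start, iv.start)
        hi = min(target.end, iv.end)
        if hi > lo:
            total += hi - lo
    return total
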