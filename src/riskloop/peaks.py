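"""High-confidence peak derivation and genomic-context classification.

A high-confidence (HC) peak is a ChIP-seq peak reproduced in both biological
replicates: the HC set keeps the replicate-1 records (full coordinates and
summit offsets) that overlap at least one replicate-2 peak. Context
classification assigns each query interval one category from {promoter, exon,
TTS, intron, intergenic} against a set of gene models, with a fixed priority
order, the way HOMER-style annotators report peak locations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .core import GenomicInterval, IntervalIndex, Peak, SNPRecord, overlaps

CATEGORIES = ("promoter", "exon", "TTS", "intron", "intergenic")
_PRIORITY = {c: i for i, c in enumerate(CATEGORIES)}

__all__ = [
    "CATEGORIES",
    "GeneModel",
    "ContextCall",
    "HCPeakSet",
    "derive_hc_peaks",
    "classify_context",
    "summarize_peak_classes",
]


@dataclass(frozen=True)
class GeneModel:
    """A stranded gene: TSS/TES positions (0-based) plus exon intervals."""

    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    tss_pos0: int
    tes_pos0: int
    exons: tuple = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        lo, hi = self.span.start, self.span.end
        for ex in self.exons:
            if ex.start < lo or ex.end > hi:
                raise ValueError(f"gene {self.gene_id}: exon outside gene span")

    @property
    def span(self) -> GenomicInterval:
        lo = min(self.tss_pos0, self.tes_pos0)
        hi = max(self.tss_pos0, self.tes_pos0)
        return GenomicInterval(self.chrom, lo, hi + 1, self.strand)


@dataclass(frozen=True)
class ContextCall:
    category: str
    gene_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.category == "intergenic" and self.gene_id is not None:
            raise ValueError("intergenic calls carry no gene_id")


@dataclass
class HCPeakSet:
    """Replicate-reproducible peaks for one mark / cell line / condition."""

    mark: str
    cell_line: str
    condition: str = ""
    peaks: list = field(default_factory=list)

    @property
    def label(self) -> str:
        parts = [self.mark, self.cell_line]
        if self.condition:
            parts.append(self.condition)
        return ":".join(parts)

    def __len__(self) -> int:
        return len(self.peaks)


def derive_hc_peaks(
    rep1: Sequence[Peak],
    rep2: Sequence[Peak],
    condition: str = "",
    coords: str = "rep1",
) -> HCPeakSet:
    """Peaks present in both replicates.

    Returns the replicate-1 peaks overlapping >= 1 replicate-2 peak, sorted by
    (chrom, start); ``coords="merged"`` instead reports the union span of each
    rep1 peak with all rep2 peaks it touches (summits dropped). Raises if the
    two replicates disagree on mark or cell line.
    """
    if coords not in ("rep1", "merged"):
        raise ValueError("coords must be 'rep1' or 'merged'")
    tags = {(p.mark, p.cell_line) for p in rep1} | {(p.mark, p.cell_line) for p in rep2}
    if len(tags) > 1:
        raise ValueError(f"replicates mix marks/cell lines: {sorted(tags)}")
    mark, cell_line = next(iter(tags)) if tags else ("", "")

    index = IntervalIndex(rep2)
    hc: list[Peak] = []
    for p in rep1:
        partners = index.overlapping(p.interval.chrom, p.interval.start, p.interval.end)
        if not partners:
            continue
        if coords == "rep1":
            hc.append(p)
        else:
            lo = min([p.interval.start] + [q.interval.start for q in partners])
            hi = max([p.interval.end] + [q.interval.end for q in partners])
            hc.append(
                Peak(
                    interval=GenomicInterval(p.interval.chrom, lo, hi),
                    name=p.name,
                    score=p.score,
                    summit_offset=None,
                    mark=p.mark,
                    cell_line=p.cell_line,
                    replicate="HC",
                )
            )
    hc.sort(key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end))
    return HCPeakSet(mark=mark, cell_line=cell_line, condition=condition, peaks=hc)


def _promoter_interval(gene: GeneModel, upstream: int, downstream: int) -> GenomicInterval:
    t = gene.tss_pos0
    if gene.strand == "+":
        return GenomicInterval(gene.chrom, max(0, t - upstream), t + downstream)
    return GenomicInterval(gene.chrom, max(0, t - downstream + 1), t + upstream + 1)


def _tts_interval(gene: GeneModel, flank: int) -> GenomicInterval:
    t = gene.tes_pos0
    return GenomicInterval(gene.chrom, max(0, t - flank), t + flank + 1)


def _gene_category(
    query: GenomicInterval,
    gene: GeneModel,
    promoter_upstream: int,
    promoter_downstream: int,
    tts_flank: int,
) -> Optional[str]:
    if gene.chrom != query.chrom:
        return None
    if overlaps(query, _promoter_interval(gene, promoter_upstream, promoter_downstream)):
        return "promoter"
    if any(overlaps(query, ex) for ex in gene.exons):
        return "exon"
    if overlaps(query, _tts_interval(gene, tts_flank)):
        return "TTS"
    if overlaps(query, gene.span):
        return "intron"
    return None


def classify_context(
    query: Union[GenomicInterval, Peak, SNPRecord],
    genes: Sequence[GeneModel],
    promoter_upstream: int = 1000,
    promoter_downstream: int = 100,
    tts_flank: int = 1000,
) -> ContextCall:
    """Assign one genomic-context category to a query interval.

    The promoter window runs from ``promoter_upstream`` bp upstream of the TSS
    to ``promoter_downstream`` bp downstream (strand-aware; defaults 1 kb / 100
    bp); the TTS window is +/- ``tts_flank`` of the transcription end site.
    Categories compete by fixed priority promoter > exon > TTS > intron >
    intergenic; ties between genes in the same category break by distance from
    the query midpoint to the TSS.
    """
    iv = query if isinstance(query, GenomicInterval) else query.interval
    best: Optional[tuple[int, int, str, str]] = None
    for gene in genes:
        cat = _gene_category(iv, gene, promoter_upstream, promoter_downstream, tts_flank)
        if cat is None:
            continue
        key = (_PRIORITY[cat], abs(iv.mid - gene.tss_pos0), gene.gene_id, cat)
        if best is None or key < best:
            best = key
    if best is None:
        return ContextCall("intergenic")
    return ContextCall(best[3], gene_id=best[2])


def summarize_peak_classes(
    hc_sets: Iterable[HCPeakSet],
    genes: Sequence[GeneModel],
    **classify_kwargs,
) -> pd.DataFrame:
    """Per-HC-set genomic-context composition (counts and fractions).

    Returns one row per set with ``n_<category>`` counts summing to the set
    size and ``frac_<category>`` fractions summing to 1 (all-zero with a
    warning for an empty set).
    """
    rows = []
    for hc in hc_sets:
        counts = dict.fromkeys(CATEGORIES, 0)
        for p in hc.peaks:
            counts[classify_context(p, genes, **classify_kwargs).category] += 1
        n = len(hc.peaks)
        if n == 0:
            warnings.warn(f"HC set {hc.label} is empty; reporting zero fractions")
        row = {"set": hc.label, "mark": hc.mark, "cell_line": hc.cell_line, "n_peaks": n}
        for c in CATEGORIES:
            row[f"n_{c}"] = counts[c]
            row[f"frac_{c}"] = counts[c] / n if n else 0.0
        rows.append(row)
    return pd.DataFrame(rows)
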