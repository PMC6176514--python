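"""Enhancer-desert detection, repressive-mark coverage, target-gene
prediction, and enhancer-adoption candidate nomination.

An enhancer desert is the interior of a risk loop (between the inner anchor
edges, excluding the anchor bins themselves) that contains no H3K27Ac HC peak
from any roster dataset and is at least ``min_desert_len`` long. Deserts of
interest in repressed loci are typically covered by the polycomb mark
H3K27me3; coverage is reported as a continuous merged-base fraction, with no
boolean threshold. When the insulating anchor is deleted, the caged gene's
most plausible activator is the nearest pre-existing H3K27Ac peak outside the
desert — the adoption candidate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

from .core import GenomicInterval, Peak, covered_bases, merge_intervals
from .loops import RiskLoop
from .peaks import GeneModel, HCPeakSet
from .snp_funnel import AnnotatedSNP

__all__ = [
    "DesertCall",
    "TargetGenePrediction",
    "AdoptionCandidate",
    "loop_interior",
    "find_deserts",
    "repressive_coverage",
    "predict_targets",
    "adoption_candidates",
]


@dataclass(frozen=True)
class DesertCall:
    loop: RiskLoop
    interior: Optional[GenomicInterval]  # None when anchors touch/overlap
    n_k27ac_interior: int
    is_desert: bool
    k27me3_covered_fraction: float = 0.0


@dataclass(frozen=True)
class TargetGenePrediction:
    risk_site_id: str
    gene_id: str
    basis: str  # within_loop | within_window
    distance_bp: int

    def __post_init__(self) -> None:
        if self.basis not in ("within_loop", "within_window"):
            raise ValueError(f"unknown basis {self.basis!r}")


@dataclass(frozen=True)
class AdoptionCandidate:
    peak: Peak
    distance_bp: int
    contains_risk_snp: bool
    rank: int


def loop_interior(loop: RiskLoop) -> Optional[GenomicInterval]:
    """Region between the inner anchor edges; None if the anchors touch."""
    a1, a2 = loop.loop.anchor1, loop.loop.anchor2
    if a2.start <= a1.end:
        return None
    return GenomicInterval(a1.chrom, a1.end, a2.start)


def find_deserts(
    risk_loops: Sequence[RiskLoop],
    k27ac: Sequence[HCPeakSet],
    min_desert_len: int = 100_000,
    k27me3: Sequence[Peak] = (),
) -> list[DesertCall]:
    """Flag H3K27Ac-devoid loop interiors.

    Counts H3K27Ac HC peaks from any roster dataset overlapping each loop
    interior; ``is_desert`` iff the count is zero and the interior is at least
    ``min_desert_len`` long. Overlapping anchors give a zero-length interior
    and is_desert False. When H3K27me3 peaks are supplied the interior's
    repressive coverage fraction is reported alongside.
    """
    all_peaks = [p for hc in k27ac for p in hc.peaks]
    calls = []
    for rl in risk_loops:
        interior = loop_interior(rl)
        if interior is None:
            calls.append(DesertCall(rl, None, 0, False, 0.0))
            continue
        n = sum(
            1
            for p in all_peaks
            if p.interval.chrom == interior.chrom
            and p.interval.start < interior.end
            and interior.start < p.interval.end
        )
        cov = repressive_coverage(interior, k27me3) if k27me3 else 0.0
        calls.append(
            DesertCall(
                rl,
                interior,
                n,
                n == 0 and interior.length >= min_desert_len,
                cov,
            )
        )
    return calls


def repressive_coverage(interior: Optional[GenomicInterval], k27me3: Sequence[Peak]) -> float:
    """Fraction of the interior covered by the merged union of H3K27me3 peaks."""
    if interior is None or interior.length == 0:
        warnings.warn("repressive_coverage of a zero-length interior is 0")
        return 0.0
    return covered_bases(interior, (p.interval for p in k27me3)) / interior.length


def predict_targets(
    risk_site: tuple[str, int],
    risk_loops: Sequence[RiskLoop],
    genes: Sequence[GeneModel],
    window: int = 1_000_000,
) -> list[TargetGenePrediction]:
    """Candidate target genes of a risk site.

    Union of genes whose TSS falls inside any risk-loop span (outer anchor
    edges) and genes whose TSS is within +/- ``window`` of the site;
    deduplicated with within_loop taking precedence. Gene membership uses the
    TSS, not the full gene span, so loop-edge calls are unambiguous.
    """
    chrom, pos0 = risk_site
    preds: dict[str, TargetGenePrediction] = {}
    spans = [
        GenomicInterval(rl.loop.anchor1.chrom, rl.loop.anchor1.start, rl.loop.anchor2.end)
        for rl in risk_loops
        if rl.loop.is_intra
    ]
    for g in genes:
        if g.chrom != chrom:
            continue
        dist = abs(g.tss_pos0 - pos0)
        in_loop = any(sp.contains(g.chrom, g.tss_pos0) for sp in spans)
        if in_loop:
            preds[g.gene_id] = TargetGenePrediction("", g.gene_id, "within_loop", dist)
        elif window > 0 and dist <= window:
            preds[g.gene_id] = TargetGenePrediction("", g.gene_id, "within_window", dist)
    return sorted(preds.values(), key=lambda p: (p.distance_bp, p.gene_id))


def adoption_candidates(
    deleted_site: tuple[str, int],
    desert: DesertCall,
    k27ac: Sequence[HCPeakSet],
    risk_snps: Sequence[AnnotatedSNP] = (),
    max_distance: int = 2_000_000,
) -> list[AdoptionCandidate]:
    """Rank candidate adopted enhancers after an anchor deletion.

    H3K27Ac HC peaks outside the desert interior (the pre-deletion desert) on
    the deleted site's chromosome, within ``max_distance``, ranked by distance
    to the deleted site. Peaks containing an H3K27Ac-stage risk SNP are
    flagged. Distinct overlapping peaks from different roster datasets are
    merged into one candidate site before ranking.
    """
    chrom, pos0 = deleted_site
    interior = desert.interior
    sites = merge_intervals(
        p.interval
        for hc in k27ac
        for p in hc.peaks
        if p.interval.chrom == chrom
    )
    risk_positions = [
        a.snp.pos0 for a in risk_snps if a.snp.chrom == chrom and a.in_dhs and a.any_k27ac
    ]
    out = []
    for iv in sites:
        if interior is not None and iv.start < interior.end and interior.start < iv.end:
            continue  # inside the desert: post-deletion-only signal, not pre-existing
        if iv.contains(chrom, pos0):
            dist = 0
        else:
            dist = min(abs(iv.start - pos0), abs(iv.end - 1 - pos0))
        if dist > max_distance:
            continue
        flagged = any(iv.start <= rp < iv.end for rp in risk_positions)
        out.append((dist, iv, flagged))
    out.sort(key=lambda t: (t[0], t[1].start))
    return [
        AdoptionCandidate(
            peak=Peak(interval=iv, name=f"candidate_{i + 1}", mark="H3K27Ac"),
            distance_bp=dist,
            contains_risk_snp=flagged,
            rank=i + 1,
        )
        for i, (dist, iv, flagged) in enumerate(out)
    ]
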