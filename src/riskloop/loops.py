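"""Loop filtering, anchor association, cross-dataset support, and CTCF motif
convergence.

Loops enter the pipeline pre-called (significant contacts between 10-kb anchor
bins); this module applies the span/q-value input filter (50 kb – 10 Mb,
q < 0.05 by default), associates risk sites with anchors, counts how many
independent interaction datasets reproduce a loop (anchor midpoints within one
bin of slack), and classifies the motif orientation at the two anchors —
convergent (+/-) being the configuration loop-extrusion models require.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from .core import GenomicInterval, IntervalIndex, LoopRecord, MotifSite

logger = logging.getLogger(__name__)

CONVERGENCE_CLASSES = ("convergent", "tandem", "divergent", "ambiguous", "no_motif")

__all__ = [
    "CONVERGENCE_CLASSES",
    "RiskLoop",
    "filter_loops",
    "anchor_hits",
    "cross_dataset_support",
    "classify_convergence",
    "build_risk_loop",
]


@dataclass(frozen=True)
class RiskLoop:
    """A loop anchored at a risk site, with reproducibility and orientation."""

    loop: LoopRecord
    support: int
    supporting_datasets: tuple
    convergence: str
    span_bp: int

    def __post_init__(self) -> None:
        if self.support < 1:
            raise ValueError("support counts the loop's own dataset; must be >= 1")
        if self.span_bp <= 0:
            raise ValueError("span must be positive")
        if self.convergence not in CONVERGENCE_CLASSES:
            raise ValueError(f"unknown convergence class {self.convergence!r}")


def filter_loops(
    loops: Sequence[LoopRecord],
    min_span: int = 50_000,
    max_span: int = 10_000_000,
    max_q: float = 0.05,
) -> list[LoopRecord]:
    """Input filter: intra-chromosomal loops with min_span <= span < max_span
    and q_value < max_q (strict). Inter-chromosomal records are dropped and
    their count logged."""
    kept: list[LoopRecord] = []
    n_inter = 0
    for lp in loops:
        if not lp.is_intra:
            n_inter += 1
            continue
        if min_span <= lp.span_bp < max_span and lp.q_value < max_q:
            kept.append(lp)
    if n_inter:
        logger.info("filter_loops: rejected %d inter-chromosomal record(s)", n_inter)
    return kept


def anchor_hits(
    position: tuple[str, int],
    loops: Sequence[LoopRecord],
) -> list[tuple[LoopRecord, int]]:
    """All (loop, anchor index) pairs whose anchor contains the position.

    Anchor index is 1 or 2; a position in the loop interior is not a hit.
    """
    chrom, pos0 = position
    out = []
    for lp in loops:
        if lp.anchor1.contains(chrom, pos0):
            out.append((lp, 1))
        if lp.anchor2.contains(chrom, pos0):
            out.append((lp, 2))
    return out


def cross_dataset_support(
    query_loop: LoopRecord,
    all_datasets: Mapping[str, Sequence[LoopRecord]],
    slack: int = 10_000,
) -> tuple[int, tuple[str, ...]]:
    """How many interaction datasets contain a loop matching the query.

    A dataset supports the query iff it has a loop whose two anchor midpoints
    lie within ``slack`` bp of the query's respective anchor midpoints (the
    default slack is one 10-kb matrix bin). The query's own dataset always
    counts. Returns (support, sorted supporting dataset names).
    """
    if slack < 0:
        raise ValueError("slack must be >= 0")
    if not query_loop.is_intra:
        raise ValueError("cross_dataset_support requires an intra-chromosomal loop")
    m1, m2 = query_loop.anchor1.mid, query_loop.anchor2.mid
    chrom = query_loop.anchor1.chrom
    supporting = {query_loop.dataset} if query_loop.dataset else set()
    for ds, lps in all_datasets.items():
        if ds in supporting:
            continue
        for lp in lps:
            if not lp.is_intra or lp.anchor1.chrom != chrom:
                continue
            if abs(lp.anchor1.mid - m1) <= slack and abs(lp.anchor2.mid - m2) <= slack:
                supporting.add(ds)
                break
    return len(supporting), tuple(sorted(supporting))


def _anchor_top_motif(anchor: GenomicInterval, index: IntervalIndex):
    """Highest-scoring motif overlapping the anchor; None if none; 'tie' when
    two opposite-strand motifs share the top score."""
    hits: list[MotifSite] = index.overlapping(anchor.chrom, anchor.start, anchor.end)
    if not hits:
        return None
    top = max(m.score for m in hits)
    strands = {m.strand for m in hits if m.score == top}
    if len(strands) > 1:
        return "tie"
    return next(m for m in hits if m.score == top)


def classify_convergence(loop: LoopRecord, motifs: Sequence[MotifSite]) -> str:
    """Motif-orientation class of a loop's anchor pair.

    Per anchor the highest-scoring overlapping motif is chosen; with anchors
    in canonical genomic order the strand pair maps (+,-) -> convergent,
    (+,+)/(-,-) -> tandem, (-,+) -> divergent. An anchor without a motif gives
    no_motif; equal-score opposite-strand motifs at an anchor give ambiguous.
    """
    index = IntervalIndex(motifs)
    picks = [_anchor_top_motif(loop.anchor1, index), _anchor_top_motif(loop.anchor2, index)]
    if any(p is None for p in picks):
        return "no_motif"
    if any(p == "tie" for p in picks):
        return "ambiguous"
    s1, s2 = picks[0].strand, picks[1].strand
    if (s1, s2) == ("+", "-"):
        return "convergent"
    if (s1, s2) == ("-", "+"):
        return "divergent"
    return "tandem"


def build_risk_loop(
    loop: LoopRecord,
    all_datasets: Mapping[str, Sequence[LoopRecord]],
    motifs: Sequence[MotifSite],
    slack: int = 10_000,
) -> RiskLoop:
    """Assemble the RiskLoop record: support, orientation class, and span."""
    support, supporting = cross_dataset_support(loop, all_datasets, slack=slack)
    return RiskLoop(
        loop=loop,
        support=support,
        supporting_datasets=supporting,
        convergence=classify_convergence(loop, motifs),
        span_bp=loop.span_bp,
    )
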