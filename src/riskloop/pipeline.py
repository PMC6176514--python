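"""End-to-end driver: from raw replicate peaks, loops, SNPs, motifs, and gene
models to annotated SNPs, funnel counts, and risk-loop calls.

Thin composition layer over the stage modules; the in-memory entry point
:func:`analyze` is what the CLI, the tests, and the acceptance script all run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .core import GenomicInterval, LoopRecord, MotifSite, SNPRecord
from .loops import RiskLoop, anchor_hits, build_risk_loop, filter_loops
from .peaks import GeneModel, derive_hc_peaks
from .snp_funnel import (
    FunnelCounts,
    annotate_snps,
    attach_loop_hits,
    funnel_counts,
)
from .simulate import LandscapeTruth

__all__ = ["PipelineResult", "analyze", "analyze_truth", "risk_loops_at"]


@dataclass
class PipelineResult:
    k27ac_sets: list
    ctcf_sets: list
    loops_filtered: dict
    annotated: list
    counts: FunnelCounts
    genes: Sequence[GeneModel]
    motifs: Sequence[MotifSite]

    def risk_loops_at(self, site: tuple[str, int], slack: int = 10_000) -> list[RiskLoop]:
        return risk_loops_at(site, self.loops_filtered, self.motifs, slack=slack)


def analyze(
    snps: Sequence[SNPRecord],
    dhs: Sequence[GenomicInterval],
    k27ac_replicates: Mapping[str, tuple],
    ctcf_replicates: Mapping[str, tuple],
    loop_datasets: Mapping[str, Sequence[LoopRecord]],
    genes: Sequence[GeneModel] = (),
    motifs: Sequence[MotifSite] = (),
    ctcf_flank: int = 1000,
    min_span: int = 50_000,
    max_span: int = 10_000_000,
    max_q: float = 0.05,
) -> PipelineResult:
    """Run the full annotation pipeline on in-memory records.

    ``k27ac_replicates`` / ``ctcf_replicates`` map dataset label to the
    (rep1, rep2) peak lists; HC sets are derived per dataset, loops are
    filtered per interaction dataset, SNPs annotated, loop anchor membership
    attached, and the funnel counted.
    """
    k27ac_sets = [derive_hc_peaks(r1, r2) for r1, r2 in k27ac_replicates.values()]
    ctcf_sets = [derive_hc_peaks(r1, r2) for r1, r2 in ctcf_replicates.values()]
    loops_filtered = {
        ds: filter_loops(lps, min_span=min_span, max_span=max_span, max_q=max_q)
        for ds, lps in loop_datasets.items()
    }
    annotated = annotate_snps(snps, dhs, k27ac_sets, ctcf_sets, genes=genes, ctcf_flank=ctcf_flank)
    attach_loop_hits(annotated, loops_filtered)
    return PipelineResult(
        k27ac_sets=k27ac_sets,
        ctcf_sets=ctcf_sets,
        loops_filtered=loops_filtered,
        annotated=annotated,
        counts=funnel_counts(annotated),
        genes=genes,
        motifs=motifs,
    )


def analyze_truth(truth: LandscapeTruth) -> PipelineResult:
    """Run :func:`analyze` directly on a simulated landscape's raw inputs."""
    cfg = truth.config
    k27 = {
        ds: (truth.chip_peaks[("H3K27Ac", ds, "rep1")], truth.chip_peaks[("H3K27Ac", ds, "rep2")])
        for ds in cfg.chip_datasets
    }
    ctcf = {
        ds: (truth.chip_peaks[("CTCF", ds, "rep1")], truth.chip_peaks[("CTCF", ds, "rep2")])
        for ds in cfg.chip_datasets
    }
    return analyze(
        snps=truth.snps,
        dhs=truth.dhs,
        k27ac_replicates=k27,
        ctcf_replicates=ctcf,
        loop_datasets=truth.loops,
        genes=truth.genes,
        motifs=truth.motifs,
    )


def risk_loops_at(
    site: tuple[str, int],
    loops_filtered: Mapping[str, Sequence[LoopRecord]],
    motifs: Sequence[MotifSite],
    slack: int = 10_000,
) -> list[RiskLoop]:
    """Distinct risk loops anchored at a site, with support and convergence.

    Loops found in several datasets are collapsed to one RiskLoop per
    anchor-pair equivalence class (midpoints within ``slack``), keeping the
    lowest-q representative.
    """
    all_loops = [lp for lps in loops_filtered.values() for lp in lps]
    hits = anchor_hits(site, all_loops)
    chosen: list[LoopRecord] = []
    for lp, _idx in sorted(hits, key=lambda t: (t[0].q_value, t[0].dataset)):
        dup = any(
            abs(lp.anchor1.mid - c.anchor1.mid) <= slack
            and abs(lp.anchor2.mid - c.anchor2.mid) <= slack
            for c in chosen
        )
        if not dup:
            chosen.append(lp)
    chosen.sort(key=lambda lp: lp.span_bp)
    return [build_risk_loop(lp, loops_filtered, motifs, slack=slack) for lp in chosen]
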