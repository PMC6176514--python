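"""The SNP annotation funnel.

Fine-mapped risk SNPs are annotated in nested stages: (1) the SNP base must
fall in an open-chromatin (DHS) interval; (2) DHS-positive SNPs are tested
against each H3K27Ac HC peak set (full peak intervals) and each CTCF HC set
(+/- 1 kb windows around peak summits — histone peaks are broad so the whole
peak counts, while CTCF binding is point-like so a summit window is used);
(3) the loops module adds per-interaction-dataset anchor membership. Evidence
vectors are all-false below the DHS stage, so stage counts are monotone by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from .core import GenomicInterval, IntervalIndex, LoopRecord, SNPRecord, window_around
from .peaks import ContextCall, GeneModel, HCPeakSet, classify_context

__all__ = [
    "AnnotatedSNP",
    "FunnelCounts",
    "annotate_snps",
    "attach_loop_hits",
    "funnel_counts",
    "evidence_matrix",
]


@dataclass
class AnnotatedSNP:
    """One evidence-matrix row: a SNP plus per-dataset regulatory evidence."""

    snp: SNPRecord
    in_dhs: bool
    k27ac_hits: dict[str, bool]
    ctcf_hits: dict[str, bool]
    context: ContextCall
    loop_hits: Optional[dict[str, bool]] = None

    @property
    def any_k27ac(self) -> bool:
        return any(self.k27ac_hits.values())

    @property
    def any_ctcf(self) -> bool:
        return any(self.ctcf_hits.values())

    @property
    def any_loop(self) -> bool:
        return bool(self.loop_hits) and any(self.loop_hits.values())


@dataclass(frozen=True)
class FunnelCounts:
    """Stage counts of the funnel; loop stages are None when loops were not run."""

    n_input: int
    n_dhs: int
    n_dhs_k27ac: int
    n_dhs_ctcf: int
    n_dhs_k27ac_loop: Optional[int] = None
    n_dhs_ctcf_loop: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.n_input >= self.n_dhs >= self.n_dhs_k27ac:
            raise ValueError("funnel counts must be nested: input >= dhs >= dhs+k27ac")
        if self.n_dhs < self.n_dhs_ctcf:
            raise ValueError("funnel counts must be nested: dhs >= dhs+ctcf")
        if self.n_dhs_k27ac_loop is not None and self.n_dhs_k27ac < self.n_dhs_k27ac_loop:
            raise ValueError("funnel counts must be nested: dhs+k27ac >= dhs+k27ac+loop")
        if self.n_dhs_ctcf_loop is not None and self.n_dhs_ctcf < self.n_dhs_ctcf_loop:
            raise ValueError("funnel counts must be nested: dhs+ctcf >= dhs+ctcf+loop")

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_dhs": self.n_dhs,
            "n_dhs_k27ac": self.n_dhs_k27ac,
            "n_dhs_ctcf": self.n_dhs_ctcf,
            "n_dhs_k27ac_loop": self.n_dhs_k27ac_loop,
            "n_dhs_ctcf_loop": self.n_dhs_ctcf_loop,
        }


def annotate_snps(
    snps: Sequence[SNPRecord],
    dhs: Sequence[GenomicInterval],
    k27ac_sets: Sequence[HCPeakSet],
    ctcf_sets: Sequence[HCPeakSet],
    genes: Sequence[GeneModel] = (),
    ctcf_flank: int = 1000,
) -> list[AnnotatedSNP]:
    """Annotate each SNP with nested DHS / H3K27Ac / CTCF evidence per dataset.

    The SNP's single base is tested against the DHS catalog; only DHS-positive
    SNPs are tested against H3K27Ac HC peaks (full intervals) and CTCF HC
    summit windows (summit +/- ``ctcf_flank``; peak midpoint when no summit
    was called). Context is computed for every SNP. Raises on duplicate rsids;
    output preserves input order.
    """
    if ctcf_flank <= 0:
        raise ValueError("ctcf_flank must be > 0")
    seen: set[str] = set()
    for s in snps:
        if s.rsid in seen:
            raise ValueError(f"duplicate rsid {s.rsid!r} in SNP table")
        seen.add(s.rsid)

    dhs_index = IntervalIndex(dhs)
    k27_indexes = {hc.label: IntervalIndex(hc.peaks) for hc in k27ac_sets}
    ctcf_indexes = {
        hc.label: IntervalIndex(
            window_around(p.interval.chrom, p.summit_pos0, ctcf_flank) for p in hc.peaks
        )
        for hc in ctcf_sets
    }

    out: list[AnnotatedSNP] = []
    for s in snps:
        in_dhs = dhs_index.any_overlap(s.chrom, s.pos0, s.pos0 + 1)
        if in_dhs:
            k27 = {lab: idx.any_overlap(s.chrom, s.pos0, s.pos0 + 1) for lab, idx in k27_indexes.items()}
            ctcf = {lab: idx.any_overlap(s.chrom, s.pos0, s.pos0 + 1) for lab, idx in ctcf_indexes.items()}
        else:  # stages are nested: no mark evidence outside open chromatin
            k27 = dict.fromkeys(k27_indexes, False)
            ctcf = dict.fromkeys(ctcf_indexes, False)
        out.append(
            AnnotatedSNP(
                snp=s,
                in_dhs=in_dhs,
                k27ac_hits=k27,
                ctcf_hits=ctcf,
                context=classify_context(s, genes),
            )
        )
    return out


def attach_loop_hits(
    annotated: Sequence[AnnotatedSNP],
    loop_datasets: Mapping[str, Sequence[LoopRecord]],
) -> None:
    """Fill per-interaction-dataset anchor membership (in place).

    A dataset hit means the SNP base lies inside either anchor of one of that
    dataset's (already filtered) loops. Nesting is preserved: SNPs outside
    open chromatin get all-false vectors.
    """
    indexes = {
        ds: IntervalIndex([lp.anchor1 for lp in lps] + [lp.anchor2 for lp in lps])
        for ds, lps in loop_datasets.items()
    }
    for a in annotated:
        if not a.in_dhs:
            a.loop_hits = dict.fromkeys(indexes, False)
            continue
        a.loop_hits = {
            ds: idx.any_overlap(a.snp.chrom, a.snp.pos0, a.snp.pos0 + 1)
            for ds, idx in indexes.items()
        }


def funnel_counts(annotated: Sequence[AnnotatedSNP]) -> FunnelCounts:
    """Stage counts; each SNP counts once per stage however many datasets hit."""
    has_loops = any(a.loop_hits is not None for a in annotated)
    n_dhs = sum(a.in_dhs for a in annotated)
    n_k27 = sum(a.in_dhs and a.any_k27ac for a in annotated)
    n_ctcf = sum(a.in_dhs and a.any_ctcf for a in annotated)
    return FunnelCounts(
        n_input=len(annotated),
        n_dhs=n_dhs,
        n_dhs_k27ac=n_k27,
        n_dhs_ctcf=n_ctcf,
        n_dhs_k27ac_loop=(
            sum(a.in_dhs and a.any_k27ac and a.any_loop for a in annotated) if has_loops else None
        ),
        n_dhs_ctcf_loop=(
            sum(a.in_dhs and a.any_ctcf and a.any_loop for a in annotated) if has_loops else None
        ),
    )


def evidence_matrix(annotated: Sequence[AnnotatedSNP], mark: str = "H3K27Ac") -> pd.DataFrame:
    """Per-SNP x per-dataset evidence table for one mark.

    Rows are the SNPs passing that mark's stage (DHS-positive and hit in >= 1
    dataset of the mark), ordered by (chrom, pos, rsid); columns are the
    dataset roster booleans, the genomic context, and — when loops were
    attached — the interaction-dataset booleans.
    """
    if mark not in ("H3K27Ac", "CTCF"):
        raise ValueError("mark must be 'H3K27Ac' or 'CTCF'")
    picker = (lambda a: a.k27ac_hits) if mark == "H3K27Ac" else (lambda a: a.ctcf_hits)
    rows = []
    for a in annotated:
        if not (a.in_dhs and any(picker(a).values())):
            continue
        row = {"rsid": a.snp.rsid, "chrom": a.snp.chrom, "pos": a.snp.pos0 + 1}
        row.update(picker(a))
        row["context"] = a.context.category
        if a.loop_hits is not None:
            row.update(a.loop_hits)
        rows.append(row)
    if not rows:
        # header-only frame with the roster columns of the first record, if any
        cols = ["rsid", "chrom", "pos"]
        if annotated:
            cols += list(picker(annotated[0])) + ["context"]
            if annotated[0].loop_hits is not None:
                cols += list(annotated[0].loop_hits)
        return pd.DataFrame(columns=cols)
    df = pd.DataFrame(rows)
    return df.sort_values(["chrom", "pos", "rsid"], kind="mergesort").reset_index(drop=True)
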