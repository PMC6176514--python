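"""Fully labeled synthetic regulatory landscape with planted ground truth.

The generator lays out two chromosomes and plants, with known labels, every
structure the pipeline consumes: fine-mapped SNPs at controlled funnel depths
(none / DHS / DHS+H3K27Ac / DHS+CTCF, each mark stratum split into
loop-anchored and not), replicate ChIP-seq peak pairs with a controlled
reproducibility rate, chromatin loops across several interaction datasets
with planted motif-orientation classes, q-values and spans straddling the
input filters, and two "repressed locus" models: a risk CTCF anchor shared by
two loops whose interiors are H3K27Ac deserts covered by H3K27me3, a caged
gene inside, neighbor genes across the +/- 1 Mb window, and a pre-existing
enhancer just outside the desert ~70 kb from the caged gene's TSS.

Layout is block-based: every planted SNP owns a disjoint slot sized for its
evidence (plus anchors and interior for loop strata), background peaks live
in dedicated zones on 25-kb centers, so no label can be contaminated by a
neighboring feature. Regenerating with the same seed is byte-identical.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .core import GenomicInterval, LoopRecord, MotifSite, Peak, SNPRecord
from .deletion import DeletionExperiment
from .peaks import GeneModel
from . import io as rio

SCENARIOS = ("risk_anchor_deleted", "partner_anchor_deleted", "double_partner_deleted", "control")
LABELS = ("none", "dhs", "k27ac", "k27ac_loop", "ctcf", "ctcf_loop")

__all__ = [
    "SCENARIOS",
    "LABELS",
    "LandscapeConfig",
    "PlantedLoop",
    "SpecialLocus",
    "LandscapeTruth",
    "simulate_landscape",
    "write_landscape",
    "simulate_deletion_expression",
    "scenario_true_effects",
]


@dataclass
class LandscapeConfig:
    """Conditions of the synthetic landscape — the modeled experiment.

    The funnel strata default to a prostate-cancer-scale fine-mapping
    scenario (2181 input SNPs, 443 in DHS, 222/93 also in H3K27Ac/CTCF,
    203/85 of those loop-anchored); the ChIP roster defaults to nine
    cell-line/condition datasets per mark (seven prostate lines, two also
    +/- DHT, in duplicate) and five chromatin-interaction datasets.
    """

    # funnel strata (nested counts)
    n_snps: int = 2181
    n_dhs: int = 443
    n_k27ac: int = 222
    n_ctcf: int = 93
    n_k27ac_loop: int = 203
    n_ctcf_loop: int = 85
    # dataset rosters
    chip_datasets: tuple = (
        "PrEC",
        "RWPE-1",
        "RWPE-2",
        "22Rv1",
        "22Rv1-DHT",
        "C4-2B",
        "LNCaP",
        "LNCaP-DHT",
        "VCaP",
    )
    loop_datasets: tuple = (
        "RWPE1-HiC",
        "22Rv1-HiC",
        "C4-2B-HiC",
        "GM12878-HiC",
        "GM12878-HiChIP",
    )
    # replicate structure
    reproducibility: float = 0.8
    rep_jitter_sd: float = 50.0  # bp, replicate-2 edge jitter
    summit_jitter_sd: float = 20.0
    # geometry
    snp_slot: int = 4_000
    anchor_size: int = 10_000
    # interiors sized so even jitter-shrunk spans clear the 50-kb loop filter
    # while staying below the 100-kb desert-length floor
    loop_interior_range: tuple = (44_000, 80_000)
    loop_anchor_jitter: int = 2_000  # per-dataset anchor shift, < matching slack
    dhs_width: int = 300
    k27ac_width: int = 1_500
    ctcf_width: int = 600
    motif_width: int = 19
    # loop statistics
    q_pass_range: tuple = (0.001, 0.049)
    convergence_mix: dict = field(
        default_factory=lambda: {"convergent": 0.5, "tandem": 0.3, "divergent": 0.2}
    )
    include_filter_decoys: bool = True
    # background
    n_background_sites: int = 150  # per chromosome, 25-kb centers
    background_presence: float = 0.5
    n_background_dhs: int = 300
    n_background_genes: int = 12
    # repressed loci (two, mirroring a 220/320-kb and a 300/715-kb loop pair)
    locus_spans: dict = field(
        default_factory=lambda: {"A": (220_000, 320_000), "B": (300_000, 715_000)}
    )
    adoption_offset: int = 70_000  # enhancer center upstream of the caged TSS
    caged_tss_offset: int = 30_000  # caged TSS past the risk anchor midpoint
    # expression model
    caged_baseline: float = 100.0
    nb_dispersion: float = 0.1
    # unlinked transcriptome rows in the expression matrix; keeps library
    # totals stable so one strongly induced gene cannot skew normalization
    n_transcriptome_genes: int = 2_000
    scenario_effects: dict = field(
        default_factory=lambda: {
            "risk_anchor_deleted": 100.0,
            "partner_anchor_deleted": 2.0,
            "double_partner_deleted": 7.0,
            "control": 1.0,
        }
    )
    secondary_effects: dict = field(  # locus B co-responders in the risk scenario
        default_factory=lambda: {"CAGEB2": 10.0, "CAGEB3": 5.0, "CAGEB4": 3.0}
    )

    # ------------------------------------------------------------- derived
    @property
    def n_none(self) -> int:
        return self.n_snps - self.n_dhs

    @property
    def n_dhs_only(self) -> int:
        return self.n_dhs - self.n_k27ac - self.n_ctcf

    @property
    def n_k27ac_noloop(self) -> int:
        return self.n_k27ac - self.n_k27ac_loop

    @property
    def n_ctcf_noloop(self) -> int:
        return self.n_ctcf - self.n_ctcf_loop

    def validate(self) -> None:
        for name in ("n_none", "n_dhs_only", "n_k27ac_noloop", "n_ctcf_noloop"):
            if getattr(self, name) < 0:
                raise ValueError(f"infeasible funnel strata: derived {name} is negative")
        if self.n_ctcf_loop < len(self.locus_spans):
            raise ValueError("need one ctcf+loop SNP per repressed locus")
        if self.n_k27ac_noloop < len(self.locus_spans):
            raise ValueError("need one k27ac SNP per repressed locus (adoption enhancer)")
        if not 0.0 <= self.reproducibility <= 1.0:
            raise ValueError("reproducibility must be in [0, 1]")
        lo, hi = self.loop_interior_range
        if lo >= hi or lo <= 0:
            raise ValueError("loop_interior_range must be an increasing positive pair")
        if lo + self.anchor_size - 2 * self.loop_anchor_jitter < 50_000:
            raise ValueError(
                "loop_interior_range too small: a jitter-shrunk planted loop could "
                "fall below the 50-kb span filter and lose its SNP's loop evidence"
            )
        for name, spans in self.locus_spans.items():
            smallest = min(spans)
            needed = self.anchor_size + self.caged_tss_offset + 10_000
            if smallest <= needed:
                raise ValueError(
                    f"locus {name}: desert loop span {smallest} too small to cage a gene "
                    f"(needs > {needed})"
                )
        if abs(sum(self.convergence_mix.values()) - 1.0) > 1e-9:
            raise ValueError("convergence_mix must sum to 1")

    @classmethod
    def small(cls) -> "LandscapeConfig":
        """Desk-scale configuration for fast unit tests."""
        return cls(
            n_snps=60,
            n_dhs=24,
            n_k27ac=12,
            n_ctcf=8,
            n_k27ac_loop=8,
            n_ctcf_loop=6,
            chip_datasets=("PrEC", "22Rv1", "C4-2B"),
            loop_datasets=("RWPE1-HiC", "22Rv1-HiC", "GM12878-HiC"),
            n_background_sites=25,
            n_background_dhs=40,
            n_background_genes=4,
        )


@dataclass
class PlantedLoop:
    loop_id: str
    chrom: str
    anchor1: GenomicInterval
    anchor2: GenomicInterval
    span_bp: int
    convergence: str
    datasets: tuple
    q_value: float
    is_desert: bool
    snp_rsid: Optional[str] = None


@dataclass
class SpecialLocus:
    name: str
    chrom: str
    risk_rsid: str
    risk_pos0: int
    anchor1: GenomicInterval
    partner_anchors: tuple
    loop_ids: tuple
    primary_gene: str
    caged_genes: tuple
    adoption_rsid: str
    enhancer: GenomicInterval
    desert_interiors: tuple  # one per loop, inner-anchor-edge intervals
    window_genes: tuple


@dataclass
class LandscapeTruth:
    config: LandscapeConfig
    seed: int
    genome: dict
    snps: list
    snp_labels: dict
    snp_mark_datasets: dict
    snp_loop_datasets: dict
    dhs: list
    chip_peaks: dict  # (mark, dataset, rep) -> [Peak]
    reproducible_counts: dict  # (mark, dataset) -> int planted HC truth
    k27me3_peaks: dict  # rep -> [Peak]
    loops: dict  # dataset -> [LoopRecord]
    planted_loops: list
    decoy_loops: list  # (LoopRecord, expected_kept: bool)
    motifs: list
    genes: list
    special_loci: dict
    baseline_expr: dict
    files: dict = field(default_factory=dict)

    def gene_by_id(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


# ------------------------------------------------------------------ builder


class _Builder:
    def __init__(self, cfg: LandscapeConfig, seed: int):
        cfg.validate()
        self.cfg = cfg
        self.rng = np.random.default_rng(seed)
        self.seed = seed
        self.chroms = ("chr1", "chr2")
        # ordinary SNP blocks start past the repressed-locus regions
        # (locus base 1.1 Mb + largest downstream window ~1 Mb + margin)
        self.cursor = {"chr1": 2_200_000, "chr2": 2_200_000}
        self.snps: list[SNPRecord] = []
        self.snp_labels: dict[str, str] = {}
        self.snp_mark_datasets: dict[str, tuple] = {}
        self.snp_loop_datasets: dict[str, tuple] = {}
        self.dhs: list[GenomicInterval] = []
        self.chip: dict[tuple, list[Peak]] = {
            (mark, ds, rep): []
            for mark in ("H3K27Ac", "CTCF")
            for ds in cfg.chip_datasets
            for rep in ("rep1", "rep2")
        }
        self.repro_counts: dict[tuple, int] = {
            (mark, ds): 0 for mark in ("H3K27Ac", "CTCF") for ds in cfg.chip_datasets
        }
        self.k27me3: dict[str, list[Peak]] = {"rep1": [], "rep2": []}
        self.loops: dict[str, list[LoopRecord]] = {ds: [] for ds in cfg.loop_datasets}
        self.planted_loops: list[PlantedLoop] = []
        self.decoy_loops: list[tuple] = []
        self.motifs: list[MotifSite] = []
        self.genes: list[GeneModel] = []
        self.special: dict[str, SpecialLocus] = {}
        self.baseline_expr: dict[str, float] = {}
        self._n_rsid = 0
        self._n_loop = 0

    # -------------------------------------------------------------- helpers
    def _rsid(self) -> str:
        self._n_rsid += 1
        return f"rs{self._n_rsid:06d}"

    def _loop_id(self) -> str:
        self._n_loop += 1
        return f"loop{self._n_loop:05d}"

    def _jit(self, sd: float) -> int:
        return int(np.clip(round(self.rng.normal(0.0, sd)), -3 * sd, 3 * sd))

    def _plant_replicated_peak(
        self, mark: str, dataset: str, chrom: str, start: int, end: int,
        summit_offset: Optional[int], name: str, reproducible: bool = True,
    ) -> None:
        cfg = self.cfg
        score = float(round(self.rng.uniform(100, 1000), 1))
        p1 = Peak(
            interval=GenomicInterval(chrom, start, end),
            name=name,
            score=score,
            summit_offset=summit_offset,
            mark=mark,
            cell_line=dataset,
            replicate="rep1",
        )
        self.chip[(mark, dataset, "rep1")].append(p1)
        if not reproducible:
            return
        self.repro_counts[(mark, dataset)] += 1
        ds, de = self._jit(cfg.rep_jitter_sd), self._jit(cfg.rep_jitter_sd)
        s2 = max(0, start + ds)
        e2 = max(s2 + 50, end + de)
        # keep the replicate pair overlapping and the summit inside
        if summit_offset is not None:
            summit_abs = start + summit_offset + self._jit(cfg.summit_jitter_sd)
            summit_abs = int(np.clip(summit_abs, s2, e2 - 1))
            so2 = summit_abs - s2
        else:
            so2 = None
        if s2 >= end or e2 <= start:  # defensive; jitter is clamped well below width
            s2, e2, so2 = start, end, summit_offset
        self.chip[(mark, dataset, "rep2")].append(
            Peak(
                interval=GenomicInterval(chrom, s2, e2),
                name=name,
                score=score,
                summit_offset=so2,
                mark=mark,
                cell_line=dataset,
                replicate="rep2",
            )
        )

    def _plant_dhs(self, chrom: str, pos0: int) -> None:
        half = self.cfg.dhs_width // 2
        self.dhs.append(GenomicInterval(chrom, max(0, pos0 - half), pos0 + half))

    def _choose_datasets(self, roster: tuple) -> tuple:
        m = 1 + int(self.rng.integers(0, len(roster)))
        picked = self.rng.choice(len(roster), size=m, replace=False)
        return tuple(roster[i] for i in sorted(picked))

    def _plant_motif_pair(self, chrom: str, a1: GenomicInterval, a2: GenomicInterval, klass: str) -> None:
        if klass == "convergent":
            s1, s2 = "+", "-"
        elif klass == "divergent":
            s1, s2 = "-", "+"
        else:  # tandem
            s1 = s2 = "+" if self.rng.random() < 0.5 else "-"
        for anchor, strand in ((a1, s1), (a2, s2)):
            score = float(round(self.rng.uniform(10, 15), 2))
            m0 = anchor.mid - self.cfg.motif_width // 2
            self.motifs.append(
                MotifSite(
                    interval=GenomicInterval(chrom, m0, m0 + self.cfg.motif_width, strand),
                    score=score,
                    name="CTCF_motif",
                )
            )
            if self.rng.random() < 0.3:  # weaker decoy motif on the opposite strand
                d0 = anchor.mid + 2_000
                self.motifs.append(
                    MotifSite(
                        interval=GenomicInterval(
                            chrom, d0, d0 + self.cfg.motif_width, "-" if strand == "+" else "+"
                        ),
                        score=float(round(score - self.rng.uniform(2, 5), 2)),
                        name="CTCF_motif_decoy",
                    )
                )

    def _plant_loop(
        self, chrom: str, a1: GenomicInterval, a2: GenomicInterval,
        datasets: tuple, q_lo: float, q_hi: float, klass: str,
        is_desert: bool, snp_rsid: Optional[str],
    ) -> PlantedLoop:
        cfg = self.cfg
        loop_id = self._loop_id()
        q = float(round(self.rng.uniform(q_lo, q_hi), 6))
        for ds in datasets:
            j1 = int(self.rng.integers(-cfg.loop_anchor_jitter, cfg.loop_anchor_jitter + 1))
            j2 = int(self.rng.integers(-cfg.loop_anchor_jitter, cfg.loop_anchor_jitter + 1))
            self.loops[ds].append(
                LoopRecord(
                    anchor1=GenomicInterval(chrom, a1.start + j1, a1.end + j1),
                    anchor2=GenomicInterval(chrom, a2.start + j2, a2.end + j2),
                    dataset=ds,
                    q_value=q,
                    name=loop_id,
                )
            )
        self._plant_motif_pair(chrom, a1, a2, klass)
        planted = PlantedLoop(
            loop_id=loop_id,
            chrom=chrom,
            anchor1=a1,
            anchor2=a2,
            span_bp=a2.mid - a1.mid,
            convergence=klass,
            datasets=datasets,
            q_value=q,
            is_desert=is_desert,
            snp_rsid=snp_rsid,
        )
        self.planted_loops.append(planted)
        return planted

    def _next_chrom(self) -> str:
        return min(self.chroms, key=lambda c: (self.cursor[c], c))

    def _add_gene(
        self, gene_id: str, name: str, chrom: str, tss: int, length: int, strand: str = "+"
    ) -> GeneModel:
        if strand == "+":
            start, end = tss, tss + length
            exons = (
                GenomicInterval(chrom, start, start + 1_000, strand),
                GenomicInterval(chrom, end - 1_000, end, strand),
            )
            g = GeneModel(gene_id, name, chrom, strand, tss, end - 1, exons)
        else:
            start, end = tss - length + 1, tss + 1
            exons = (
                GenomicInterval(chrom, start, start + 1_000, strand),
                GenomicInterval(chrom, end - 1_000, end, strand),
            )
            g = GeneModel(gene_id, name, chrom, strand, tss, start, exons)
        self.genes.append(g)
        self.baseline_expr[gene_id] = float(round(self.rng.uniform(50, 500), 1))
        return g

    # -------------------------------------------------------- special locus
    def _build_locus(self, name: str, chrom: str) -> None:
        cfg = self.cfg
        spans = tuple(sorted(cfg.locus_spans[name]))
        base = 1_100_000  # anchor bin start; upstream window genes fit above the decoy zone
        anchor1 = GenomicInterval(chrom, base, base + cfg.anchor_size)
        risk_pos = anchor1.mid
        risk_rsid = self._rsid()
        self.snps.append(SNPRecord(risk_rsid, chrom, risk_pos))
        self.snp_labels[risk_rsid] = "ctcf_loop"
        self._plant_dhs(chrom, risk_pos)
        # CTCF bound in every roster dataset, summit at the SNP
        half = cfg.ctcf_width // 2
        for ds in cfg.chip_datasets:
            self._plant_replicated_peak(
                "CTCF", ds, chrom, risk_pos - half, risk_pos + half, half,
                f"CTCF_{name}_risk",
            )
        self.snp_mark_datasets[risk_rsid] = ("CTCF", tuple(cfg.chip_datasets))
        self.snp_loop_datasets[risk_rsid] = tuple(cfg.loop_datasets)

        loop_ids, partners, interiors = [], [], []
        for span in spans:
            m2 = risk_pos + span
            anchor2 = GenomicInterval(chrom, m2 - cfg.anchor_size // 2, m2 + cfg.anchor_size // 2)
            partners.append(anchor2)
            for ds in cfg.chip_datasets:  # partner CTCF site, also robustly bound
                self._plant_replicated_peak(
                    "CTCF", ds, chrom, anchor2.mid - half, anchor2.mid + half, half,
                    f"CTCF_{name}_partner",
                )
            planted = self._plant_loop(
                chrom, anchor1, anchor2, tuple(cfg.loop_datasets),
                0.001, 0.02, "convergent", is_desert=True, snp_rsid=risk_rsid,
            )
            loop_ids.append(planted.loop_id)
            interiors.append(GenomicInterval(chrom, anchor1.end, anchor2.start))

        # H3K27me3 blanket over the widest interior (~83% merged coverage)
        wide = interiors[-1]
        pos = wide.start
        while pos + 20_000 <= wide.end:
            p1 = Peak(
                interval=GenomicInterval(chrom, pos, pos + 20_000),
                name=f"K27me3_{name}", score=200.0, mark="H3K27me3",
                cell_line="22Rv1", replicate="rep1",
            )
            j = self._jit(cfg.rep_jitter_sd)
            p2 = Peak(
                interval=GenomicInterval(chrom, pos + j, pos + 20_000 + j),
                name=f"K27me3_{name}", score=200.0, mark="H3K27me3",
                cell_line="22Rv1", replicate="rep2",
            )
            self.k27me3["rep1"].append(p1)
            self.k27me3["rep2"].append(p2)
            pos += 24_000

        # caged genes inside the loops
        caged = []
        primary = f"CAGE{name}1"
        g = self._add_gene(primary, primary, chrom, risk_pos + cfg.caged_tss_offset, 8_000)
        self.baseline_expr[primary] = cfg.caged_baseline
        caged.append(primary)
        if name == "B":
            for i, off in ((2, 60_000), (3, 90_000)):
                gid = f"CAGE{name}{i}"
                self._add_gene(gid, gid, chrom, risk_pos + off, 8_000)
                caged.append(gid)
            # one caged gene between the two partner anchors (outside the small
            # loop, inside the large one)
            gid = f"CAGE{name}4"
            self._add_gene(gid, gid, chrom, partners[0].end + 25_000, 8_000)
            caged.append(gid)

        # pre-existing enhancer outside the desert, ~adoption_offset from the
        # caged TSS, flagged by its own H3K27Ac-stage risk SNP
        enh_center = (risk_pos + cfg.caged_tss_offset) - cfg.adoption_offset
        ehalf = cfg.k27ac_width // 2
        enhancer = GenomicInterval(chrom, enh_center - ehalf, enh_center + ehalf)
        enh_datasets = self._choose_datasets(cfg.chip_datasets)
        for ds in enh_datasets:
            self._plant_replicated_peak(
                "H3K27Ac", ds, chrom, enhancer.start, enhancer.end, ehalf, f"K27Ac_{name}_enh"
            )
        adoption_rsid = self._rsid()
        self.snps.append(SNPRecord(adoption_rsid, chrom, enh_center))
        self.snp_labels[adoption_rsid] = "k27ac"
        self._plant_dhs(chrom, enh_center)
        self.snp_mark_datasets[adoption_rsid] = ("H3K27Ac", enh_datasets)
        self.snp_loop_datasets[adoption_rsid] = ()

        # neighbor genes across the +/- 1 Mb window
        window_genes = []
        for j in range(1, 7):
            tss = base - 130_000 * j
            gid = f"WIN{name}U{j}"
            self._add_gene(gid, gid, chrom, tss, 6_000)
            window_genes.append(gid)
        tss = risk_pos + max(spans) + 40_000
        j = 1
        while tss <= risk_pos + 1_000_000 - 10_000:
            gid = f"WIN{name}D{j}"
            self._add_gene(gid, gid, chrom, tss, 6_000)
            window_genes.append(gid)
            tss += 130_000
            j += 1

        self.special[name] = SpecialLocus(
            name=name,
            chrom=chrom,
            risk_rsid=risk_rsid,
            risk_pos0=risk_pos,
            anchor1=anchor1,
            partner_anchors=tuple(partners),
            loop_ids=tuple(loop_ids),
            primary_gene=primary,
            caged_genes=tuple(caged),
            adoption_rsid=adoption_rsid,
            enhancer=enhancer,
            desert_interiors=tuple(interiors),
            window_genes=tuple(window_genes),
        )

    # ----------------------------------------------------- ordinary strata
    def _build_snp_blocks(self) -> None:
        cfg = self.cfg
        n_special_ctcf_loop = len(self.cfg.locus_spans)
        n_special_k27 = len(self.cfg.locus_spans)
        labels = (
            ["none"] * cfg.n_none
            + ["dhs"] * cfg.n_dhs_only
            + ["k27ac"] * (cfg.n_k27ac_noloop - n_special_k27)
            + ["k27ac_loop"] * cfg.n_k27ac_loop
            + ["ctcf"] * cfg.n_ctcf_noloop
            + ["ctcf_loop"] * (cfg.n_ctcf_loop - n_special_ctcf_loop)
        )
        order = self.rng.permutation(len(labels))
        classes = list(cfg.convergence_mix)
        probs = [cfg.convergence_mix[c] for c in classes]
        for idx in order:
            label = labels[idx]
            chrom = self._next_chrom()
            cur = self.cursor[chrom]
            rsid = self._rsid()
            if label in ("k27ac_loop", "ctcf_loop"):
                interior = int(self.rng.integers(*cfg.loop_interior_range))
                a1 = GenomicInterval(chrom, cur, cur + cfg.anchor_size)
                a2 = GenomicInterval(
                    chrom, cur + cfg.anchor_size + interior, cur + 2 * cfg.anchor_size + interior
                )
                snp_pos = a1.mid
                self.cursor[chrom] = a2.end + 2_000
            else:
                snp_pos = cur + cfg.snp_slot // 2
                self.cursor[chrom] = cur + cfg.snp_slot
            self.snps.append(SNPRecord(rsid, chrom, snp_pos))
            self.snp_labels[rsid] = label

            if label == "none":
                self.snp_mark_datasets[rsid] = ("", ())
                self.snp_loop_datasets[rsid] = ()
                if self.rng.random() < 0.1:  # decoy peak without open chromatin
                    ds = cfg.chip_datasets[int(self.rng.integers(len(cfg.chip_datasets)))]
                    half = cfg.k27ac_width // 2
                    self._plant_replicated_peak(
                        "H3K27Ac", ds, chrom, snp_pos - half, snp_pos + half, half, "K27Ac_decoy"
                    )
                continue

            self._plant_dhs(chrom, snp_pos)
            if label == "dhs":
                self.snp_mark_datasets[rsid] = ("", ())
                self.snp_loop_datasets[rsid] = ()
                continue

            if label.startswith("k27ac"):
                datasets = self._choose_datasets(cfg.chip_datasets)
                half = cfg.k27ac_width // 2
                center = snp_pos + int(self.rng.integers(-400, 401))
                for ds in datasets:
                    self._plant_replicated_peak(
                        "H3K27Ac", ds, chrom, center - half, center + half, half, "K27Ac_site"
                    )
                self.snp_mark_datasets[rsid] = ("H3K27Ac", datasets)
            else:
                datasets = self._choose_datasets(cfg.chip_datasets)
                half = cfg.ctcf_width // 2
                summit = snp_pos + int(self.rng.integers(-800, 801))
                for ds in datasets:
                    self._plant_replicated_peak(
                        "CTCF", ds, chrom, summit - half, summit + half, half, "CTCF_site"
                    )
                self.snp_mark_datasets[rsid] = ("CTCF", datasets)

            if label.endswith("_loop"):
                loop_ds = self._choose_datasets(cfg.loop_datasets)
                klass = classes[int(self.rng.choice(len(classes), p=probs))]
                self._plant_loop(
                    chrom, a1, a2, loop_ds, *cfg.q_pass_range, klass,
                    is_desert=False, snp_rsid=rsid,
                )
                self.snp_loop_datasets[rsid] = loop_ds
            else:
                self.snp_loop_datasets[rsid] = ()

    # ----------------------------------------------------------- background
    def _build_background(self) -> None:
        cfg = self.cfg
        for chrom in self.chroms:
            zone_start = self.cursor[chrom] + 50_000
            pos = zone_start
            for _ in range(cfg.n_background_sites):
                center = pos + 12_500
                for mark, width in (("H3K27Ac", cfg.k27ac_width), ("CTCF", cfg.ctcf_width)):
                    half = width // 2
                    for ds in cfg.chip_datasets:
                        r = self.rng.random()
                        if r >= cfg.background_presence:
                            continue
                        reproducible = self.rng.random() < cfg.reproducibility
                        if reproducible:
                            self._plant_replicated_peak(
                                mark, ds, chrom, center - half, center + half, half,
                                "bg", reproducible=True,
                            )
                        elif self.rng.random() < 0.5:  # rep1-only: fails the HC rule
                            self._plant_replicated_peak(
                                mark, ds, chrom, center - half, center + half, half,
                                "bg_rep1only", reproducible=False,
                            )
                        else:  # rep2-only
                            self.chip[(mark, ds, "rep2")].append(
                                Peak(
                                    interval=GenomicInterval(chrom, center - half, center + half),
                                    name="bg_rep2only",
                                    score=float(round(self.rng.uniform(100, 1000), 1)),
                                    summit_offset=half,
                                    mark=mark,
                                    cell_line=ds,
                                    replicate="rep2",
                                )
                            )
                pos += 25_000
            # background open chromatin, away from every planted SNP
            zone_end = pos
            for _ in range(cfg.n_background_dhs):
                p = int(self.rng.integers(zone_start, zone_end))
                self._plant_dhs(chrom, p)
            # background genes on 40-kb centers past the peak zone
            gpos = zone_end + 20_000
            for j in range(cfg.n_background_genes):
                strand = "+" if self.rng.random() < 0.5 else "-"
                length = int(self.rng.integers(5_000, 15_000))
                tss = gpos if strand == "+" else gpos + length - 1
                self._add_gene(f"BG{chrom[3:]}G{j + 1}", f"BG{chrom[3:]}G{j + 1}", chrom, tss, length, strand)
                gpos += 40_000
            self.cursor[chrom] = gpos + 50_000

    def _build_decoys(self) -> None:
        """Loops that straddle the span/q filters, in a reserved SNP-free zone."""
        cfg = self.cfg
        if not cfg.include_filter_decoys:
            return
        ds = cfg.loop_datasets[0]
        chrom = "chr1"

        def bin_at(mid: int) -> GenomicInterval:
            return GenomicInterval(chrom, mid - 5_000, mid + 5_000)

        cases = [
            (bin_at(25_000), bin_at(75_000), 0.01, True),  # span exactly 50 kb
            (bin_at(25_000), bin_at(74_999), 0.01, False),  # 49,999: below range
            (bin_at(25_000), bin_at(10_025_000), 0.01, False),  # 10 Mb: at the cap
            (bin_at(25_000), bin_at(85_000), 0.05, False),  # q at the cutoff
            (bin_at(25_000), bin_at(85_000), 0.2, False),  # q above
        ]
        for a1, a2, q, kept in cases:
            rec = LoopRecord(a1, a2, dataset=ds, q_value=q, name="decoy")
            self.loops[ds].append(rec)
            self.decoy_loops.append((rec, kept))
        inter = LoopRecord(
            GenomicInterval("chr1", 20_000, 30_000),
            GenomicInterval("chr2", 20_000, 30_000),
            dataset=ds,
            q_value=0.01,
            name="decoy_inter",
        )
        self.loops[ds].append(inter)
        self.decoy_loops.append((inter, False))

    # -------------------------------------------------------------- finish
    def build(self) -> LandscapeTruth:
        self._build_locus("A", "chr1")
        self._build_locus("B", "chr2")
        self._build_snp_blocks()
        self._build_background()
        self._build_decoys()
        for i in range(self.cfg.n_transcriptome_genes):
            self.baseline_expr[f"TX{i + 1:05d}"] = float(round(self.rng.uniform(50, 500), 1))
        genome = {
            c: max(self.cursor[c] + 100_000, 10_100_000 if c == "chr1" else 0)
            for c in self.chroms
        }
        self.genes.sort(key=lambda g: (g.chrom, g.span.start, g.gene_id))
        self.dhs.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
        self.motifs.sort(key=lambda m: (m.interval.chrom, m.interval.start, -m.score))
        for key in self.chip:
            self.chip[key].sort(key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end))
        return LandscapeTruth(
            config=self.cfg,
            seed=self.seed,
            genome=genome,
            snps=self.snps,
            snp_labels=self.snp_labels,
            snp_mark_datasets=self.snp_mark_datasets,
            snp_loop_datasets=self.snp_loop_datasets,
            dhs=self.dhs,
            chip_peaks=self.chip,
            reproducible_counts=self.repro_counts,
            k27me3_peaks=self.k27me3,
            loops=self.loops,
            planted_loops=self.planted_loops,
            decoy_loops=self.decoy_loops,
            motifs=self.motifs,
            genes=self.genes,
            special_loci=self.special,
            baseline_expr=self.baseline_expr,
        )


def simulate_landscape(
    config: Optional[LandscapeConfig] = None,
    seed: int = 0,
    outdir: Optional[str] = None,
) -> LandscapeTruth:
    """Generate the labeled landscape; optionally write every input file.

    Same config and seed give identical truth objects and byte-identical
    files. Raises on infeasible configurations (negative derived strata,
    desert loops too small to cage a gene, ...).
    """
    truth = _Builder(config or LandscapeConfig(), seed).build()
    if outdir is not None:
        write_landscape(truth, outdir)
    return truth


def write_landscape(truth: LandscapeTruth, outdir) -> dict:
    """Write SNP table, DHS BED, replicate narrowPeaks, BEDPE loops, motif
    BED6, GTF gene models, and a truth-label JSON under ``outdir``."""
    outdir = str(outdir)
    chip_dir = os.path.join(outdir, "chip")
    loop_dir = os.path.join(outdir, "loops")
    os.makedirs(chip_dir, exist_ok=True)
    os.makedirs(loop_dir, exist_ok=True)
    files = {}

    files["snps"] = os.path.join(outdir, "snps.tsv")
    rio.write_records(truth.snps, files["snps"], "snp")
    files["dhs"] = os.path.join(outdir, "dhs.bed")
    rio.write_records(truth.dhs, files["dhs"], "bed3")
    files["motifs"] = os.path.join(outdir, "ctcf_motifs.bed")
    rio.write_records(truth.motifs, files["motifs"], "motif")
    files["genes"] = os.path.join(outdir, "genes.gtf")
    rio.write_records(truth.genes, files["genes"], "gtf")

    files["chip"] = {}
    for (mark, ds, rep), peaks in truth.chip_peaks.items():
        path = os.path.join(chip_dir, f"{mark}_{ds}_{rep}.narrowPeak")
        rio.write_records(peaks, path, "narrowpeak")
        files["chip"][(mark, ds, rep)] = path
    files["k27me3"] = {}
    for rep, peaks in truth.k27me3_peaks.items():
        path = os.path.join(chip_dir, f"H3K27me3_22Rv1_{rep}.narrowPeak")
        rio.write_records(peaks, path, "narrowpeak")
        files["k27me3"][rep] = path

    files["loops"] = {}
    for ds, lps in truth.loops.items():
        path = os.path.join(loop_dir, f"{ds}.bedpe")
        rio.write_records(lps, path, "bedpe")
        files["loops"][ds] = path

    files["truth"] = os.path.join(outdir, "truth.json")
    summary = {
        "seed": truth.seed,
        "genome": truth.genome,
        "strata": {
            "n_snps": truth.config.n_snps,
            "n_dhs": truth.config.n_dhs,
            "n_k27ac": truth.config.n_k27ac,
            "n_ctcf": truth.config.n_ctcf,
            "n_k27ac_loop": truth.config.n_k27ac_loop,
            "n_ctcf_loop": truth.config.n_ctcf_loop,
        },
        "snp_labels": truth.snp_labels,
        "reproducible_counts": {
            f"{mark}:{ds}": n for (mark, ds), n in truth.reproducible_counts.items()
        },
        "planted_loops": [
            {
                "loop_id": pl.loop_id,
                "chrom": pl.chrom,
                "anchor1": [pl.anchor1.start, pl.anchor1.end],
                "anchor2": [pl.anchor2.start, pl.anchor2.end],
                "span_bp": pl.span_bp,
                "convergence": pl.convergence,
                "datasets": list(pl.datasets),
                "q_value": pl.q_value,
                "is_desert": pl.is_desert,
                "snp_rsid": pl.snp_rsid,
            }
            for pl in truth.planted_loops
        ],
        "special_loci": {
            name: {
                "chrom": sl.chrom,
                "risk_rsid": sl.risk_rsid,
                "risk_pos0": sl.risk_pos0,
                "primary_gene": sl.primary_gene,
                "caged_genes": list(sl.caged_genes),
                "adoption_rsid": sl.adoption_rsid,
                "enhancer": [sl.enhancer.start, sl.enhancer.end],
                "window_genes": list(sl.window_genes),
            }
            for name, sl in truth.special_loci.items()
        },
        "baseline_expr": truth.baseline_expr,
    }
    with open(files["truth"], "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    truth.files = files
    return files


def scenario_true_effects(truth: LandscapeTruth, scenario: str, locus: str = "A") -> dict:
    """True per-gene fold effects for a deletion scenario at a repressed locus."""
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    sl = truth.special_loci[locus]
    cfg = truth.config
    effects = {g: 1.0 for g in truth.baseline_expr}
    effects[sl.primary_gene] = cfg.scenario_effects[scenario]
    if scenario == "risk_anchor_deleted":
        for gid, eff in cfg.secondary_effects.items():
            if gid in sl.caged_genes:
                effects[gid] = eff
    return effects


def simulate_deletion_expression(
    truth: LandscapeTruth,
    scenario: str,
    locus: str = "A",
    n_reps: int = 3,
    seed: int = 0,
    dispersion: Optional[float] = None,
) -> DeletionExperiment:
    """Negative-binomial expression matrix for one deletion scenario.

    Genes are those with a TSS within +/- 1 Mb of the locus risk site. The
    caged gene's mean is multiplied by the scenario's true effect (defaults
    100 / 2 / 7 / 1 for risk, single-partner, double-partner, control);
    locus-B secondary caged genes get their smaller planted effects in the
    risk scenario. Per-sample library sizes vary by +/- 30% so that the
    fold-change normalization is exercised.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    cfg = truth.config
    phi = cfg.nb_dispersion if dispersion is None else dispersion
    sl = truth.special_loci[locus]
    rng = np.random.default_rng(seed)
    gene_ids = [
        g.gene_id
        for g in truth.genes
        if g.chrom == sl.chrom and abs(g.tss_pos0 - sl.risk_pos0) <= 1_000_000
    ] + sorted(g for g in truth.baseline_expr if g.startswith("TX"))
    effects = scenario_true_effects(truth, scenario, locus)
    samples = [f"ctrl_{i + 1}" for i in range(n_reps)] + [f"del_{i + 1}" for i in range(n_reps)]
    scales = rng.uniform(0.7, 1.3, size=2 * n_reps)
    base = np.array([truth.baseline_expr[g] for g in gene_ids])
    eff = np.array([effects[g] for g in gene_ids])
    mu = base[:, None] * scales[None, :]
    mu[:, n_reps:] *= eff[:, None]
    if phi > 0:
        r = 1.0 / phi
        mat = rng.negative_binomial(r, r / (r + mu))
    else:
        mat = rng.poisson(mu)
    expr = pd.DataFrame(mat, index=gene_ids, columns=samples)

    if scenario == "partner_anchor_deleted":
        deleted = sl.partner_anchors[0]
        deletion = GenomicInterval(sl.chrom, deleted.mid - 450, deleted.mid + 450)
    elif scenario == "double_partner_deleted":
        lo = sl.partner_anchors[0].mid - 450
        hi = sl.partner_anchors[-1].mid + 450
        deletion = GenomicInterval(sl.chrom, lo, hi)
    else:  # risk anchor (and, for the vector control, the targeted region)
        deletion = GenomicInterval(sl.chrom, sl.risk_pos0 - 800, sl.risk_pos0 + 807)
    return DeletionExperiment(
        deletion=deletion,
        control_samples=[s for s in samples if s.startswith("ctrl_")],
        deleted_samples=[s for s in samples if s.startswith("del_")],
        expression=expr,
    )
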