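"""Expression consequences of a loop-anchor deletion.

This is the descriptive fold-change layer shown for single loci: per-gene
fold changes of deleted vs control samples on library-size-normalized values,
restricted to the +/- 1 Mb window around the deleted site, with the top
responder called by |log2 fold change|. A permutation p-value (group-label
shuffling) is available as an optional significance annotation; genome-wide
differential-expression modeling is out of scope.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import GenomicInterval
from .loops import RiskLoop
from .peaks import GeneModel

__all__ = [
    "DeletionExperiment",
    "DeletionEffect",
    "WindowReport",
    "compute_fold_changes",
    "window_report",
    "permutation_pvalue",
]


@dataclass
class DeletionExperiment:
    """A deletion assay: the removed interval, sample groups, and a gene x
    sample matrix of non-negative expression values (counts)."""

    deletion: GenomicInterval
    control_samples: list
    deleted_samples: list
    expression: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.control_samples or not self.deleted_samples:
            raise ValueError("both sample groups must be non-empty")
        missing = [
            s
            for s in list(self.control_samples) + list(self.deleted_samples)
            if s not in self.expression.columns
        ]
        if missing:
            raise ValueError(f"samples missing from expression matrix: {missing}")
        if (self.expression[list(self.control_samples) + list(self.deleted_samples)] < 0).any().any():
            raise ValueError("expression values must be non-negative")


@dataclass(frozen=True)
class DeletionEffect:
    gene_id: str
    mean_control: float
    mean_deleted: float
    fold_change: float
    log2fc: float
    in_window: Optional[bool] = None
    in_loop: Optional[bool] = None


@dataclass
class WindowReport:
    table: pd.DataFrame
    top_responder: Optional[str]
    responder_called: bool


CPM_TARGET = 1_000_000.0


def _normalize_columns(mat: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample so column sums are equal (counts per million).

    A fixed target (rather than e.g. the mean library size) makes fold
    changes exactly invariant to rescaling any single sample's column, which
    would otherwise leak through the pseudocount.
    """
    totals = mat.sum(axis=0)
    scale = totals.replace(0, np.nan)
    out = mat / scale * CPM_TARGET
    return out.fillna(0.0)


def compute_fold_changes(
    exp: DeletionExperiment,
    pseudocount: float = 0.5,
    normalize: bool = True,
) -> list[DeletionEffect]:
    """Per-gene fold change (deleted vs control) on normalized values.

    fold_change = (mean(deleted) + pseudocount) / (mean(control) + pseudocount)
    after per-sample library-size normalization (disable with
    ``normalize=False`` for pre-normalized inputs). The pseudocount keeps
    fold changes finite and pins unexpressed genes at 1.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    cols = list(exp.control_samples) + list(exp.deleted_samples)
    mat = exp.expression[cols].astype(float)
    if normalize:
        mat = _normalize_columns(mat)
    mean_c = mat[list(exp.control_samples)].mean(axis=1)
    mean_d = mat[list(exp.deleted_samples)].mean(axis=1)
    out = []
    for gene in exp.expression.index:
        fc = (mean_d[gene] + pseudocount) / (mean_c[gene] + pseudocount)
        out.append(
            DeletionEffect(
                gene_id=gene,
                mean_control=float(mean_c[gene]),
                mean_deleted=float(mean_d[gene]),
                fold_change=float(fc),
                log2fc=float(math.log2(fc)),
            )
        )
    return out


def window_report(
    effects: Sequence[DeletionEffect],
    site: tuple[str, int],
    genes: Sequence[GeneModel],
    risk_loops: Sequence[RiskLoop] = (),
    window: int = 1_000_000,
    responder_threshold: float = 2.0,
) -> WindowReport:
    """Ranked fold-change report for all genes near the deleted site.

    Restricts to genes whose TSS lies within +/- ``window`` of the site,
    annotates loop membership (TSS inside any risk-loop span), sorts by
    |log2fc| descending with ties broken by genomic distance, and calls the
    top responder — None (with ``responder_called`` False) when the largest
    effect is below ``responder_threshold``-fold in either direction. A gene
    in the window but absent from ``effects`` raises, naming the gene.
    """
    chrom, pos0 = site
    by_gene = {e.gene_id: e for e in effects}
    spans = [
        GenomicInterval(rl.loop.anchor1.chrom, rl.loop.anchor1.start, rl.loop.anchor2.end)
        for rl in risk_loops
        if rl.loop.is_intra
    ]
    rows = []
    for g in genes:
        if g.chrom != chrom or abs(g.tss_pos0 - pos0) > window:
            continue
        if g.gene_id not in by_gene:
            raise KeyError(f"gene {g.gene_id!r} is in the window but absent from the expression matrix")
        e = by_gene[g.gene_id]
        rows.append(
            {
                "gene_id": g.gene_id,
                "gene_name": g.gene_name,
                "tss_pos0": g.tss_pos0,
                "distance_bp": abs(g.tss_pos0 - pos0),
                "mean_control": e.mean_control,
                "mean_deleted": e.mean_deleted,
                "fold_change": e.fold_change,
                "log2fc": e.log2fc,
                "in_loop": any(sp.contains(g.chrom, g.tss_pos0) for sp in spans),
            }
        )
    if not rows:
        warnings.warn("no genes with TSS in the deletion window; empty report")
        return WindowReport(pd.DataFrame(rows), None, False)
    df = pd.DataFrame(rows)
    df["abs_log2fc"] = df["log2fc"].abs()
    df = df.sort_values(
        ["abs_log2fc", "distance_bp", "gene_id"], ascending=[False, True, True], kind="mergesort"
    ).reset_index(drop=True)
    top_fc = df.loc[0, "fold_change"]
    called = top_fc >= responder_threshold or top_fc <= 1.0 / responder_threshold
    return WindowReport(df, df.loc[0, "gene_id"] if called else None, called)


def permutation_pvalue(
    exp: DeletionExperiment,
    gene_id: str,
    n_permutations: int = 1000,
    pseudocount: float = 0.5,
    seed: int = 0,
) -> float:
    """Label-shuffling p-value for one gene's |log2 fold change|.

    Permutes sample group labels ``n_permutations`` times and reports the
    fraction of permutations (with add-one smoothing) whose |log2fc| meets or
    exceeds the observed one.
    """
    if gene_id not in exp.expression.index:
        raise KeyError(f"gene {gene_id!r} absent from the expression matrix")
    cols = list(exp.control_samples) + list(exp.deleted_samples)
    mat = _normalize_columns(exp.expression[cols].astype(float))
    values = mat.loc[gene_id].to_numpy()
    n_ctrl = len(exp.control_samples)

    def stat(perm: np.ndarray) -> float:
        c = values[perm[:n_ctrl]].mean()
        d = values[perm[n_ctrl:]].mean()
        return abs(math.log2((d + pseudocount) / (c + pseudocount)))

    rng = np.random.default_rng(seed)
    observed = stat(np.arange(len(cols)))
    hits = sum(
        stat(rng.permutation(len(cols))) >= observed for _ in range(n_permutations)
    )
    return (hits + 1) / (n_permutations + 1)
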