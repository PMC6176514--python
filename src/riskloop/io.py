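"""Readers and writers for the genomic text formats the pipeline touches.

Supported format tags: ``bed3``, ``bed6``, ``narrowpeak``, ``bedpe``, ``gtf``,
``snp``, ``motif``. BED-family inputs stay 0-based half-open; SNP tables
(1-based) and GTF (1-based inclusive) are converted on read. All writers emit
tab-separated text with '#'-prefixed header lines, and ``write -> read ->
write`` is byte-identical on canonical records.

GTF gene models are parsed through :mod:`gffutils` (in-memory database); the
remaining formats are read line-by-line so malformed input can be reported
with its line number.
"""

from __future__ import annotations

import os
from typing import Sequence

import gffutils

from .core import GenomicInterval, LoopRecord, MotifSite, Peak, SNPRecord
from .peaks import GeneModel

FORMATS = ("bed3", "bed6", "narrowpeak", "bedpe", "gtf", "snp", "motif")

__all__ = ["FORMATS", "ParseError", "read_records", "write_records"]


class ParseError(ValueError):
    """Malformed record in an input file; message carries the 1-based line number."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = path
        self.lineno = lineno


def _fmt_score(x: float) -> str:
    """Render a float the way it round-trips: integers without a decimal point."""
    if float(x) == int(x):
        return str(int(x))
    return repr(float(x))


def _data_lines(path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            yield lineno, line


def _split(path, lineno: int, line: str, min_cols: int) -> list[str]:
    fields = line.split("\t")
    if len(fields) < min_cols:
        raise ParseError(path, lineno, f"expected >= {min_cols} columns, got {len(fields)}")
    return fields


def _int(path, lineno, value, what):
    try:
        return int(value)
    except ValueError:
        raise ParseError(path, lineno, f"non-integer {what}: {value!r}") from None


def _float(path, lineno, value, what):
    try:
        return float(value)
    except ValueError:
        raise ParseError(path, lineno, f"non-numeric {what}: {value!r}") from None


# ---------------------------------------------------------------- BED3 / BED6


def _read_bed(path, n_cols: int) -> list[GenomicInterval]:
    out = []
    for lineno, line in _data_lines(path):
        f = _split(path, lineno, line, n_cols)
        strand = f[5] if n_cols >= 6 else "."
        try:
            out.append(
                GenomicInterval(
                    f[0],
                    _int(path, lineno, f[1], "start"),
                    _int(path, lineno, f[2], "end"),
                    strand,
                )
            )
        except ValueError as exc:
            raise ParseError(path, lineno, str(exc)) from None
    return out


def _write_bed3(records: Sequence[GenomicInterval], fh) -> None:
    fh.write("#chrom\tstart\tend\n")
    for iv in records:
        fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def _write_bed6(records: Sequence[GenomicInterval], fh) -> None:
    fh.write("#chrom\tstart\tend\tname\tscore\tstrand\n")
    for iv in records:
        fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")


# ----------------------------------------------------------------- narrowPeak


def _read_narrowpeak(path, mark="", cell_line="", replicate="") -> list[Peak]:
    out = []
    for lineno, line in _data_lines(path):
        f = _split(path, lineno, line, 10)
        start = _int(path, lineno, f[1], "start")
        end = _int(path, lineno, f[2], "end")
        summit = _int(path, lineno, f[9], "summit offset")
        try:
            out.append(
                Peak(
                    interval=GenomicInterval(f[0], start, end, f[5] if f[5] in "+-" else "."),
                    name=f[3],
                    score=_float(path, lineno, f[4], "score"),
                    summit_offset=None if summit == -1 else summit,
                    mark=mark,
                    cell_line=cell_line,
                    replicate=replicate,
                )
            )
        except ValueError as exc:
            raise ParseError(path, lineno, str(exc)) from None
    return out


def _write_narrowpeak(records: Sequence[Peak], fh) -> None:
    fh.write(
        "#chrom\tstart\tend\tname\tscore\tstrand\tsignalValue\tpValue\tqValue\tsummit\n"
    )
    for p in records:
        iv = p.interval
        summit = -1 if p.summit_offset is None else p.summit_offset
        fh.write(
            f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.name}\t{_fmt_score(p.score)}\t"
            f"{iv.strand}\t0\t-1\t-1\t{summit}\n"
        )


# --------------------------------------------------------------------- BEDPE


def _read_bedpe(path, dataset: str = "", q_col: int = 8) -> list[LoopRecord]:
    """BEDPE loops: 6 anchor coordinates, name, score, q-value (column index
    ``q_col``, 0-based, default 8). A missing/'.' q-value passes filters (0.0);
    anchors given in reverse genomic order are canonicalized by LoopRecord."""
    out = []
    for lineno, line in _data_lines(path):
        f = _split(path, lineno, line, 7)
        if q_col < len(f) and f[q_col] not in (".", ""):
            q = _float(path, lineno, f[q_col], "q-value")
        else:
            q = 0.0
        try:
            out.append(
                LoopRecord(
                    anchor1=GenomicInterval(
                        f[0], _int(path, lineno, f[1], "start1"), _int(path, lineno, f[2], "end1")
                    ),
                    anchor2=GenomicInterval(
                        f[3], _int(path, lineno, f[4], "start2"), _int(path, lineno, f[5], "end2")
                    ),
                    dataset=dataset,
                    q_value=q,
                    name=f[6] if len(f) > 6 else ".",
                )
            )
        except ValueError as exc:
            raise ParseError(path, lineno, str(exc)) from None
    return out


def _write_bedpe(records: Sequence[LoopRecord], fh) -> None:
    fh.write(
        "#chrom1\tstart1\tend1\tchrom2\tstart2\tend2\tname\tscore\tqValue\n"
    )
    for lp in records:
        a, b = lp.anchor1, lp.anchor2
        fh.write(
            f"{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t{b.end}\t"
            f"{lp.name}\t0\t{_fmt_score(lp.q_value)}\n"
        )


# ------------------------------------------------------------------- SNP TSV


def _read_snps(path) -> list[SNPRecord]:
    """Tab-separated SNP table with header (rsid, chrom, pos); positions are
    1-based in the file and converted to 0-based on read."""
    out = []
    seen = set()
    for lineno, line in _data_lines(path):
        f = line.split("\t")
        if f[0] == "rsid":  # tolerate an unprefixed header line
            continue
        if len(f) < 3:
            raise ParseError(path, lineno, f"expected 3 columns (rsid, chrom, pos), got {len(f)}")
        rsid = f[0]
        if rsid in seen:
            raise ParseError(path, lineno, f"duplicate rsid {rsid!r}")
        seen.add(rsid)
        pos1 = _int(path, lineno, f[2], "position")
        try:
            out.append(SNPRecord(rsid=rsid, chrom=f[1], pos0=pos1 - 1))
        except ValueError as exc:
            raise ParseError(path, lineno, str(exc)) from None
    return out


def _write_snps(records: Sequence[SNPRecord], fh) -> None:
    fh.write("#rsid\tchrom\tpos\n")
    for s in records:
        fh.write(f"{s.rsid}\t{s.chrom}\t{s.pos0 + 1}\n")


# --------------------------------------------------------------- motif BED6


def _read_motifs(path) -> list[MotifSite]:
    out = []
    for lineno, line in _data_lines(path):
        f = _split(path, lineno, line, 6)
        if f[5] not in ("+", "-"):
            raise ParseError(path, lineno, f"motif strand must be + or -, got {f[5]!r}")
        try:
            out.append(
                MotifSite(
                    interval=GenomicInterval(
                        f[0], _int(path, lineno, f[1], "start"), _int(path, lineno, f[2], "end"), f[5]
                    ),
                    score=_float(path, lineno, f[4], "score"),
                    name=f[3],
                )
            )
        except ValueError as exc:
            raise ParseError(path, lineno, str(exc)) from None
    return out


def _write_motifs(records: Sequence[MotifSite], fh) -> None:
    fh.write("#chrom\tstart\tend\tname\tscore\tstrand\n")
    for m in records:
        iv = m.interval
        fh.write(
            f"{iv.chrom}\t{iv.start}\t{iv.end}\t{m.name}\t{_fmt_score(m.score)}\t{iv.strand}\n"
        )


# ----------------------------------------------------------------------- GTF


def _read_gtf(path) -> list[GeneModel]:
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes = []
    for g in db.features_of_type("gene", order_by=("seqid", "start")):
        if g.strand not in ("+", "-"):
            raise ValueError(f"gene {g.id} has no strand; gene models must be stranded")
        start0, end0 = g.start - 1, g.end  # GTF is 1-based inclusive
        exons = [
            GenomicInterval(e.seqid, e.start - 1, e.end, g.strand)
            for e in db.children(g, featuretype="exon", order_by="start")
        ]
        tss = start0 if g.strand == "+" else end0 - 1
        tes = end0 - 1 if g.strand == "+" else start0
        genes.append(
            GeneModel(
                gene_id=g.attributes.get("gene_id", [g.id])[0],
                gene_name=g.attributes.get("gene_name", [g.id])[0],
                chrom=g.seqid,
                strand=g.strand,
                tss_pos0=tss,
                tes_pos0=tes,
                exons=tuple(exons),
            )
        )
    return genes


def _write_gtf(records: Sequence[GeneModel], fh) -> None:
    for g in records:
        start1 = min(g.tss_pos0, g.tes_pos0) + 1
        end1 = max(g.tss_pos0, g.tes_pos0) + 1
        attrs = f'gene_id "{g.gene_id}"; gene_name "{g.gene_name}";'
        fh.write(
            f"{g.chrom}\tsynthetic\tgene\t{start1}\t{end1}\t.\t{g.strand}\t.\t{attrs}\n"
        )
        tattrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.1"; gene_name "{g.gene_name}";'
        fh.write(
            f"{g.chrom}\tsynthetic\ttranscript\t{start1}\t{end1}\t.\t{g.strand}\t.\t{tattrs}\n"
        )
        for ex in g.exons:
            fh.write(
                f"{g.chrom}\tsynthetic\texon\t{ex.start + 1}\t{ex.end}\t.\t{g.strand}\t.\t{tattrs}\n"
            )


# ------------------------------------------------------------------ dispatch

_READERS = {
    "bed3": lambda path, **kw: _read_bed(path, 3),
    "bed6": lambda path, **kw: _read_bed(path, 6),
    "narrowpeak": lambda path, **kw: _read_narrowpeak(path, **kw),
    "bedpe": lambda path, **kw: _read_bedpe(path, **kw),
    "gtf": lambda path, **kw: _read_gtf(path),
    "snp": lambda path, **kw: _read_snps(path),
    "motif": lambda path, **kw: _read_motifs(path),
}

_WRITERS = {
    "bed3": _write_bed3,
    "bed6": _write_bed6,
    "narrowpeak": _write_narrowpeak,
    "bedpe": _write_bedpe,
    "gtf": _write_gtf,
    "snp": _write_snps,
    "motif": _write_motifs,
}


def _norm_format(fmt: str) -> str:
    key = fmt.lower().replace("-", "").replace("_", "")
    aliases = {"bed": "bed3", "snptsv": "snp", "gtfgenes": "gtf", "motifbed6": "motif"}
    key = aliases.get(key, key)
    if key not in _READERS:
        raise ValueError(f"unknown format {fmt!r}; supported formats: {', '.join(FORMATS)}")
    return key


def read_records(path, format: str, **kwargs):
    """Read a file into typed records; see module docstring for conventions.

    ``narrowpeak`` accepts ``mark=``, ``cell_line=``, ``replicate=`` tags;
    ``bedpe`` accepts ``dataset=`` and ``q_col=``.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    return _READERS[_norm_format(format)](path, **kwargs)


def write_records(records, path, format: str) -> None:
    """Write typed records as tab-separated text with a '#'-prefixed header."""
    fmt = _norm_format(format)
    with open(path, "w") as fh:
        _WRITERS[fmt](records, fh)
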