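"""Readers and writers for the standard formats the pipeline touches.

BED6, ENCODE narrowPeak (10 columns), GFF3/GTF exon/CDS features, VCF 4.x,
FASTA and chrom.sizes. Internal coordinates are 0-based half-open; GFF/VCF
ingestion subtracts 1 from starts and the writers restore the native
convention. Chromosome names are normalised (``chr`` prefix stripped) on read;
writers can restore the prefix via ``chr_prefix=True``.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    ExonRecord,
    GenomicInterval,
    TfPeak,
    TssRecord,
    Variant,
    normalize_chrom,
    reverse_complement,
)


class ParseError(ValueError):
    """A malformed line in an input file (message carries the line number)."""


class RecordError(ValueError):
    """A syntactically valid record violating a semantic constraint."""


def _chrom_out(name: str, chr_prefix: bool) -> str:
    return f"chr{name}" if chr_prefix else name


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str) -> list[GenomicInterval]:
    """Read a BED3/BED6 file into GenomicIntervals (strand '.' if absent)."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        return []
    out = []
    for ln, row in enumerate(df.itertuples(index=False), start=1):
        fields = list(row)
        try:
            chrom = normalize_chrom(fields[0])
            start, end = int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 and pd.notna(fields[3]) else ""
            strand = fields[5] if len(fields) > 5 and pd.notna(fields[5]) else "."
            out.append(GenomicInterval(chrom, start, end, strand, str(name)))
        except (ValueError, IndexError) as exc:
            raise ParseError(f"{path}:{ln}: {exc}") from exc
    return out


def write_bed(
    records: Iterable[GenomicInterval],
    path: str,
    chrom_sizes: Mapping[str, int] | None = None,
    chr_prefix: bool = False,
) -> None:
    """Write intervals as BED6; round-trips with :func:`read_bed`."""
    with open(path, "w") as fh:
        for iv in records:
            if chrom_sizes is not None and normalize_chrom(iv.chrom) not in {
                normalize_chrom(c) for c in chrom_sizes
            }:
                raise RecordError(f"unknown chromosome {iv.chrom!r}")
            fh.write(
                f"{_chrom_out(iv.chrom, chr_prefix)}\t{iv.start}\t{iv.end}"
                f"\t{iv.name or '.'}\t0\t{iv.strand}\n"
            )


def read_tss_bed(path: str, kind: str = "annotated_tss") -> list[TssRecord]:
    """Read point features (1 bp BED records use their start) as TssRecords."""
    return [
        TssRecord(iv.chrom, iv.start, iv.strand, kind=kind) for iv in read_bed(path)
    ]


def write_tss_bed(records: Iterable[TssRecord], path: str, chr_prefix: bool = False) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{_chrom_out(r.chrom, chr_prefix)}\t{r.position}\t{r.position + 1}"
                f"\t{r.kind}\t0\t{r.strand}\n"
            )


# ---------------------------------------------------------------------------
# narrowPeak
# ---------------------------------------------------------------------------

_NARROWPEAK_COLS = [
    "chrom", "chromStart", "chromEnd", "name", "score",
    "strand", "signalValue", "pValue", "qValue", "peak",
]


def _split_peak_name(name: str) -> tuple[str, str]:
    """ReMap-style peak names are 'dataset.TF[.biotype]'; else the whole name is the TF."""
    parts = str(name).split(".")
    if len(parts) >= 2:
        return parts[0], parts[1]
    return "", parts[0]


def read_narrowpeak(path: str) -> list[TfPeak]:
    """Read a 10-column ENCODE narrowPeak file.

    The summit is chromStart plus the column-10 offset; an offset of -1 means
    no point source was called and the summit is imputed at the interval
    midpoint (flagged). Offsets outside the interval are rejected.
    """
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#", names=_NARROWPEAK_COLS
        )
    except pd.errors.EmptyDataError:
        return []
    if df.shape[1] != 10:
        raise ParseError(f"{path}: expected 10 narrowPeak columns")
    out = []
    for ln, row in enumerate(df.itertuples(index=False), start=1):
        start, end, offset = int(row.chromStart), int(row.chromEnd), int(row.peak)
        dataset, tf = _split_peak_name(row.name)
        iv = GenomicInterval(
            normalize_chrom(row.chrom), start, end,
            row.strand if row.strand in ("+", "-") else ".", str(row.name),
        )
        if offset == -1:
            summit, imputed = (start + end) // 2, True
        else:
            summit, imputed = start + offset, False
            if not (start <= summit < end):
                raise RecordError(
                    f"{path}:{ln}: summit offset {offset} outside [{start}, {end})"
                )
        out.append(
            TfPeak(iv, tf_name=tf, summit=summit, dataset_id=dataset,
                   score=float(row.signalValue), summit_imputed=imputed)
        )
    return out


def write_narrowpeak(peaks: Iterable[TfPeak], path: str, chr_prefix: bool = False) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            name = f"{p.dataset_id}.{p.tf_name}" if p.dataset_id else p.tf_name
            iv = p.interval
            fh.write(
                f"{_chrom_out(iv.chrom, chr_prefix)}\t{iv.start}\t{iv.end}\t{name}"
                f"\t0\t{iv.strand}\t{p.score:g}\t-1\t-1\t{p.summit - iv.start}\n"
            )


# ---------------------------------------------------------------------------
# GFF3 / GTF
# ---------------------------------------------------------------------------

def _validate_gff_lines(path: str) -> None:
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{ln}: expected 9 tab-separated fields")
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ParseError(f"{path}:{ln}: non-integer coordinates") from exc
            if end < start:
                raise RecordError(f"{path}:{ln}: end {end} < start {start}")


def _attr_first(feature, *keys) -> str | None:
    for key in keys:
        if key in feature.attributes:
            vals = feature.attributes[key]
            if vals:
                return vals[0]
    return None


def read_gff_exons(path: str, feature_filter: str = "CDS") -> list[ExonRecord]:
    """Read exon-like features from GFF3/GTF into ExonRecords.

    GFF coordinates are 1-based inclusive and converted to 0-based half-open.
    ``gene_id``/``transcript_id`` and the transcript support level are taken
    from the feature attributes, falling back to the parent transcript for the
    TSL; records without a TSL are retained with ``tsl=None``.
    """
    _validate_gff_lines(path)
    db = gffutils.create_db(
        path, dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    tsl_by_transcript: dict[str, int | None] = {}
    for ftype in ("mRNA", "transcript"):
        for tr in db.features_of_type(ftype):
            raw = _attr_first(tr, "transcript_support_level", "tsl")
            tid = _attr_first(tr, "transcript_id", "ID") or tr.id
            try:
                tsl_by_transcript[tid] = int(raw) if raw is not None else None
            except ValueError:
                tsl_by_transcript[tid] = None
    out = []
    for feat in db.features_of_type(feature_filter):
        gene = _attr_first(feat, "gene_id", "gene") or ""
        tid = _attr_first(feat, "transcript_id", "Parent") or ""
        raw_tsl = _attr_first(feat, "transcript_support_level", "tsl")
        if raw_tsl is not None:
            try:
                tsl = int(raw_tsl)
            except ValueError:
                tsl = None
        else:
            tsl = tsl_by_transcript.get(tid)
        try:
            phase = int(feat.frame) if feat.frame not in (None, ".") else 0
        except (TypeError, ValueError):
            phase = 0
        name = _attr_first(feat, "ID", "exon_id") or ""
        out.append(
            ExonRecord(
                GenomicInterval(
                    normalize_chrom(feat.seqid), feat.start - 1, feat.end,
                    feat.strand if feat.strand in ("+", "-") else ".", name,
                ),
                gene_id=gene, transcript_id=tid, tsl=tsl, phase=phase,
            )
        )
    return out


def attach_cds(exons: Sequence[ExonRecord], sequences: Mapping[str, str]) -> None:
    """Fill ``cds_seq`` from genome sequences (reverse-complemented on '-')."""
    seqs = {normalize_chrom(c): s for c, s in sequences.items()}
    for ex in exons:
        iv = ex.interval
        chunk = seqs[normalize_chrom(iv.chrom)][iv.start : iv.end].upper()
        ex.cds_seq = reverse_complement(chunk) if iv.strand == "-" else chunk


# ---------------------------------------------------------------------------
# FASTA / chrom.sizes / bedGraph
# ---------------------------------------------------------------------------

def read_fasta(path: str) -> dict[str, str]:
    return {
        normalize_chrom(rec.id): str(rec.seq).upper()
        for rec in SeqIO.parse(path, "fasta")
    }


def write_fasta(sequences: Mapping[str, str], path: str, chr_prefix: bool = False) -> None:
    records = [
        SeqRecord(Seq(seq), id=_chrom_out(name, chr_prefix), description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, path, "fasta")


def read_chrom_sizes(path: str) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return {normalize_chrom(r.chrom): int(r.size) for r in df.itertuples(index=False)}


def write_chrom_sizes(sizes: Mapping[str, int], path: str, chr_prefix: bool = False) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{_chrom_out(chrom, chr_prefix)}\t{size}\n")


def read_gc_bedgraph(path: str) -> dict[str, np.ndarray]:
    """Read a per-window GC bedGraph into per-chromosome window arrays."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "value"])
    out: dict[str, np.ndarray] = {}
    for chrom, grp in df.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        out[normalize_chrom(chrom)] = grp["value"].to_numpy(dtype=float)
    return out


def write_gc_bedgraph(
    build, path: str, chr_prefix: bool = False
) -> None:
    with open(path, "w") as fh:
        for chrom, track in build.gc_tracks.items():
            size, w = build.chrom_sizes[chrom], build.gc_window
            for i, v in enumerate(track):
                fh.write(
                    f"{_chrom_out(chrom, chr_prefix)}\t{i * w}\t{min((i + 1) * w, size)}\t{v:.4f}\n"
                )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str) -> list[Variant]:
    """Read SNVs from a VCF 4.x file (CHROM/POS/REF/ALT/FILTER/INFO:AF).

    Multi-allelic rows contribute one Variant per ALT; positions are converted
    to 0-based. ``passed`` reflects FILTER == PASS (or '.').
    """
    from cyvcf2 import VCF

    out = []
    for var in VCF(path):
        af = var.INFO.get("AF")
        info = {k: str(v) for k, v in var.INFO}
        for i, alt in enumerate(var.ALT):
            this_af = af[i] if isinstance(af, (tuple, list)) else af
            out.append(
                Variant(
                    chrom=normalize_chrom(var.CHROM),
                    pos=var.start,
                    ref=var.REF,
                    alt=alt,
                    af=float(this_af) if this_af is not None else None,
                    passed=var.FILTER is None,
                    info=info,
                )
            )
    return out


def write_vcf(
    variants: Iterable[Variant],
    path: str,
    contigs: Mapping[str, int],
    chr_prefix: bool = False,
) -> None:
    """Write SNVs as a minimal VCF 4.2 file with AF (and any str INFO keys)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, size in contigs.items():
            fh.write(f"##contig=<ID={_chrom_out(chrom, chr_prefix)},length={size}>\n")
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">\n')
        fh.write('##INFO=<ID=VC,Number=1,Type=String,Description="Variant consequence">\n')
        fh.write('##FILTER=<ID=lowconf,Description="Low-confidence call">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(variants, key=lambda x: (x.chrom, x.pos, x.alt)):
            parts = []
            if v.af is not None:
                parts.append(f"AF={v.af:.6g}")
            for k, val in v.info.items():
                if k != "AF":
                    parts.append(f"{k}={val}")
            info = ";".join(parts) or "."
            filt = "PASS" if v.passed else "lowconf"
            fh.write(
                f"{_chrom_out(v.chrom, chr_prefix)}\t{v.pos + 1}\t.\t{v.ref}\t{v.alt}"
                f"\t.\t{filt}\t{info}\n"
            )


# ---------------------------------------------------------------------------
# Mask
# ---------------------------------------------------------------------------

def read_mask_bed(path: str) -> dict[str, np.ndarray]:
    ivs = read_bed(path)
    out: dict[str, list[tuple[int, int]]] = {}
    for iv in ivs:
        out.setdefault(iv.chrom, []).append((iv.start, iv.end))
    return {c: np.asarray(sorted(v), dtype=np.int64) for c, v in out.items()}


def write_mask_bed(mask: Mapping[str, np.ndarray], path: str, chr_prefix: bool = False) -> None:
    with open(path, "w") as fh:
        for chrom, arr in mask.items():
            for s, e in np.asarray(arr).reshape(-1, 2):
                fh.write(f"{_chrom_out(chrom, chr_prefix)}\t{s}\t{e}\n")


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
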