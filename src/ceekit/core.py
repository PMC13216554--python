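"""Coordinate conventions, domain records and genome-level tracks.

All coordinates are 0-based half-open on the forward strand of a single
genome build. Readers for the 1-based formats (GFF, VCF) convert on ingestion
and the writers restore the native convention. Chromosome names are
normalised internally by stripping a leading ``chr`` prefix so that mixed
annotation dialects can be combined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

STRANDS = ("+", "-", ".")

#: Default GC-bin edges: ten equal-width bins on [0, 1].
GC_BIN_EDGES = tuple(np.linspace(0.0, 1.0, 11))

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def normalize_chrom(name: str) -> str:
    """Strip a leading ``chr`` prefix (case-insensitive) from a chromosome name."""
    name = str(name)
    return name[3:] if name[:3].lower() == "chr" else name


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open coordinate span with strand.

    ``strand == "."`` means unstranded; strand-aware filters treat it as
    matching both strands.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class TfPeak:
    """A TF ChIP-seq peak: an interval plus factor label, score and summit.

    The summit is an absolute bp position (0-based) and must lie inside the
    peak interval; ``summit_imputed`` marks peaks whose source record carried
    no point-source offset (narrowPeak column 10 of -1).
    """

    interval: GenomicInterval
    tf_name: str
    summit: int
    dataset_id: str = ""
    score: float = 0.0
    summit_imputed: bool = False

    def __post_init__(self) -> None:
        if not self.tf_name:
            raise ValueError("tf_name must be non-empty")
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError(
                f"summit {self.summit} outside peak "
                f"[{self.interval.start}, {self.interval.end})"
            )


@dataclass
class ExonRecord:
    """A protein-coding exon with optional in-frame coding sequence.

    ``cds_seq`` is on the coding strand; its length must equal the interval
    length. ``tsl`` is the transcript support level (``None`` when the
    annotation does not state one). ``phase`` is the codon frame offset of the
    exon's first base within the transcript CDS.
    """

    interval: GenomicInterval
    gene_id: str = ""
    transcript_id: str = ""
    tsl: int | None = None
    phase: int = 0
    cds_seq: str | None = None

    def __post_init__(self) -> None:
        if self.phase not in (0, 1, 2):
            raise ValueError(f"invalid phase {self.phase}")
        if self.cds_seq is not None and len(self.cds_seq) != self.interval.length:
            raise ValueError(
                f"cds_seq length {len(self.cds_seq)} != interval length "
                f"{self.interval.length}"
            )

    @property
    def exon_id(self) -> str:
        return self.interval.name or f"{self.gene_id}:{self.interval.start}-{self.interval.end}"


@dataclass(frozen=True)
class TssRecord:
    """A transcription start/end site or CAGE peak as a 1 bp point feature."""

    chrom: str
    position: int
    strand: str
    kind: str = "annotated_tss"

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.kind not in ("annotated_tss", "annotated_tes", "cage_peak"):
            raise ValueError(f"invalid kind {self.kind!r}")


@dataclass(frozen=True)
class Variant:
    """A single-nucleotide variant (0-based position, forward-strand alleles)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    af: float | None = None
    passed: bool = True
    info: Mapping[str, str] = field(default_factory=dict)


def gc_fraction(seq: str) -> float | None:
    """GC fraction of a nucleotide string, excluding N from the denominator.

    Returns ``None`` when the fraction is undefined (empty or all-N input);
    raises on characters outside {A, C, G, T, N}.
    """
    s = seq.upper()
    if set(s) - set("ACGTN"):
        bad = sorted(set(s) - set("ACGTN"))
        raise ValueError(f"illegal characters in sequence: {bad}")
    denom = len(s) - s.count("N")
    if denom == 0:
        return None
    return (s.count("G") + s.count("C")) / denom


def strands_compatible(a: str, b: str) -> bool:
    """Whether two strand labels match; '.' is unstranded and matches both."""
    return a == "." or b == "." or a == b


def distance_to_nearest(
    query: GenomicInterval,
    features: Iterable[TssRecord],
    same_strand: bool = False,
) -> float:
    """Edge-to-edge bp distance from an interval to the nearest point feature.

    A point at position p occupies [p, p+1). Returns 0 when the point lies
    inside the query and ``math.inf`` when no feature qualifies on the query's
    chromosome (after the optional strand filter).
    """
    best = math.inf
    for f in features:
        if normalize_chrom(f.chrom) != normalize_chrom(query.chrom):
            continue
        if same_strand and not strands_compatible(query.strand, f.strand):
            continue
        d = max(query.start - (f.position + 1), f.position - query.end, 0)
        if d < best:
            best = d
    return best


def gc_bin(gc: float | np.ndarray, edges: Sequence[float] = GC_BIN_EDGES):
    """Bin index of a GC fraction under ordered bin edges spanning [0, 1]."""
    e = np.asarray(edges, dtype=float)
    idx = np.digitize(gc, e) - 1
    return np.clip(idx, 0, len(e) - 2)


def _validate_mask(mask: np.ndarray, size: int) -> np.ndarray:
    m = np.asarray(mask, dtype=np.int64).reshape(-1, 2)
    if m.size == 0:
        return m
    if np.any(m[:, 0] >= m[:, 1]) or m[0, 0] < 0 or m[-1, 1] > size:
        raise ValueError("mask intervals must be non-empty and inside the chromosome")
    if np.any(m[1:, 0] < m[:-1, 1]):
        raise ValueError("mask intervals must be sorted and disjoint")
    return m


class GenomeBuild:
    """Chromosome sizes plus a windowed GC track and a mappability mask.

    The GC track stores one GC fraction per non-overlapping window of
    ``gc_window`` bp (last window possibly shorter). Interval GC is the
    length-weighted mean of the covered windows, so it can be evaluated for
    arbitrary spans without the underlying sequence.
    """

    def __init__(
        self,
        chrom_sizes: Mapping[str, int],
        gc_window: int = 100,
        gc_tracks: Mapping[str, np.ndarray] | None = None,
        mask: Mapping[str, np.ndarray] | None = None,
    ) -> None:
        if gc_window <= 0:
            raise ValueError("gc_window must be positive")
        self.gc_window = int(gc_window)
        self.chrom_sizes = {normalize_chrom(c): int(s) for c, s in chrom_sizes.items()}
        self.gc_tracks: dict[str, np.ndarray] = {}
        self.mask: dict[str, np.ndarray] = {}
        self._gc_cum: dict[str, np.ndarray] = {}
        gc_tracks = {normalize_chrom(c): v for c, v in (gc_tracks or {}).items()}
        mask = {normalize_chrom(c): v for c, v in (mask or {}).items()}
        for chrom, size in self.chrom_sizes.items():
            nwin = -(-size // self.gc_window)
            track = np.asarray(
                gc_tracks.get(chrom, np.full(nwin, 0.5)), dtype=float
            )
            if len(track) != nwin:
                raise ValueError(
                    f"gc track for {chrom} has {len(track)} windows, expected {nwin}"
                )
            widths = np.full(nwin, self.gc_window, dtype=float)
            widths[-1] = size - self.gc_window * (nwin - 1)
            self.gc_tracks[chrom] = track
            self._gc_cum[chrom] = np.concatenate([[0.0], np.cumsum(track * widths)])
            self.mask[chrom] = _validate_mask(
                mask.get(chrom, np.array([[0, size]])), size
            )

    @classmethod
    def from_sequences(
        cls,
        sequences: Mapping[str, str],
        gc_window: int = 100,
        mask: Mapping[str, np.ndarray] | None = None,
    ) -> "GenomeBuild":
        sizes = {c: len(s) for c, s in sequences.items()}
        tracks = {}
        for chrom, seq in sequences.items():
            arr = np.frombuffer(seq.upper().encode(), dtype="S1")
            is_gc = (arr == b"G") | (arr == b"C")
            is_n = arr == b"N"
            nwin = -(-len(seq) // gc_window)
            starts = np.arange(nwin) * gc_window
            gc_counts = np.add.reduceat(is_gc.astype(np.int64), starts)
            n_counts = np.add.reduceat(is_n.astype(np.int64), starts)
            widths = np.full(nwin, gc_window, dtype=np.int64)
            widths[-1] = len(seq) - gc_window * (nwin - 1)
            valid = widths - n_counts
            with np.errstate(invalid="ignore"):
                gc = np.where(valid > 0, gc_counts / np.maximum(valid, 1), 0.5)
            tracks[chrom] = gc
        return cls(sizes, gc_window=gc_window, gc_tracks=tracks, mask=mask)

    def _gc_integral(self, chrom: str, x: np.ndarray) -> np.ndarray:
        """Integral of the per-base GC value (window-constant) from 0 to x."""
        w = self.gc_window
        track = self.gc_tracks[chrom]
        cum = self._gc_cum[chrom]
        x = np.asarray(x, dtype=np.int64)
        i = np.minimum(x // w, len(track) - 1)
        return cum[i] + (x - i * w) * track[i]

    def interval_gc(self, chrom: str, start, end) -> np.ndarray | float:
        """Length-weighted mean GC over [start, end) (vectorised over arrays)."""
        chrom = normalize_chrom(chrom)
        start = np.asarray(start, dtype=np.int64)
        end = np.asarray(end, dtype=np.int64)
        out = (self._gc_integral(chrom, end) - self._gc_integral(chrom, start)) / (
            end - start
        )
        return float(out) if out.ndim == 0 else out

    def window_gc(self, chrom: str, starts: np.ndarray, length: int) -> np.ndarray:
        """GC of fixed-length windows at the given starts (vectorised)."""
        starts = np.asarray(starts, dtype=np.int64)
        return self.interval_gc(chrom, starts, starts + length)


class MergedIntervals:
    """Sorted, merged interval set per chromosome with vectorised stabbing."""

    def __init__(self, intervals: Iterable[GenomicInterval]):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            by_chrom.setdefault(normalize_chrom(iv.chrom), []).append(
                (iv.start, iv.end)
            )
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for chrom, spans in by_chrom.items():
            spans.sort()
            merged: list[list[int]] = []
            for s, e in spans:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            arr = np.asarray(merged, dtype=np.int64)
            self._starts[chrom] = arr[:, 0]
            self._ends[chrom] = arr[:, 1]

    def any_overlap(self, chrom: str, starts, ends) -> np.ndarray | bool:
        """Whether [start, end) spans intersect any merged interval."""
        chrom = normalize_chrom(chrom)
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        if chrom not in self._starts:
            out = np.zeros(starts.shape, dtype=bool)
            return bool(out) if out.ndim == 0 else out
        ms, me = self._starts[chrom], self._ends[chrom]
        idx = np.searchsorted(ms, ends, side="left")
        out = (idx > 0) & (me[np.maximum(idx - 1, 0)] > starts)
        return bool(out) if out.ndim == 0 else out

    def overlaps_interval(self, iv: GenomicInterval) -> bool:
        return bool(self.any_overlap(iv.chrom, iv.start, iv.end))
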