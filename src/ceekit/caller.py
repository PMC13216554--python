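"""Candidate exonic enhancer (cEE) identification.

A coding exon is called a cEE when, after promoter-proximity filtering, it
carries an enhancer-like TF ChIP-seq occupancy profile: (i) at least
``min_distinct_tfs`` distinct factors overlap the exon, (ii) the maximum TF
summit density inside the exon strictly exceeds the density in the +/-
``flank_bp`` flanking regions (rejecting clusters that merely straddle an
exon-intron boundary), and (iii) at least ``min_summit_ratio`` of the
overlapping peaks have their summit inside the exon. Exons that survive the
same filters but carry zero peaks form the negative control set; intergenic
candidate cis-regulatory elements passing the same criteria form the positive
control set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .core import (
    ExonRecord,
    GenomicInterval,
    MergedIntervals,
    TfPeak,
    TssRecord,
    distance_to_nearest,
    normalize_chrom,
)

SPECIES_PRESETS = {
    # TSS/TES exclusion bp, TSS-peak window bp, TSL=1 filter, promoter-mark filter
    "human": (1000, 500, True, True),
    "mouse": (1000, 500, False, True),
    "fly": (100, 100, False, False),
    "arabidopsis": (100, 100, False, False),
}


@dataclass
class CallerConfig:
    tss_tes_exclusion_bp: int = 1000
    tss_peak_window_bp: int = 500
    merge_size_diff_bp: int = 50
    min_distinct_tfs: int = 10
    min_summit_ratio: float = 0.5
    flank_bp: int = 50
    density_window_bp: int = 50
    require_tsl1: bool = False
    promoter_mark_exclusion: bool = False

    def __post_init__(self) -> None:
        for name in ("tss_tes_exclusion_bp", "tss_peak_window_bp", "flank_bp",
                     "density_window_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.min_summit_ratio <= 1.0):
            raise ValueError("min_summit_ratio must lie in [0, 1]")

    @classmethod
    def for_species(cls, species: str, **overrides) -> "CallerConfig":
        try:
            excl, window, tsl1, marks = SPECIES_PRESETS[species.lower()]
        except KeyError as exc:
            raise ValueError(
                f"no preset for species {species!r}; "
                f"choose from {sorted(SPECIES_PRESETS)}"
            ) from exc
        cfg = cls(
            tss_tes_exclusion_bp=excl,
            tss_peak_window_bp=window,
            require_tsl1=tsl1,
            promoter_mark_exclusion=marks,
        )
        return replace(cfg, **overrides) if overrides else cfg


@dataclass
class ExonTfProfile:
    """TF occupancy summary of one exon (summits drive the density terms)."""

    n_peaks_overlapping: int = 0
    n_distinct_tfs: int = 0
    n_summits_inside: int = 0
    max_exon_density: float = 0.0
    flank_density: float = 0.0

    @property
    def summit_ratio(self) -> float:
        if self.n_peaks_overlapping == 0:
            return 0.0
        return self.n_summits_inside / self.n_peaks_overlapping


@dataclass
class CeeCall:
    """An exon with its occupancy profile and per-criterion pass/fail ledger."""

    exon: ExonRecord
    profile: ExonTfProfile
    ledger: dict[str, bool | str] = field(default_factory=dict)
    label: str = "excluded"  # cEE | ctrl_neg | excluded | insufficient_tf | ctrl_pos


def consolidate_exons(
    exons: Sequence[ExonRecord], merge_size_diff_bp: int = 50
) -> list[ExonRecord]:
    """Merge overlapping same-gene isoform exons whose lengths differ by <= the threshold.

    Merging takes the coordinate union and is applied transitively until a
    fixpoint; other exons are retained separately. Exact duplicate coordinates
    collapse to one record. Output is sorted by (chrom, start, end).
    """
    by_gene: dict[tuple[str, str, str], list[ExonRecord]] = {}
    for ex in exons:
        key = (ex.gene_id, normalize_chrom(ex.interval.chrom), ex.interval.strand)
        by_gene.setdefault(key, []).append(ex)
    def _merge(a: ExonRecord, b: ExonRecord) -> ExonRecord:
        union = GenomicInterval(
            a.interval.chrom,
            min(a.interval.start, b.interval.start),
            max(a.interval.end, b.interval.end),
            a.interval.strand,
            a.interval.name or b.interval.name,
        )
        tsls = [t for t in (a.tsl, b.tsl) if t is not None]
        keep_cds = (
            a.cds_seq
            if union.start == a.interval.start and union.end == a.interval.end
            else None
        )
        return ExonRecord(
            union,
            gene_id=a.gene_id,
            transcript_id=a.transcript_id,
            tsl=min(tsls) if tsls else None,
            phase=a.phase,
            cds_seq=keep_cds,
        )

    out: list[ExonRecord] = []
    for group in by_gene.values():
        records = sorted(group, key=lambda e: (e.interval.start, e.interval.end))
        changed = True
        while changed:
            changed = False
            for i in range(len(records)):
                for j in range(i + 1, len(records)):
                    a, b = records[i], records[j]
                    same = (
                        a.interval.start == b.interval.start
                        and a.interval.end == b.interval.end
                    )
                    overlap = a.interval.overlaps(b.interval)
                    diff = abs(a.interval.length - b.interval.length)
                    if same or (overlap and diff <= merge_size_diff_bp):
                        records[i] = _merge(a, b)
                        del records[j]
                        changed = True
                        break
                if changed:
                    records.sort(key=lambda e: (e.interval.start, e.interval.end))
                    break
        out.extend(records)
    return sorted(out, key=lambda e: (e.interval.chrom, e.interval.start, e.interval.end))


def filter_promoter_proximal(
    exons: Sequence[ExonRecord],
    tss_tes: Sequence[TssRecord],
    exclusion_bp: int,
    same_orientation: bool = True,
) -> tuple[list[ExonRecord], list[tuple[ExonRecord, TssRecord]]]:
    """Remove exons within ``exclusion_bp`` (inclusive) of a TSS/TES.

    With ``same_orientation`` only strand-matched sites count ('.' matches
    both strands). Returns (kept, removed-with-triggering-feature).
    """
    kept, removed = [], []
    for ex in exons:
        trigger = None
        for f in tss_tes:
            d = distance_to_nearest(ex.interval, [f], same_strand=same_orientation)
            if d <= exclusion_bp:
                trigger = f
                break
        if trigger is None:
            kept.append(ex)
        else:
            removed.append((ex, trigger))
    return kept, removed


def filter_tss_peak_overlap(
    exons: Sequence[ExonRecord],
    tss_peaks: Sequence[TssRecord],
    window_bp: int,
) -> tuple[list[ExonRecord], list[ExonRecord]]:
    """Remove exons with any TSS/CAGE peak within ``window_bp`` (strand-agnostic)."""
    kept, removed = [], []
    for ex in exons:
        d = distance_to_nearest(ex.interval, tss_peaks, same_strand=False)
        (removed if d <= window_bp else kept).append(ex)
    return kept, removed


def _chrom_peak_arrays(peaks: Sequence[TfPeak]) -> dict[str, dict[str, np.ndarray]]:
    by_chrom: dict[str, list[TfPeak]] = {}
    for p in peaks:
        by_chrom.setdefault(normalize_chrom(p.interval.chrom), []).append(p)
    out = {}
    for chrom, plist in by_chrom.items():
        out[chrom] = {
            "start": np.array([p.interval.start for p in plist], dtype=np.int64),
            "end": np.array([p.interval.end for p in plist], dtype=np.int64),
            "summit": np.array([p.summit for p in plist], dtype=np.int64),
            "tf": np.array([p.tf_name for p in plist], dtype=object),
        }
    return out


def _max_window_density(summits: np.ndarray, start: int, end: int, window: int) -> float:
    """Max summit count per bp over sliding windows kept inside [start, end)."""
    w = min(window, end - start)
    inside = np.sort(summits[(summits >= start) & (summits < end)])
    if inside.size == 0:
        return 0.0
    # The maximum over all window placements is attained with a window whose
    # left edge sits at a summit (clamped so the window stays inside the exon).
    anchors = np.clip(inside, start, end - w)
    counts = np.searchsorted(inside, anchors + w, side="left") - np.searchsorted(
        inside, anchors, side="left"
    )
    return float(counts.max()) / w


def profile_tf_occupancy(
    exon: ExonRecord,
    peaks: Sequence[TfPeak],
    flank_bp: int = 50,
    density_window_bp: int = 50,
    _arrays: dict[str, np.ndarray] | None = None,
) -> ExonTfProfile:
    """TF occupancy profile of one exon.

    Overlap means >= 1 bp; distinct TFs deduplicate ``tf_name`` across
    datasets; summit densities count peak summits per bp in sliding windows
    inside the exon and in each flank (max of the two flanks reported).
    """
    iv = exon.interval
    if _arrays is None:
        _arrays = _chrom_peak_arrays(peaks).get(normalize_chrom(iv.chrom))
    if _arrays is None or _arrays["start"].size == 0:
        return ExonTfProfile()
    a = _arrays
    overlapping = (a["start"] < iv.end) & (a["end"] > iv.start)
    n_peaks = int(overlapping.sum())
    n_tfs = len(set(a["tf"][overlapping]))
    summits_of_overlapping = a["summit"][overlapping]
    n_inside = int(
        ((summits_of_overlapping >= iv.start) & (summits_of_overlapping < iv.end)).sum()
    )
    max_density = _max_window_density(a["summit"], iv.start, iv.end, density_window_bp)
    left = ((a["summit"] >= iv.start - flank_bp) & (a["summit"] < iv.start)).sum()
    right = ((a["summit"] >= iv.end) & (a["summit"] < iv.end + flank_bp)).sum()
    flank_density = max(int(left), int(right)) / flank_bp
    return ExonTfProfile(
        n_peaks_overlapping=n_peaks,
        n_distinct_tfs=n_tfs,
        n_summits_inside=n_inside,
        max_exon_density=max_density,
        flank_density=flank_density,
    )


def density_criterion(profile: ExonTfProfile) -> bool:
    """Pass iff the in-exon maximum density strictly exceeds the flank density."""
    return profile.max_exon_density > profile.flank_density


def call_cees(
    exons: Sequence[ExonRecord],
    peaks: Sequence[TfPeak],
    tss_tes: Sequence[TssRecord] = (),
    tss_peaks: Sequence[TssRecord] = (),
    promoter_marks: Sequence[GenomicInterval] = (),
    config: CallerConfig | None = None,
) -> list[CeeCall]:
    """Run the full cEE decision pipeline over a set of coding exons.

    Order: exon consolidation -> TSS/TES proximity filter -> TSS-peak window
    filter -> optional TSL=1 filter -> optional promoter-mark exclusion ->
    occupancy criteria. Every consolidated exon receives a CeeCall with a
    pass/fail ledger; the label is ``cEE`` iff every criterion passes,
    ``ctrl_neg`` for fully filtered exons with zero overlapping peaks,
    ``insufficient_tf`` for exons failing only the distinct-TF minimum, and
    ``excluded`` otherwise.
    """
    config = config or CallerConfig()
    consolidated = consolidate_exons(exons, config.merge_size_diff_bp)
    arrays = _chrom_peak_arrays(peaks)
    marks_idx = MergedIntervals(promoter_marks) if promoter_marks else None
    calls = []
    for ex in consolidated:
        ledger: dict[str, bool | str] = {}
        d_tss = distance_to_nearest(ex.interval, tss_tes, same_strand=True)
        ledger["tss_tes_distance"] = d_tss > config.tss_tes_exclusion_bp
        d_peak = distance_to_nearest(ex.interval, tss_peaks, same_strand=False)
        ledger["tss_peak_window"] = d_peak > config.tss_peak_window_bp
        if config.require_tsl1:
            ledger["tsl1"] = ex.tsl == 1
        if config.promoter_mark_exclusion and marks_idx is not None:
            ledger["promoter_mark"] = not marks_idx.overlaps_interval(ex.interval)
        prefilters_ok = all(
            ledger[k]
            for k in ("tss_tes_distance", "tss_peak_window", "tsl1", "promoter_mark")
            if k in ledger
        )
        profile = profile_tf_occupancy(
            ex, peaks, config.flank_bp, config.density_window_bp,
            _arrays=arrays.get(normalize_chrom(ex.interval.chrom)),
        )
        ledger["min_distinct_tfs"] = profile.n_distinct_tfs >= config.min_distinct_tfs
        ledger["density"] = density_criterion(profile)
        ledger["summit_ratio"] = (
            profile.n_peaks_overlapping > 0
            and profile.summit_ratio >= config.min_summit_ratio
        )
        if not prefilters_ok:
            label = "excluded"
        elif profile.n_peaks_overlapping == 0:
            label = "ctrl_neg"
        elif not ledger["min_distinct_tfs"]:
            label = "insufficient_tf"
        elif ledger["density"] and ledger["summit_ratio"]:
            label = "cEE"
        else:
            label = "excluded"
        calls.append(CeeCall(exon=ex, profile=profile, ledger=ledger, label=label))
    return calls


def build_controls(
    calls: Sequence[CeeCall],
    intergenic_ccres: Sequence[GenomicInterval],
    peaks: Sequence[TfPeak],
    config: CallerConfig | None = None,
    tss_tes: Sequence[TssRecord] = (),
    tss_peaks: Sequence[TssRecord] = (),
) -> tuple[list[CeeCall], list[CeeCall]]:
    """Negative and positive control sets.

    Negative controls are fully filtered exons with zero overlapping TF peaks
    (label ``ctrl_neg`` from :func:`call_cees`). Positive controls are
    intergenic cCREs passing the same proximity/summit/density criteria with
    at least ``min_distinct_tfs`` distinct factors (label ``ctrl_pos``).
    """
    config = config or CallerConfig()
    ctrl_neg = [c for c in calls if c.label == "ctrl_neg"]
    arrays = _chrom_peak_arrays(peaks)
    ctrl_pos = []
    for iv in intergenic_ccres:
        ex = ExonRecord(iv)
        ledger: dict[str, bool | str] = {}
        ledger["tss_tes_distance"] = (
            distance_to_nearest(iv, tss_tes, same_strand=False)
            > config.tss_tes_exclusion_bp
        )
        ledger["tss_peak_window"] = (
            distance_to_nearest(iv, tss_peaks, same_strand=False)
            > config.tss_peak_window_bp
        )
        profile = profile_tf_occupancy(
            ex, peaks, config.flank_bp, config.density_window_bp,
            _arrays=arrays.get(normalize_chrom(iv.chrom)),
        )
        ledger["min_distinct_tfs"] = profile.n_distinct_tfs >= config.min_distinct_tfs
        ledger["density"] = density_criterion(profile)
        ledger["summit_ratio"] = (
            profile.n_peaks_overlapping > 0
            and profile.summit_ratio >= config.min_summit_ratio
        )
        if all(v for v in ledger.values()):
            ctrl_pos.append(CeeCall(ex, profile, ledger, label="ctrl_pos"))
    return ctrl_neg, ctrl_pos
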