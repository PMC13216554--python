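"""Matched-shuffle permutation enrichment and overlap statistics.

The central primitive places a genomic interval uniformly at random on its own
chromosome, preserving its exact length and its GC-content bin, and staying
inside a uniquely-mappable mask. Repeating this for every query interval once
per permutation yields a null distribution of overlap counts against a fixed
target set; fold-enrichment is observed over mean-expected and the empirical
two-tailed p-value is 2*(k + 1)/(n_permutations + 1), where k counts
permutations at least as extreme as the observed value on the side of the null
mean where the observation fell (clamped to 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .core import (
    GC_BIN_EDGES,
    GenomeBuild,
    GenomicInterval,
    MergedIntervals,
    TfPeak,
    gc_bin,
    normalize_chrom,
)


class PlacementError(RuntimeError):
    """No legal shuffled placement exists for an interval."""


@dataclass
class ShuffleConfig:
    n_permutations: int = 10_000
    gc_bin_edges: tuple[float, ...] = GC_BIN_EDGES
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        edges = np.asarray(self.gc_bin_edges, dtype=float)
        if np.any(np.diff(edges) <= 0):
            raise ValueError("gc_bin_edges must be strictly increasing")


@dataclass
class EnrichmentResult:
    observed: int
    expected_mean: float
    fold: float
    k: int
    p_two_tailed: float
    null_distribution: np.ndarray


@dataclass
class CorrespondenceResult:
    observed_rate: float
    null_rates: np.ndarray
    wilcoxon_p: float
    signflip_p: float
    paired_differences: np.ndarray = field(default=None)  # type: ignore[assignment]


# Rejection-sampling budget before falling back to exhaustive enumeration of
# all legal placements (guarantees termination on tight masks).
_REJECTION_BUDGET = 1000


class MatchedShuffler:
    """Length-, chromosome- and GC-bin-preserving interval shuffler.

    Exhaustively enumerated candidate start sets are cached per
    (chromosome, length, GC bin), which makes repeated shuffles of the same
    interval — the permutation-test workload — cheap.
    """

    def __init__(self, build: GenomeBuild, config: ShuffleConfig | None = None):
        self.build = build
        self.config = config or ShuffleConfig()
        self._edges = np.asarray(self.config.gc_bin_edges, dtype=float)
        self._cache: dict[tuple[str, int, int], np.ndarray] = {}
        # Legal start ranges per chromosome depend only on the length.
        self._range_cache: dict[tuple[str, int], tuple[np.ndarray, np.ndarray]] = {}

    def interval_bin(self, interval: GenomicInterval) -> int:
        gc = self.build.interval_gc(interval.chrom, interval.start, interval.end)
        return int(gc_bin(gc, self._edges))

    def _legal_ranges(self, chrom: str, length: int):
        """(range_starts, range_counts): start in range i is range_starts[i]..+counts[i]-1."""
        key = (chrom, length)
        if key not in self._range_cache:
            m = self.build.mask[chrom]
            if m.size == 0:
                starts = np.empty(0, dtype=np.int64)
                counts = np.empty(0, dtype=np.int64)
            else:
                widths = m[:, 1] - m[:, 0]
                ok = widths >= length
                starts = m[ok, 0]
                counts = widths[ok] - length + 1
            self._range_cache[key] = (starts, counts)
        return self._range_cache[key]

    def candidate_starts(self, chrom: str, length: int, bin_idx: int) -> np.ndarray:
        """All legal start positions for (chrom, length) whose GC bin matches."""
        key = (chrom, length, bin_idx)
        if key not in self._cache:
            starts, counts = self._legal_ranges(chrom, length)
            if starts.size == 0:
                self._cache[key] = np.empty(0, dtype=np.int64)
            else:
                all_starts = np.concatenate(
                    [s + np.arange(c, dtype=np.int64) for s, c in zip(starts, counts)]
                )
                bins = gc_bin(self.build.window_gc(chrom, all_starts, length), self._edges)
                self._cache[key] = all_starts[bins == bin_idx]
        return self._cache[key]

    def shuffle_starts(
        self, interval: GenomicInterval, rng: np.random.Generator, size: int
    ) -> np.ndarray:
        """Draw ``size`` legal shuffled start positions for ``interval``.

        Placement is uniform over legal positions: candidates are equally
        likely both under rejection sampling (uniform proposal, bin
        acceptance) and under exhaustive enumeration.
        """
        chrom = normalize_chrom(interval.chrom)
        length = interval.length
        target_bin = self.interval_bin(interval)
        key = (chrom, length, target_bin)
        if key in self._cache:
            cand = self._cache[key]
            if cand.size == 0:
                raise PlacementError(
                    f"no legal placement for {interval.name or interval} "
                    f"(chrom {chrom}, length {length}, gc bin {target_bin})"
                )
            return rng.choice(cand, size=size, replace=True)
        range_starts, range_counts = self._legal_ranges(chrom, length)
        total = int(range_counts.sum()) if range_counts.size else 0
        if total == 0:
            raise PlacementError(
                f"no mask window can host {interval.name or interval} "
                f"(length {length} on {chrom})"
            )
        out = np.empty(size, dtype=np.int64)
        filled = 0
        rejected = 0
        cum = np.concatenate([[0], np.cumsum(range_counts)])
        while filled < size and rejected < _REJECTION_BUDGET:
            need = size - filled
            batch = max(4 * need, 64)
            u = rng.integers(0, total, size=batch)
            ridx = np.searchsorted(cum, u, side="right") - 1
            props = range_starts[ridx] + (u - cum[ridx])
            bins = gc_bin(self.build.window_gc(chrom, props, length), self._edges)
            ok = props[bins == target_bin]
            take = min(need, ok.size)
            out[filled : filled + take] = ok[:take]
            filled += take
            rejected += batch - ok.size
        if filled < size:
            cand = self.candidate_starts(chrom, length, target_bin)
            if cand.size == 0:
                raise PlacementError(
                    f"no legal placement for {interval.name or interval} "
                    f"(chrom {chrom}, length {length}, gc bin {target_bin})"
                )
            out[filled:] = rng.choice(cand, size=size - filled, replace=True)
        return out


def shuffle_interval(
    interval: GenomicInterval,
    build: GenomeBuild,
    config: ShuffleConfig | None = None,
    rng: np.random.Generator | None = None,
    shuffler: MatchedShuffler | None = None,
) -> GenomicInterval:
    """One matched shuffle of an interval (same chrom, length and GC bin)."""
    shuffler = shuffler or MatchedShuffler(build, config)
    rng = rng if rng is not None else np.random.default_rng(
        shuffler.config.seed
    )
    start = int(shuffler.shuffle_starts(interval, rng, 1)[0])
    return GenomicInterval(
        normalize_chrom(interval.chrom), start, start + interval.length,
        interval.strand, interval.name,
    )


def _empirical_p(null: np.ndarray, observed: float, n_perm: int) -> tuple[int, float]:
    if observed >= null.mean():
        k = int((null >= observed).sum())
    else:
        k = int((null <= observed).sum())
    p = min(1.0, 2.0 * (k + 1) / (n_perm + 1))
    return k, p


def permutation_enrichment(
    query: Sequence[GenomicInterval],
    targets: Sequence[GenomicInterval],
    build: GenomeBuild,
    config: ShuffleConfig | None = None,
    rng: np.random.Generator | None = None,
    shuffler: MatchedShuffler | None = None,
    shuffle_side: str = "query",
) -> EnrichmentResult:
    """Matched-shuffle permutation test of query/target interval overlap.

    The statistic is the number of query intervals intersecting at least one
    target. Each permutation re-places every interval of the shuffled side
    (``query`` by default; ``targets`` optionally) once. Placement failures
    propagate as :class:`PlacementError` naming the offending interval.
    """
    if not query or not targets:
        raise ValueError("query and target sets must be non-empty")
    if shuffle_side not in ("query", "targets"):
        raise ValueError("shuffle_side must be 'query' or 'targets'")
    config = config or ShuffleConfig()
    shuffler = shuffler or MatchedShuffler(build, config)
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n_perm = config.n_permutations
    target_idx = MergedIntervals(targets)
    observed = int(sum(target_idx.overlaps_interval(q) for q in query))
    if shuffle_side == "query":
        null = np.zeros(n_perm, dtype=np.int64)
        for q in query:
            starts = shuffler.shuffle_starts(q, rng, n_perm)
            hits = target_idx.any_overlap(q.chrom, starts, starts + q.length)
            null += hits
    else:
        draws = [
            (t, shuffler.shuffle_starts(t, rng, n_perm)) for t in targets
        ]
        null = np.zeros(n_perm, dtype=np.int64)
        for i in range(n_perm):
            shuffled = [
                GenomicInterval(normalize_chrom(t.chrom), int(s[i]),
                                int(s[i]) + t.length)
                for t, s in draws
            ]
            idx = MergedIntervals(shuffled)
            null[i] = sum(idx.overlaps_interval(q) for q in query)
    expected = float(null.mean())
    if expected > 0:
        fold = observed / expected
    else:
        fold = float("inf") if observed > 0 else float("nan")
    k, p = _empirical_p(null, observed, n_perm)
    return EnrichmentResult(
        observed=observed, expected_mean=expected, fold=fold, k=k,
        p_two_tailed=p, null_distribution=null,
    )


def fisher_overlap_test(
    n_hit_query: int, n_query: int, n_hit_ctrl: int, n_ctrl: int,
    alternative: str = "greater",
) -> float:
    """One-sided Fisher's exact test for enrichment of hits in the query set."""
    for v in (n_hit_query, n_query, n_hit_ctrl, n_ctrl):
        if v < 0:
            raise ValueError("counts must be non-negative")
    if n_hit_query > n_query or n_hit_ctrl > n_ctrl:
        raise ValueError("hits cannot exceed totals")
    if n_query == 0 or n_ctrl == 0:
        raise ValueError("degenerate margins: empty query or control set")
    table = [
        [n_hit_query, n_query - n_hit_query],
        [n_hit_ctrl, n_ctrl - n_hit_ctrl],
    ]
    return float(stats.fisher_exact(table, alternative=alternative)[1])


def tfbs_correspondence_rate(
    element: GenomicInterval,
    peaks: Sequence[TfPeak],
    motif_sites: Sequence[GenomicInterval],
    score_threshold: float | None = None,
) -> float | None:
    """Fraction of high-score element-overlapping peaks whose same-TF motif
    site also overlaps the element.

    The score threshold defaults to the median score of all supplied peaks;
    motif sites are matched to peaks through their ``name`` (TF label).
    Returns ``None`` when no peak qualifies.
    """
    if score_threshold is None:
        if not peaks:
            return None
        score_threshold = float(np.median([p.score for p in peaks]))
    qualifying = [
        p for p in peaks
        if p.score >= score_threshold and p.interval.overlaps(element)
    ]
    if not qualifying:
        return None
    sites_by_tf: dict[str, list[GenomicInterval]] = {}
    for s in motif_sites:
        sites_by_tf.setdefault(s.name, []).append(s)
    n_matched = sum(
        any(s.overlaps(element) for s in sites_by_tf.get(p.tf_name, ()))
        for p in qualifying
    )
    return n_matched / len(qualifying)


def sign_flip_test(
    diffs: np.ndarray,
    n_flips: int = 100_000,
    rng: np.random.Generator | None = None,
    method: str = "sampling",
) -> float:
    """Two-sided paired sign-flip permutation test on the mean difference.

    The observed mean is compared with the distribution of means under random
    sign assignment; the tail on the observed side is doubled and clamped to
    1. ``method='exact'`` enumerates all 2^n sign vectors (n <= 20).
    """
    d = np.asarray(diffs, dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 paired differences")
    obs = d.mean()
    if method == "exact":
        if d.size > 20:
            raise ValueError("exact enumeration limited to n <= 20")
        signs = np.array(
            [[1 if (m >> i) & 1 else -1 for i in range(d.size)]
             for m in range(2 ** d.size)],
            dtype=float,
        )
        means = signs @ d / d.size
        denom = means.size
    else:
        rng = rng if rng is not None else np.random.default_rng()
        signs = rng.integers(0, 2, size=(n_flips, d.size)) * 2 - 1
        means = signs @ d / d.size
        denom = n_flips
    if obs >= 0:
        count = int((means >= obs).sum())
    else:
        count = int((means <= obs).sum())
    return min(1.0, 2.0 * count / denom)


def correspondence_randomisation_test(
    elements: Sequence[GenomicInterval],
    peaks: Sequence[TfPeak],
    motif_sites: Sequence[GenomicInterval],
    build: GenomeBuild,
    config: ShuffleConfig | None = None,
    n_randomisations: int = 100,
    n_flips: int = 100_000,
    rng: np.random.Generator | None = None,
) -> CorrespondenceResult:
    """Observed vs randomised TF-peak/motif correspondence rates.

    Peaks are re-placed genome-wide (same chromosome and GC bin) in each
    randomisation; per-element paired differences (observed - mean null rate)
    are tested with a two-sided Wilcoxon signed-rank test and a paired
    sign-flip permutation test on the mean difference.
    """
    config = config or ShuffleConfig()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    shuffler = MatchedShuffler(build, config)
    observed: list[float] = []
    null_means: list[float] = []
    all_null_rates: list[float] = []
    for element in elements:
        obs = tfbs_correspondence_rate(element, peaks, motif_sites)
        if obs is None:
            continue
        nulls = []
        for _ in range(n_randomisations):
            shuffled_peaks = []
            for p in peaks:
                s = int(shuffler.shuffle_starts(p.interval, rng, 1)[0])
                iv = GenomicInterval(
                    normalize_chrom(p.interval.chrom), s, s + p.interval.length,
                    p.interval.strand, p.interval.name,
                )
                shuffled_peaks.append(
                    TfPeak(iv, p.tf_name, s + (p.summit - p.interval.start),
                           p.dataset_id, p.score, p.summit_imputed)
                )
            rate = tfbs_correspondence_rate(element, shuffled_peaks, motif_sites)
            nulls.append(0.0 if rate is None else rate)
        observed.append(obs)
        null_means.append(float(np.mean(nulls)))
        all_null_rates.extend(nulls)
    diffs = np.asarray(observed) - np.asarray(null_means)
    if diffs.size < 2:
        raise ValueError("fewer than 2 paired differences; test undefined")
    if np.allclose(diffs, 0.0):
        wilcoxon_p = 1.0
    else:
        wilcoxon_p = float(stats.wilcoxon(diffs, alternative="two-sided").pvalue)
    signflip_p = sign_flip_test(diffs, n_flips=n_flips, rng=rng)
    return CorrespondenceResult(
        observed_rate=float(np.mean(observed)),
        null_rates=np.asarray(all_null_rates),
        wilcoxon_p=wilcoxon_p,
        signflip_p=signflip_p,
        paired_differences=diffs,
    )
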