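import itertools
import math

import numpy as np
import pytest
from scipy import stats

from ceekit.core import GenomeBuild, GenomicInterval, TfPeak
from ceekit.enrichment import (
    MatchedShuffler,
    PlacementError,
    ShuffleConfig,
    correspondence_randomisation_test,
    fisher_overlap_test,
    permutation_enrichment,
    shuffle_interval,
    sign_flip_test,
    tfbs_correspondence_rate,
)
from ceekit.simulate import _random_sequence


@pytest.fixture(scope="module")
def toy_build():
    rng = np.random.default_rng(42)
    seq = _random_sequence(rng, 100_000, 10_000, (0.3, 0.7)).tobytes().decode()
    mask = {"1": np.array([[0, 40_000], [50_000, 100_000]])}
    return GenomeBuild.from_sequences({"1": seq}, gc_window=100, mask=mask)


class TestShuffle:
    def test_forced_placement(self):
        """A mask admitting exactly one legal window returns that window."""
        build = GenomeBuild({"1": 10_000}, mask={"1": np.array([[500, 600]])})
        iv = GenomicInterval("1", 2000, 2100)
        out = shuffle_interval(iv, build, rng=np.random.default_rng(0))
        assert (out.start, out.end) == (500, 600)

    def test_contract_on_every_output(self, toy_build, rng):
        shuffler = MatchedShuffler(toy_build)
        iv = GenomicInterval("1", 1000, 1250)
        bin_in = shuffler.interval_bin(iv)
        starts = shuffler.shuffle_starts(iv, rng, 2000)
        assert starts.shape == (2000,)
        bins = [
            shuffler.interval_bin(GenomicInterval("1", int(s), int(s) + 250))
            for s in starts[:200]
        ]
        assert set(bins) == {bin_in}
        inside = ((starts >= 0) & (starts + 250 <= 40_000)) | (
            (starts >= 50_000) & (starts + 250 <= 100_000)
        )
        assert inside.all()

    def test_placement_failure_names_interval(self):
        build = GenomeBuild({"1": 10_000}, mask={"1": np.array([[0, 50]])})
        iv = GenomicInterval("1", 0, 100, name="too_long")
        with pytest.raises(PlacementError, match="too_long"):
            shuffle_interval(iv, build, rng=np.random.default_rng(0))

    def test_rare_bin_falls_back_to_enumeration(self):
        # one extreme-GC window in an otherwise AT genome
        seq = "AT" * 5_000 + "GC" * 50 + "AT" * 5_000
        build = GenomeBuild.from_sequences({"1": seq}, gc_window=100)
        iv = GenomicInterval("1", 10_000, 10_100)  # the all-GC window
        shuffler = MatchedShuffler(build)
        out = shuffle_interval(iv, build, rng=np.random.default_rng(1),
                               shuffler=shuffler)
        assert shuffler.interval_bin(out) == shuffler.interval_bin(iv)


class TestPermutationEnrichment:
    def test_pvalue_formula_k0(self, toy_build):
        """Observed overlap never reached by shuffles gives p = 2/(N+1)."""
        build = GenomeBuild(
            {"1": 300_000}, mask={"1": np.array([[200_000, 300_000]])}
        )
        query = [GenomicInterval("1", 100, 300)]
        targets = [GenomicInterval("1", 50, 400)]
        res = permutation_enrichment(
            query, targets, build, ShuffleConfig(n_permutations=10_000),
            rng=np.random.default_rng(0),
        )
        assert res.observed == 1
        assert res.k == 0
        assert res.p_two_tailed == pytest.approx(2 / 10_001)

    def test_p_clamped_at_one(self, toy_build, rng):
        query = [GenomicInterval("1", s, s + 200) for s in range(1000, 21_000, 1000)]
        targets = [GenomicInterval("1", s, s + 500) for s in range(0, 100_000, 2000)]
        res = permutation_enrichment(
            query, targets, toy_build, ShuffleConfig(n_permutations=200), rng=rng
        )
        assert 0 < res.p_two_tailed <= 1.0

    def test_fold_is_observed_over_expected(self, toy_build, rng):
        query = [GenomicInterval("1", s, s + 200) for s in range(1000, 11_000, 1000)]
        targets = [GenomicInterval("1", 500, 60_000)]
        res = permutation_enrichment(
            query, targets, toy_build, ShuffleConfig(n_permutations=100), rng=rng
        )
        assert res.fold == pytest.approx(res.observed / res.expected_mean)
        assert len(res.null_distribution) == 100

    def test_target_shuffling_mode(self, toy_build, rng):
        query = [GenomicInterval("1", s, s + 200) for s in range(1000, 6000, 1000)]
        targets = [GenomicInterval("1", 1000, 1400), GenomicInterval("1", 30_000, 30_200)]
        res = permutation_enrichment(
            query, targets, toy_build, ShuffleConfig(n_permutations=50),
            rng=rng, shuffle_side="targets",
        )
        assert res.observed >= 1
        assert len(res.null_distribution) == 50

    def test_empty_sets_rejected(self, toy_build):
        with pytest.raises(ValueError):
            permutation_enrichment([], [GenomicInterval("1", 0, 10)], toy_build)


def fisher_greater_oracle(a, b, c, d):
    """Exact one-sided hypergeometric tail by enumerating 2x2 tables."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    denom = math.comb(n, col1)
    p = 0.0
    for x in range(max(0, col1 - (c + d)), min(row1, col1) + 1):
        if x >= a:
            p += math.comb(row1, x) * math.comb(n - row1, col1 - x) / denom
    return p


class TestFisher:
    @pytest.mark.parametrize("table", [
        (8, 10, 2, 10), (1, 1, 0, 1), (5, 12, 5, 12), (0, 3, 3, 3), (12, 12, 0, 12),
    ])
    def test_matches_enumeration_oracle(self, table):
        hq, nq, hc, nc = table
        expected = fisher_greater_oracle(hq, nq - hq, hc, nc - hc)
        assert fisher_overlap_test(hq, nq, hc, nc) == pytest.approx(expected)

    def test_exhaustive_small_margins(self):
        for nq in range(1, 7):
            for nc in range(1, 7):
                for hq in range(nq + 1):
                    for hc in range(nc + 1):
                        got = fisher_overlap_test(hq, nq, hc, nc)
                        want = fisher_greater_oracle(hq, nq - hq, hc, nc - hc)
                        assert got == pytest.approx(want), (hq, nq, hc, nc)

    def test_identical_rates_not_enriched(self):
        assert fisher_overlap_test(5, 10, 5, 10) >= 0.5

    def test_degenerate_margins_rejected(self):
        with pytest.raises(ValueError):
            fisher_overlap_test(0, 0, 1, 2)


def motif(chrom, start, end, tf):
    return GenomicInterval(chrom, start, end, name=tf)


def tf_peak(chrom, start, end, tf, score):
    return TfPeak(GenomicInterval(chrom, start, end), tf, (start + end) // 2,
                  score=score)


class TestCorrespondence:
    def test_rate_counts_matching_motifs(self):
        element = GenomicInterval("1", 1000, 1200)
        peaks = [
            tf_peak("1", 1000, 1100, "A", 10),
            tf_peak("1", 1050, 1150, "B", 10),
            tf_peak("1", 1100, 1200, "C", 10),
            tf_peak("1", 1100, 1190, "D", 10),
        ]
        motifs = [motif("1", 1010, 1020, "A"), motif("1", 1100, 1110, "B"),
                  motif("1", 5000, 5010, "C")]
        rate = tfbs_correspondence_rate(element, peaks, motifs, score_threshold=0)
        assert rate == pytest.approx(0.5)

    def test_median_threshold_application(self):
        element = GenomicInterval("1", 1000, 1200)
        peaks = [tf_peak("1", 1000, 1100, t, s)
                 for t, s in zip("ABCD", [1, 2, 3, 4])]
        motifs = [motif("1", 1010, 1020, t) for t in "ABCD"]
        # median score 2.5: only C and D qualify
        rate = tfbs_correspondence_rate(element, peaks, motifs)
        assert rate == pytest.approx(1.0)
        rate = tfbs_correspondence_rate(element, peaks, [])
        assert rate == pytest.approx(0.0)

    def test_no_qualifying_peaks_undefined(self):
        element = GenomicInterval("1", 1000, 1200)
        peaks = [tf_peak("1", 5000, 5100, "A", 10)]
        assert tfbs_correspondence_rate(element, peaks, [], score_threshold=0) is None


class TestSignFlip:
    def test_all_zero_differences_give_p_one(self, rng):
        assert sign_flip_test(np.zeros(5), n_flips=100, rng=rng) == 1.0

    def test_sampling_matches_exhaustive_enumeration(self, rng):
        d = np.array([0.5, 1.0, 0.2, 0.8, 1.2, 0.3, 0.9, 0.6, 1.1, 0.4])
        exact = sign_flip_test(d, method="exact")
        sampled = sign_flip_test(d, n_flips=100_000, rng=rng)
        assert exact == pytest.approx(2 * 1 / 2**10)
        assert sampled == pytest.approx(exact, abs=4e-3)

    def test_exact_oracle_by_direct_enumeration(self):
        d = np.array([1.0, -0.5, 2.0, 0.25])
        means = [
            np.mean([s * x for s, x in zip(signs, d)])
            for signs in itertools.product((1, -1), repeat=4)
        ]
        obs = d.mean()
        expected = min(1.0, 2 * sum(m >= obs for m in means) / len(means))
        assert sign_flip_test(d, method="exact") == pytest.approx(expected)


def wilcoxon_exact_oracle(diffs):
    """Two-sided signed-rank p by enumerating all sign assignments."""
    d = np.asarray(diffs, dtype=float)
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    total = ranks.sum()
    ws = []
    for signs in itertools.product((0, 1), repeat=n):
        ws.append(sum(r for s, r in zip(signs, ranks) if s))
    ws = np.asarray(ws, dtype=float)
    centred = abs(w_obs - total / 2)
    p = np.mean(np.abs(ws - total / 2) >= centred - 1e-12)
    return p


class TestCorrespondenceRandomisation:
    def test_wilcoxon_matches_exact_enumeration(self):
        d = np.array([1.0, 2.0, 3.0, -4.0, 5.0, -6.0])
        got = stats.wilcoxon(d, alternative="two-sided", method="exact").pvalue
        assert got == pytest.approx(wilcoxon_exact_oracle(d))

    def test_planted_correspondence_detected(self, toy_build, rng):
        elements = [GenomicInterval("1", 1000 + 3000 * i, 1200 + 3000 * i)
                    for i in range(6)]
        peaks, motifs = [], []
        for i, el in enumerate(elements):
            for t in range(3):
                peaks.append(tf_peak("1", el.start, el.end, f"T{i}_{t}", 10))
                motifs.append(motif("1", el.start + 10, el.start + 20, f"T{i}_{t}"))
        res = correspondence_randomisation_test(
            elements, peaks, motifs, toy_build,
            ShuffleConfig(n_permutations=1), n_randomisations=20,
            n_flips=5000, rng=rng,
        )
        assert res.observed_rate == pytest.approx(1.0)
        assert (res.paired_differences > 0).all()
        assert res.signflip_p < 0.05

    def test_too_few_pairs_rejected(self, toy_build, rng):
        el = GenomicInterval("1", 1000, 1200)
        peaks = [tf_peak("1", 1000, 1200, "A", 10)]
        with pytest.raises(ValueError):
            correspondence_randomisation_test(
                [el], peaks, [], toy_build, n_randomisations=2, rng=rng
            )
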