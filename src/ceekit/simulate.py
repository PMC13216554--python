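"""Synthetic data with planted ground truth for every pipeline stage.

The generator emits a small exon/intron genome with in-frame coding sequences,
TF ChIP-seq peak catalogues with planted multi-TF clusters on chosen exons,
codon-aware variant calls with a configurable allele-frequency spectrum,
negative-binomial STARR-seq count tables with planted activities and variant
shifts, orthologous coding-sequence pairs with known divergence, planted
enhancer-target evidence tables, and query/target interval sets with a planted
overlap enrichment. All generators are deterministic given the config seed and
emit objects (and, via the CLI, files) that the standard readers parse.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .core import (
    ExonRecord,
    GenomeBuild,
    GenomicInterval,
    MergedIntervals,
    TfPeak,
    TssRecord,
    Variant,
    reverse_complement,
)
from .enrichment import MatchedShuffler, ShuffleConfig

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_STOPS = {"TAA", "TAG", "TGA"}
_NONSTOP_CODONS = sorted(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS
)


@dataclass
class SimConfig:
    """Study-scale defaults for the synthetic datasets.

    The desk-scale preset (2 chromosomes x 5 Mb, 50 genes, 15 TFs, 20 planted
    cEEs) keeps a full pipeline run fast while leaving the planted clusters
    comfortably above the caller thresholds (12 TFs per cluster vs a minimum
    of 10; 10 bp summit jitter around the exon midpoint). The allele-frequency
    mixture defaults to 91% ultra-rare / 6% rare / 2% low-frequency / 1%
    common variants.
    """

    seed: int = 0
    # genome
    n_chroms: int = 2
    chrom_length: int = 5_000_000
    n_genes: int = 50
    exons_per_gene: tuple[int, int] = (3, 8)
    exon_length: tuple[int, int] = (90, 300)       # drawn as multiples of 3
    intron_length: tuple[int, int] = (1500, 4000)
    intergenic_gap: tuple[int, int] = (5000, 20000)
    minus_strand_fraction: float = 0.5
    gc_window: int = 100
    gc_block: int = 50_000
    gc_range: tuple[float, float] = (0.35, 0.65)
    mask_fraction: float = 0.9
    # TF peaks
    n_tfs: int = 15
    background_peaks_per_mb: float = 30.0
    n_planted_cees: int = 20
    tfs_per_cluster: int = 12
    summit_jitter_sd: float = 10.0
    peak_width: int = 200
    # variants
    snv_rate: float = 0.02
    af_weights: tuple[float, float, float, float] = (0.91, 0.06, 0.02, 0.01)
    fail_filter_fraction: float = 0.05
    # STARR
    n_cee_inserts: int = 150
    n_ctrl_neg: int = 80
    n_ctrl_pos: int = 80
    n_starr_plus: int = 60
    n_starr_minus: int = 60
    n_variant_inserts: int = 60
    input_depth: float = 2000.0
    insert_depth_cv: float = 0.5
    input_replicate_cv: float = 0.005
    input_unstable_fraction: float = 0.05
    input_unstable_cv: float = 0.05
    nb_dispersion: float = 50.0
    n_input_samples: int = 2
    n_cdna_replicates: int = 3
    replicate_noise_sd: float = 0.2
    cee_activity_values: tuple[float, ...] = (0.0, 1.0, 2.5)
    cee_activity_weights: tuple[float, ...] = (0.70, 0.20, 0.10)
    ctrl_pos_activity_values: tuple[float, ...] = (0.0, 1.0, 2.5)
    ctrl_pos_activity_weights: tuple[float, ...] = (0.55, 0.30, 0.15)
    starr_plus_activity: float = 2.0
    starr_minus_activity: float = -0.5
    activity_jitter_sd: float = 0.1
    variant_shift_mean: float = -1.0
    variant_shift_sd: float = 0.5
    # orthologs
    n_ortholog_pairs: int = 30
    ortholog_codons: int = 300
    target_dn: float = 0.02
    target_ds: float = 0.06
    # interactions
    n_interaction_elements: int = 12
    robust_interaction_fraction: float = 0.5

    def __post_init__(self) -> None:
        if abs(sum(self.af_weights) - 1.0) > 1e-9:
            raise ValueError("af_weights must sum to 1")
        if self.tfs_per_cluster < 1 or self.tfs_per_cluster > self.n_tfs:
            raise ValueError("tfs_per_cluster must be in [1, n_tfs]")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class SimGenome:
    sequences: dict[str, str]
    build: GenomeBuild
    exons: list[ExonRecord]
    genes: dict[str, GenomicInterval]
    gene_cds: dict[str, str]
    tss: list[TssRecord]
    tes: list[TssRecord]
    cage: list[TssRecord]

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}


def _random_sequence(
    rng: np.random.Generator, length: int, gc_block: int, gc_range: tuple[float, float]
) -> np.ndarray:
    """Random sequence (S1 array) with block-wise GC variation."""
    out = np.empty(length, dtype="S1")
    for start in range(0, length, gc_block):
        n = min(gc_block, length - start)
        gc = rng.uniform(*gc_range)
        probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        idx = np.searchsorted(np.cumsum(probs), rng.random(n), side="right")
        out[start : start + n] = _BASES[np.minimum(idx, 3)]
    return out


def _random_mask(
    rng: np.random.Generator, length: int, mask_fraction: float, n_gaps: int = 3
) -> np.ndarray:
    """Mask covering ~mask_fraction of a chromosome as disjoint intervals."""
    gap_total = int(round(length * (1.0 - mask_fraction)))
    if gap_total <= 0:
        return np.array([[0, length]], dtype=np.int64)
    gap_len = max(1, gap_total // n_gaps)
    gap_starts = np.sort(rng.integers(0, length - gap_len, size=n_gaps))
    gaps = []
    for s in gap_starts:
        e = s + gap_len
        if gaps and s <= gaps[-1][1]:
            gaps[-1][1] = max(gaps[-1][1], e)
        else:
            gaps.append([s, e])
    mask = []
    cursor = 0
    for s, e in gaps:
        if s > cursor:
            mask.append([cursor, s])
        cursor = max(cursor, e)
    if cursor < length:
        mask.append([cursor, length])
    return np.asarray(mask, dtype=np.int64)


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """An in-frame CDS: start codon, non-stop body, terminal stop codon."""
    body = rng.choice(len(_NONSTOP_CODONS), size=n_codons - 2)
    stop = ("TAA", "TAG", "TGA")[rng.integers(0, 3)]
    return "ATG" + "".join(_NONSTOP_CODONS[i] for i in body) + stop


def simulate_genome(config: SimConfig, rng: np.random.Generator | None = None) -> SimGenome:
    """Exon/intron genome with embedded in-frame CDS, TSS/TES and CAGE peaks.

    Genes are placed non-overlapping with intergenic gaps; every exon length
    is a multiple of 3 (phase 0 throughout) and the concatenated exon sequence
    of a gene starts with ATG, contains no internal stop, and ends with a stop
    codon. Byte-identical outputs are guaranteed for a fixed seed.
    """
    rng = rng if rng is not None else config.rng()
    chroms = [str(i + 1) for i in range(config.n_chroms)]
    seqs = {
        c: _random_sequence(rng, config.chrom_length, config.gc_block, config.gc_range)
        for c in chroms
    }
    cursors = {c: 0 for c in chroms}
    exons: list[ExonRecord] = []
    genes: dict[str, GenomicInterval] = {}
    gene_cds: dict[str, str] = {}
    tss, tes, cage = [], [], []
    for g in range(config.n_genes):
        n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        ex_lens = (
            rng.integers(config.exon_length[0] // 3, config.exon_length[1] // 3 + 1,
                         size=n_ex) * 3
        )
        in_lens = rng.integers(
            config.intron_length[0], config.intron_length[1] + 1, size=n_ex - 1
        )
        span = int(ex_lens.sum() + in_lens.sum())
        gap = int(rng.integers(*config.intergenic_gap))
        placed = None
        for c in sorted(chroms, key=lambda c: cursors[c]):
            start = cursors[c] + gap
            if start + span < config.chrom_length - 1000:
                placed = (c, start)
                break
        if placed is None:
            raise ValueError("genome too small for the requested gene count")
        chrom, start = placed
        cursors[chrom] = start + span
        strand = "-" if rng.random() < config.minus_strand_fraction else "+"
        gene_id = f"g{g:03d}"
        # genomic-order exon spans
        spans = []
        pos = start
        for k in range(n_ex):
            spans.append((pos, pos + int(ex_lens[k])))
            if k < n_ex - 1:
                pos += int(ex_lens[k]) + int(in_lens[k])
            else:
                pos += int(ex_lens[k])
        cds = _random_cds(rng, int(ex_lens.sum()) // 3)
        gene_cds[gene_id] = cds
        coding_order = spans if strand == "+" else spans[::-1]
        offset = 0
        slices: dict[tuple[int, int], str] = {}
        for s, e in coding_order:
            slices[(s, e)] = cds[offset : offset + (e - s)]
            offset += e - s
        for k, (s, e) in enumerate(spans):
            chunk = slices[(s, e)]
            genomic = reverse_complement(chunk) if strand == "-" else chunk
            seqs[chrom][s:e] = np.frombuffer(genomic.encode(), dtype="S1")
            coding_index = k if strand == "+" else n_ex - 1 - k
            exons.append(
                ExonRecord(
                    GenomicInterval(chrom, s, e, strand, f"{gene_id}.e{coding_index}"),
                    gene_id=gene_id,
                    transcript_id=f"t{g:03d}",
                    tsl=1,
                    phase=0,
                    cds_seq=chunk,
                )
            )
        genes[gene_id] = GenomicInterval(chrom, start, pos, strand, gene_id)
        tss_pos = start if strand == "+" else pos - 1
        tes_pos = pos - 1 if strand == "+" else start
        tss.append(TssRecord(chrom, tss_pos, strand, "annotated_tss"))
        tes.append(TssRecord(chrom, tes_pos, strand, "annotated_tes"))
        cage.append(TssRecord(chrom, tss_pos, strand, "cage_peak"))
    sequences = {c: arr.tobytes().decode() for c, arr in seqs.items()}
    mask = {
        c: _random_mask(rng, config.chrom_length, config.mask_fraction) for c in chroms
    }
    build = GenomeBuild.from_sequences(sequences, gc_window=config.gc_window, mask=mask)
    return SimGenome(
        sequences=sequences, build=build, exons=exons, genes=genes,
        gene_cds=gene_cds, tss=tss, tes=tes, cage=cage,
    )


def _interior_exons(genome: SimGenome) -> dict[str, list[ExonRecord]]:
    by_gene: dict[str, list[ExonRecord]] = {}
    for ex in genome.exons:
        by_gene.setdefault(ex.gene_id, []).append(ex)
    out = {}
    for gid, exs in by_gene.items():
        exs = sorted(exs, key=lambda e: e.interval.start)
        if len(exs) >= 3:
            out[gid] = exs[1:-1]
    return out


def simulate_tf_peaks(
    config: SimConfig, genome: SimGenome, rng: np.random.Generator | None = None
) -> tuple[list[TfPeak], list[str]]:
    """TF peak catalogue with planted multi-TF clusters on interior exons.

    Each planted exon receives one peak per sampled TF, with the summit
    jittered around the exon midpoint (Normal, SD ``summit_jitter_sd``);
    background peaks are Poisson-scattered within the mappable mask with a
    random factor each. Returns (peaks, planted exon ids).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    tf_names = [f"TF{i:02d}" for i in range(config.n_tfs)]
    interior = _interior_exons(genome)
    eligible_genes = sorted(interior)
    if len(eligible_genes) < config.n_planted_cees:
        raise ValueError("not enough multi-exon genes for the requested planted cEEs")
    chosen = rng.choice(len(eligible_genes), size=config.n_planted_cees, replace=False)
    peaks: list[TfPeak] = []
    planted_ids = []
    exp_counter = 0
    half = config.peak_width // 2
    for gi in sorted(chosen):
        gene = eligible_genes[gi]
        candidates = interior[gene]
        exon = candidates[rng.integers(0, len(candidates))]
        planted_ids.append(exon.interval.name)
        mid = exon.interval.midpoint
        tf_idx = rng.choice(config.n_tfs, size=config.tfs_per_cluster, replace=False)
        for t in sorted(tf_idx):
            summit = int(mid + round(rng.normal(0.0, config.summit_jitter_sd)))
            size = genome.chrom_sizes[exon.interval.chrom]
            summit = int(np.clip(summit, half, size - half - 1))
            iv = GenomicInterval(
                exon.interval.chrom, summit - half, summit + half, ".",
            )
            peaks.append(
                TfPeak(iv, tf_names[t], summit, dataset_id=f"exp{exp_counter}",
                       score=float(rng.uniform(1, 1000)))
            )
            exp_counter += 1
    total_mb = config.n_chroms * config.chrom_length / 1e6
    n_background = int(rng.poisson(config.background_peaks_per_mb * total_mb))
    chrom_names = sorted(genome.sequences)
    for _ in range(n_background):
        chrom = chrom_names[rng.integers(0, len(chrom_names))]
        m = genome.build.mask[chrom]
        widths = m[:, 1] - m[:, 0]
        ridx = rng.choice(len(widths), p=widths / widths.sum())
        summit = int(rng.integers(m[ridx, 0], m[ridx, 1]))
        size = genome.chrom_sizes[chrom]
        summit = int(np.clip(summit, half, size - half - 1))
        iv = GenomicInterval(chrom, summit - half, summit + half, ".")
        peaks.append(
            TfPeak(iv, tf_names[rng.integers(0, config.n_tfs)], summit,
                   dataset_id=f"exp{exp_counter}", score=float(rng.uniform(1, 1000)))
        )
        exp_counter += 1
    return peaks, planted_ids


_AF_RANGES = {
    "ultra_rare": (1e-6, 1e-4),
    "rare": (1e-4, 1e-3),
    "low_frequency": (1e-3, 1e-2),
    "common": (1e-2, 0.5),
}
_AF_BIN_NAMES = ("ultra_rare", "rare", "low_frequency", "common")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def simulate_variants(
    config: SimConfig, genome: SimGenome, rng: np.random.Generator | None = None
) -> tuple[list[Variant], pd.DataFrame]:
    """Codon-aware SNVs over all coding sequence with planted consequences.

    Positions are drawn per coding base at ``snv_rate`` (start codon included,
    terminal stop codon excluded); alternate alleles are uniform over the
    three non-reference bases; the consequence is computed from the true codon
    (Biopython translation) so downstream classification can be validated
    against generator truth. Allele frequencies are drawn log-uniformly inside
    a mixture over the four AF bins.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    weights = np.asarray(config.af_weights)
    variants: list[Variant] = []
    rows = []
    by_gene: dict[str, list[ExonRecord]] = {}
    for ex in genome.exons:
        by_gene.setdefault(ex.gene_id, []).append(ex)
    for gene_id in sorted(by_gene):
        cds = genome.gene_cds[gene_id]
        strand = genome.genes[gene_id].strand
        exs = sorted(by_gene[gene_id], key=lambda e: e.interval.start)
        coding_order = exs if strand == "+" else exs[::-1]
        offset = 0
        coding_pos_to_genome: dict[int, tuple[str, int]] = {}
        for ex in coding_order:
            for j in range(ex.interval.length):
                if strand == "+":
                    gpos = ex.interval.start + j
                else:
                    gpos = ex.interval.end - 1 - j
                coding_pos_to_genome[offset + j] = (ex.interval.chrom, gpos)
            offset += ex.interval.length
        usable = len(cds) - 3  # exclude the terminal stop codon
        hits = np.flatnonzero(rng.random(usable) < config.snv_rate)
        for cpos in hits:
            ref_c = cds[cpos]
            alt_c = "ACGT".replace(ref_c, "")[rng.integers(0, 3)]
            codon_index, pos_in_codon = divmod(int(cpos), 3)
            codon = cds[3 * codon_index : 3 * codon_index + 3]
            alt_codon = (
                codon[:pos_in_codon] + alt_c + codon[pos_in_codon + 1 :]
            )
            aa_ref = str(Seq(codon).translate())
            aa_alt = str(Seq(alt_codon).translate())
            if aa_alt == aa_ref:
                consequence = "synonymous"
            elif aa_alt == "*":
                consequence = "nonsense"
            else:
                consequence = "missense"
            bin_name = _AF_BIN_NAMES[rng.choice(4, p=weights)]
            lo, hi = _AF_RANGES[bin_name]
            af = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            passed = bool(rng.random() >= config.fail_filter_fraction)
            chrom, gpos = coding_pos_to_genome[int(cpos)]
            if strand == "+":
                g_ref, g_alt = ref_c, alt_c
            else:
                g_ref, g_alt = _COMPLEMENT[ref_c], _COMPLEMENT[alt_c]
            variants.append(
                Variant(chrom, gpos, g_ref, g_alt, af=af, passed=passed,
                        info={"VC": consequence})
            )
            rows.append(
                {
                    "chrom": chrom, "pos": gpos, "ref": g_ref, "alt": g_alt,
                    "gene_id": gene_id, "codon_index": codon_index,
                    "position_in_codon": pos_in_codon,
                    "cds_ref": ref_c, "cds_alt": alt_c,
                    "consequence": consequence, "af": af, "passed": passed,
                }
            )
    truth = pd.DataFrame(rows)
    return variants, truth


def simulate_starr_counts(
    config: SimConfig, rng: np.random.Generator | None = None
):
    """STARR-seq count tables with planted activities and variant shifts.

    Input representation per insert is log-normal around ``input_depth`` with
    small technical noise between input samples (a configurable minority of
    inserts is made unstable so the input-SD filter has work to do); cDNA
    counts are negative-binomial around input abundance scaled by
    2^(activity + replicate noise). Planted activities are centred so the
    abundance-weighted mean linear activity is 1 — the component of activity
    identifiable from a ratio-based assay — and the centred values are the
    recorded truth. Returns (CountTable, truth DataFrame).
    """
    from .starr import CountTable

    rng = rng if rng is not None else np.random.default_rng(config.seed + 3)
    ids, cats, raw = [], [], []

    def add(prefix, n, values, weights=None):
        for i in range(n):
            ids.append(f"{prefix}_{i:03d}")
            cats.append(prefix if prefix in (
                "cEE", "ctrl_neg", "ctrl_pos", "starr_plus", "starr_minus"
            ) else "variant")
            if weights is None:
                base = values
            else:
                base = values[rng.choice(len(values), p=weights)]
            raw.append(base + rng.normal(0.0, config.activity_jitter_sd))

    add("cEE", config.n_cee_inserts,
        np.asarray(config.cee_activity_values), np.asarray(config.cee_activity_weights))
    add("ctrl_neg", config.n_ctrl_neg, 0.0)
    add("ctrl_pos", config.n_ctrl_pos,
        np.asarray(config.ctrl_pos_activity_values),
        np.asarray(config.ctrl_pos_activity_weights))
    add("starr_plus", config.n_starr_plus, config.starr_plus_activity)
    add("starr_minus", config.n_starr_minus, config.starr_minus_activity)
    raw = list(raw)
    cee_ids = [i for i, c in zip(ids, cats) if c == "cEE"]
    ref_idx = rng.choice(len(cee_ids), size=config.n_variant_inserts, replace=False)
    pairs_rows = []
    shifts = {}
    for i, ri in enumerate(sorted(ref_idx)):
        vid = f"var_{i:03d}"
        ref_id = cee_ids[ri]
        shift = float(rng.normal(config.variant_shift_mean, config.variant_shift_sd))
        ids.append(vid)
        cats.append("variant")
        raw.append(raw[ids.index(ref_id)] + shift)
        shifts[vid] = shift
        pairs_rows.append({"variant": vid, "reference": ref_id})
    raw = np.asarray(raw, dtype=float)
    n = len(ids)
    latent = config.input_depth * np.exp(
        rng.normal(0.0, config.insert_depth_cv, size=n)
    )
    # centre activities on the abundance-weighted mean (ratio-identifiable scale)
    offset = np.log2(np.average(np.exp2(raw), weights=latent))
    activity = raw - offset
    unstable = rng.random(n) < config.input_unstable_fraction
    cv = np.where(unstable, config.input_unstable_cv, config.input_replicate_cv)
    counts = {}
    for k in range(config.n_input_samples):
        noise = np.exp(rng.normal(0.0, cv))
        counts[f"input_{k + 1}"] = np.maximum(
            np.round(latent * noise).astype(np.int64), 0
        )
    r = config.nb_dispersion
    for j in range(config.n_cdna_replicates):
        eps = rng.normal(0.0, config.replicate_noise_sd, size=n)
        mu = latent * np.exp2(activity + eps)
        counts[f"cdna_{j + 1}"] = rng.negative_binomial(r, r / (r + mu))
    counts_df = pd.DataFrame(counts, index=pd.Index(ids, name="insert"))
    design = pd.DataFrame(
        {
            "role": ["input"] * config.n_input_samples
            + ["cdna_replicate"] * config.n_cdna_replicates
        },
        index=pd.Index(list(counts), name="sample"),
    )
    pairs = pd.DataFrame(pairs_rows, columns=["variant", "reference"])
    table = CountTable(
        counts=counts_df, design=design,
        categories=pd.Series(cats, index=counts_df.index, name="category"),
        pairs=pairs,
    )
    truth = pd.DataFrame(
        {
            "category": cats,
            "activity": activity,
            "latent_input": latent,
            "unstable_input": unstable,
            "shift": [shifts.get(i, np.nan) for i in ids],
        },
        index=counts_df.index,
    )
    truth.attrs["activity_offset"] = float(offset)
    return table, truth


def _codon_variants(codon: str) -> list[tuple[int, str, str]]:
    """(position, alt_base, alt_codon) for the 9 single-base changes."""
    out = []
    for pos in range(3):
        for b in "ACGT":
            if b != codon[pos]:
                out.append((pos, b, codon[:pos] + b + codon[pos + 1 :]))
    return out


def simulate_ortholog_pairs(
    config: SimConfig, rng: np.random.Generator | None = None
) -> list[dict]:
    """Orthologous CDS pairs with planted synonymous/nonsynonymous differences.

    The second sequence applies single-base changes at distinct codons of the
    first to hit target per-site divergence proportions (stops avoided), so
    pathway counting on the pair is exact and the realised (Nd, Sd) are
    recorded as truth alongside the targets.
    """
    from .popgen import GENETIC_CODE, count_potential_sites

    rng = rng if rng is not None else np.random.default_rng(config.seed + 4)
    out = []
    for pair_idx in range(config.n_ortholog_pairs):
        codons = [
            _NONSTOP_CODONS[i]
            for i in rng.choice(len(_NONSTOP_CODONS), size=config.ortholog_codons)
        ]
        seq_a = "".join(codons)
        sites = count_potential_sites(seq_a)
        nd_target = int(round(config.target_dn * sites.n_sites))
        sd_target = int(round(config.target_ds * sites.s_sites))
        order = rng.permutation(len(codons))
        seq_b_codons = list(codons)
        nd = sd = 0
        for ci in order:
            codon = codons[ci]
            aa = GENETIC_CODE[codon]
            if nd < nd_target:
                options = [
                    v for v in _codon_variants(codon)
                    if GENETIC_CODE[v[2]] not in ("*", aa)
                ]
                if options:
                    _, _, alt = options[rng.integers(0, len(options))]
                    seq_b_codons[ci] = alt
                    nd += 1
                    continue
            if sd < sd_target:
                options = [
                    v for v in _codon_variants(codon)
                    if GENETIC_CODE[v[2]] == aa and GENETIC_CODE[v[2]] != "*"
                ]
                if options:
                    _, _, alt = options[rng.integers(0, len(options))]
                    seq_b_codons[ci] = alt
                    sd += 1
                    continue
            if nd >= nd_target and sd >= sd_target:
                break
        out.append(
            {
                "pair_id": f"pair_{pair_idx:03d}",
                "seq_a": seq_a,
                "seq_b": "".join(seq_b_codons),
                "nd_true": nd,
                "sd_true": sd,
                "target_dn": config.target_dn,
                "target_ds": config.target_ds,
            }
        )
    return out


def simulate_interactions(
    config: SimConfig,
    genome: SimGenome,
    planted_ids: Sequence[str],
    rng: np.random.Generator | None = None,
):
    """Planted enhancer-target evidence across the three channels.

    Elements are planted cEE exons; each targets its host gene (internal) or a
    different gene (external) with support from 1-3 distinct sources, plus
    decoy rE2G rows below the coverage threshold. Returns
    (elements, re2g, pchic, eqtl, truth DataFrame).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 5)
    exon_by_id = {ex.interval.name: ex for ex in genome.exons}
    chosen = list(planted_ids)[: config.n_interaction_elements]
    elements = {eid: exon_by_id[eid].interval for eid in chosen}
    gene_names = sorted(genome.genes)
    re2g_rows, pchic_rows, eqtl_rows, truth_rows = [], [], [], []
    for eid in chosen:
        ex = exon_by_id[eid]
        iv = ex.interval
        host = ex.gene_id
        if rng.random() < 0.5:
            target = host
        else:
            others = [g for g in gene_names if g != host]
            target = others[rng.integers(0, len(others))]
        robust = rng.random() < config.robust_interaction_fraction
        n_src = int(rng.integers(2, 4)) if robust else 1
        sources = sorted(
            np.array(["pchic", "re2g", "eqtl"])[
                rng.choice(3, size=n_src, replace=False)
            ]
        )
        for src in sources:
            if src == "re2g":
                re2g_rows.append(
                    {
                        "chrom": iv.chrom, "start": iv.start - 20,
                        "end": iv.end + 20, "gene_id": target,
                    }
                )
            elif src == "pchic":
                gene_iv = genome.genes[target]
                bait_anchor = (
                    gene_iv.start if gene_iv.strand == "+" else gene_iv.end - 1
                )
                pchic_rows.append(
                    {
                        "bait_chrom": gene_iv.chrom,
                        "bait_start": max(0, bait_anchor - 2000),
                        "bait_end": bait_anchor + 2000,
                        "bait_gene": target,
                        "oe_chrom": iv.chrom,
                        "oe_start": max(0, iv.start - 500),
                        "oe_end": iv.end + 500,
                        "oe_gene": None,
                    }
                )
            else:
                eqtl_rows.append(
                    {"chrom": iv.chrom, "pos": iv.midpoint, "gene_id": target}
                )
        gene_iv = genome.genes[target]
        relation = "internal" if gene_iv.contains(iv) and target == host else "external"
        truth_rows.append(
            {
                "element": eid, "gene": target, "n_sources": len(sources),
                "robust": len(sources) >= 2, "relation": relation,
            }
        )
        # decoy: sub-threshold rE2G coverage pointing at an unrelated gene
        decoy_gene = gene_names[rng.integers(0, len(gene_names))]
        third = max(1, iv.length // 3)
        re2g_rows.append(
            {
                "chrom": iv.chrom, "start": iv.end - third,
                "end": iv.end + 200, "gene_id": f"{decoy_gene}_decoy",
            }
        )
    re2g = pd.DataFrame(re2g_rows, columns=["chrom", "start", "end", "gene_id"])
    pchic = pd.DataFrame(
        pchic_rows,
        columns=["bait_chrom", "bait_start", "bait_end", "bait_gene",
                 "oe_chrom", "oe_start", "oe_end", "oe_gene"],
    )
    eqtl = pd.DataFrame(eqtl_rows, columns=["chrom", "pos", "gene_id"])
    truth = pd.DataFrame(truth_rows)
    return elements, re2g, pchic, eqtl, truth


@dataclass
class EnrichmentDataset:
    query: list[GenomicInterval]
    targets: list[GenomicInterval]
    build: GenomeBuild
    planted_fold: float
    expected_overlap: float
    planted_observed: int


def simulate_enrichment_dataset(
    rng: np.random.Generator | None = None,
    seed: int = 0,
    chrom_length: int = 300_000,
    n_query: int = 80,
    n_targets: int = 80,
    query_length: tuple[int, int] = (100, 400),
    target_length: int = 150,
    fold: float = 3.0,
    gc_block: int = 10_000,
    gc_range: tuple[float, float] = (0.35, 0.65),
    gc_window: int = 100,
) -> EnrichmentDataset:
    """Query/target interval sets with a planted overlap fold-enrichment.

    Target intervals are scattered uniformly; query intervals are first placed
    uniformly (fixing their length and GC bin), then re-placed within their
    own matched-candidate sets so that the realised overlap count equals
    ``fold`` times the exact null expectation computed from those candidate
    sets. The measured fold therefore estimates ``fold`` up to rounding and
    permutation noise.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    seq = _random_sequence(rng, chrom_length, gc_block, gc_range)
    build = GenomeBuild.from_sequences(
        {"S": seq.tobytes().decode()}, gc_window=gc_window
    )
    targets = []
    for i in range(n_targets):
        s = int(rng.integers(0, chrom_length - target_length))
        targets.append(GenomicInterval("S", s, s + target_length, name=f"t{i}"))
    target_idx = MergedIntervals(targets)
    shuffler = MatchedShuffler(build, ShuffleConfig(n_permutations=1))
    base = []
    for i in range(n_query):
        length = int(rng.integers(query_length[0], query_length[1] + 1))
        s = int(rng.integers(0, chrom_length - length))
        base.append(GenomicInterval("S", s, s + length, name=f"q{i}"))
    cand_sets, hit_probs = [], []
    for q in base:
        cand = shuffler.candidate_starts("S", q.length, shuffler.interval_bin(q))
        hits = target_idx.any_overlap("S", cand, cand + q.length)
        cand_sets.append((cand, hits))
        hit_probs.append(float(hits.mean()))
    expected = float(np.sum(hit_probs))
    planted_obs = int(round(fold * expected))
    if planted_obs > n_query:
        raise ValueError("planted fold exceeds the attainable overlap count")
    order = rng.permutation(n_query)
    can_hit = [i for i in order if cand_sets[i][1].any()]
    hit_set = set(can_hit[:planted_obs])
    if len(hit_set) < planted_obs:
        raise ValueError("not enough queries can overlap the targets")
    query = []
    for i, q in enumerate(base):
        cand, hits = cand_sets[i]
        pool = cand[hits] if i in hit_set else cand[~hits]
        if pool.size == 0:
            pool = cand  # fully constrained query: keep its matched placement
        s = int(pool[rng.integers(0, pool.size)])
        query.append(GenomicInterval("S", s, s + q.length, name=q.name))
    realised = int(sum(target_idx.overlaps_interval(q) for q in query))
    return EnrichmentDataset(
        query=query, targets=targets, build=build, planted_fold=fold,
        expected_overlap=expected, planted_observed=realised,
    )


# ---------------------------------------------------------------------------
# File emission (used by the CLI `simulate` command)
# ---------------------------------------------------------------------------

def write_genome_files(genome: SimGenome, outdir: str) -> None:
    import json
    import os

    from . import io as cio

    os.makedirs(outdir, exist_ok=True)
    cio.write_fasta(genome.sequences, os.path.join(outdir, "genome.fa"))
    cio.write_chrom_sizes(genome.chrom_sizes, os.path.join(outdir, "chrom.sizes"))
    cio.write_tss_bed(genome.tss, os.path.join(outdir, "tss.bed"))
    cio.write_tss_bed(genome.tes, os.path.join(outdir, "tes.bed"))
    cio.write_tss_bed(genome.cage, os.path.join(outdir, "cage.bed"))
    cio.write_gc_bedgraph(genome.build, os.path.join(outdir, "gc.bedgraph"))
    cio.write_mask_bed(genome.build.mask, os.path.join(outdir, "mask.bed"))
    with open(os.path.join(outdir, "genes.gff3"), "w") as fh:
        fh.write("##gff-version 3\n")
        for gid in sorted(genome.genes):
            gene = genome.genes[gid]
            fh.write(
                f"{gene.chrom}\tceekit\tgene\t{gene.start + 1}\t{gene.end}\t.\t"
                f"{gene.strand}\t.\tID={gid};gene_id={gid}\n"
            )
            tid = f"t{gid[1:]}"
            fh.write(
                f"{gene.chrom}\tceekit\tmRNA\t{gene.start + 1}\t{gene.end}\t.\t"
                f"{gene.strand}\t.\tID={tid};Parent={gid};gene_id={gid};"
                f"transcript_id={tid};transcript_support_level=1\n"
            )
        for ex in sorted(genome.exons, key=lambda e: (e.interval.chrom, e.interval.start)):
            iv = ex.interval
            fh.write(
                f"{iv.chrom}\tceekit\tCDS\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t0\t"
                f"ID={iv.name};Parent={ex.transcript_id};gene_id={ex.gene_id};"
                f"transcript_id={ex.transcript_id};transcript_support_level={ex.tsl}\n"
            )
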