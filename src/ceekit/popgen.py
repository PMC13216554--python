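"""Polymorphism/divergence constraint statistics for coding exon sets.

Implements counting-based selection statistics on codon sequences: potential
synonymous/nonsynonymous site enumeration, variant consequence classification,
the pN/pS polymorphism ratio, the Nei-Gojobori pairwise divergence estimator
(shortest-pathway averaging with Jukes-Cantor correction), the
Direction-of-Selection statistic, the Fixation Index, allele-frequency
binning, and TF-load decile stratification with Cramer's V effect sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from scipy import stats

_BASES = "ACGT"
_STANDARD = CodonTable.unambiguous_dna_by_id[1]
#: codon -> amino acid, with '*' for stop codons.
GENETIC_CODE: dict[str, str] = dict(_STANDARD.forward_table)
for _stop in _STANDARD.stop_codons:
    GENETIC_CODE[_stop] = "*"

AF_BINS = ("ultra_rare", "rare", "low_frequency", "common")
#: Inclusive upper edges of the AF bins (fractions): <=0.01%, <=0.1%, <=1%, >1%.
AF_BIN_EDGES = (1e-4, 1e-3, 1e-2)


class CodonError(ValueError):
    pass


@dataclass(frozen=True)
class SiteCounts:
    """Potential synonymous (S) and nonsynonymous (N) sites; S + N = 3/codon."""

    s_sites: float
    n_sites: float

    @property
    def total(self) -> float:
        return self.s_sites + self.n_sites


@dataclass
class PolymorphismCounts:
    pn_count: int = 0  # missense SNVs
    ps_count: int = 0  # synonymous SNVs
    nonsense_count: int = 0  # reported separately, excluded from pN
    length_bp: int = 0
    af_spectrum: dict[str, int] | None = None

    @property
    def missense_density(self) -> float | None:
        return self.pn_count / self.length_bp if self.length_bp else None

    @property
    def synonymous_density(self) -> float | None:
        return self.ps_count / self.length_bp if self.length_bp else None


@dataclass
class DivergenceCounts:
    nd: float
    sd: float
    n_sites: float
    s_sites: float
    pn: float
    ps: float
    dn: float
    ds: float
    dnds: float | None
    n_codons: int
    n_codons_skipped: int = 0


@dataclass
class ConstraintSummary:
    pnps: float | None
    dnds: float | None
    dos: float | None
    fi: float | None
    ultra_rare_fraction: float | None


def _check_codon(codon: str) -> str:
    c = codon.upper()
    if len(c) != 3 or set(c) - set(_BASES):
        raise CodonError(f"invalid codon {codon!r}")
    return c


def codon_site_counts(codon: str) -> SiteCounts:
    """Potential sites of one codon.

    Each position contributes (#synonymous single-base changes)/3 to S and the
    complement to N; changes creating a stop codon count as nonsynonymous.
    """
    c = _check_codon(codon)
    aa = GENETIC_CODE[c]
    if aa == "*":
        raise CodonError(f"stop codon {c} has no defined site counts")
    s = 0.0
    for pos in range(3):
        syn = 0
        for b in _BASES:
            if b == c[pos]:
                continue
            alt = c[:pos] + b + c[pos + 1 :]
            if GENETIC_CODE[alt] == aa:
                syn += 1
        s += syn / 3.0
    return SiteCounts(s_sites=s, n_sites=3.0 - s)


def count_potential_sites(cds: str) -> SiteCounts:
    """Potential S and N sites of an in-frame coding sequence.

    The sequence length must be a multiple of 3 with no internal stop codons;
    a terminal stop codon is permitted and contributes no sites.
    """
    seq = cds.upper()
    if len(seq) % 3 != 0:
        raise CodonError(f"CDS length {len(seq)} not a multiple of 3")
    if set(seq) - set(_BASES):
        raise CodonError("ambiguous or illegal bases in CDS")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    s = n = 0.0
    for i, codon in enumerate(codons):
        if GENETIC_CODE[codon] == "*":
            if i == len(codons) - 1:
                continue
            raise CodonError(f"internal stop codon {codon} at codon {i}")
        counts = codon_site_counts(codon)
        s += counts.s_sites
        n += counts.n_sites
    return SiteCounts(s_sites=s, n_sites=n)


def classify_variant(
    cds: str, codon_index: int, position_in_codon: int, ref: str, alt: str
) -> str:
    """Consequence of a single-nucleotide change: synonymous/missense/nonsense."""
    seq = cds.upper()
    codon = _check_codon(seq[3 * codon_index : 3 * codon_index + 3])
    if codon[position_in_codon] != ref.upper():
        raise ValueError(
            f"reference mismatch at codon {codon_index} pos {position_in_codon}: "
            f"cds has {codon[position_in_codon]}, got {ref}"
        )
    if GENETIC_CODE[codon] == "*":
        raise CodonError("reference codon is a stop codon")
    alt_codon = codon[:position_in_codon] + alt.upper() + codon[position_in_codon + 1 :]
    alt_aa = GENETIC_CODE[_check_codon(alt_codon)]
    if alt_aa == GENETIC_CODE[codon]:
        return "synonymous"
    if alt_aa == "*":
        return "nonsense"
    return "missense"


def af_bin(af: float) -> str:
    """Allele-frequency bin with inclusive upper edges.

    ultra_rare: AF <= 0.01%; rare: (0.01%, 0.1%]; low_frequency: (0.1%, 1%];
    common: > 1%.
    """
    if not (0.0 < af <= 1.0):
        raise ValueError(f"allele frequency {af} outside (0, 1]")
    for name, edge in zip(AF_BINS, AF_BIN_EDGES):
        if af <= edge:
            return name
    return "common"


def pn_ps(
    pn_count: float, n_sites: float, ps_count: float, s_sites: float
) -> float | None:
    """Site-normalised missense-to-synonymous polymorphism ratio.

    (pN/N) / (pS/S); ``None`` when undefined (zero synonymous count or zero
    site totals), to be excluded from pooled statistics.
    """
    if ps_count <= 0 or s_sites <= 0 or n_sites <= 0:
        return None
    return (pn_count / n_sites) / (ps_count / s_sites)


@lru_cache(maxsize=4096)
def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """(nonsynonymous, synonymous) differences between two codons.

    Averages over all shortest mutational pathways; pathways passing through a
    stop codon are excluded. If every pathway is blocked by stops, all
    pathways are used with stop-involving steps counted as nonsynonymous.
    """
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    if not diffs:
        return 0.0, 0.0

    def walk(order, count_blocked):
        nd = sd = 0.0
        cur = c1
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            aa_cur, aa_nxt = GENETIC_CODE[cur], GENETIC_CODE[nxt]
            if aa_nxt == "*" and nxt != c2 and not count_blocked:
                return None
            if aa_cur == aa_nxt and aa_cur != "*":
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        return nd, sd

    results = [r for r in (walk(o, False) for o in permutations(diffs)) if r]
    if not results:
        results = [walk(o, True) for o in permutations(diffs)]
    nd = float(np.mean([r[0] for r in results]))
    sd = float(np.mean([r[1] for r in results]))
    return nd, sd


def jukes_cantor(p: float) -> float:
    """Jukes-Cantor multiple-hit correction d = -(3/4) ln(1 - 4p/3)."""
    if p >= 0.75:
        raise ValueError(f"proportion {p} >= 3/4: Jukes-Cantor correction undefined")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def neigojobori_dnds(cds_a: str, cds_b: str) -> DivergenceCounts:
    """Nei-Gojobori pairwise dN/dS between two aligned in-frame sequences.

    Nd/Sd are counted per codon averaging over shortest mutational pathways;
    potential sites are averaged between the two sequences; proportions are
    Jukes-Cantor corrected. Gapped codons and terminal stop codons are skipped
    (counted in ``n_codons_skipped``); a dS of zero leaves the ratio undefined
    (``None``).
    """
    a, b = cds_a.upper(), cds_b.upper()
    if len(a) != len(b):
        raise ValueError("sequences must be aligned to equal lengths")
    if len(a) % 3 != 0:
        raise ValueError("alignment length must be a multiple of 3")
    nd = sd = s_a = n_a = s_b = n_b = 0.0
    used = skipped = 0
    n_codons = len(a) // 3
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        if "-" in ca or "-" in cb or set(ca + cb) - set(_BASES):
            skipped += 1
            continue
        if GENETIC_CODE[ca] == "*" or GENETIC_CODE[cb] == "*":
            skipped += 1
            continue
        d_nd, d_sd = _pathway_counts(ca, cb)
        nd += d_nd
        sd += d_sd
        sc_a, sc_b = codon_site_counts(ca), codon_site_counts(cb)
        s_a += sc_a.s_sites
        n_a += sc_a.n_sites
        s_b += sc_b.s_sites
        n_b += sc_b.n_sites
        used += 1
    if used == 0:
        raise ValueError("no comparable codons in the alignment")
    s_sites = (s_a + s_b) / 2.0
    n_sites = (n_a + n_b) / 2.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ps = sd / s_sites if s_sites > 0 else 0.0
    try:
        dn = jukes_cantor(pn)
        ds = jukes_cantor(ps)
    except ValueError as exc:
        raise ValueError(f"{exc} (Nd={nd}, Sd={sd}, codons={used})") from exc
    dnds = dn / ds if ds > 0 else None
    return DivergenceCounts(
        nd=nd, sd=sd, n_sites=n_sites, s_sites=s_sites, pn=pn, ps=ps,
        dn=dn, ds=ds, dnds=dnds, n_codons=n_codons, n_codons_skipped=skipped,
    )


def dos(nd: float, sd: float, pn_count: float, ps_count: float) -> float | None:
    """Direction of Selection: Nd/(Nd+Sd) - pN/(pN+pS) on raw counts.

    Positive values indicate relatively nonsynonymous-enriched divergence
    (adaptive fixation); ``None`` when either denominator is zero.
    """
    if nd + sd <= 0 or pn_count + ps_count <= 0:
        return None
    return nd / (nd + sd) - pn_count / (pn_count + ps_count)


def fixation_index(dnds: float | None, pnps: float | None) -> float | None:
    """Fixation Index: (dN/dS) / (pN/pS); ``None`` when undefined."""
    if dnds is None or pnps is None or pnps <= 0:
        return None
    return dnds / pnps


def pooled_dnds(pairs: Sequence[tuple[str, str]]) -> DivergenceCounts:
    """Pooled dN/dS: sum Nd/Sd and site counts over pairs, then correct.

    The per-exon route (average the per-pair ratios) is available by mapping
    :func:`neigojobori_dnds` over the pairs; both are reported by the CLI.
    """
    nd = sd = n_sites = s_sites = 0.0
    total = skipped = 0
    for a, b in pairs:
        d = neigojobori_dnds(a, b)
        nd += d.nd
        sd += d.sd
        n_sites += d.n_sites
        s_sites += d.s_sites
        total += d.n_codons
        skipped += d.n_codons_skipped
    pn = nd / n_sites if n_sites > 0 else 0.0
    ps = sd / s_sites if s_sites > 0 else 0.0
    dn, ds = jukes_cantor(pn), jukes_cantor(ps)
    return DivergenceCounts(
        nd=nd, sd=sd, n_sites=n_sites, s_sites=s_sites, pn=pn, ps=ps,
        dn=dn, ds=ds, dnds=dn / ds if ds > 0 else None,
        n_codons=total, n_codons_skipped=skipped,
    )


def constraint_summary(
    poly: PolymorphismCounts,
    sites: SiteCounts,
    div: DivergenceCounts | None = None,
) -> ConstraintSummary:
    pnps = pn_ps(poly.pn_count, sites.n_sites, poly.ps_count, sites.s_sites)
    dnds_val = div.dnds if div is not None else None
    dos_val = (
        dos(div.nd, div.sd, poly.pn_count, poly.ps_count) if div is not None else None
    )
    fi = fixation_index(dnds_val, pnps)
    ultra = None
    if poly.af_spectrum:
        total = sum(poly.af_spectrum.values())
        if total:
            ultra = poly.af_spectrum.get("ultra_rare", 0) / total
    return ConstraintSummary(
        pnps=pnps, dnds=dnds_val, dos=dos_val, fi=fi, ultra_rare_fraction=ultra
    )


def decile_stratify(
    elements: pd.DataFrame,
    key: str,
    n_groups: int = 10,
    tiebreak: Sequence[str] = ("chrom", "start"),
) -> pd.DataFrame:
    """Rank elements by ``key`` and split into ``n_groups`` equal-size groups.

    Ranking is stable with a deterministic coordinate tie-break; returns a copy
    with a 0-based ``decile`` column (0 = lowest key values). Group sizes
    differ by at most one when n is not a multiple of ``n_groups``.
    """
    if len(elements) < n_groups:
        raise ValueError(f"need at least {n_groups} elements")
    sort_cols = [key] + [c for c in tiebreak if c in elements.columns]
    out = elements.sort_values(sort_cols, kind="mergesort").copy()
    splits = np.array_split(np.arange(len(out)), n_groups)
    decile = np.empty(len(out), dtype=int)
    for g, idx in enumerate(splits):
        decile[idx] = g
    out["decile"] = decile
    return out


def cramers_v(table: np.ndarray | pd.DataFrame) -> float:
    """Cramer's V effect size: sqrt(chi2 / (n * (min(r, c) - 1)))."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or min(t.shape) < 2:
        raise ValueError("need a contingency table with at least 2 rows and columns")
    n = t.sum()
    if n <= 0:
        raise ValueError("empty contingency table")
    chi2 = stats.chi2_contingency(t, correction=False)[0]
    return math.sqrt(chi2 / (n * (min(t.shape) - 1)))


def af_spectrum_by_decile(
    variants: pd.DataFrame,
    decile_col: str = "decile",
    bin_col: str = "af_bin",
) -> tuple[pd.DataFrame, float]:
    """Contingency table of AF bins across deciles, with Cramer's V."""
    table = (
        variants.groupby([decile_col, bin_col]).size().unstack(fill_value=0)
        .reindex(columns=list(AF_BINS), fill_value=0)
    )
    return table, cramers_v(table.to_numpy())
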