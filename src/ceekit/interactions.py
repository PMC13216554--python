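"""Enhancer-target assignment from three evidence channels.

Evidence comes from promoter-capture Hi-C fragment pairs, predicted
enhancer-to-gene links (rE2G-style intervals requiring >=50% element
coverage), and eQTL positions inside the element. A pair (element, gene) is
"robust" when at least two of the three resources support it; each pair is
classified internal (the element lies within the target gene's own body) or
external, and elements targeting genes of both kinds are summarised as mixed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .core import GenomicInterval, normalize_chrom

SOURCES = ("pchic", "re2g", "eqtl")


@dataclass(frozen=True)
class InteractionEvidence:
    source: str
    element_id: str
    gene_id: str
    configuration: str = ""
    score: float | None = None

    def __post_init__(self) -> None:
        if self.source not in SOURCES:
            raise ValueError(f"unknown evidence source {self.source!r}")
        if not self.gene_id:
            raise ValueError("gene id must be non-empty")


def _overlap_bp(a: GenomicInterval, chrom: str, start: int, end: int) -> int:
    if normalize_chrom(a.chrom) != normalize_chrom(chrom):
        return 0
    return max(0, min(a.end, end) - max(a.start, start))


def overlap_evidence(
    elements: Mapping[str, GenomicInterval],
    re2g: pd.DataFrame | None = None,
    pchic: pd.DataFrame | None = None,
    eqtl: pd.DataFrame | None = None,
    min_fraction_re2g: float = 0.5,
) -> list[InteractionEvidence]:
    """Collect per-source (element, gene) evidence from overlap rules.

    re2g columns: chrom, start, end, gene_id — a hit requires the prediction
    interval to cover at least ``min_fraction_re2g`` of the element
    (inclusive). pchic columns: bait_chrom/bait_start/bait_end/bait_gene plus
    oe_chrom/oe_start/oe_end and optional oe_gene — the element in the
    other-end fragment targets the bait gene (element-in-target-fragment);
    an element inside the bait fragment of a bait-bait interaction targets
    the other bait's gene (element-in-baited-fragment). eqtl columns: chrom,
    pos (0-based), gene_id — a hit requires the position inside the element.
    """
    out: list[InteractionEvidence] = []
    for eid, iv in elements.items():
        if re2g is not None:
            for row in re2g.itertuples(index=False):
                bp = _overlap_bp(iv, row.chrom, int(row.start), int(row.end))
                if bp / iv.length >= min_fraction_re2g:
                    out.append(InteractionEvidence("re2g", eid, str(row.gene_id)))
        if pchic is not None:
            for row in pchic.itertuples(index=False):
                if _overlap_bp(iv, row.oe_chrom, int(row.oe_start), int(row.oe_end)) > 0:
                    out.append(
                        InteractionEvidence(
                            "pchic", eid, str(row.bait_gene),
                            configuration="element_in_target_fragment",
                        )
                    )
                oe_gene = getattr(row, "oe_gene", None)
                if oe_gene and not pd.isna(oe_gene):
                    if _overlap_bp(
                        iv, row.bait_chrom, int(row.bait_start), int(row.bait_end)
                    ) > 0:
                        out.append(
                            InteractionEvidence(
                                "pchic", eid, str(oe_gene),
                                configuration="element_in_baited_fragment",
                            )
                        )
        if eqtl is not None:
            for row in eqtl.itertuples(index=False):
                if (
                    normalize_chrom(str(row.chrom)) == normalize_chrom(iv.chrom)
                    and iv.start <= int(row.pos) < iv.end
                ):
                    out.append(InteractionEvidence("eqtl", eid, str(row.gene_id)))
    return out


def classify_relation(
    element: GenomicInterval,
    target_gene: str,
    gene_bodies: Mapping[str, GenomicInterval],
) -> str:
    """``internal`` iff the element lies within the target gene's own body."""
    body = gene_bodies.get(target_gene)
    if body is not None and body.contains(element):
        return "internal"
    return "external"


def robust_pairs(
    evidence: Sequence[InteractionEvidence],
    elements: Mapping[str, GenomicInterval],
    gene_bodies: Mapping[str, GenomicInterval],
    min_sources: int = 2,
) -> pd.DataFrame:
    """Target assignments with source counts, robustness and relation labels.

    Duplicate evidence rows (same element, gene and source — e.g. both PCHi-C
    configurations) collapse before counting, so ``n_sources`` counts distinct
    resources. ``robust`` is ``n_sources >= min_sources``. The per-element
    summary is ``internal``/``external``/``mixed`` over that element's
    assignments.
    """
    seen: dict[tuple[str, str], set[str]] = {}
    for ev in evidence:
        seen.setdefault((ev.element_id, ev.gene_id), set()).add(ev.source)
    rows = []
    for (eid, gene), sources in sorted(seen.items()):
        relation = classify_relation(elements[eid], gene, gene_bodies)
        rows.append(
            {
                "element": eid,
                "gene": gene,
                "relation": relation,
                "n_sources": len(sources),
                "sources": ",".join(sorted(sources)),
                "robust": len(sources) >= min_sources,
            }
        )
    df = pd.DataFrame(
        rows, columns=["element", "gene", "relation", "n_sources", "sources", "robust"]
    )
    if df.empty:
        df["element_summary"] = pd.Series(dtype=str)
        return df
    summary = {}
    for eid, grp in df.groupby("element"):
        kinds = set(grp["relation"])
        summary[eid] = "mixed" if len(kinds) > 1 else next(iter(kinds))
    df["element_summary"] = df["element"].map(summary)
    return df
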