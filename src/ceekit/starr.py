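"""STARR-seq count processing, activity classes and variant-effect testing.

Counts-per-million normalisation, input-depth/variability filtering, per-insert
log2 activity (cDNA over input), three-way activity classification anchored at
the median of positive technical controls, reference-vs-variant Wald tests with
Benjamini-Hochberg correction, and a regression-to-the-mean null simulation for
the relationship between baseline activity and variant effect.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

CATEGORIES = ("cEE", "ctrl_neg", "ctrl_pos", "starr_plus", "starr_minus", "variant")
ACTIVITY_CLASSES = ("inactive", "moderate", "strong")


@dataclass
class CountTable:
    """Raw STARR-seq read counts with the sample design and variant links.

    ``counts``: inserts x samples integer matrix. ``design``: per-sample role,
    ``input`` or ``cdna_replicate``. ``categories``: per-insert category.
    ``pairs``: two columns, ``variant`` and ``reference`` insert ids.
    """

    counts: pd.DataFrame
    design: pd.DataFrame
    categories: pd.Series
    pairs: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        roles = set(self.design["role"])
        if not {"input", "cdna_replicate"} <= roles:
            raise ValueError("design needs >=1 input and >=1 cdna_replicate sample")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative read counts")
        missing = set(self.counts.columns) - set(self.design.index)
        if missing:
            raise ValueError(f"samples missing from design: {sorted(missing)}")
        bad = set(self.categories.dropna()) - set(CATEGORIES)
        if bad:
            raise ValueError(f"unknown insert categories: {sorted(bad)}")

    @property
    def input_samples(self) -> list[str]:
        return [s for s in self.counts.columns if self.design.loc[s, "role"] == "input"]

    @property
    def cdna_samples(self) -> list[str]:
        return [
            s for s in self.counts.columns
            if self.design.loc[s, "role"] == "cdna_replicate"
        ]


def cpm_normalise(counts: pd.DataFrame) -> pd.DataFrame:
    """Scale every column to sum to one million (counts per million)."""
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"all-zero count columns: {bad}")
    return counts * (1e6 / totals)


def filter_inserts(
    table: CountTable,
    min_input: float = 500.0,
    max_input_sd: float = 20.0,
) -> tuple[list[str], pd.DataFrame]:
    """Input-depth and input-variability filter.

    An insert is discarded when its mean raw input count is below
    ``min_input`` (strict) or when the standard deviation of its input CPM
    across input samples is at or above ``max_input_sd`` (single input sample:
    SD is 0). Returns (kept insert ids, discarded table with reasons).
    """
    inputs_raw = table.counts[table.input_samples]
    inputs_cpm = cpm_normalise(table.counts)[table.input_samples]
    mean_raw = inputs_raw.mean(axis=1)
    if len(table.input_samples) > 1:
        sd_cpm = inputs_cpm.std(axis=1, ddof=1)
    else:
        sd_cpm = pd.Series(0.0, index=inputs_cpm.index)
    reasons = []
    for insert in table.counts.index:
        why = []
        if mean_raw[insert] < min_input:
            why.append("low_input")
        if sd_cpm[insert] >= max_input_sd:
            why.append("high_input_sd")
        if why:
            reasons.append((insert, ";".join(why), mean_raw[insert], sd_cpm[insert]))
    discarded = pd.DataFrame(
        reasons, columns=["insert", "reason", "mean_input", "input_cpm_sd"]
    ).set_index("insert")
    kept = [i for i in table.counts.index if i not in discarded.index]
    return kept, discarded


def log2_activity(
    cdna_cpm: np.ndarray | float,
    input_cpm: np.ndarray | float,
    pseudocount: float = 0.5,
) -> np.ndarray | float:
    """log2((cDNA CPM + pc) / (input CPM + pc))."""
    c = np.asarray(cdna_cpm, dtype=float)
    i = np.asarray(input_cpm, dtype=float)
    if np.any(i + pseudocount <= 0):
        raise ValueError("input CPM plus pseudocount must be positive")
    out = np.log2((c + pseudocount) / (i + pseudocount))
    return float(out) if out.ndim == 0 else out


def activity_records(
    table: CountTable,
    kept: Sequence[str] | None = None,
    pseudocount: float = 0.5,
    input_mode: str = "shared",
) -> pd.DataFrame:
    """Per-insert activity table: per-replicate log2fc, mean, SD and QC flags.

    ``input_mode='shared'`` compares every cDNA replicate with the mean input
    CPM; ``'matched'`` pairs cDNA replicate j with input sample j (requires
    equal sample counts).
    """
    if input_mode not in ("shared", "matched"):
        raise ValueError("input_mode must be 'shared' or 'matched'")
    cpm = cpm_normalise(table.counts)
    ids = list(kept) if kept is not None else list(table.counts.index)
    cdna = cpm.loc[ids, table.cdna_samples].to_numpy()
    inputs = cpm.loc[ids, table.input_samples].to_numpy()
    if input_mode == "matched":
        if inputs.shape[1] != cdna.shape[1]:
            raise ValueError("matched mode requires equal input/cdna sample counts")
        ref = inputs
    else:
        ref = inputs.mean(axis=1, keepdims=True)
    reps = log2_activity(cdna, ref, pseudocount)
    raw_zero = (table.counts.loc[ids, table.cdna_samples].to_numpy() == 0).any(axis=1)
    n_reps = reps.shape[1]
    df = pd.DataFrame(
        {
            "category": table.categories.reindex(ids).to_numpy(),
            "cpm_input": inputs.mean(axis=1),
            "cpm_cdna_mean": cdna.mean(axis=1),
            "log2fc": reps.mean(axis=1),
            "replicate_sd": reps.std(axis=1, ddof=1) if n_reps > 1 else 0.0,
            "n_replicates": n_reps,
            "qc_zero_cdna": raw_zero,
        },
        index=pd.Index(ids, name="insert"),
    )
    df.attrs["replicate_log2fc"] = pd.DataFrame(
        reps, index=df.index, columns=table.cdna_samples
    )
    return df


def classify_activity(log2fc: float, median_ctrl_pos: float) -> str:
    """Activity class from the positive-control anchor.

    inactive: log2fc <= 0; strong: log2fc >= median of the positive technical
    controls (inclusive); moderate: strictly in between.
    """
    if log2fc <= 0.0:
        return "inactive"
    if log2fc >= median_ctrl_pos:
        return "strong"
    return "moderate"


def classify_records(
    records: pd.DataFrame, anchor_category: str = "starr_plus"
) -> pd.DataFrame:
    """Add an ``activity_class`` column anchored at the median log2fc of the
    kept positive technical controls."""
    anchors = records.loc[records["category"] == anchor_category, "log2fc"]
    if anchors.empty:
        raise ValueError(f"no kept inserts in anchor category {anchor_category!r}")
    median = float(anchors.median())
    out = records.copy()
    out["activity_class"] = [
        classify_activity(v, median) for v in out["log2fc"].to_numpy()
    ]
    out.attrs["ctrl_median"] = median
    return out


def variant_effect_test(
    ref_replicates: np.ndarray, var_replicates: np.ndarray
) -> dict[str, float]:
    """Two-sided Wald test of a variant insert against its reference insert.

    The statistic is the difference of mean per-replicate log2fc over the
    pooled standard error, referred to a standard normal. A zero pooled
    variance with a nonzero difference yields the smallest representable
    p-value and a flag.
    """
    r = np.asarray(ref_replicates, dtype=float)
    v = np.asarray(var_replicates, dtype=float)
    if r.size < 2 or v.size < 2:
        raise ValueError("need >=2 replicates per arm")
    delta = v.mean() - r.mean()
    se = np.sqrt(r.var(ddof=1) / r.size + v.var(ddof=1) / v.size)
    degenerate = False
    if se == 0.0:
        if delta == 0.0:
            wald, p = 0.0, 1.0
        else:
            wald = np.inf if delta > 0 else -np.inf
            p = np.nextafter(0, 1)
            degenerate = True
    else:
        wald = delta / se
        p = 2.0 * stats.norm.sf(abs(wald))
    return {
        "delta": float(delta),
        "wald_stat": float(wald),
        "p": float(p),
        "zero_variance": degenerate,
    }


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def variant_effect_table(
    records: pd.DataFrame,
    pairs: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Batch variant-effect tests with BH correction and direction calls.

    ``pairs`` columns: ``variant``, ``reference``; replicate-level log2fc is
    taken from ``records.attrs['replicate_log2fc']``. Direction is ``ns``
    unless the adjusted p-value is below ``alpha``.
    """
    reps = records.attrs["replicate_log2fc"]
    rows = []
    for pair in pairs.itertuples(index=False):
        if pair.variant not in reps.index or pair.reference not in reps.index:
            continue  # filtered out upstream
        res = variant_effect_test(
            reps.loc[pair.reference].to_numpy(), reps.loc[pair.variant].to_numpy()
        )
        rows.append({"variant": pair.variant, "reference": pair.reference, **res})
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["padj"] = bh_adjust(out["p"].to_numpy())
    out["direction"] = np.where(
        out["padj"] >= alpha, "ns", np.where(out["delta"] > 0, "up", "down")
    )
    return out


@dataclass
class RtmSimResult:
    beta_obs: float
    beta_sims: np.ndarray
    p_emp: float
    n_sim: int
    seed: int | None = None


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom == 0.0:
        raise ValueError("degenerate regressor: all baseline activities equal")
    return float(xc @ (y - y.mean()) / denom)


def rtm_null_simulation(
    wt_log2fc: np.ndarray,
    wt_sigma: np.ndarray,
    observed_wt_log2fc: np.ndarray,
    observed_delta: np.ndarray,
    n_sim: int = 10_000,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> RtmSimResult:
    """Regression-to-the-mean null for variant-effect vs baseline slopes.

    beta_obs is the OLS slope (with intercept) of the observed variant effects
    (delta = variant - WT log2fc) on WT log2fc. Each simulation draws one
    pseudo-variant activity per WT insert from N(log2fc_WT, sigma_i^2),
    regresses the simulated deltas on the WT activities and records the slope;
    the empirical p-value is the plain proportion of simulations with
    beta_sim <= beta_obs.
    """
    x = np.asarray(wt_log2fc, dtype=float)
    sig = np.asarray(wt_sigma, dtype=float)
    if x.size < 3:
        raise ValueError("need >=3 WT inserts with defined replicate SD")
    if np.any(sig < 0):
        raise ValueError("negative replicate SD")
    rng = rng if rng is not None else np.random.default_rng(seed)
    beta_obs = _ols_slope(
        np.asarray(observed_wt_log2fc, dtype=float),
        np.asarray(observed_delta, dtype=float),
    )
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom == 0.0:
        raise ValueError("degenerate regressor: all WT activities equal")
    # Delta_sim = A_sim - x = sigma * Z, so the slope reduces to a projection.
    z = rng.standard_normal((n_sim, x.size))
    deltas = z * sig
    beta_sims = (deltas - deltas.mean(axis=1, keepdims=True)) @ xc / denom
    p_emp = float((beta_sims <= beta_obs).mean())
    return RtmSimResult(
        beta_obs=beta_obs, beta_sims=beta_sims, p_emp=p_emp, n_sim=n_sim, seed=seed
    )


def library_summary(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-category activity-class counts/fractions and a rank-order table.

    Fractions are within category (rows sum to 1); empty categories yield zero
    rows. Ranking is by descending log2fc with the insert id as deterministic
    tie-break.
    """
    counts = (
        records.groupby(["category", "activity_class"], observed=False)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=list(ACTIVITY_CLASSES), fill_value=0)
    )
    counts = counts.reindex(
        [c for c in CATEGORIES if c in set(records["category"])], fill_value=0
    )
    totals = counts.sum(axis=1)
    fractions = counts.div(totals.where(totals > 0, 1), axis=0)
    ranked = records.copy()
    ranked["_id"] = ranked.index.astype(str)
    ranked = ranked.sort_values(["log2fc", "_id"], ascending=[False, True],
                                kind="mergesort").drop(columns="_id")
    ranked["rank"] = np.arange(1, len(ranked) + 1)
    summary = counts.join(fractions, lsuffix="_n", rsuffix="_frac")
    return summary, ranked
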