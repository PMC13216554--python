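# Methods

This note documents the models, conventions and numerical choices behind
`ceekit`, in the order of the analysis chain. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Coordinates and formats

All internal coordinates are 0-based half-open on the forward strand of one
genome build; GFF and VCF readers subtract 1 from starts, writers restore the
native convention, and round-trip identity holds for BED, narrowPeak, the GFF
subset and the VCF subset the pipeline uses. Chromosome names are normalised
by stripping a leading `chr` so that annotation dialects can be mixed; writers
can restore the prefix. A strand of `.` means unstranded and matches both
strands in every strand-aware filter (CAGE peaks may be unstranded).

GC content is carried as a windowed track (default 100 bp windows) rather
than raw sequence; the GC of an arbitrary interval is the length-weighted
mean of the covered windows. This makes GC-matched shuffling independent of
sequence availability and O(1) per evaluation via prefix sums. All-N windows
fall back to GC 0.5.

## The cEE caller

The decision pipeline is: isoform-exon consolidation → TSS/TES proximity
filter → TSS-peak window filter → optional TSL=1 filter → optional
promoter-mark exclusion → three occupancy criteria. Every exon receives a
pass/fail ledger, so the reason for any exclusion is inspectable.

Choices where the procedure was genuinely open:

- **Consolidation** merges overlapping same-gene exons whose lengths differ
  by ≤ `merge_size_diff_bp` (default 50), taking the coordinate union and
  iterating to a fixpoint, since the merging rule is transitive in intent
  (avoid fragmenting one regulatory element across isoform variants).
- **"TF density"** is defined as summit count per bp in a sliding window
  (default 50 bp) kept inside the exon; the maximum over placements is
  computed exactly by anchoring candidate windows at summits. Summits, not
  peak bodies, carry the density signal because they are point sources.
- **Flanks** are the 50 bp genomic regions immediately outside each exon
  boundary; the flank density is the maximum of the two flanks, and the
  in-exon maximum must exceed it strictly. An exon with no summits anywhere
  therefore fails.
- **Distance thresholds are inclusive** for removal ("within 1 kb" removes an
  exon at exactly 1 kb). Distances are edge-to-edge with point features
  treated as 1 bp intervals, so a feature inside the exon has distance 0.
- **Distinct TFs** deduplicate the factor label across datasets and cell
  types; the summit-ratio denominator counts peaks (not distinct factors),
  and the threshold of 0.5 is inclusive. Whether the denominator should
  instead count factors is a recognised sensitivity-analysis knob; the peak
  denominator is the stricter reading when one factor contributes several
  peaks.
- **Labels**: `cEE` (all criteria pass), `ctrl_neg` (all pre-filters pass,
  zero overlapping peaks), `insufficient_tf` (pre-filters pass, fewer
  distinct TFs than the minimum), `excluded` (everything else). Positive
  controls are intergenic cCREs passed through the same proximity and
  occupancy criteria.

Species presets: human/mouse use 1 kb TSS/TES exclusion and a 500 bp
TSS-peak window; fly/Arabidopsis use 100 bp for both. The TSL=1 filter is a
human-preset refinement; promoter-mark exclusion applies to human and mouse
and removes an exon on ≥1 bp overlap with any supplied promoter-like
element.

## Matched-shuffle enrichment

Each query interval is re-placed uniformly among all positions on its own
chromosome that preserve exact length, GC bin (default: ten equal-width bins
on [0,1]) and containment in the mappability mask. Sampling is by rejection
from the legal-position ranges with a fail-over to exhaustive enumeration of
all candidate starts after 1,000 rejections, which guarantees termination on
tight masks; enumerated candidate sets are cached per (chromosome, length,
bin), which is what makes 10,000-permutation runs cheap. Both uniformity
routes (accepted rejections and enumeration) give the uniform distribution
over the same candidate set.

The test statistic is the number of query intervals intersecting at least one
target. The direction of "at least as extreme" follows the side of the null
mean on which the observation fell, and p = min(1, 2·(k+1)/(N+1)); the clamp
matters for central observations where the doubled formula exceeds 1. Either
side (queries or targets) may be the shuffled set; the choice is a flag.

The correspondence analysis computes, per element, the fraction of
high-score (≥ median) overlapping TF peaks whose same-factor motif site also
overlaps the element, compares it with rates under genome-wide peak
randomisation (same chromosome and GC bin), and tests the paired differences
with a two-sided Wilcoxon signed-rank test and a paired sign-flip permutation
test on the mean difference (default 100,000 flips; exact enumeration is
available for n ≤ 20). Elements with no qualifying peak are excluded rather
than scored 0.

## Constraint statistics

Potential sites follow the counting convention in which each codon position
contributes (number of synonymous single-base changes)/3 to S, with changes
that create stop codons counted as nonsynonymous; S+N = 3 per codon, checked
exhaustively over the code. A terminal stop codon is tolerated and
contributes nothing; internal stops are errors.

Pairwise divergence uses Nei–Gojobori counting: per differing codon, all
shortest mutational pathways are enumerated and the synonymous/nonsynonymous
step counts averaged; pathways passing through a stop codon are excluded,
and if every pathway is blocked the full set is used with stop-involving
steps counted as nonsynonymous (a rare multi-hit corner case that needs a
defined answer). Site totals are averaged between the two sequences, raw
proportions are reported alongside Jukes–Cantor-corrected rates
d = −(3/4)·ln(1 − 4p/3), and p ≥ 3/4 raises rather than silently saturating.
dS = 0 leaves the ratio undefined (`None`) so pooled statistics can exclude
it. Pooling across pairs sums counts and site totals before correcting; the
average of per-pair ratios is the alternative route and both are exposed.

DoS = Nd/(Nd+Sd) − pN/(pN+pS) is computed on raw counts (the count-based
form of the statistic), FI = (dN/dS)/(pN/pS), and pN/pS normalises counts by
potential sites. Allele-frequency bins use inclusive upper edges
(ultra-rare ≤ 10⁻⁴, rare ≤ 10⁻³, low-frequency ≤ 10⁻², common above).
Nonsense variants are excluded from the missense numerator and reported
separately. Decile stratification sorts on the key with a deterministic
coordinate tie-break and splits into ten groups whose sizes differ by at
most one; Cramér's V is √(χ²/(n·(min(r,c)−1))) without continuity
correction.

## STARR-seq activity

CPM normalisation scales each sample column to 10⁶. The input filter
discards an insert when its mean raw input count is below 500 (strict) or
the standard deviation of its input CPM across input samples is at or above
20; with a single input sample the SD is zero. The SD is computed on the CPM
scale because raw-scale read-count noise grows with depth, whereas
representation instability is a relative phenomenon. Activities are
log2((cDNA CPM + pc)/(input CPM + pc)) with a 0.5 pseudocount; inserts with
raw-zero cDNA replicates carry a QC flag. By default every cDNA replicate is
compared with the mean input (shared-input mode); a matched-input mode pairs
replicate j with input sample j.

Classification anchors at the median log2FC of the kept positive technical
controls: ≤ 0 inactive, ≥ median strong (inclusive), otherwise moderate —
a monotone function of log2FC for a fixed anchor.

Variant effects use a Wald statistic, the difference of mean per-replicate
log2FC over the pooled standard error, referred to a standard normal, with
Benjamini–Hochberg correction across the batch and direction calls only
below the FDR threshold. A zero pooled variance with a nonzero difference
yields the smallest representable p and a flag. The normal reference is
deliberately simple; with three replicates per arm its tails are lighter
than the implied t distribution, which the FDR-control check in the test
suite covers empirically.

The regression-to-the-mean null regresses observed variant effects
ΔA = log2FC_variant − log2FC_WT on log2FC_WT by OLS with intercept, then
draws, per simulation, one pseudo-variant activity per WT insert from
N(log2FC_WT, σᵢ²), recomputes the slope, and reports the plain proportion of
simulated slopes ≤ the observed slope (one-sided, no +1 smoothing, per the
statistic's definition as a proportion). Because ΔA_sim = σᵢ·Z, the slope
reduces to a projection and the whole simulation vectorises.

## Target-gene integration

rE2G-style interval evidence requires the prediction to cover ≥ 50 % of the
element (inclusive, fraction on the element as the query operand); PCHi-C
evidence accepts either configuration — element in the other-end fragment of
a baited interaction (target = bait gene) or element inside the bait fragment
of a bait–bait interaction (target = the other bait's gene) — with ≥ 1 bp
fragment overlap; eQTL evidence requires the position inside the element and
the eQTL's own target gene is the assigned gene. Duplicate rows collapse per
(element, gene, source) before counting, so the two PCHi-C configurations are
one resource; robustness requires ≥ 2 distinct resources. A pair is internal
when the element lies within the target gene's own body; an element with both
internal and external assignments is summarised as mixed.

## Synthetic data

The generator emulates the structure of the real inputs, not their scale.
Desk-scale defaults: 2 chromosomes × 5 Mb with block-wise GC variation
(50 kb blocks, GC 0.35–0.65), 50 non-overlapping genes (3–8 exons of
90–300 bp in multiples of 3, introns 1.5–4 kb, both strands), in-frame CDS
with start/stop and no internal stops embedded into the sequence, a
mappability mask covering 90 % of each chromosome, 15 TFs with 20 planted
12-TF clusters whose summits jitter N(0, 10 bp) around interior-exon
midpoints over a Poisson background of 30 peaks/Mb, codon-aware SNVs at
2×10⁻² per coding bp with the AF mixture 91/6/2/1 % over the four bins
(log-uniform within bins so the ultra-rare mass is not degenerate at the
edge), and 490 STARR inserts across the six categories.

STARR counts are negative-binomial (dispersion 50) around a log-normal
per-insert input abundance (CV 0.5, mean 2,000 reads), with small
multiplicative technical noise between input samples (CV 0.005; a 5 %
unstable minority at CV 0.05 gives the input-SD filter genuine work), and
cDNA means scaled by 2^(activity + N(0, 0.2)) per replicate. Because a
ratio-based assay only identifies activity relative to the library
composition, planted activities are centred so the abundance-weighted mean
linear activity is 1; the centred values are the recorded truth, which is
what the estimator can and does recover. Variant inserts shift a reference
cEE's activity by N(−1.0, 0.5) log2 units.

Ortholog pairs apply single-base synonymous/nonsynonymous changes at
distinct codons to hit target per-site divergence proportions (stops
avoided), so pathway counting is exact and the realised counts are truth.
Interaction truth plants (element, gene, source-set) triples with decoy
sub-threshold rE2G rows. The enrichment generator first places query
intervals uniformly (fixing length and GC bin), computes each query's exact
null overlap probability from its matched-candidate set, and then re-places
queries so the realised overlap count equals the planted fold times the
exact expectation.

What the generator does **not** emulate: linkage disequilibrium and
haplotype structure, chromatin-state or cell-type structure in TF binding,
read-level artefacts (mapping, duplicates, UMIs), overlapping genes and
alternative isoforms, and realistic genome-scale peak catalogues. Passing
tests therefore demonstrate algorithmic correctness and calibration under
the stated noise models, not performance on any real catalogue; the
published genome-scale counts depend on external accessions and are out of
scope.

## Problem sizes and determinism

The test suite and the acceptance script run the study conditions at desk
scale: 10 caller seeds on the full preset, 200 calibration datasets × 1,000
permutations, 10,000-draw shuffle contracts, 200 random 30-codon oracle
pairs, 1,000 variant-effect tests per regime, and 1,000 (suite) / 200
(script) regression-to-the-mean replicates at 2,000 simulations each. Every
stochastic component takes a seed or a NumPy `Generator`; identical seeds
give byte-identical generator output, and the CLI logs the seed with every
result it writes.

## Known limitations

- The caller's density criterion depends on the window width (default 50 bp);
  very short exons use the exon length as the window.
- The Wald test's normal reference is anti-conservative at very small
  replicate counts; a t reference can be substituted by the caller of
  `variant_effect_test` when replicate counts are tiny and calibrated
  per-test error rates matter more than batch FDR behaviour.
- Exhaustive candidate enumeration caches per (chromosome, length, GC bin);
  pathological workloads with millions of distinct lengths on very long
  chromosomes would grow the cache — bounded in practice by the workloads
  the pipeline runs (per-dataset interval sets).
- `consolidate_exons` is quadratic per gene group, which is irrelevant at
  isoform counts but would need an interval tree for pathological inputs.
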