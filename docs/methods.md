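# Methods

## The problem and the estimator

Field metatranscriptomes report expression on an arbitrary scale: read
depth, community composition and RNA recovery all differ between samples,
so a stress-responsive transcript's raw abundance says little about the
organism's physiological state. `gmindex` removes the scale in two steps.
First, every abundance is made *relative* within its sample (normalization
to the total reads assigned to the organism of interest). Second, the
statistic of interest is a *ratio* between a stress-regulated transcript
and a constantly expressed transcript within the same sample, which cancels
any remaining per-sample factor exactly — the classic housekeeping-gene
normalization, turned into a field-deployable index.

The lab experiment calibrates the ratio. For pair *i* = (regulated *r*,
constant *c*), `x_min` is the ratio of condition-mean relative abundances
in the control, `x_max` the same under the stress treatment, and a field
sample's ratio `x_i` maps to

```
GMI_i = (x_i - x_min) / (x_max - x_min) * 100
```

This is an affine (min–max) normalization: 0 and 100 are the lab control
and treatment endpoints by construction, for up- and down-regulated markers
alike, and values outside [0, 100] are meaningful output ("beyond the lab
range"), not errors. In-range values are binned into quartiles
[0,25), [25,50), [50,75), [75,100] for reporting; the out-of-range fractions
are reported separately on each side.

**Replicate aggregation is mean-then-ratio**: bounds are ratios of
replicate-mean abundances rather than means of per-replicate ratios. Ratios
of means are stabler at low counts, and they make the recovery property
below exact in expectation. Pairs whose constant transcript has zero mean
in either condition, or whose bounds differ by less than `delta = 1e-9`
(after normalization), are dropped with a logged reason — a vanishing
denominator or a degenerate range carries no information. In field samples,
a zero constant-transcript abundance causes the record to be *skipped*, not
pseudocounted: any pseudocount would break the exact invariance of the
index to per-sample scaling, which we consider the more valuable property.

## Marker classification

The regulation classifier is deliberately lightweight: log2 fold change of
condition-mean CPM (counts per million; pseudocount 0.5 in the ratio only),
a Welch two-sample t-test on log2(CPM + 1), and Benjamini–Hochberg FDR
across all transcripts tested per stressor. A transcript is regulated when
it clears all three published thresholds at once — fold change > 2,
p < 0.05, FDR < 0.05 — and `read_regulation_table` accepts precomputed
tables from dedicated count-model DE tools (edgeR, DESeq2) for users who
prefer them; the catalog logic downstream is identical for both paths.

"Constantly expressed" is not quantitatively defined in common usage, so we
fix it: not regulated under either stressor, |log2FC| < 0.5 under both
(`stability_threshold`), and nonzero mean abundance in every lab condition.
The catalog then partitions regulated transcripts into single-stressor sets
(the ratio markers), a dual-regulated set (kept separately; it re-enters
only the dataset-2 profile comparison) and attaches the constant set. The
partition is validated: constant ∩ regulated must be empty, and the
single-stressor and dual sets are disjoint by construction.

A power caveat worth knowing: with three replicates the Welch test cannot
produce p-values much below ~2e-4 (df ≈ 2), so an isolated true positive
among a thousand null transcripts cannot survive BH correction. Detection
at the published thresholds needs either more replicates or many true
positives sharing the FDR burden — both of which hold in realistic stress
experiments, where thousands of transcripts respond.

## Field matching

Field contigs are accepted as belonging to the reference organism when a
precomputed BLASTN tabular hit reaches percent identity ≥ 98 and
e-value ≤ 1e-50 (both inclusive). The stricter e-value 1e-66 that appears
in the study's hit-funnel summary is exposed as `STRICT_MAX_EVALUE` /
config override. Each contig keeps one best hit (bit score, then identity,
then lexicographically smallest subject — fully deterministic), and contigs
assigned to the same reference transcript have their abundances summed,
treating them as fragments of one gene; taking the maximum instead would
discard reads. The original study's final manual curation of the hit list
is not algorithmically specified and is not reproduced; an exclusion-list
hook covers externally verified removals.

## Whole-profile comparison

Bray–Curtis dissimilarity on per-sample relative abundances, Ward.D2
agglomerative clustering, and a recursive SIMPROF permutation test. The
SIMPROF null holds each transcript's values exchangeable across the tested
group's samples: the observed profile is the sorted vector of pairwise
similarities (1 − dissimilarity); `n_expected = 999` independent row-wise
permutations define the mean null profile; the statistic π is the summed
absolute deviation of the observed profile from that mean; `n_simulated =
999` further permutations give the p-value with the plus-one rule
(p ≥ 1/(B+1), never exactly zero). The root group is always tested, descent
continues only into children of significant nodes (α = 0.05 per node,
uncorrected, as is standard SIMPROF practice), groups smaller than three
samples are terminal, and the maximal groups without significant internal
structure are the reported clusters.

Permutation streams are keyed by the *sorted member set* of the tested
group (CRC32 of the joined names, combined with the user seed), and rows
and columns are sorted by ID before permuting, so results are invariant to
the input's sample order and fully reproducible under a seed.

Ward.D2 is applied directly to Bray–Curtis input via the Lance–Williams
recurrence on squared dissimilarities. Bray–Curtis is not Euclidean, so
Ward's within-cluster-variance interpretation is approximate and height
inversions are theoretically possible; this mirrors standard ecological
practice and is left as a documented caveat. Exact distance ties merge the
lexicographically smallest pair of cluster labels (a cluster's label being
its sorted member tuple), making merge order deterministic. The
implementation is cross-checked against scipy's ward linkage in the test
suite. Dendrograms serialize to Newick with branch lengths as height
differences and tested nodes labelled `p=<value>`; the output round-trips
through standard Newick parsers.

## Synthetic data: what it emulates, and what it does not

The generator mirrors the study design at desk scale. Counts are negative
binomial with variance μ + φμ² (φ = `dispersion`; φ = 0 degenerates to
Poisson), matching the noise model the standard DE tools assume. Per
transcript, a baseline mean is drawn log-uniformly from
`baseline_mean_range` (default 20–500 expression units); regulated
transcripts get true fold changes uniform in `fold_change_range` (default
4–8, lower bound required > 2 so the truth is learnable at the published
threshold); per-sample library sizes are uniform in `library_size_range`
(default 1–2 million). Defaults use three replicates per lab condition —
the study's field design sequenced three and four replicates per site — and
three field samples at latent stress fractions (0.25, 0.5, 0.75), chosen to
span the index's range; field noise uses the same dispersion parameter as
the lab, since the study characterizes no separate field noise.

Dual-regulated transcripts are planted so that a fraction
`overlap_fraction` (default 1/3, the study's reported overlap) of each
stressor's *total* regulated set is shared: with S single-stressor
transcripts per stressor, the dual count d solves d/(S + d) = f.

Field samples interpolate expected abundances *arithmetically*,
E[field | s] = (1 − s)·E[control] + s·E[stress]. With a constant
denominator this makes the expected pair ratio linear in s, hence expected
GMI = 100 s — the analytic basis of the recovery tests (in-range median
within ±10 of 100 s at dispersion 0.005, 300 pairs). Identity hits give
every true transcript identity ∈ [98, 100] and e-value ≤ 1e-60, while
decoys alternate between low identity ([80, 98)) and failing e-values, so
default filtering retains exactly the truth.

What the generator does *not* emulate: community composition (no non-target
taxa; field "contigs" map 1:1 to reference transcripts plus decoys),
assembly artifacts (no fragmented or chimeric contigs, so the
multiple-contigs-per-gene summation path is exercised only by explicit
fixtures), sequence content of any kind, compositional biases between lab
and field RNA extraction, and correlated regulation across transcripts
(truth effects are independent). Passing tests therefore demonstrate the
*statistical machinery* — classification, calibration, recovery,
significance — not robustness to assembly noise or cross-taxon bleed-through.

All randomness derives from one scenario seed via numpy `SeedSequence`
spawn keys (0 = lab, 1 = field cold, 2 = field desiccation, 3 = identity
hits), so adding a simulator never perturbs existing streams, and
byte-identical outputs under identical configuration are a tested pipeline
invariant.

A deterministic fixture mirrors the published per-site marker-set sizes
(cold: 13 constant with 11 regulated at site 1 and 10 at site 3;
desiccation: 12 constant with 8 regulated), with noise-free counts whose
ratio bounds are all non-degenerate — enumeration yields exactly 143, 130
and 96 pairs, the study's printed combination counts.

## Problem sizes and tolerances

The test suite and examples run at desk scale by design: hundreds to a few
thousand transcripts, 3–5 replicates, 99–999 permutations. SIMPROF
calibration uses 500 replicate null runs at 99 + 99 permutations and checks
the root rejection rate against the binomial 99% CI around α = 0.05; the
oracle comparisons require Bray–Curtis agreement to 1e-12 and exact Ward.D2
merge-order agreement with scipy on 20 random 6-sample matrices. Floating
output uses a fixed 9-significant-digit TSV dialect so regression
comparisons are byte-exact.

## Known limitations

- The classifier is a location test on log-CPM, not a count model; at very
  low counts or 2–3 replicates, dedicated DE tools have more power. The
  plug-in table path exists for exactly this reason.
- GMI normalization uses the organism-subset totals everywhere;
  whole-dataset totals can be supplied by normalizing upstream, but the two
  conventions differ when the organism's share of the community varies.
- SIMPROF p-values are per-node and uncorrected; with deep dendrograms the
  family-wise error across nodes grows, which is inherent to the standard
  recursive procedure.
- Ward.D2 on Bray–Curtis can produce height inversions (negative Newick
  branch lengths) on pathological inputs; they are preserved, not clipped.
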