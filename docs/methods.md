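# Methods

This note documents the statistical models, the synthetic-data generator, the
numerical conventions, and the design decisions behind `ncats_eval`.

## Setting

Nanopore Cas9-targeted sequencing (nCATS) enriches a small number of genomic
regions by guided Cas9 cleavage before long-read sequencing; methylation is
called per read at CpGs from the native-DNA signal, so each read phases the
methylation states of every CpG it covers. The package analyses such an
experiment with two individuals (a smoker and a non-smoker in the default
emulation), three targeted regions, and an external array EWAS summary as a
reference comparison.

## Per-site methylation quantification

Per-read calls carry a log-likelihood ratio (LLR) of methylated versus
unmethylated. Following the conventions of the caller's companion frequency
script:

* calls with |LLR| < 2.0 are discarded as ambiguous (cutoff exposed as
  `llr_cutoff`);
* surviving calls are binarized by sign;
* CpG-group calls (`num_motifs` > 1, closely spaced CpGs given one joint
  call) are split into one record per constituent CpG, each inheriting the
  group state; constituent positions are located by scanning the local
  sequence context for CG dinucleotides, anchored at the group start;
* per (sample, site) frequencies are methylated / total read counts, with
  sites below a minimum depth of 10 reads excluded (`min_depth`).

Coordinates are 0-based half-open internally; 1-based inclusive coordinates
appear only in human-readable summaries. CpG positions are forward-strand C
coordinates; calls on either strand collapse onto them. Duplicate
(read, site) records are an error rather than silently merged — a single
molecule must not be counted twice.

Site clustering (for the "n CpGs in m regions" summary) merges consecutive
sites whose gap is at most `cluster_max_gap` (default 100 bp). The clustering
rule behind the original summary is not documented anywhere we could follow,
so the gap is plain configuration with no claimed equivalence.

## Enrichment QC

"High quality" filtering retains primary alignments with MAPQ ≥ 20 (both
exposed). On-target counting uses any-overlap (≥ 1 bp, half-open): a read
abutting a region does not count, and regions must be non-overlapping so no
read is double-counted. Percentages are reported with round-half-away-from-
zero at the printed precision (integer for retention, two decimals for
on-target shares). Depth at a position counts reads whose interval contains
it; genome-wide summaries average depth over fixed-size bins (10 kb default).
Statistics of an empty region are reported as undefined (`None`), never as
zero.

## Differential methylation

At each CpG with depth ≥ 10 in *both* samples (strictly-greater variant
available via `depth_rule_inclusive=False`, since "at least 10" and ">10"
are both defensible readings), the methylated/unmethylated read counts form
a 2×2 table tested with a two-sided Fisher exact test. The p-value is the
sum of hypergeometric probabilities of all tables with the observed margins
no more probable than the observed table, with the standard 1e-7 relative
tie tolerance; the hypergeometric pmf comes from scipy, and the test suite
verifies agreement with exact integer enumeration for every table with
total ≤ 60 and with R's `fisher.test`.

Family-wise error is controlled by Bonferroni as a threshold comparison
(significant iff p ≤ α/m with m the number of sites actually tested), not by
inflating p-values, to avoid capping artifacts. The effect size is
`diff = frequency(sample1) − frequency(sample2)` with the case (smoker)
as sample 1, so hypomethylation in the smoker is negative.

The EWAS comparison joins on genomic position and reports the fraction of
joined sites whose effects agree in sign (sites with an exactly zero effect
on either side are uninformative and excluded), the 2×2 overlap of
significance calls, and per-site (combined depth, −log10 EWAS p) pairs for
depth-versus-power inspection. Chromatin-state annotation assigns each site
the first containing interval of a ChromHMM-style BED track, warning if the
track's intervals overlap.

## Read-phased co-methylation linkage

For each pair of CpGs on the same chromosome co-observed on at least
`min_shared_reads` reads (default 10, pooled across both samples — the
per-sample reading of that rule is available by filtering the input), the
joint proportions p_MM, p_MU, p_UM, p_UU are computed over exactly the reads
with a surviving post-threshold call at *both* sites. Counting uses
read-by-site indicator matrices per chromosome (coverage matrix A,
methylation matrix S: AᵀA gives shared-read counts, SᵀS both-methylated
counts), which makes the all-pairs tally tractable at tens of thousands of
pairs; a per-read brute-force tally serves as the test oracle.

The concordance excess is

    D = p_MM + p_UU − (p₁p₂ + (1 − p₁)(1 − p₂)),

standardized to D′ = |D| / D_max. Two normalizers are shipped because the
published form has two degenerate corners:

* **literal**: D_max = p_MM + p_UU if D < 0, else 1 − p_MM − p_UU. This is
  the printed definition and the default. It can exceed its own bound
  (p_MM = p_UU = 0.4, p₁ = p₂ = 0.5 gives D = 0.3, D_max = 0.2, D′ = 1.5)
  and yields 0/0 for perfectly concordant pairs.
* **bounded**: substitutes the expected concordance
  e = p₁p₂ + (1 − p₁)(1 − p₂), i.e. D_max = e if D < 0 else 1 − e. Since
  D = (p_MM + p_UU) − e and the observed concordance lies in [0, 1], this
  guarantees D′ ∈ [0, 1] (verified exhaustively over all joint tables with
  n ≤ 20).

Whether the expected concordance was the intended normalizer cannot be
settled from the published definition alone, so neither mode is presented as
authorial intent; outputs always record the mode. When D = 0 the normalizer
is defined as 1 so D′ = 0; a 0/0-degenerate D′ is reported as NaN and
flagged, never raised. D and D′ are invariant under swapping the two sites
and under globally relabelling M↔U (property-tested).

Distance-decay analysis exports all (distance, D′) points and
distance-binned medians; the linkage matrix export is symmetric with unit
diagonal and NaN for unobserved pairs, suitable for external heatmap tools.

## Synthetic-data generator

The generator produces the three inputs the analysis consumes — alignments
(SAM and a tabular fallback), per-sample Nanopolish-dialect call TSVs, and a
wide array-beta CSV — plus a truth table for oracles. One RNG seed drives
everything through per-stage sub-streams (layout / calls / array / map), so
identical configurations give byte-identical files.

**Read layout.** On-target reads start within ±5 bp (uniform jitter) of a
uniformly chosen guide cut site and extend downstream on the guide's strand,
with truncated log-normal lengths; they get MAPQ 60. Off-target reads are
uniform over the genome with MAPQ uniform on {0..60}, so MAPQ filtering has
something to do. Each read is assigned to one of the two samples with equal
probability.

**Methylation calls.** For each read and covered CpG, a binary state is
drawn from the sample's true proportion; configured pairs additionally copy
the upstream partner's state with the pair's coupling excess c, giving
expected concordance c + (1 − c)·(p₁p₂ + (1 − p₁)(1 − p₂)) — monotone in c,
and exactly the independence expectation at c = 0. The emitted LLR is
Gaussian with location +5 (methylated) or −5 (unmethylated) and scale 2:
separable, but with enough overlap that the |LLR| ≥ 2 threshold discards a
realistic fraction of calls.

**Array betas.** A probe's beta is the true proportion compressed toward the
interior (t ↦ γ + t(1 − 2γ), γ = `array_edge_compression`, default 0.15 —
the array loses sensitivity near 0 and 1) plus Gaussian noise (sd 0.08 by
default), clipped to [0, 1].

**Default study emulation** (`study_config`). Three chromosomes of 20 Mb
carry three target regions with the study's printed sizes — 140.5 kb
("AHRR", ten guides, six tiled across the interior), 8.3 kb (intergenic,
four guides at the ends) and 17.6 kb ("GFI1", four guides). The CpG map is
dense inside targets (log-normal gaps, median 35 bp) and sparse outside
(~1/3 kb). Base methylation is bimodal (mostly high, a low-methylation
island fraction), shared between samples. Twelve DMPs — ten in the large
region, six of them clustered within 400 bp, and two ~1 kb apart in the
intergenic region — are set to 0.85 in the non-smoker and hypomethylated by
0.5 in the smoker. DMPs are placed just downstream of forward guides, at the
acute coverage peaks, reflecting that detectable sites in this design are
the high-depth ones. The probe panel subsamples in-target CpGs (159/25/45
per region), array-like sparsity relative to the sequencing map.

Problem sizes are scaled for desk-scale reproducibility: 20 000 reads with
an on-target fraction of 0.032 reproduce the study's absolute on-target read
count (~640) and per-region coverages on a 60 Mb genome, while the
off-target background is proportionally denser than on a full genome. At
this depth only DMPs at coverage peaks reach Bonferroni significance —
the same depth-limited power the real experiment reported — so a default run
finds ~3 of the 12 designated DMPs, all hypomethylated in the smoker.

**What the generator does not emulate:** basecalling or alignment error,
signal-level artifacts, CpG-group calls (it emits singleton calls; group
splitting is exercised by parser-level tests), strand-specific calling
asymmetries, copy-number or SNP effects on probes, and inter-individual
variability beyond the two configured samples. Passing tests therefore
demonstrate correctness of the analysis machinery under the assumed
generative model, not robustness to real-data artifacts.

## Numerical conventions

* Percentages and kb sizes round half away from zero at the printed
  precision.
* Fisher ties use the standard 1e-7 relative tolerance on the hypergeometric
  pmf.
* Undefined statistics (retention of an empty input, Pearson r under zero
  variance, statistics of an empty region, 0/0 D′) are `None`/NaN with the
  RMSE or counts still reported — never silently zero.
* All randomness flows from a single integer seed via named
  `numpy.random.SeedSequence` sub-streams; adding a stage never perturbs
  earlier streams.

## Known limitations

* The pair-counting matrices are dense per chromosome; beyond ~10⁴
  depth-passing sites per chromosome a sparse implementation would be
  needed.
* The literal D′ mode is reported as printed, including values above 1;
  consumers comparing across modes must check the recorded `mode` column.
* `run_differential` tests marginal 2×2 tables site by site; no spatial
  smoothing or region-level testing is provided.
* The CLI's `simulate --config` accepts only the scalar knobs of the study
  emulation; fully custom genomes/CpG maps are constructed through the
  `SimConfig` API.
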