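# Methods

This note documents the models and procedures `orcmap` implements, the
parameters that matter, the design choices made where the procedure was
genuinely open, and what the synthetic-data generator does and does not
emulate.

## Chromosome demarcation

Chromosomes are partitioned into three region classes by scanning the
ordered gene list inward from each end. The terminal segment of an arm is
the maximal run of non-`ordinary` genes; within it, everything from the
telomere through the innermost *VSG* is `vsg_array` (the arm must carry at
least `min_array_genes` VSGs, default 1 — because the scan stops at the
first ordinary gene, an isolated VSG pseudogene deep in the core can never
seed an array), and the remaining run is `subtelomere` when it contains at
least one trigger-category gene (*RHS*, *VSG-related*, *ESAG*; *ESAG3* is
excluded because it also occurs inside arrays). The span of all remaining
non-hypothetical genes is `core`. Interior runs of ≥ `min_island_run`
(default 2) consecutive trigger-category genes are relabelled
`subtelomere` — relics of ancestral chromosome fusions. Hypothetical genes
never influence class decisions but remain members of their transcription
units.

Gap convention: gaps between genes of one class inherit that class; gaps
between classes are split at the midpoint; the outermost intervals extend
to the chromosome ends. This makes the track a deterministic partition of
[0, L) with no orphan margins. Coordinates are 0-based half-open
internally; GFF3 emission converts to 1-based inclusive.

DGCs are maximal runs of same-strand genes; SSRs are the gaps between
opposite-strand neighbours, `divergent` for reverse→forward (bidirectional
initiation) and `convergent` for forward→reverse (termination). VSG
cassettes are anchored on 70 bp-repeat features: each repeat claims the
first downstream VSG ORF before the next repeat; the 5′ flank is the
repeat-to-ORF span and the 3′ flank runs to the next repeat or the array
boundary. A repeat with no downstream ORF yields a flagged, ORF-less
cassette rather than an error.

## ChIP peak calling and randomization FDR

Probe log2 sample/input ratios are first shifted so the track minimum is
exactly zero; every downstream statistic is therefore invariant to
additive rescaling of the raw ratios. The detector computes, per
chromosome, a *hypothetical maximum* M = mean + 6 SD of the rescaled
signals, slides a 500 bp window anchored at every probe (probe-centric
stepping matches the tiling design and is deterministic), and flags
windows in which ≥ 4 probes exceed `cutoff_fraction × M`; overlapping hit
windows are unioned into candidate intervals. The cutoff grid descends
from 0.90 to 0.15 in steps of 0.10 (endpoints were fixed; the
intermediate grid is our choice).

The FDR at each cutoff is estimated by permuting probe values uniformly
across probe positions within each chromosome (preserving both the
marginal signal distribution and the probe density) and re-running the
detector 20 times; FDR = mean null candidate count / observed count,
capped at 1 and undefined (NaN) when nothing is observed. A candidate
keeps the most stringent confidence class achieved at any cutoff — high
(FDR ≤ 0.05), mid (≤ 0.1), low (≤ 0.2) — and candidates never detected at
FDR ≤ 0.2 are dropped. Mean and SD for M are computed per chromosome
after rescaling.

Merging groups sites whose edge-to-edge gap is strictly less than
`merge_gap` (default 10 kbp, matching "closer than"); the merged count is
the "unique sites" statistic and merging is idempotent. H4K10Ac loci are
merged first and then filtered for span ≥ 1 kbp, in that order. Sites are
assigned to region categories by their midpoint — a partition, so
category counts are additive; occupancy of a feature set uses interval
overlap. Mean spacing within a category is category length ÷ merged-site
count.

## MFA-seq

Per-position depths are averaged in 2,500 bp bins (the final partial bin
over its true length). The raw per-bin S/G2 ratio is normalized by a
per-chromosome baseline so unreplicated territory sits at 1; the baseline
estimator is the median of the lowest quartile of bins, which stays
anchored to the unreplicated mode even when ~half the chromosome shows
replication (the mean does not). Bins with zero G2 depth are excluded and
flagged; bins below a mapping-quality floor can be flagged via
`quality_ok` and are kept in the track but ignored by peak calling.

Peak calling is not prescribed by the upstream protocol, so the
procedure, all parameters exposed: running-median pre-smoothing (5 bins);
local maxima with amplitude ≥ 0.15 above baseline and width at half
amplitude ≥ 10 bins; peak boundaries where the smoothed track returns to
within one noise SD of baseline. The noise SD is estimated robustly from
the median absolute first difference of the bins (÷ 0.6745√2):
differencing removes the slowly varying replication profile, and the MAD
ignores genuine peak edges. (An earlier estimator using only sub-baseline
bins underestimated the noise several-fold, because the lowest-quartile
normalization leaves few bins below 1.)

Flank slopes are least-squares fits from apex to each boundary on the
smoothed track. Under constant per-cell fork speed and uniform sampling
through the observed S window, the expected profile falls linearly with
distance d from the origin, P = 1 − d/(v·w), so the slope magnitude is
inversely proportional to the fork speed v on that flank; the fork-rate
fold is |steeper|/|shallower| and the shallower flank is the faster
(transcription-codirectional) one. A peak is symmetric when the slope
ratio lies in [0.8, 1.25]. Peaks are named `OBR:{chromosome}:{Mbp}` with
two decimals.

A bin counts as replicated when its normalized ratio exceeds 1 + t with
t = 3 × the robust noise SD by default (the upstream threshold is
unstated; recovery is verified against generator truth only). The
genome-wide origin prediction scales the observed peak count by the
reciprocal of the analyzed S-phase fraction (default 0.5, the first half
of S captured by the sorting gate); origin density is genome length ÷
predicted count, and the per-chromosome count–length relation is fit
through the origin with the Pearson correlation reported.

## ΔΔCt

Replicates (≥2 per amplicon/sample, typically 4) are aggregated by mean
Ct, matching the canonical method. ΔCt subtracts the calibrator within
each sample, ΔΔCt subtracts G2 from S, and quantity = 2^(−ΔΔCt) with
amplification efficiency fixed at 2 (no efficiency correction). Replicate
SDs propagate through the four means in quadrature to a quantity
interval. Global Ct shifts cancel exactly and
quantity(a,b)·quantity(b,a) = 1.

## RNAi response

Quantile normalization maps each track, rank for rank, onto the mean of
the two sorted distributions; tied observations share the mean of their
tied block. On tie-free inputs the two outputs have exactly identical
sorted values; with ties the block-averaging necessarily perturbs the two
sorted multisets slightly — both properties cannot hold at once on tied
data, and we follow the standard block-averaging convention.

The 250 bp log2(induced/uninduced) track takes the median of per-position
ratios per bin, excluding positions where either sample is zero; those
positions belong to the presence track, where zeros are replaced by 1e−5
and a bin is flagged one-sample-only when its median log2 ratio exceeds
half of log2(read_floor/zero_sub) (≈ 8.3 at the defaults) — far beyond
any genuine two-sample ratio, so presence and ratio calls are disjoint by
construction. Running-median smoothing (window 7, shrinking at the edges)
is pandas rolling-median, cross-checked against a naive reimplementation.

Per-gene abundance is the mean depth over the gene body per condition and
the fold change is their ratio (zero-guarded); genes are flagged at
> 1.4-fold, with no additional test imposed. Boundary enrichment is the
mean binned signal within 10 kbp of any DGC boundary minus the mean
elsewhere, with a cyclic-shift permutation null (1,000 shifts, per
chromosome, seeded) and a per-boundary-type breakdown.

## Synthetic data generator

Each chromosome is laid out as
[vsg_array | subtelomere | core | subtelomere | vsg_array] with per-end
array/subtelomere fractions 5%/2.5%. The core is tiled with
alternating-strand DGCs separated by 4 kbp SSR gaps; cluster sizes are
drawn uniformly at ±50% around a mean of 40 genes (2.3 kbp per gene unit,
~92 kbp clusters — a scaled analog of the real ~50-gene clusters; the
jitter keeps the core aperiodic, which the cyclic-shift null requires).
Every fifth interior core gene is hypothetical. Arrays are tiled with
14 kbp cassettes (40% 5′ flank, 50% ORF, every third ORF a pseudogene);
subtelomeres cycle through the RHS/ESAG/VSG-related/ESAG3 families.
Sequence, when requested, uses class-specific AT fractions
(0.70/0.65/0.60). Ground-truth region boundaries use the same
midpoint-split convention as the demarcation scan, so the round trip is
exact by construction.

ChIP probes tile every 61 bp with Gaussian noise (SD 0.25); planted sites
add log2(4) over a 1 kbp footprint — the low, ~4-fold enrichment regime
characteristic of initiator ChIP. Truth sites default to SSR midpoints.

Replication: each origin fires with its efficiency at its firing time;
forks extend at a constant per-flank speed — base 150 kbp per S phase
against transcription, ×2 co-directionally, assigned from the flanking
cluster strands (both flanks fast at divergent SSRs, hence symmetric
peaks). A cell sampled at a time uniform over the observed window (first
half of S) has replicated a locus iff some fired origin's fork arrived in
time; expected copy number is 1 + P(replicated). P is computed exactly by
integrating the piecewise-constant survival function over the window (on
a 100 bp grid, interpolated to positions; the profile varies on the
fork-travel scale so nothing is lost), and an independent per-cell
Monte-Carlo enumeration is kept in the test suite as the oracle. Origins
default to divergent SSR midpoints at ≥500 kbp spacing (the scaled analog
of the observed ~530 kbp inter-origin distance), kept one fork-extent
from chromosome ends so telomeres do not truncate peak flanks. Read
counts are negative binomial with variance m(1 + αm), α = 0.02 (Poisson
at α = 0), mean depth 30× at copy number 2.

RNAi: uninduced cells express uniformly (depth 20) within DGC spans and
are silent elsewhere; designated MVSG/BVSG-like genes keep a basal depth
of 2. Induction multiplies expression by 2 within 5 kbp of each cluster
boundary, spills reads 5 kbp past the starts/stops into the silent
flanks, derepresses MVSG-like genes 8-fold and BVSG-like genes 2-fold,
and switches on silent presence loci (a cassette 5′ flank per array).
qPCR Ct values are base 20 + per-amplicon offset − log2(quantity) +
replicate noise (SD 0.1 cycles, quadruplicate).

All generators are deterministic given (seed, config).

### What the generator does not emulate

Read-level artifacts (mappability, GC bias, duplicates), multi-mapping
ambiguity in repeat families, probe-specific hybridization bias and dye
effects, late-firing/stochastic origin timing distributions, and
biological replicate variability. Passing recovery tests therefore
demonstrates the correctness of the statistical procedures under the
stated generative model, not robustness to these real-data failure
modes. One consequence is documented and load-bearing: quantile
normalization assumes near-identical depth distributions, but the
simulated induced/uninduced pair differs genuinely (a substantial
fraction of the scaled genome is derepressed), so normalizing the
simulated pair distorts low-expression loci. The generator emits tracks
at matched library size, and fold-change recovery is computed on them
directly; quantile normalization remains the between-sample step for
real inputs, validated by its distributional identities.

## Problem sizes

Tests and the acceptance script run on 0.2–2 Mbp chromosomes: 2 Mbp for
binding-site recovery (20 planted sites), 50 × 200 kbp pure-noise
replicates for the false-call rate, 50 replication replicates of a 1 Mbp
chromosome for origin-center recovery, and a 1.2 Mbp chromosome for the
derepression analysis. These sizes give the same per-bin and per-probe
statistics as full-genome runs (all estimators are local or
per-chromosome) while keeping the whole suite under a minute per stage.

## Known limitations

- The FDR is a global per-cutoff estimate, not per-site; a site's class
  reflects the best cutoff that detected it.
- The VSG-array spacing denominator (region length vs probe-covered
  length) changes the spacing statistic severalfold on sparsely tiled
  arrays; `mean_spacing` takes the caller's length, and the choice is the
  caller's.
- Fork-rate folds assume linear flanks (constant speed, uniform sampling);
  origin clusters closer than one fork extent blur both slopes.
- `boundary_enrichment` assumes boundaries are sparse relative to the
  near-distance; if the near-mask covers most of the genome the statistic
  loses power (visible on heavily scaled-down genomes).
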