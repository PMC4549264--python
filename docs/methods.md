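# Methods

This note records the models, conventions and numerical choices behind
`nucarch`, and what the synthetic benchmark does and does not establish.

## Occupancy model

A paired-end mononucleosomal fragment is treated as evidence for one
nucleosome whose dyad is the fragment midpoint; even-length fragments
round the midpoint down (leftward), consistently everywhere in the
package. The nucleosome occupancy score (NOS) at a base is the number of
inferred dyad-centered 147-bp cores covering it. This is coverage
re-expressed at nucleosome size: away from chromosome ends a track sums
to exactly 147 per accepted fragment, and no additional smoothing is
applied — the 147-bp box is already the natural kernel. Exact duplicate
intervals are clonal PCR artifacts and are capped (default: one copy)
before scoring.

Normalization scales a dataset to a genome-wide mean NOS of 100. The
target is arbitrary but fixed; all cross-dataset quantities downstream
are ratios, correlations or ranks, so its value is immaterial. Any
absolute occupancy cutoff must therefore be re-derived per dataset,
which is why the high-occupancy methylation subset defines its threshold
as the mean called summit rather than a hard-coded number.

### Nucleosome calling

Calling is greedy non-maximum suppression: repeatedly take the highest
remaining summit as a dyad, emit the core [dyad−73, dyad+74), and
exclude [dyad−149, dyad+149] from further summit selection, so
consecutive dyads are ≥ 150 bp apart (one nucleosome per 150 bp at
saturation). Two tie-break rules make the output deterministic:

* distinct summits of equal height resolve to the leftmost;
* a contiguous equal-value plateau yields its **midpoint**.

The second rule matters because box-kernel NOS makes every summit a
plateau (all bases covered by the same fragment set score identically).
The plateau spans [max(midpoints)−73, min(midpoints)+73], so its center
is the midrange of the supporting fragment midpoints — the natural dyad
estimate, and the exact truth when jitter is zero. A leftmost rule
inside plateaus would bias every call ~50 bp leftward.

The caller's greedy set is characterized exactly by a lexicographic
optimality property (best summit first, position breaking ties), which
the test suite verifies against brute-force enumeration over all maximal
legal dyad subsets on small instances.

### Map comparison

`binned_pcc` drops masked bases (structural variants, blacklists),
averages the rest in fixed 10-bp windows anchored at coordinate 0, and
computes Pearson's r over the concatenated bins. Bins with no usable
base are dropped; fewer than two usable bins or zero variance is an
error, not a NaN.

## Sequence periodicity

Dyad-relative frequency profiles cover offsets −73..+73; a dinucleotide
is coordinated by its first base, so the +73 pair reads one base past
the core edge and sites lacking that base are skipped for that offset
only. Periodograms mean-subtract the profile (no window, no detrending
beyond the mean — profiles are short and zero-padding to 1024 points
suffices), take the squared rfft magnitude, and pick the in-band maximum
with quadratic interpolation across the three bins around the peak
(period resolution ~0.05 bp at 10 bp).

A dominant period is only reported when the peak power exceeds
`peak_ratio` times the median in-band power. The ratio is calibrated to
the band's multiplicity: over the default 2–20 bp band (~150 effectively
independent bins) the spectral maximum of a structureless profile
reaches ~7–11× the median, while planted periodicities measure 190× and
higher, so the default is 30. The phasing periodogram scans the narrow
120–300 bp repeat-length band (~5 independent bins over a 1001-lag
autocorrelation) where unphased tracks measure ~3× and tiled arrays
~33×; its default ratio is 4. Both are configurable.

The phasing estimate itself averages the biased autocorrelation of
mean-centered NOS over uniformly sampled 2-kb windows (lags 0..1000),
excluding constant windows, and runs the same periodogram on the result.

## Metaprofiles and clustering

Profile rows for minus-strand features are reversed before any
averaging, so positive offsets are always downstream in transcription
direction. Features within one flank of a chromosome end are dropped and
counted. Defaults: ±1000 bp around TSS/TTS, ±500 bp around point
features such as TFBS and methylation sites.

Total RNA signal adds the two strand tracks after scaling each nonzero
strand to the mean of their totals (nucleosomes are strand-blind;
transcription is not). Expression is the signal sum over the gene span;
quartiles are taken on ranks with stable-order tie breaking, so tied
(e.g. all-silent) genes split deterministically. A gene is silent when
its mean signal over the span ±500 bp is ≤ eps (default 0 — literally
no signal).

Clustering input is the per-gene profile divided by its own maximum, so
clusters encode *where* nucleosomes sit rather than how deep the
library was; aggregate metaprofiles use depth-normalized NOS without
row scaling. k-means is Euclidean (scikit-learn) with a fixed seed and
10 restarts; k defaults to 10. Per-cluster, the offset of the centroid
maximum summarizes the dominant nucleosome position.

The +1 nucleosome of an oriented profile is the first local maximum
strictly downstream of the TSS within (0, 300], after 5-bp moving-
average smoothing (recorded in output); plateau maxima resolve to their
last base. Shifts are differences of such locations.

Active sites are TFBS whose mean DNase signal is at or above the 0.75
quantile of per-site means and whose mean NOS is at or below the 0.25
quantile — explicit, quantile-based stand-ins for "high" and "low",
inclusive at the boundary so a single site is active by convention.

## Methylation geometry

Contexts are mCG, mCHG, mCHH and hmC; mCG calls at positions re-called
as hmC are removed on ingest (bisulfite cannot distinguish them). A site
belongs to a nucleosome iff its position lies in the half-open core;
with ≥150-bp spacing cores never overlap, so membership is unique.

Occupancy stratification buckets nucleosomes by in-core count
(0,1,2,3,4+; the open top bucket keeps sparse tails testable) and uses
the core-mean NOS as the occupancy value (the summit is an alternative,
configurable). Kruskal–Wallis runs across buckets, followed by all
pairwise two-sided Mann–Whitney tests, Bonferroni-corrected over the
pairwise family; scipy's exact method applies automatically for small
tie-free groups and matches brute-force relabeling enumeration.

Distance-to-dyad histograms use the signed distance to the nearest dyad
(positive = downstream of the dyad); a site exactly midway between two
dyads goes to the downstream dyad (negative distance). The sign
convention is cosmetic — the profiles are symmetric — but fixed. Core
views span −73..+73 and report frequency percent summing to 100; out-of-
range sites are excluded but counted.

## Architecture scan

Positioning score = summit NOS / mean non-core NOS within ±500 bp (1.0
on a flat track; +inf above all finite scores when the background is
empty). The enhancer-like pattern requires, for an adjacent called
pair: both scores ≥ 2.0, inter-dyad gap in [250, 600] bp, gap trough ≤
0.5 × the smaller summit, and at least one further well-positioned
nucleosome within 450 bp on each outer side. Hits are emitted at the
trough-plateau midpoint with score mean(pair scores) × (1 −
trough/min summit), and overlapping 200-bp windows keep the best hit.
All thresholds live in `ScanConfig`; because every rule is a ratio of
NOS values, the scan is invariant under uniform scaling of the track.

## The synthetic benchmark

The generator emulates, with known truth: GC-enriched cores (+0.10 over
a 0.40 background) carrying sinusoidally placed AA/TT dinucleotides
(period 10 bp, amplitude 0.6, placement rate 0.2 — chosen so cores stay
GC-enriched while the periodicity is detectable from ~3,000 cores); a
185-bp-repeat landscape of 70% positioned (jitter sd 10 bp) and 30%
fuzzy (sd 22 bp) particles; gene TSSs with ten architecture classes
(anchor nucleosome at ±60/105/150/195/240 bp in transcription
direction, 1.8–3.2× occupancy rising with expression tier, a weak
filler particle on the opposite side whose occupancy halves per tier —
so expression empties the NDR and strengthens the +1); planted enhancers
(depleted center, 2.8× flanking pair 500 bp apart, 2.4× supports at
±490 bp behind secondary gaps); 50-kb lognormal occupancy domains
(sd 0.6), mirroring the large-scale heterogeneity that makes replicate
maps concordant; 400,000 fragments of length ~N(151, 15) truncated to
[100, 220] bp (gel size selection) with 10% exact duplicates; per-base
Poisson RNA at the tier rate on the gene strand; and methylation placed
at C/G positions with context-specific dyad-relative densities (mCG
modes at 0 and ±40 bp; mCHG at ±55; mCHH mostly in linkers; hmC broad),
a placement rate proportional to nucleosome occupancy weight, and a
dyad-focused sharpening of the profile for high-weight nucleosomes — the
planted counterpart of "more methylated nucleosomes are more occupied,
and high-occupancy mCG sits nearer the dyad".

Where the noise scales were free, they were set so the package's own
recovery analyses are informative at desk scale: positioned dyads are
recoverable to ±20 bp, the ten TSS classes are separable by k-means,
planted enhancers are detectable at the default scan thresholds, and
split-half maps correlate above 0.9 at half of the default depth. The
defaults are study conditions, not tuning knobs; tests run against them
unchanged.

What passing does **not** show about real data: no sequence-dependent
MNase bias, no mappability or alignment artifacts, unimodal Gaussian
jitter rather than alternative rotational positions, uniform fragment
sampling within a weight class, simplified RNA signal (uniform rate over
the gene body), and an idealized enhancer geometry. Results on real
libraries will be noisier in ways the simulator does not model.

## Degenerate inputs and determinism

All-zero datasets cannot be normalized or correlated (errors, not
NaNs); empty fragment sets give zero tracks and empty calls; a caller
dyad needs a full core inside the chromosome; constant profiles have no
dominant period; a single nonempty methylation bucket is a named error.
Every stochastic stage draws from `numpy.random.default_rng([seed,
stage_tag])`, so stages are independently reproducible and the pipeline
manifest checksums are bit-stable for a fixed configuration; the
manifest echoes scientific parameters only, keeping checksums
independent of output paths.

## Scale and limitations

Default problem sizes (2 × 1 Mb genome, ~10,400 nucleosomes, 400,000
fragments, ~45,000 methylation sites) were chosen so the full pipeline
runs in seconds and the whole test suite in well under a minute of
compute per simulation, while FFT, clustering and rank statistics remain
stable. The caller's resolution is bounded by the 147-bp box kernel:
fragments from a fuzzy neighbor that leak into a positioned summit
window can still displace a call by tens of bp, which is the main
residual error mode in dyad recovery. The scan detects the planted
geometry class, not every biological enhancer shape; its thresholds are
starting points for real data, not universal constants.
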