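# Methods

This note documents the models, parameter choices and numerical conventions
behind metabocompare, and what the synthetic benchmarks do and do not show.

## Mass conventions

Monoisotopic atomic masses are the IUPAC values (¹²C exactly 12 Da,
H 1.00782503, N 14.00307401, O 15.99491462, P 30.97376163, S 31.97207100,
¹³C 13.00335484; electron 0.00054858 Da). Theoretical ion m/z is always
electron-inclusive: `[M−H]⁻` removes one hydrogen atom and adds one electron
mass, divided by |z|. At the four decimals routinely printed for
orbitrap-resolution data the electron mass (0.55 mDa) is material, and
agreement within ±0.0005 Da is treated as a match to a 4-decimal printed
value. ppm error is 10⁶·(observed − theoretical)/theoretical.

Formula enumeration is an exhaustive bounded depth-first search over integer
CHNOPS compositions (defaults C≤50 H≤100 N≤10 O≤20 P≤4 S≤4), pruned by
running mass against the target neutral mass implied by the ion rule.
Ring-and-double-bond equivalents are computed as C − H/2 + N/2 + 1 and only
RDBE < 0 is rejected — deliberately permissive, since tighter chemical
filters (Senior rules, element ratios) belong to dedicated formula-scoring
tools, not this candidate generator.

## Peak detection

Detection is a simplified centWave: the full wavelet machinery (fitgauss,
integration modes, firstBaselineCheck) is not reproduced, because detection
is a commodity stage here; the comparative and MS/MS layers are the point.
The detector shares centWave's parameter names and defaults — 4 ppm ROI
tolerance, 3–20 s peak width, S/N ≥ 3, prefilter of ≥ 3 scans ≥ 100 counts,
noise floor 0, wMean m/z centering — so settings translate directly.

Mechanics: all MS1 centroids are pooled and gap-clustered in m/z (a gap
larger than the ppm window at the current m/z starts a new region of
interest). Each ROI's per-scan trace is searched iteratively: take the
apex, descend on both sides until intensity falls below 0.5 % of the apex
or a local minimum is passed (those boundaries define rtmin/rtmax and the
trapezoidal area), then carve the peak *and its monotone tails* out of the
trace before looking for the next apex — carving only to the reported
boundaries leaves sub-threshold Gaussian tails that would be re-detected as
spurious peaks, while stopping at local minima preserves co-eluting
isomers. S/N is (apex − median of flanking trace) / max(sd of flanking
trace, 1); on a clean trace with empty flanks this degrades to the apex
intensity, which is the desired "obviously real" behavior. Reported m/z is
the intensity-weighted mean of the member centroids.

## Feature grouping and filling

Grouping mirrors XCMS `group.density`: peaks are binned in m/z, then
retention times within a bin are clustered by a Gaussian kernel density
(bandwidth `bw` = 2 s) cut at its local minima. A cluster becomes a feature
if it contains peaks from ≥ `minfrac` (0.2) of the samples of at least one
group and ≥ `minsamp` (1) samples; duplicate peaks from one sample keep the
maximum intensity (conservative and deterministic). The m/z binning is
sorted gap-clustering at `mzwid` (0.002 Da) rather than XCMS's overlapping
sliding bins: deterministic, order-independent, and equivalent whenever
features are separated by more than the bin width, which the generator
guarantees and real orbitrap data usually satisfies at this width.

Filling integrates the raw EIC at the feature m/z (±3 ppm) over the feature
RT range widened by ±3 s and reports the maximum intensity (area optional),
never touching detected values; filled cells are flagged so the operation
is idempotent.

Peak quality is this package's stand-in for an idealized-peak-shape score
(the concept is established; no published formula exists to copy): per
sample, the Pearson correlation between the EIC window and a least-squares
Gaussian anchored at the apex, clipped to [0, 1] and averaged over samples
with signal. Correlation rather than residuals makes the score
scale-invariant. The fitted σ is bounded below by the scan spacing — a peak
narrower than the sampling grid is unphysical, and without the bound a
single noise spike fits perfectly. Windows with fewer than 4 points score 0.

## Comparative statistics

Missing intensities count as zero in group means, matching the
fill-then-compare workflow. Blank subtraction keeps a feature iff
mean(biological samples) ≥ 10 × mean(blanks); blank-absent features are
always kept. The t-test is Welch's unequal-variance two-sided test — the
robust default for the n = 3–6 replicate counts typical of metabolomics —
with no multiple-testing correction by default (Benjamini-Hochberg is an
opt-in function), since discovery cascades of this kind filter on
unadjusted p jointly with fold and intensity. Fold change divides by
max(control mean, ε) with ε = 10⁻³ × the smallest positive intensity in the
table, so features absent from the control (often the most interesting
discoveries) survive fold filters instead of dividing by zero. On null
data (no group effect, 20 % lognormal replicate noise, n = 3 vs 3) the
empirical p < 0.05 rate is ~3–4 %: Welch at n = 3 is slightly conservative,
within the accepted 3–7 % band.

Filter cascades are conjunctions evaluated against the parent table: "top
1.25 % by intensity" means the top percentile of *all* detected features,
not of whatever earlier predicates left over. The intensity percentile is
applied to the post-blank-subtraction table, and that choice is recorded in
provenance. ceil(fraction × N) features are kept, ties broken by feature id.

## MS/MS networking and patterns

Merging averages scans of one feature: peaks single-linkage-clustered
within 0.002 Da, merged m/z intensity-weighted, merged intensity the mean
of per-scan relative intensities (absent scans contribute zero),
renormalized to max 1. The cosine follows the feature-based molecular
networking convention: candidate peak pairs within the fragment tolerance
(optionally also shifted by the precursor mass difference — modified
cosine, off by default) are accepted greedily by descending intensity
product, each peak used once; the score normalizes by the norms over *all*
peaks, penalizing unshared intensity. Raw relative intensities are the
default weighting with square-root available by flag; both defaults are
deliberate choices where the convention in the field varies, and both are
surfaced in `NetworkParams`. The greedy matching reproduces matchms's
CosineGreedy scores exactly on spectra whose peak spacing exceeds the
tolerance (verified in the test suite).

Network defaults — cosine ≥ 0.7, ≥ 6 matched peaks, ≤ 10 edges per node,
≤ 100 nodes per cluster — are the GNPS-conventional values; the
simplification keeps an edge only when it is top-K for both endpoints, then
deletes weakest edges of oversized components until the cap holds
(deterministic, idempotent). Pattern search declares a hit when all (or a
configured minimum of) pattern elements are found: a fragment element
matches any peak within its tolerance above the minimum relative intensity
(default 0.01), a neutral-loss element matches a peak at precursor − loss.

## Label finding

For every feature with unlabeled-group signal and every n in the configured
range, a heavy partner must sit at m/z + n·Δ/|z| (Δ = 1.0033548 Da for
¹³C) within 5 ppm, co-elute within 5 s, and be ≥ 5-fold more abundant
(group mean) in labeled than unlabeled samples — absent unlabeled signal
counts as maximal enrichment. The 5-fold enrichment default is this
package's choice; published descriptions of such tools do not fix a value.
Charge 1 is assumed in the shift arithmetic (configurable). Full
isotopologue-envelope fitting and natural-abundance correction are out of
scope: the finder reports shifted partners, not fractional enrichment.

## Synthetic benchmarks: what they show

The generator plants Gaussian chromatographic peaks (σ = 3 s) on a 1 s scan
grid, with unit-mean lognormal between-replicate intensity noise (CV 0.2),
≤ 0.5 ppm m/z jitter, uniform noise centroids (20 per scan, exponential
intensities of mean 30), and one clean MS2 scan near each apex for
compounds with planted fragment spectra. Compound m/z values sit on a
jittered grid with guaranteed separation, so grouping ambiguity is excluded
by construction; compounds closer than the resolvable spacing produce a
ground-truth warning rather than an error.

The bundled comparative benchmark is 4000 sample-derived compounds (plus
100 blank-only) across 3 wildtype + 3 mutant + 2 blank runs. Fifty
compounds are planted 20-fold mutant-enriched: the discovery filter is
fold ≥ 10, and a true fold exactly at a threshold is recovered only ~half
the time under sampling noise, so the planted effect represents the
"ten-fold or more" enrichment regime the cascade is meant to catch — a
power consideration settled before the benchmark was frozen. Their base
intensities place them in the top intensity percentile, as strong
biological signals are in practice. At these conditions the full pipeline
(detect → group → fill → blank subtract → Welch → fold/p/top-1.25 %
cascade) recovers ≥ 90 % of the planted set with zero false survivors over
seeds 1–5, and blank subtraction removes exactly the blank-only plants.

Passing these benchmarks shows the pipeline's bookkeeping, thresholds and
statistics behave as specified on resolvable, Gaussian, aligned data. It
does not demonstrate robustness to retention-time drift (alignment is out
of scope; runs are assumed aligned), peak tailing, isotope envelopes,
adduct ladders, chimeric MS2, or detector saturation — real-data concerns
that the quality score and tolerances only partially absorb.

## Problem sizes and determinism

Test and benchmark sizes (4000-feature runs, 50-spectrum networks,
2500-feature null tables, 1000-draw noise-model checks) were chosen so the
whole suite runs in about a minute on one core while keeping binomial
confidence intervals comfortably inside the asserted bands. All randomness
flows from explicit integer seeds through `numpy.random.default_rng`; the
same seed yields byte-identical runs, and the workflow driver's outputs are
hash-stable across reruns.
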