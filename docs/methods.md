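# Methods

This note documents the models, rules and numerical choices behind
`nailseq`, what the synthetic-data generator does and does not emulate, and
the design decisions taken where more than one reasonable reading existed.

## Coordinates and interval algebra

All coordinates are 0-based half-open (BED). Two intervals overlap iff they
share ≥ 1 base; "within d bp" means edge-to-edge distance ≤ d, with overlap
counting as distance 0 (bedtools-closest semantics). `merge_within(g)`
joins neighbors whose gap is *strictly* below g, transitively; with g = 0
only strictly overlapping intervals merge, so touching intervals stay
distinct. Set subtraction and width fractions treat their inputs as base
coverage (internally unioned); intersection-selection keeps whole elements,
never clipping, so hits and misses always partition the input exactly.
Shuffled intervals keep their chromosome and length and may overlap each
other — the simplest null for occupancy expectations.

All four operations are fuzz-tested against a per-base brute-force oracle
(boolean base arrays / naive pairwise rules) on random small genomes.

## Binned coverage and normalizations

Reads are assigned to bins by fragment midpoint — symmetric, count-
conserving, and insensitive to fragment length at the 1–5-kb bin scales
used. Normalizations: RPM_i = c_i·10⁶/T; RPKM_i = c_i·10⁹/(T·bin_bp);
RPK is raw reads/kb, optionally rescaled to a reference library size
(10⁷ reads for the human nascent-RNA densities, 10⁶ for mouse). Fold
change is (t+ε)/(c+ε) with a configurable pseudocount (default 1 count
equivalent) to keep sparse control tracks finite. Z-scores are genome-wide
with population SD, computed over all bins excluding chrY/chrM (matching
the peak-calling exclusions) and applied to every chromosome. The final
short bin of each chromosome is retained and length-weighted in interval
means rather than silently dropped.

## Peak calling

**Islands.** Eligible 5-kb windows (read count upper-tail Poisson
p < level against the genome-wide mean rate) are chained into islands
tolerating ≤ 3 ineligible windows between eligible ones — a window/gap
scheme in the SICER tradition (-w 5000 -g 3). The eligibility level
defaults to 1e-5, chosen so that islands mark high-confidence
first-label territory: at the package's simulated depths a background
window essentially never qualifies, while any window with several-fold
enrichment always does. The level is a parameter for other depth regimes.

**Dual-label (E−B) caller.** ΔEB = E − B per 5-kb bin, both RPM. Bins with
ΔEB > 0.3 seed peaks; extension runs through contiguous bins with ΔEB
strictly > 0; candidate regions must be strictly longer than 20 kb and
have ≥ 50 % of their length covered by islands ("falling in" EdU
territory; the 50 % default tolerates island edge wobble, and a strict
containment mode is available via the parameter). Replicate support:
a peak counts as reproducible when it overlaps (≥ 1 bp) a peak in at least
one other replicate (any-pair rule, min_support = 2 by default); supported
peaks from all replicates are unioned, preserving extent.

**EdU/HU caller.** A fixed 1-kb-bin scan against the global Poisson rate
(no local rate, no shift model — the regime the original MACS14 flags
`--nolambda --nomodel` select), upper-tail p < 1e-5. Adjacent candidate
bins fuse into candidate peaks. Fold enrichment is the candidate peak's
read density divided by the *background* density, computed over
non-candidate bins only: with strong planted peaks on a small genome the
global density is dominated by the peaks themselves, which would deflate
every fold estimate — against the intent of an enrichment test "against a
random Poisson background". (On real genomes, where peaks occupy a tiny
fraction of bins, the two denominators coincide to within a percent.)
Peaks with fold ≥ 400 are gap-merged (10 kb default; 20 kb is the
documented alternative convention for a second cell line), merged peaks
below 10 kb are discarded, and peaks on chrY/chrM or touching a blacklist
interval are removed whole.

**ERIZ definition.** ERIZs are EdU/HU peaks overlapping an E−B peak
(element selection); non-ERIZs are the rest. Each peak is annotated with
its length-weighted mean replication-timing value; > 0.5 is labelled
early, otherwise late, with "unknown" reserved for peaks without timing
coverage (no imputation).

## Transcription context

Human activity rules: active = promoter nascent-RNA density > 0 and
gene-body RPK > 4; silent = zero promoter density and RPK ≤ 1; mouse:
active = RPK > 1, silent = RPK 0; everything else is intermediate. The
promoter extent feeding the density is an input to the table, not fixed by
the classifier.

Non-TRs are the gaps strictly between two active-gene footprint blocks
(overlapping active genes are unioned first) inside an A compartment; gaps
touching a compartment edge lack a second flank and are dropped. The
display/statistic set keeps 20–100-kb gaps, optionally restricted to those
overlapping an ERIZ. For the density statistic, the non-TR and both flank
bodies are trimmed by 200 bp at each end (excluding TSS/TTS
neighbourhoods); flank reads are summed and divided by summed flank
length; the ratio is log2((d_ntr+ε)/(d_tr+ε)) with ε defaulting to half a
read over the combined assessed length so sparse regions stay finite.

The rank-sum test delegates to the Mann–Whitney implementation: exact
enumeration for small untied samples (both n ≤ 25), tie-corrected
continuity-corrected normal approximation otherwise.

Heatmap matrices: midpoint mode covers midpoint ± 100 kb in 1-kb columns
with rows ordered by increasing region width; scaled mode maps gene bodies
onto 100 proportional columns with 50 real-scale 1-kb flank columns per
side, rows ordered by increasing gene width (smallest on top),
minus-strand rows flipped so transcription reads left to right.
Off-chromosome columns are NaN.

## Epigenetic predictor

A compartments are tiled from their starts into 50-kb windows; a final
partial window is kept when it spans at least half a window. A window is
labelled 1 on ≥ 1 bp ERIZ overlap. Per marker, the observed occupancy
p_obs of a window is the fraction of its 1-kb bins touching ≥ 1 peak.

The expected side comes from within-chromosome shuffles of the marker
peaks (10 by default, seedable). It is accumulated **on the log-odds
scale**: logit(occupancy) is computed per shuffled window and averaged over
the chromosome's windows and shuffles, and the score is
logit(p_obs) − E[logit(p_shuffled)] (natural log, pseudo-probability
ε = 0.01 guarding the {0, 1} endpoints). Averaging occupancies first and
taking the logit afterwards looks equivalent but is not: the logit is
concave over the relevant range, so a smooth expectation subtracted from a
noisy observed logit leaves a systematic negative offset (~−0.4 at the
package's densities) even for randomly placed peaks. Matching the noise on
both sides centres the null at zero, which is what a calibrated
enrichment score must do. The expectation remains chromosome-level.

Balancing keeps all positive windows plus an equal-count uniform draw of
negatives (single draw by default; multiple draws available for
coefficient averaging). The logistic fit is plain maximum likelihood via
IRLS with step-halving (guaranteeing a non-decreasing log-likelihood),
Wald standard errors from the observed information, a truthful convergence
flag, and a quasi-separation warning when fitted probabilities saturate.
Scores enter the fit raw (unstandardized); standardizing would rescale
coefficients without changing signs or ranks.

## Barrier analysis

RPK in sliding bins (1 kb advancing by 200 bp for the ± 5-kb default
locus geometry; 3 kb/300 bp for the wider variant) divided by the mean RPK
of the B compartments on the same chromosome — a per-sample background
that cancels depth differences exactly (doubling all reads leaves ratios
unchanged). Only fully contained bins are reported, so offsets are
symmetric with spacing equal to the slide. The up/down test takes, per
replicate, one ratio for the 2-kb bin immediately upstream and one
immediately downstream of the site — upstream meaning the side the
polymerase arrives from, set by the locus orientation — and applies a
two-sided equal-variance Student's t-test across replicates (the classic
reading of an unpaired "Student's t-test"; pairing is not assumed).

## The synthetic-data generator

The generator is the package's test substrate; its defaults are the study
conditions used by the test suite and the acceptance script.

Geometry: 2 chromosomes × 25 Mb; alternating A/B compartments of
1.5–2.5 Mb; A compartments tiled with genes (30–80 kb) separated by
gene-free gaps (60–140 kb — wide enough that planted zone widths follow
their own distribution rather than being truncated by the host gap);
70 % of genes active, 25 % silent, the rest intermediate, with nascent-RNA
densities drawn to satisfy the activity thresholds exactly. Fifty zones
with lognormal widths (median ≈ 70 kb, σ = 0.25, clipped to 30–110 kb)
are planted only in gaps flanked by two active genes, with a 2-kb margin;
infeasible requests raise rather than silently relax. A perturbation
switch relocates a stated fraction of zones into active gene bodies,
emulating replication invading transcribed chromatin after transcription
disturbance.

Signals (Poisson throughout, 150-bp fragments, midpoint-binned):
dual-label background 4 reads/kb with 10× EdU enrichment over zones and
10× BrdU enrichment over 25-kb outward-displaced flanks (the order of
15-min fork travel; a simulation knob, not a biological claim); EdU/HU
background 0.1 reads/kb with 1000× zone concentration, so the ≥ 400-fold
filter is exercised from both sides; marker peaks (2 kb) inside zones with
probability 0.8 (positive marker) or inside zone-distal active gene bodies
with probability 0.8 (negative marker — active genes within 50 kb of a
zone are excluded, because zone-flanking genes are active by construction
and a marker placed there would co-locate with the zones it is meant to
avoid), both over ~1 background peak/Mb; a timing track at 0.75 over A,
0.25 over B, Gaussian noise σ = 0.05; barrier loci at 5 reads/kb with a
5× 2-kb upstream pile-up in blocked mode and 3 replicates.

What passing tests show — and what they do not. The generator reproduces
the *structure* the callers assume (zone pile-ups, displaced second label,
sparse HU background, transcription-shaped marker placement, replicate
noise), so end-to-end recovery demonstrates that the rules are implemented
coherently and are well calibrated for their own signal model. It does not
model mappability, GC or copy-number bias, overdispersion (a
negative-binomial switch exists for robustness checks but is off by
default), fragment-length variation, or the RPM scale of gigabase genomes:
on a 50-Mb genome the background RPM per 5-kb bin (~20) is far above the
real-genome scale where the 0.3-RPM seed threshold acts as a noise floor.
Specificity on synthetic data therefore rests on the island constraint and
the 400-fold filter — exactly the pipeline's own design — rather than on
the seed threshold, and performance numbers on synthetic data should not
be read as expected performance on real libraries.

Problem sizes in the shipped tests and acceptance script (50-Mb genomes,
5–50 seeds per check, 10 shuffles per enrichment estimate) were chosen as
the smallest sizes at which each statistical check is comfortably powered.

## Known limitations

* The EdU/HU scan is an explicit Poisson surrogate for the original
  MACS 1.4 behaviour, not a bit-exact re-implementation; likewise the
  island caller for SICER. Sub-bin peak boundaries are not resolved.
* RPKM tracks do not replicate any particular tool's edge-bin behaviour
  bit for bit; the final short bin is kept and length-weighted.
* Interval algebra is strandless; strand lives only on gene records.
* The flank density in the non-TR statistic uses full (trimmed) flanking
  gene bodies; no maximum flank distance is imposed.
* BAM/BigWig input is out of scope: readers consume BED, bedGraph, TSV
  and chrom.sizes text.
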