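# Methods

## The rhythm test

Rhythmicity is tested nonparametrically in the JTK_CYCLE family.  For a
series x(t_1..t_n) and a cosine reference template with period T and lag
L, the reference ranks are those of cos(2π(t − L)/T) at the sampled
timepoints (rounded to 9 decimals before ranking, so symmetric phases
tie exactly).  The statistic is

    S = #concordant − #discordant pairs,

taken over index pairs untied in the reference; pairs tied in the data
contribute zero.  τ divides S by the number of pairs untied in both
reference and data.

**Exact null.**  Under the null the data are an exchangeable random
ordering, so the concordant-pair count K (with S = 2K − M, M the number
of reference-untied pairs) is distributed as the number of "crossings"
of a uniformly random permutation of a multiset whose group sizes are
the reference's tie-group sizes.  Its generating function is the
Gaussian (q-)multinomial coefficient, which factors into q-binomials
[s_k choose t_k]_q over the groups; we build each q-binomial by the
lattice-path recurrence f(i,j) = f(i−1,j) + q^i f(i,j−1) and convolve.
This is the Jonckheere–Terpstra null for the reference's tie pattern.
Two-sided p = P(|S_null| ≥ |S|); P(|S| ≥ 0) is pinned to exactly 1.
The DP is exact for n ≤ 50 (counts stay well inside float64); longer
series fall back to a seeded permutation estimate.  A brute-force
enumeration over all n! orderings is the test oracle for n ≤ 7.

**Template grid.**  Periods are restricted to integer multiples of the
sampling interval within the 20–28 h window (21/24/27 h at 3-h
sampling): reference ranks only exist at sampled phases.  Lags step by
the sampling interval in [0, T).  Templates with identical rank vectors
are deduplicated; the Bonferroni adjustment multiplies the minimum p by
the deduplicated template count, paying for the free amplitude/phase
search.  Ties in the minimum p break by larger |τ|, then larger signed
τ, then smaller period, then smaller lag.  The signed-τ level exists
because the two-sided test cannot distinguish a template from its
antiphase, and for 21/27-h periods the antiphase lag is **not** on the
3-h lag grid — without the extra level a discordant fit could claim the
phase.

**Reported lag.**  `best_lag_h` is the estimated peak clock time in
[0, 24): the winning template's lag, shifted by half a period when the
fit is discordant (τ < 0), then averaged over the two in-window peaks
(lag and lag + T, mod 24) since off-24 periods drift across the two
sampled cycles.  For a concordant 24-h fit this is the template lag
itself.

**Data ties and missingness.**  Missing entries are excluded pairwise;
for features with missing values the reference ranks and tie pattern are
recomputed on the observed subset.  The exact null conditions only on
reference ties (conservative for modest data ties); when more than 25%
of a feature's pairs are data-tied, a seeded permutation p (10,000
draws) replaces the exact null.  All-tied or <4-point features pass
through with p = 1.

**Amplitude.**  The published tests in this family fix no amplitude
estimator; we
use half the contrast between the mean of values at the winning
template's top-quartile reference ranks and at its bottom-quartile ranks
(non-canonical, recorded as such).

**Thresholds.**  p_adj < 0.1 defines the cycling proteome layers and
p_adj < 0.05 the cycling transcripts, both strict.  Whether the
published convention gates on a raw or search-adjusted p is ambiguous;
both are reported and the gate uses p_adj (the conservative reading).

## Normalization

iBAQ → FOT divides each column by its total over non-missing entries (a
plain fraction; no ppm scaling, since downstream z-scoring is
scale-invariant).  z = (x − μ)/σ is computed per feature within each
24-h cycle, with the sample (n−1) standard deviation — the convention
for 8 points per cycle.  σ = 0 or <2 observed points in a cycle sets
that cycle's entries to missing rather than 0: a constant feature
carries no rhythm information and must not enter the rank test as
fabricated ties.  Whether the two cycles are standardised jointly or
separately is ambiguous in the source convention ("of one cycle");
per-cycle is the default, `joint=True` is available.

## Time phases

TP1..TP4 are half-open 6-h bins anchored at ZT0 after mod-24 reduction;
daytime is ZT0–12 (lights on).  The TP-specific rule reads "more than
twofold greater than the rest" in the stronger per-TP sense — the peak
TP's mean must exceed fold × the mean of **each** other TP — which
guarantees a unique assigned TP; a pooled-rest mode is available.  TP
means are computed on the FOT scale (fold ratios are meaningless on
zero-centred values), pooling both cycles.  Peak times use the rhythm
table's lag for rhythmic features and the cycle-averaged argmax
otherwise.  The day/night screen selects FC = max/min of day and night
means strictly above 5; a zero minimum yields infinite FC, selected and
flagged.

## DR-TF nomination

"Controls the diurnal rhythmicity of its downstream target genes" is
concretised as a one-sided hypergeometric enrichment of rhythmic targets
against the transcriptome background, with defaults min_tg = 3 and
enrich_alpha = 0.05 (no threshold is stated in the source convention;
both are configurable and recorded in the manifest).  Target sets are
joined across layers by exact, case-sensitive gene symbol.  Edge signs
use Pearson r over the 16 timepoints, pairwise-complete, strict at
±0.5.  Ubiquitylation cross-tabs report percentages over rhythmic /
non-rhythmic TFs and the unions of their target sets (a shared target
counts once); empty denominators are undefined, never 0.  The
resampling test draws same-size TF sets without replacement and reports
the add-one estimator p = (1 + #{null ≥ obs})/(n_iter + 1), which never
returns 0.

## Network analyses

Shortest paths are unweighted BFS; unreachable pairs are excluded from
per-substrate means rather than assigned a pseudo-distance.  "Pair
tailed Student's t" is read as a paired two-tailed t-test; path
comparisons pair by substrate, correlation comparisons pair by Mediator
subunit (average r per mediator within each TF group), since the
original pairing unit is unstated.  Identical correlation sets return
t = 0, p = 1 rather than erroring (all-zero differences with zero mean
in the path comparison, by contrast, are a degenerate error).  Mediator
linking takes the k = 3 largest correlations, ties broken
lexicographically by mediator id.  Set enrichment is the hypergeometric
upper tail with BH correction across sets (configurable off).  PPI
edges are unweighted; confidence filtering is assumed upstream of the
supplied edge lists.

## The synthetic generator

Planted model: x(t) = baseline + amplitude·cos(2π(t − acrophase)/24) +
N(0, noise_sd), truncated at 0 for raw layers.  Design sizes mirror the
emulated study: 16 timepoints (ZT0..45, 3 h) for the main layers, one
8-point cycle for the ubiquitylome, four points (ZT0/6/12/18) for the
KC proteome.  Defaults: 40 TFs, half rhythmic; 8 targets per TF;
repressor fraction 0.3; snr (amplitude/noise_sd) 4.  noise_sd is the
*reference* amplitude (rel_amplitude × baseline) divided by snr for
every feature, rhythmic or not, so snr = inf is the noiseless limit.

Rhythmic TF acrophases cycle through the TP midpoints ZT1.5/7.5/13.5/
19.5 with relative amplitude 5 — an on/off DNA-binding pattern (the
emulated assay sees strong presence/absence across the day) under which
a planted TF satisfies the twofold TP rule with a comfortable noise
margin.  Because amplitude ≫ baseline, these profiles are generated
unclipped and truncated at zero by the generator itself;
`simulate_profile`'s `nonneg_clip` flag instead enforces the
conservative positivity condition baseline > 3(amplitude + 3·noise_sd)
for callers who need a guaranteed-inactive clip.  Targets of dominant
TFs oscillate around a positive baseline (relative amplitude 0.5) at the
TF's acrophase (+12 h for repressors) with independent noise — coupling
is by shared phase, not kinetic lag, because the downstream logic is
correlational.  KC "switcher" peaks are centred on the sampled day/night
bins (ZT3/ZT15) so the planted >5 fold change is decisive.
Ubiquitylation marks each TF/target with probability 0.08 (multiplied by
`ubi_rhythmic_tg_boost` for targets of rhythmic TFs; 1.0 = null).
Missingness is uniform at a configurable rate (no MNAR censoring).

What the generator does **not** emulate: intensity-dependent missing
values, peptide-level noise, isoform/phosphosite collapse, batch
effects, or non-sinusoidal wave shapes.  Passing recovery tests
therefore show correctness of the statistics under the planted model,
not robustness to every artefact of real MS data.

## Problem sizes and numerical choices

The validation suite uses: full permutation enumeration for n ≤ 7;
1,000 white-noise features for type-I error; 300 planted cosines at snr
2 for power/phase recovery; 40-TF studies for TP and DR-TF recovery; and
200 replicate null studies (40 TFs × 40 targets, 2,000 resamples each)
for calibration of the resampling p — sized so the union-count statistic
is effectively continuous, since the add-one estimator is conservative
exactly at the statistic's point masses.  Normalization invariants hold
to 1e−12; exact-null agreement with enumeration is at machine precision.
Output tables are written with deterministic ordering and float
formatting, and the manifest records config, seed and SHA-256 hashes, so
identical (inputs, config, seed) reruns are byte-identical.

## Known limitations

The test has essentially no power for 4-point layers under the
Bonferroni gate (minimum attainable two-sided p at n = 4 is 1/12);
the KC analysis is therefore the fold-change screen.  Period resolution
is the 3-h admissible grid {21, 24, 27} — the search window is honoured
but periods between grid points are attributed to a neighbour.  Gene
symbols are the only join key across layers; isoform- or site-level
identity is out of scope.
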