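# Methods

This note documents the models behind each pipeline stage, the parameters
that matter, what the synthetic-data generator does and does not emulate, and
the numerical choices made where the design was genuinely open.

## Binned genome and tracks

Coordinates are 0-based, half-open (BED/bedGraph convention). A genome is a
list of chromosomes with lengths; each chromosome has `ceil(length/bin_size)`
bins (default bin size 10 kb), the last possibly truncated. The global bin
index concatenates chromosomes in declaration order — order comes from the
chrom.sizes file, not lexicographic sorting, so indexing is stable. Tracks
are integer counts per bin; real-valued vectors carry an exclusion mask that
propagates through arithmetic as a union, so an unreliable bin never enters
any downstream aggregate.

## Sigma values

**Normalization.** `norm_b = sample_b / control_b × median(control over
reliable bins)`. The genomic-DNA control measures per-bin library and
mappability bias; the quotient cancels whatever bias the two libraries share.
Rescaling by the median control keeps values on the count scale. Bins whose
control count is below 25% of the median control are masked (`floor_frac`
parameter): there the quotient is dominated by control shot noise. The
operation is invariant to uniform control rescaling and linear in uniform
sample rescaling.

**Background model.** The background rate λ is the central-50% trimmed mean
of the unmasked normalized track (trimming keeps origin peaks from inflating
the estimate; at the default genome ~7% of bins are peak-covered, well inside
the trim). Sigma is `norm_b / sqrt(λ)` — a Poisson-noise unit. Sigma is *not*
mean-centered: background bins sit near `sqrt(λ)` (≈10 at λ=100) with
fluctuations of sd ≈ 1, and thresholds are therefore expressed as an excess
over `sqrt(λ)`. The exact scale of published sigma tracks produced by other
implementations may differ by a monotone rescaling; all operations here are
internally consistent with the definition above. At least 50 unmasked bins
are required, below which background estimation is refused.

**Adjusted sigma.** `aσ_b = σ_t,b − σ_0,b` against the matched no-release
(0 min) sample, masks united. Subtraction (rather than a ratio) preserves
sigma units, makes the 0-min profile identically zero and is antisymmetric —
the natural way to isolate synthesis that happened after release.

## Origin analysis

**Peak calling.** A bin is above threshold when unmasked and
`σ ≥ sqrt(λ) + min_sigma_excess` (default excess 3). Maximal above-threshold
runs separated by at most `merge_gap` (default 1) sub-threshold bins are
merged; merged runs with at least `min_run` (default 2) above-threshold bins
yield one locus at the argmax bin. The run requirement suppresses single-bin
noise excursions; with unit sigma noise the per-bin false-positive rate at
+3 is ~2×10⁻³ and consecutive pairs are rare. Defaults were chosen so that
recall and precision against planted truth both exceed 0.95 at the
generator's default noise settings; all three parameters are exposed on the
CLI. Because HU-arrest peaks are flat-topped (forks travel a similar short
distance in most cells), the argmax can fall anywhere on the block —
matching a call to a known origin therefore uses a tolerance of the HU travel
distance in bins (3 by default), and the union of NE and OE calls is
deduplicated at the same tolerance.

**Efficiency.** Maximum sigma within ±1 bin of the summit, floored at 0;
missing (NaN) when the whole neighborhood is masked. The maximum, not the
area, because under HU arrest peaks are narrow and height is the established
efficiency proxy. Note this is the *total* sigma including the `sqrt(λ)`
background level, not the excess.

**Classification.** `ρ = (eff_OE + 1) / (eff_NE + 1)`; `ρ ≥ 4` → Oi,
`2 ≤ ρ < 4` → intermediate, else CN. The pseudocount (exposed) stabilizes
near-zero NE efficiencies; with pseudocount 0 the rule is exactly
scale-invariant. Because efficiency includes the background level, the
generator plants OE fold changes on the same total-sigma scale (below), so
planted folds are recovered by this ratio.

**Correlation summaries.** Per class, paired efficiencies of two samples with
Pearson r as the headline (Spearman alongside); pairs with a missing value in
either sample are excluded and counted. Classes with <2 complete pairs or
zero variance report NaN.

## Fork dynamics

**Metagene.** Mean (adjusted) sigma at offsets −300..+300 kb (default) in
bin steps around a locus set, masked bins excluded per offset with the
contributing-origin count tracked; windows are clipped at chromosome ends.
Averaging is over the full supplied origin list by default (a class subset
can be passed instead).

**Progression rate.** The full width at half maximum of the profile (linear
interpolation between offsets, outermost crossings) is a robust fork-travel
summary: after release the labeled band sits at `hu + v·t` from the origin on
both sides, so FWHM ≈ 2(hu + v·t) and the slope of FWHM/2 against time is the
per-fork speed; the HU-travel intercept cancels. With two timepoints this is
exactly Δ(FWHM)/2 ÷ Δt. Any monotone width functional would serve; FWHM has
closed-form behavior on rectangles and triangles and ignores amplitude
changes. Confidence intervals are percentile bootstrap over origins (the
exchangeable unit; default 1,000 resamples, seeded).

**Fibers.** Rate = analog track length (µm) × `kb_per_um` ÷ pulse duration
(min). The µm→kb factor defaults to 2.0 for combed DNA and is exposed because
it is protocol-dependent; the IdU pulse default is 40 min. Group comparison
is a two-way fixed-effects ANOVA (genotype × condition, type-II SS via
statsmodels) followed by Fisher's LSD in its classical unprotected form:
pairwise t-tests on the pooled error mean square with the ANOVA residual df.
Significance tiers use the conventional star notation (\*, P<0.05 …
\*\*\*\*, P<0.0001; ns). A degenerate design (single-level factor or empty
cell) falls back to one-way ANOVA on the crossed grouping with a warning.
Quantiles everywhere are numpy's default linear interpolation between order
statistics (type 7), the common plotting default.

## MiDAS

Positivity: a mitotic cell is MiDAS-positive with ≥2 EdU foci (exact
rational arithmetic before the final float); 53BP1-body fractions use the
same machinery with a ≥1 threshold. Fractions from replicate experiments are
compared by two-way ANOVA (genotype × treatment) with Tukey HSD on the pooled
MSE via the studentized-range distribution (range parameter = number of
cells), controlling the family-wise error rate.

Region profiles: each region's sigma signal over its span plus flanks
(default 50% of the span per side — the flank size is a free choice, exposed)
is linearly interpolated onto a common 100-point relative axis so regions of
different sizes can be averaged and stacked. Heatmap rows are ordered
double-peak regions first by genomic size descending (ties by position),
then single-peak regions by their sigma value descending — interpreted as the
region's maximum sigma, switchable to the mean (`single_rank`).

## Synthetic-data generator

The generator produces every input with known truth and one seed; named
substreams make each output bit-reproducible and independent of the others.

* **Genome**: 2 × 25 Mb, 10 kb bins (5,000 bins). Desk-scale (every stage
  runs in well under a second) while keeping peak-covered bins a small
  fraction of the genome so the trimmed-mean background estimator sees an
  uncontaminated central mass.
* **Mappability bias**: lognormal (sd 0.25) with unit mean, shared between
  control and all EdU tracks, plus 2% unmappable zero bins — so control
  normalization removes the bias exactly in expectation, and masked-bin
  handling is exercised.
* **Counts**: gamma-Poisson (negative binomial), Var = µ + αµ², α = 0.001 by
  default (mild overdispersion typical of deep count data; α = 0 gives exact
  Poisson for oracle tests). EdU background depth 100 reads/bin; control
  depth 2,000 (genomic-DNA controls are sequenced deep precisely so the
  quotient adds little noise).
* **Origins**: 50, uniformly placed with ≥150 kb spacing and a 400 kb margin
  from chromosome ends (so release bands and metagene windows stay in
  bounds); two thirds CN, one sixth intermediate, one sixth Oi. NE peak
  height above background uniform in [8, 80] sigma — a broad efficiency
  range, as in real origin sets, which is what makes within-class rank
  structure detectable. HU-arrest peaks are rectangles of half-width 30 kb
  (~3 bins): the rectangle makes width-based tests exact; real peak shapes
  are rounder but similarly compact.
* **OE fold changes**: planted per class (CN 1×, intermediate 3×, Oi 6×) on
  the *measured* total-sigma scale: the OE amplitude is chosen so that peak
  σ_OE = fold × peak σ_NE. Planting folds on the excess-amplitude scale
  instead would make a 6× fold measure as ~3× once the sqrt(λ) background
  offset enters the ratio, and planted labels would not be recoverable by the
  classification rule itself.
* **Release timecourse**: at time t the 30-min terminal EdU label occupies
  offsets [hu + v·(t−30), hu + v·t] outward on both sides of each fired
  origin; the 0-min sample is the HU-arrest track (identical stream, so the
  two generators agree bin for bin). With dNTP coupling c, the effective
  speed is v·(n_fired/n_total)^−c and the per-bin label density scales with
  the effective synthesis rate (dNTP-limited incorporation). Averaged over a
  fixed origin list, the amplitude ratio of a genotype firing a fraction f of
  origins is f^(1−c): c = 1 conserves total synthesis exactly, so the
  "fewer-origins → stronger early recovery signal" regime requires c > 1;
  the validation uses c = 1.5 with f = 0.6.
* **Fibers**: per-fiber rate ~ Normal(1.2, 0.3²) kb/min truncated positive,
  applied to both analog pulses (equal 40-min durations, so the IdU/CldU
  ratio centers on 1), with 3% lognormal measurement noise per track.
* **MiDAS**: 20 non-overlapping regions of 100–600 kb, half double-peak
  (signal blocks covering 20% of the span at each edge — synthesis initiated
  by the two converging forks) and half single-peak (one centred block);
  focus counts per cell are Poisson (mean 1.5 by default).

**What the generator does not emulate**: alignment artifacts, GC bias beyond
the shared mappability factor, replication-timing structure, fork stalling
and asymmetry at the single-molecule level, cell-to-cell firing-time
dispersion (peaks are population rectangles), or between-replicate batch
effects. Passing tests therefore demonstrate that the quantification stack
is correct and calibrated under a faithful noise model — not that any
specific biological dataset will meet the same effect sizes.

## Validation problem sizes

The recovery benchmarks (`eduseq.benchmarks`, run by the acceptance script
and test suite) use: 10,000 background bins for the sigma calibration; the
default 50-origin genome for origin recovery, replicate agreement, fork-speed
recovery (timepoints 30/90 min, planted 1.0 and 1.5 kb/min, 100 bootstrap
resamples) and the dNTP-regime check; 1,000 replications of a 2×2 design with
n = 10 per cell for the LSD type-I calibration; n = 50 per group for the
3-sd power check; 200 fibers and 1,000 cells for the rate-mean and
focus-fraction recoveries. These sizes put Monte-Carlo noise comfortably
inside the stated tolerances while keeping the whole validation under a
minute.

## Known limitations

* Sigma magnitudes are implementation-specific up to a monotone rescaling
  (the sd estimator of other pipelines is not fully specified); comparisons
  should always be within-implementation.
* Efficiency uses total sigma, so fold ratios saturate toward 1 for peaks
  near background; the pseudocount further shrinks ratios of weak origins.
  This is deliberate (it suppresses spurious Oi calls) but means fold
  thresholds act on a compressed scale for weak origins.
* The FWHM-based speed assumes the labeled band stays inside the metagene
  window and that origins are far enough apart that neighboring bands do not
  merge; at release times beyond ~150 min on the default genome both
  assumptions degrade.
* Fisher's LSD is unprotected by construction (per-comparison α), matching
  its classical definition; use the Tukey variant when family-wise control
  is wanted.
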