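# Methods

## The estimation problem

An asynchronous culture of budding yeast measured on a Coulter-type
channelyzer yields a binned histogram of cell volumes: channel sizes in
femtoliters, strictly increasing with non-uniform spacing, counts per
channel. Because division is asymmetric, newborn daughters are the
smallest cells and sit left of the histogram mode; the mode itself
approximates the largest daughter size. Birth size is estimated
population-wise: x_b(q) is the channel at which the cumulative count
over the daughter interval [x₀, x_d] first reaches a fraction q of that
interval's total. The method is deliberately coarse — parameters are
channel values with error x_p ± (x_{p+1} − x_p) — and makes no attempt
to deconvolve the daughter and mother subpopulations; the left-of-mode
partition *is* the method under study.

Everything downstream is non-parametric: Spearman rank correlations of
x_b against per-strain phenotypes within small/normal/large categories,
and two-sample comparisons of category means (Welch's t as the primary
test since means are being compared, Mann-Whitney U alongside because
screen phenotypes are skewed).

## Support detection (automated curation)

The original support interval [x₀, x_y] was curated by eye. The
automated stand-in declares a channel the support start when its count
and the counts of the next k−1 channels all reach α times the
histogram's maximum count:

- **α = 0.01** — debris channels carry on the order of a few counts per
  ~10⁴-cell acquisition while the mode carries hundreds; one percent of
  the peak separates these regimes without clipping genuine lower-tail
  daughters.
- **k = 3** — an isolated spike (one or two adjacent channels) is
  instrument debris; three consecutive above-threshold channels mark
  the rising flank of the true distribution.

x_y is the last occupied channel. A per-strain override table and an
exclusion list allow hand curation to be recorded as configuration and
make removals auditable (the pipeline manifest reports
ingested = pass + abnormal + excluded at every run). A profile is flagged
`abnormal_no_daughter_range` when no channel satisfies the start rule or
the mode falls at the support start (monotone-decreasing profiles),
which leaves no daughter interval; these testable conditions are this
package's proxy for the visually-identified abnormal profiles, not a
reconstruction of them.

Two definitional choices are exposed as options because the source
convention is implicit: the mean x_m is computed over [x₀, x_y] with
frequencies renormalized there (noise excluded) by default, with an
all-channels option for sensitivity; and mode finding accepts an odd
moving-average window (default off) to mimic by-eye smoothing of ragged
histograms, with ties breaking to the smaller bin.

## Category schemes

- **wt_sd**: small iff x_b < μ_WT − 2·SD_WT, large iff x_b > μ_WT +
  2·SD_WT, with the sample SD (n−1) over wild-type replicates. The rule
  is stated with strict inequalities, so boundary equality maps to
  normal. The strain's (binned) x_b is compared to the continuous
  threshold.
- **quantile**: the empirical tail order statistic (rank ⌈tail·n⌉, no
  interpolation) of the mutant x_b pool; because x_b is bin-valued,
  every strain sharing the boundary bin is included, so tails can
  slightly exceed the nominal 5%. Wild-type replicates are excluded
  from the pool by default (an option includes them).

Both schemes partition the qc-pass mutant set; labels are monotone in
x_b by construction.

## Statistics

Spearman ρ uses midrank ties with the large-sample t approximation for
the two-sided p; an exact enumeration p is available for n ≤ 10.
Missing phenotypes are dropped pairwise per analysis cell; cells with
fewer than 3 complete pairs report ρ as missing rather than vanishing.
Fitness is an ordinal rank (1–21) and enters rank-based analyses only.
No multiple-testing correction is applied by default (raw ρ and p are
reported); a Holm adjustment over the group comparisons is available.
Boxplot summaries report both mean and median; figure boxes draw the
band at the *mean*, matching the screen's presentation.

## Synthetic panels

The generator emulates what the method assumes about the data, with
known ground truth:

| parameter | default | rationale |
|---|---|---|
| wt_birth_mean | 23.7 fl | wild-type population birth size at the 20% cutoff |
| budding_ratio | 35/23.7 | budding at ~35 fl (elutriation-calibrated) |
| wt_birth_cv | 0.12 | cell-to-cell birth-size variability within a strain |
| daughter_fraction | 0.55 | at least half of a proliferating population is newborn daughters |
| mother_daughter_ratio | 1.6 | mothers centred well right of their daughters' birth size |
| replicate_cv | 0.04 | culture-level spread of wild-type replicates (≈ 0.99/23.7) |
| strain_cv | 0.05 | biological spread of unperturbed deletion strains |
| cells_per_strain | 20 000 | a typical acquisition |
| grid | 80 channels from 8 fl | intervals ramp linearly over the instrument's 0.385662112–1.203735813 fl range |
| noise_rate | 40 counts | low-channel debris per strain |

Per strain, daughter volumes are lognormal with median B·√r (B the true
birth size, r the budding ratio) and log-SD combining the birth-to-
budding growth spread (ln r / 4, so ±2σ spans one growth interval) with
the per-cell birth CV; mother volumes are lognormal with median 1.6·B
and 1.8× the daughter log-SD — mothers are an age mixture over many
past cycles, and the broader right-hand component keeps the mixture
unimodal with its mode at the daughter peak, the shape the left-of-mode
partition assumes. Volumes are binned to the nearest channel; Poisson
debris is added only to channels below the daughter component's 0.1
percentile, mirroring real pre-x₀ noise. Planted mutants scale B by a
known multiplier; %G1 is baseline 50 plus 1.7 percentage points per fl
of birth-size deficit for planted-small strains (≈ +10 %G1 at a ×0.75
effect) with SD-3 Gaussian noise; fitness rank is 1 + Poisson(2),
worsened by 5 ranks for outliers; published mean size is the analytic
mixture mean plus SD-0.5 noise. All draws flow from one seed;
identical spec + seed is bit-identical.

What the generator does *not* emulate: time-resolved growth or
mother-age structure beyond the two-component mixture, strain-specific
distribution shapes (bimodal or long-tailed abnormal profiles),
channelyzer saturation, or plate/batch effects. Passing recovery tests
therefore show the pipeline is correct *under the model's assumptions*,
not that the heuristic is unbiased on arbitrary real profiles — on the
generating model itself the extracted x_b sits slightly above the
continuous 20%-of-daughter-mass point (about half a channel), because
counts-per-channel on a widening grid shift the apparent mode rightward
and the cumulative sum includes whole bins.

## Numerical conventions

- Birth-size threshold comparison is "≥", endpoint bins included on
  both sums; no interpolation.
- Mode ties break to the smallest bin; the last channel's error bound
  uses the preceding interval (no successor exists).
- Frequencies normalise to 1 over the full channel range (1e−9
  tolerance in tests); x_m renormalises over the support.
- Quantile categories use ceil-rank order statistics, then bin-level
  tie inclusion; label priority small before large in the degenerate
  tail = 0.5 case.
- Counts may be non-integer (scaled instrument exports); all
  downstream math uses frequencies.

## Problem sizes

The test suite and the acceptance script run the oracle sweep at 1000
randomized histograms, the analytic-limit check on one 10⁶-cell strain,
recovery on a 500-mutant screen at 20 000 cells per strain, and the
type-I calibration over 1000 null replicates at n = 50 per group —
sizes at which each check's verdict is stable across seeds while the
whole suite completes in well under a minute.

## Known limitations

- The support-start rule depends on α relative to the *maximum* count;
  a pathologically dominant debris spike raises the threshold and can
  flag an otherwise usable profile abnormal.
- With very high within-strain birth-size variability the apparent x_b
  overestimates the birth size of a substantial fraction of newborns;
  the generator's per-strain CV can be raised to study this, but no
  target values exist to calibrate against.
- The published-screen reproduction requires the original supplementary
  spreadsheet (see `data/README.md`); it is not redistributed here.
- The 17 historically removed abnormal profiles are expressible only as
  an exclusion list once identified; the packaged list is an empty
  template.
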