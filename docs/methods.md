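# Methods

`geckodiet` implements the quantitative workflow of a stomach-flushing
diet study of an insular bent-toed gecko (*Cyrtodactylus nigriocularis*):
prey-volume estimation, a diet-composition table scored with the index of
relative importance (IRI), nonparametric comparisons of diet between sex
and age groups, and an uncorrected p-distance check of barcode
conspecificity.  Because the study's raw per-item measurements were never
published — only per-category and per-group summaries — the package ships
a calibrated synthetic-data generator so every stage of the pipeline is
exercisable and testable end to end.

## Prey volume

Each prey item is measured for maximum length `L` and maximum width `W`
(mm, at 0.1 mm resolution).  Its volume is estimated as a prolate
spheroid,

    V = (4π/3) · (L/2) · (W/2)²   [mm³],

the standard approximation for elongated invertebrate prey.  `pi_mode`
selects full-precision π (default) or π = 3.14, the truncated value used
by the classic field protocol; percentage columns and the IRI are ratios
in which π cancels, so the choice only affects absolute volumes.

Items measured wider than long raise a warning but are kept: `W` and `L`
are maxima of possibly curled specimens, and silently dropping measured
items would bias the composition counts.

## The composition table and IRI

For each prey category `i`: `F_i` is the number of stomachs containing
the category, `N_i` the number of items, `V_i` the summed item volume
(per-item summation).  Percentages divide by column totals and the
importance index is the unweighted mean

    IRI_i = (%F_i + %N_i + %V_i) / 3.

Two `%F` denominators are offered.  `sum_of_F` (default) divides by
Σ F_i, the convention that reproduces the published table for this
species (e.g. Araneae 20/75 = 26.67%); `n_stomachs` divides by the number
of stomachs analysed, the commoner convention in the diet literature,
under which `%F` no longer sums to 100.

All percentages are carried unrounded; presentation rounds half away from
zero to 2 decimals, under which each percentage column and the IRI column
of the reference table sum to 100.00.  `composition_from_aggregates`
rebuilds the table directly from printed `(F, N, V)` counts so published
tables can be recomputed without raw data.

`rank_by_iri` sorts by descending IRI with ties broken by descending `N`
then category name.  It takes a `min_stomachs` filter because published
"most important prey" narratives usually set aside categories found in a
single stomach, whose IRI can be inflated by one large item (a single
earthworm or whip scorpion); with `min_stomachs=2` the ranking matches
the published six leading categories exactly, while the default strict
ranking places the single-stomach Lumbricidae sixth.

## Group comparisons

The inferential surface wraps `scipy.stats` with explicit method
selection:

- **Pearson r** and **OLS regression** for morphometric relationships
  (SVL–MW, SVL–BM, MW–BM) and body size vs. prey size; two-sided p from
  the t transform with n−2 df.
- **Kendall's tau-b** (tie correction in both margins) for body size vs.
  per-stomach prey volume; p exact by enumeration for tie-free n ≤ 10,
  otherwise the tie-corrected normal approximation.
- **Wilcoxon rank-sum / Mann–Whitney** for between-group contrasts of
  item length, width, volume, items per stomach and total volume per
  stomach.  The groups compared (males vs. females, adults vs.
  subadults) are independent samples, so the two-independent-sample form
  is used; both the rank-sum `W` of the first sample and `U` are
  reported because software conventions differ.  p is exact by
  enumeration when `n_a·n_b ≤ 400` and the pooled sample is tie-free
  (enumeration stays well under a second at that size), otherwise a
  normal approximation with tie-corrected variance and continuity
  correction.  Exact and approximate p agree within 0.02 on tie-free
  samples in that range (tested).

All tests are two-sided and no multiple-testing correction is applied by
default, matching standard practice in small-sample diet studies; the
per-item contrasts treat items as independent, which ignores any
within-stomach clustering beyond the category mixture.

## p-distance

`p_distance` counts differing sites over comparable sites between two
aligned sequences.  Columns with a gap in either sequence are always
excluded; the default `pairwise_delete` policy also excludes columns with
any IUPAC ambiguity code (the conventional default for uncorrected
distances), while `mismatch_if_incompatible` keeps them and scores a
mismatch only when the two codes share no possible base.  On gap-free
equal-length sequences the measure is a metric.  `max_divergence`
reports the largest off-diagonal entry as a percentage rounded to 2
decimals; 3 mismatches over 657 comparable sites — the alignment length
of the study's COI matrix — gives 0.46%.

## Synthetic data generator

The generator's defaults encode the study conditions; they are fixed and
not meant to be tuned per analysis.

**Specimens.**  51 individuals (15 males, 33 females, 3 subadults).  Per
group, (SVL, MW, BM) are drawn from a trivariate log-normal: each
marginal's `(μ, σ)` is matched in closed form to the published group mean
and SD, and the published inter-trait Pearson correlations (0.860, 0.948,
0.833) are imposed as the Gaussian correlation on the log scale (the
original correlation scale is not published; this choice is approximate
by design).  Rows violating `MW < SVL` are redrawn.  Values are reported
at the 0.1-unit field resolution.

Hard truncation to the published per-group min–max ranges is available
via `envelopes` but is **off by default**: those ranges are sample
extremes of n = 15/33/3, and no distribution supported on them can attain
the published SDs (any distribution on `[a, b]` has SD ≤ (b−a)/2, and a
truncated normal at most (b−a)/√12; the male SVL range 79.77–112.31 gives
a 9.39 mm ceiling against a published SD of 10.39 mm).  Matching the
published moments was judged more important than clipping to the
published extremes.

**Prey counts.**  Items per stomach follow a zero-truncated negative
binomial (every flushed stomach contained food; SD 8.42 > mean 7.98 rules
out Poisson).  The underlying NB `(r, p)` is solved numerically so the
*truncated* distribution has exactly the target mean and SD.

**Categories and dimensions.**  Categories are i.i.d. multinomial with
probabilities proportional to the published per-category item counts (22
categories).  Per category, `(log L, log W)` are bivariate normal with a
shared category offset `s_c = (log v̄_c − Σ p_c log v̄_c)/3` derived from
the published mean item volume per category `v̄_c = V_c/N_c` (volume
scales as `L·W²`, so a common shift `s` on both log dimensions shifts log
volume by `3s`); large-bodied categories (Lumbricidae, Achatinidae)
therefore generate large items.  The within-category log-SD and grand
log-mean have closed forms making the pooled raw-scale mean and SD of the
mixture match the published pooled moments (length 7.53 ± 6.55 mm, width
1.44 ± 1.10 mm) exactly before discretisation.  The within-category
correlation between log L and log W defaults to 0.7 — unpublished; chosen
once as a realistic shape constraint that makes `W > L` draws rare —
and `W ≤ L` is enforced by resampling.  Dimensions are rounded to 0.1 mm
with a 0.1 mm floor, emulating the measurement protocol.

**Group effects.**  `group_effects` applies per-group multipliers to
item length/width or to the count model for power studies.  The default
is no effect: between-group contrasts on default synthetic data are null,
which is what the type-I-error acceptance check exercises.  The real
study reports significant sex differences in prey size; reproducing those
would require the unpublished per-sex size distributions, so they are
emulated only on request via explicit effects.

**What the generator does not emulate:** spatial/transect structure,
seasonality (the study sampled a single month), within-stomach
correlation of prey categories, measurement error beyond the 0.1 mm
rounding, and empty stomachs.  Passing tests on synthetic data therefore
validate the computational pipeline and its statistical calibration, not
ecological conclusions about the real population.

## Numerical choices and degenerate inputs

- Percentage/IRI presentation rounds half away from zero to 2 decimals;
  computation is unrounded throughout.
- A single observation reports SD = 0 with n = 1 rather than NaN.
- Constant vectors raise typed errors in correlation/regression; all-tied
  vectors raise in tau; zero comparable sites raise in p-distance.
- The NB moment solve and the correlation Cholesky raise `ConfigError`
  on infeasible configurations (e.g. a non-positive-definite correlation
  matrix).
- Problem sizes in the test and acceptance runs: 100 replicate datasets
  at study scale (51 stomachs) for the type-I-error check, ~10 000 items
  / 30 000 specimens for parameter recovery, alignments up to 1000
  columns for the p-distance oracle — sizes at which the checks'
  binomial/3-SE bands are informative while the whole suite runs in
  seconds.

## Known limitations

- One published cell (Apidae %V = 2.09) recomputes to 2.10 from the
  printed, rounded `V` column: the source evidently divided by its
  unrounded volume total, which the printed table no longer contains.
  Every other printed percentage and all IRI values reproduce exactly at
  2 decimals.
- The published rank-sum statistic for item length (W = 110 at
  n = 164 vs 217) is inconsistent with any standard convention (the
  minimum possible rank sum for the smaller sample is 13 530); only the
  direction and significance of such contrasts are used in synthetic
  checks.
- Subadult inference is unstable at the study's n = 3, and the generator
  deliberately keeps that group size.
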