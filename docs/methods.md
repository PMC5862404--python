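# Methods

## Model and procedure

The unit of analysis is the species × park × season × RCP *key*. Each key
carries 12 climate-suitability values: one per GCM (4 CMIP5 members:
CanESM2, CESM1-CAM5, HadGEM2-ES, MIROC-ESM) in each of three time periods —
the present baseline (2000–2010), an intermediate window (2011–2040)
included only to steady the trend estimate, and mid-century (2041–2070).
Suitability is a species-distribution-model output in [0, 1]; its
derivation, and the derivation of the species-specific TSS thresholds, are
upstream of this package and taken as given.

**Trend fit.** The 12 values are pooled into one OLS regression of
suitability on time, so the slope is the average trend across the GCM
ensemble. Time is coded as the calendar-year midpoint of each period —
2005, 2025.5, 2055.5 — making β₁ interpretable in suitability units per
year and preserving the unequal spacing of the windows. An ordinal coding
(0, 1, 2) is available in `ClassifierSettings.period_years` for sensitivity
checks; on noiseless linear trajectories the two codings can classify
borderline-significance keys differently because the regressor spacing
changes the slope's standard error.

**Classification.** Crossing rules are evaluated on the across-GCM period
means and take precedence over the trend test: an upward threshold crossing
is potential colonization regardless of slope significance (the crossing
itself is the event of interest; a strict variant requiring a significant
positive slope is available via
`colonization_requires_significance=True`), while a downward crossing
counts as potential extirpation only when the negative trend is itself
significant — extirpation is defined as a subset of worsening, so a
non-significant downward drift classifies as stable or worsening, never
extirpation. The significance level α defaults to 0.05, the field's
convention. Degenerate fits never raise: constant input reports slope 0 and
p = 1 (stable); a numerically perfect non-constant fit (residual variance
≤ 1e-12 of total) reports p = 0.

**Inclusion rule.** A species enters a park's analysis only if its climate
is suitable there at present or by mid-century (same period means as the
crossing rules — one definition of "suitable at present" throughout).

**Turnover.** Present list = species with present-period mean ≥ threshold;
future list = present − potential extirpations ∪ potential colonizations.
Binary Bray-Curtis over the two lists equals the vector-form Bray-Curtis on
0/1 abundances indexed by the union (restricting or extending the index set
with species absent from both lists changes nothing, so the choice of
universe is immaterial for binary data). Undefined cases are flagged as
NaN, never silently zeroed: turnover when both lists are empty, proportions
when present richness is 0, the realization fraction (extirpations per
colonization) when a park has no colonizations; flagged parks are excluded
from cross-park means with a logged count.

**Park summaries and aggregates.** Proportions use present richness as the
denominator (colonizing species are not yet in the park). System-wide
aggregates report mean ± SE (sample sd, n−1, over √n) per season × RCP;
the ">25%" park counts use strict inequality; the
colonizations-exceed-extirpations count compares raw species counts, not
proportions; the realization fraction is averaged per park (mean of ratios,
not ratio of means). Year-round counts — species currently suitable only in
summer whose winter climate becomes suitable by mid-century — are defined
per park × RCP and attached to both season rows.

**Typology.** For one stratum (summer/RCP8.5 by default) parks are placed
in the (prop_colonization, prop_extirpation) plane. Quantiles are computed
across the cohort with linear interpolation of order statistics (the common
default; the choice only moves parks lying exactly between order
statistics). The intermediate-change region is the axis-aligned
interquartile rectangle, evaluated before the median splits; a
rotated-diamond alternative (the L1 ball inscribed in that rectangle) is
available via `geometry="diamond"` since the region is sometimes drawn as a
diamond — the two geometries agree on the joint median and differ only in
the rectangle's corners. Ties exactly at a median resolve to the low-change
side. Labels are relative to the cohort: rescaling all proportions by a
positive constant leaves every label unchanged.

**Comparative statistics.** The seasonal contrast applies a Shapiro–Wilk
gate (α = 0.05 on each sample) choosing between a two-sample t-test and a
Wilcoxon rank-sum; the rank-sum (Mann-Whitney) form is the default because
the contrasts reported downstream are between park sets, and the W
convention matches R's `wilcox.test` (pair count for the first sample). A
paired variant (same parks in both seasons) exists behind `paired=True`;
the unpaired form is the default reporting convention. Exact rank-sum
p-values are used when both samples have ≤ 25 observations, otherwise the
normal approximation with continuity correction. Latitudinal analyses are
simple OLS of a park metric on latitude with Alaska excluded by default
(the study design has no parks in the latitude gap north of the contiguous
states); r² equals the squared Pearson correlation. Regional contrasts use
one-way fixed-effects ANOVA, df = (k−1, n−k), with a median-centered Levene
test reported alongside (a screen, not a gate: heteroscedasticity is
reported, the ANOVA still runs), and each region is also compared to all
other parks with a two-sided rank-sum ("region versus the system mean" is
not well-defined for a rank test against a constant, so region-vs-rest is
the operationalization). No multiple-testing correction is applied to the
per-test p-values; `holm_adjust` is provided for users who want one.

## Synthetic scenarios

The generator emulates the statistical structure the pipeline consumes —
4-member ensembles over 3 periods with bounded park-mean suitabilities —
with known ground truth. Per key it draws a planted class, positions a
linear mean trajectory against the species' threshold *t* so that a correct
classifier must recover the class, then adds independent N(0, noise_sd²)
noise per GCM × period and clips to [0, 1]:

* crossing classes move from *t* ∓ Δ/2 to *t* ± Δ/2, where
  Δ = slope_scale × 50.5 yr is the full excursion (slope exactly
  ±slope_scale);
* improving/worsening keep both endpoints at least Δ/2 from *t* on one
  side; stable draws a constant mean at least Δ/2 from *t*.

Defaults: `noise_sd = 0.01`, `slope_scale = 0.002`/yr (Δ ≈ 0.10, so the
crossing margin is ≈ 5 noise standard deviations and the slope t-statistic
is ≈ 14 — detectable but not degenerate), thresholds uniform on
(0.25, 0.75), and class mix (improving 0.25, stable 0.10, worsening 0.25,
potential extirpation 0.20, potential colonization 0.20): the crossing
weights echo typical per-park colonization/extirpation proportions under a
high-emissions pathway, and stable is the minority class because by
mid-century most trajectories trend detectably in that regime. Under these
defaults recovery is 100% without noise and ≈ 99.5% with it — the residual
errors are planted-stable keys whose fitted slope is spuriously significant
at rate α, an irreducible property of the trend test, not of the generator.
Park metadata apportions regions by largest-remainder rounding of the real
regional park counts (16, 39, 82, 36, 44, 18, 39 across Alaska, Pacific
West, Intermountain, Midwest, Southeast, National Capital, Northeast) and
draws coordinates uniformly in region-typical bands, Alaska strictly above
54°N so the Alaska-exclusion rule is always exercised.

Structural draws and noise draws come from separate seeded streams, so
scenarios differing only in `noise_sd` share trajectories and correlated
noise; the recovery-vs-noise curve is therefore monotone by construction.

What the generator does **not** emulate: spatial autocorrelation among
parks, inter-species correlation (shared climate drivers), GCM-specific
biases (noise is exchangeable across members), season asymmetries, and
non-linear suitability trajectories. Tests passing on synthetic data
therefore certify the pipeline's arithmetic and decision logic, not the
ecological realism of any projection.

## Numerical choices and degenerate inputs

* Incomplete keys (< 12 cells) are a hard error by default; `permissive`
  drops them with a warning rather than regressing on fewer points.
* Longitude is stored signed (negative = west) regardless of the "°W"
  phrasing common in descriptions of the study area.
* Canonical CSV serialization (fixed column order, LF endings, 6
  significant digits for derived reals) makes pipeline reruns byte-identical;
  input tables are round-tripped at full precision.
* Problem sizes in the test suite and acceptance script (5 000-key recovery
  cohorts, 1 000-replicate null simulations, a 274-park study scenario with
  40 species) were chosen so each check has enough resolution to detect the
  failure it guards against while the whole suite stays quick to run.

## Known limitations

* The regression treats the 12 values as independent observations; in real
  ensembles the four GCM values per period are not exchangeable draws, so
  reported p-values understate uncertainty to the extent that members are
  systematically offset.
* Classification is per-key and ignores spatial or phylogenetic pooling;
  no shrinkage across parks or species is attempted.
* The typology depends on the cohort analysed: subsetting parks changes the
  quantiles and hence labels.
* The comparative layer reports uncorrected per-test p-values by design;
  with ~dozens of tests per run, some significant results are expected
  under the null.
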