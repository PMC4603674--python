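# Methods

## Scope and unit of analysis

`cogtrend` operates on *published group summaries* — one mean and SD per
demographic group × subject × survey year — not on student-level data.
There is no psychometric modeling (no IRT, no equating, no measurement
error in the anchors): the pipeline takes the assessment program's
scale as given and re-expresses it.

## Standardization

Raw means are mapped to an IQ-like metric by anchoring a benchmark
group-year at `target_mean`/`target_sd` (default 100/15). The benchmark
defaults to the largest group (White) at the earliest survey wave with
full group breakdowns (mathematics 1978, reading 1980), which makes the
metric comparable to conventional IQ anchoring around 1979; the formula
itself is benchmark-agnostic and any group/year can be configured. Two
identities are enforced by tests: the benchmark maps exactly to the
target mean, and k benchmark SDs map to k target SDs (the map is
affine-equivariant, so linear transformations of the raw scale cancel).

Subjects surveyed in offset years are merged into display cohorts
("1978/80") by greedy earliest-first pairing within a configurable gap
(default 2 years); unpairable waves become singleton cohorts with a
warning rather than being dropped. Combined cohort values are the plain
arithmetic mean of the per-subject standardized values. Groups with
insufficient data are removed only via an explicit exclusion list.

## Trend estimation

Slopes are ordinary least squares of standardized score on calendar
year (via `scipy.stats.linregress`), fitted **per subject on that
subject's own survey years**, then averaged across subjects. This
ordering matters: with offset survey years, fitting the combined cohort
series on cohort display years gives a different (wrong) slope — for
the packaged White series ~0.070 instead of the correct 0.0465 — and a
regression test enforces the distinction. Period windows are inclusive
at both ends.

The trajectory intercept is deliberately **not** the regression
intercept: each model is anchored at the observed level of the last
survey year (2012 in the packaged data), so projections start from what
was actually measured rather than from a fitted line's value there.
Two fitting windows ship as defaults — the full 1978/80–2012 window
(steeper, "optimistic") and 1992–2012 (flatter, "pessimistic") — as a
built-in stability check on the extrapolation. No standard errors or
prediction intervals are produced: the source tables carry none, and
the projections are deterministic scenario arithmetic, not inference.

Best/worst scenarios substitute the maximum/minimum group slope for
every group, bounding what is attainable if all groups matched the
fastest (or slowest) observed trend. Slope ties are broken by the
configured group order, deterministically.

## Projection and weighting

Population values are share-weighted means of group values with shares
linearly interpolated between tabulated years; requesting a year
outside the table raises rather than extrapolating. Because the
modeled groups cover only 94–97% of the census totals (small categories
are excluded), shares are **renormalized per year** over the modeled
groups. This is not cosmetic: only renormalized weights reproduce the
published population rows (99.50 in 2012, 103.17 in 2060), and the
decomposition identity below requires weights that sum to one.
Negative projected changes are legitimate outcomes and are never
clamped.

## Decomposition

The four-term split of projected population change (baseline trend,
minority catch-up, composition, interaction) is exact by construction:
an algebraic property test verifies `e_base + e_minor + e_pop + e_pm`
equals the directly projected change to 1e-9 on 1,000 random
slope/share configurations, not just the packaged inputs. The
catch-up term uses **baseline-year** shares; the variant weighted by
horizon-year shares is a different quantity (≈2.8 instead of 1.79 at
2060 under the optimistic window) that breaks additivity, and a test
pins the distinction. Frozen shares zero `e_pop` and `e_pm` exactly;
homogeneous slopes zero `e_minor` and `e_pm` exactly.

Per-decade rates divide unrounded totals by decades elapsed
(48 years → 4.8). Reported tables round half-up to 2 decimals; "total
increase" rows are computed from unrounded endpoint levels first and
rounded once.

## Economic conversion

One standardized point is valued at $810 per capita per year
(2010/2011 purchasing-power-parity dollars), applied linearly at
constant prices — no inflation and no baseline economic growth, so the
dollar figures are a surplus attribution, not a GDP forecast. Published
dollar figures in this literature are derived from effect components at
their printed 2-decimal precision; `economic_summary` follows that path
using its own computed components. One component sits on a rounding
boundary: the pessimistic catch-up effect computes to 2.0353 from the
printed 4-decimal slopes, which rounds to 2.04 where the source's
unrounded internal slopes gave 2.03 — shifting that dollar figure by
$8 (1,652 vs 1,644). The components themselves agree to ±0.01
throughout; the discrepancy is purely input-precision rounding.

## Synthetic data generator

`SyntheticScenario` emulates the study's data shape: four groups, two
subjects offset by two years across eleven waves (1978–2012), linear
true trajectories `anchor + slope·(y − 2012)` on the standardized
scale, i.i.d. Gaussian survey noise added in standardized units and
mapped to the raw scale through the inverse standardization, raw SDs
fixed at the benchmark SD, and linearly drifting shares. Default
parameters mirror the packaged tables (subject slopes, 2012 anchors,
census share endpoints); the raw-scale benchmark means/SDs (300.4/34.9
mathematics, 293.1/41.3 reading) are plausible values on a 0–500
achievement scale and only fix the affine map, which cancels in all
standardized-scale results. `noise_sd` defaults to 0.5 standardized
points, the magnitude of the wobble around linear trends visible in the
packaged series.

Recovery experiments standardize with the scenario's *known* benchmark
parameters rather than re-deriving them from the noisy benchmark
observation — otherwise the scale is re-anchored to the benchmark
group's own noise draw and level recovery could not be exact even at
zero noise. All randomness flows from a single integer seed through
spawned `numpy` generator streams, making every dataset and experiment
bit-reproducible.

What the generator does **not** emulate: sampling design and school
clustering (survey noise is i.i.d. across cells), scale drift or
re-equating between waves, nonlinear trends, and share paths with
census-style curvature (synthetic drift is linear). Passing recovery
tests therefore demonstrate correctness of the pipeline arithmetic and
the estimator's behavior under clean Gaussian noise — not robustness to
the correlated errors of real assessment programs.

## Numerical choices

* OLS requires ≥2 points with distinct years; zero year-variance raises
  a degenerate-design error rather than returning NaN.
* Reporting uses half-up (away-from-zero) decimal rounding via
  `decimal.Decimal`, matching how published tables are rounded;
  banker's rounding would flip boundary cells.
* Golden-table comparisons use ±0.01 after rounding to printed
  precision. Two packaged cells sit on rounding boundaries relative to
  the source's unrounded internals (the optimistic 2060 population,
  103.178 vs printed 103.17, and the pessimistic worst-case total,
  −1.0955 vs printed −1.09); both are within the ±0.01 band.
* Share sums may fall below 1 but never exceed it (tolerance 1e-9);
  zero share sums raise instead of dividing by zero.
* Test problem sizes: property tests use up to 12-point series and
  4-group share tables; sampling-distribution checks use 200 replicate
  datasets, enough for the analytic-SE comparison at 20% tolerance.

## Known limitations

* Linear extrapolation over half a century is a strong assumption; the
  two windows and best/worst bounds frame, but do not quantify,
  model uncertainty.
* Anchoring at a single observed year makes projections sensitive to
  sampling error in that year's survey, which is not modeled.
* The packaged share projections embed their source's fertility,
  mortality and migration assumptions; no alternative series ships.
* The participant-share weighted "average" column of the packaged
  standardized table cannot be reconstructed from printed information
  and is excluded from all computations and checks.
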