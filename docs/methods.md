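# Methods

## Thermal-time models

Chilling is accumulated with the Utah chill-unit model: each hour
contributes a piecewise-constant weight of its temperature band —

| band (°C)        | CU/h |
|------------------|------|
| < 1.5            | 0    |
| [1.5, 2.5)       | +0.5 |
| [2.5, 9.2)       | +1   |
| [9.2, 12.5)      | +0.5 |
| [12.5, 16)       | 0    |
| [16, 18]         | −0.5 |
| > 18             | −1   |

Bands are lower-bound inclusive except the warm boundary at 18 °C, which
still belongs to the −0.5 band (the −1 band is strictly above 18 °C).
The table is a `ChillTable` value and can be swapped in configuration.
Running totals are a plain sum by default; a `floor_at_zero` option resets
negative running totals to zero for users who prefer that convention —
the two differ only when warm autumn spells precede chilling.

Heat is accumulated as growing degree hours: `GDH(T) = 0` for `T < 6`,
`min(T, 25) − 4.5` otherwise, i.e. base 4.5 °C, lower threshold 6 °C, cap
25 °C. The response is linear with slope 1 on [6, 25] and constant (20.5
°C·h) above.

Accumulation windows are inclusive of both endpoint hours, with one
deliberate exception: the chilling requirement counts the hours strictly
before the break date, so a break 500 h into a constant 1-CU/h series is
exactly 500 CU. Gaps in the hourly record of at most 3 h are filled by
linear interpolation in time; longer gaps contribute nothing, and if more
than 5% of window hours are absent from the source record a coverage
warning is attached to the result.

## Dormancy break and chilling requirement

A forcing test holds cut shoots a week in a growth chamber (22 ± 1 °C,
12 h photoperiod — recorded as metadata, not simulated) and compares the
mean fresh weight of ten forced buds with ten field buds sampled the same
day. The break criterion is a ratio of group means — forced/field ≥ 1.30 —
with an inclusive boundary; bud-level pairing is impossible because
sampling is destructive. The break date is the earliest test date
satisfying the criterion, so its resolution equals the sampling cadence
(weekly by default, but any strictly increasing date sequence is accepted).
The chilling requirement is the CU accumulated from the season start
(default September 21, configurable) to the break date. A single point
estimate is reported per cultivar-year; aggregation across years or shoots
is left to the user.

## Starch densitometry

A "color" is an axis-aligned RGB box: a pixel is starch iff each channel
lies within its inclusive [min, max] bounds. Optical density uses the luma
grayscale `I = 0.299R + 0.587G + 0.114B` (unrounded) and
`OD = log10(255 / max(I, 1))`, the standard transmitted-light form: white
is 0, saturated black caps at log10(255) ≈ 2.407. Any monotone alternative
can be substituted; results are comparable only within one OD convention.

A measurement frame is a square of fixed physical area (default 1337 µm²,
side `round(sqrt(area)/pixel size)` pixels) centered on a user-annotated
anchor; the frame anchors are deliberately user-supplied because automatic
ovary localization is out of scope. Per frame, OD is summed over masked
pixels inside the frame; the per-ovary value is the mean of its four
frames (summing instead of averaging would only rescale every downstream
statistic by 4), and per-date statistics use six ovaries.

Threshold calibration replaces an interactive raise-the-levels procedure
with a deterministic search: among RGB boxes with bounds on a quantization
grid (default step 5 intensity levels), maximize intersection-over-union
with a reference mask. Pixel counts inside any candidate box come from a
3-D integral color histogram, so each candidate costs O(1). When the
candidate count is small enough (coarse grids) the search is exhaustive and
therefore exactly optimal on the grid; otherwise a deterministic coordinate
ascent starts from the tightest grid box enclosing the reference colors and
refines one bound at a time to convergence. Ties are broken toward the
tightest, then lexicographically smallest bounds. The calibration result
records which regime produced it and the achieved IoU.

## Ovary growth

Cell layers are counted along an annotated transect of a
calcofluor-stained section: bright cellulose walls appear as intensity
peaks in the sampled profile, and n wall peaks delimit n − 1 layers. Peaks
must be at least 2 µm apart (configurable) with prominence at least 20% of
the profile's intensity range; a flat profile counts zero layers. The
ovary diameter is the transect's Euclidean length times the pixel size.

## Statistics

One-way fixed-effects ANOVA across collection dates uses the classical
sum-of-squares decomposition. Zero within-group variance with unequal
means yields an infinite F flagged as degenerate; all-identical data is an
error.

Duncan's multiple-range test compares ordered means i < j with the
critical range `R_p = q(1 − (1−α)^(p−1); p, df_within) · sqrt(MSE/n)`,
`p = j − i + 1`, with studentized-range quantiles computed numerically
(scipy) and the harmonic-mean group size for unbalanced designs. Two means
are declared different iff their difference exceeds their `R_p`; letter
groups are the maximal contiguous runs of mutually non-different ordered
means. This is the pure pairwise form of the procedure: the classical
"containment" refinement (a difference inside an already-non-significant
span is never declared significant) is intentionally not applied, keeping
the letter display in exact one-to-one correspondence with the pairwise
rule; with k = 2 groups the test reduces to the single `R_2` boundary. By
default letters are only separated after a significant overall F (the gate
can be disabled).

Pearson correlations use the product-moment estimate with the two-sided
p-value from `t = r·sqrt((n−2)/(1−r²))` on n − 2 df. The two windows pair
per-date starch with cumulative CU for dates up to the break date and with
cumulative GDH (from the break) for later dates; windows with fewer than 3
dates or a constant variable are reported as undefined with a note. The
per-ovary (n = 6) values feed the ANOVA; per-date means feed the
correlations. Significance stars follow the usual convention (** for
p < 0.01, * for p < 0.05).

## Synthetic data

The generator emulates the study's structure, not its photographs.

*Climate.* Hourly temperature = seasonal mean + diurnal cosine (amplitude
3.4 °C, warmest at 14:00) + AR(1) noise (stationary sd 1.5 °C, coefficient
0.8). The seasonal mean holds an autumn plateau of 14.25 °C and then
follows a sine-squared decline to a 2.0 °C minimum 115 days after the
cooling onset, recovering into spring. The plateau sits in the Utah dead
band, and with the 3.4 °C diurnal amplitude its hourly excursions into the
+0.5 and −0.5 bands cancel exactly, so pre-onset weather is CU-neutral: a
"mild" winter, whose onset is delayed 20 days, reaches any cumulative-CU
threshold exactly 20 days later than the "cold" winter when noise is off.

*Forcing tests.* The expected forced/field ratio is logistic in cumulative
CU, rising from 1.05 to 1.6 around the planted requirement (scale 40 CU);
bud weights are normal (sd 4 mg) around date-level means (~60 mg, slowly
increasing). The ratio passes the 1.30 criterion within a few days of the
planted requirement, so recovery error is bounded by one sampling interval
plus bud-noise jitter.

*Sections.* Images are pale textured tissue (channels ≥ 140) with
elliptical granules whose per-pixel colors are drawn from a distinct RGB
band (R 40–90, G 30–70, B 60–110, recorded in the ground truth); granules
are added until they cover the requested fraction θ of the image, and the
exact mask is returned. The planted trajectory is θ = θ_max·CU/requirement
up to fulfillment and θ = θ_max·(1 − GDH/decay) afterwards, with per-ovary
noise of sd 0.02 (10% of the default θ_max = 0.2). The decay scale is, by
default, calibrated per season so that the relative decline over half a
sampling interval after fulfillment equals the relative rise over the half
interval before it; monotonicity of both accumulations then places the
planted starch maximum at the sampling date nearest fulfillment. When
fulfillment falls almost exactly midway between two sampling dates the
*measured* maximum can still land on the other neighbor through
ovary-level noise — a property of any noisy measurement near a tie.
Wall images plant 13 cell layers through endodormancy rising to ~20 by the
last date.

What the generator does not emulate: real histology (stain variability,
uneven illumination, out-of-focus granules, overlapping tissues), weather
reanalysis realism, or bud-to-bud biological covariance. Passing tests
therefore demonstrate that the measurement and inference chain is correct
and well-calibrated on data with the assumed structure, not that the
segmentation would survive arbitrary real-world staining.

## Problem sizes and numerical choices

Default study conditions follow the emulated design: biweekly sampling
October–March (13 dates), six ovaries × four frames per date, weekly
forcing tests from November 30, 96×96 px sections at 1 µm/px. The
requirement-recovery experiment uses 100 seeded winters (alternating
cold/mild); imaging fidelity uses a 20-point θ series. Band membership is
evaluated at full floating precision; calibration and Duncan ties are
broken deterministically as described; all generators are bit-reproducible
for a fixed seed.

## Known limitations

The paper-scale cultivar chilling requirements (~1000 CU) can only be
recovered on synthetic seasons: real hourly weather, bud weights and
micrographs for the original cultivars are not distributed. The Duncan
letters omit the containment refinement (above). Calibration at fine grid
steps is locally, not globally, optimal in adversarial color
distributions. Frames are squares; the original instrument's frame shape
is not documented beyond its area.
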