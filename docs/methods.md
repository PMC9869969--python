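# Methods

This note documents the models, estimators, defaults, and design choices
behind `repstress`, and what its synthetic-data calibrations do and do not
demonstrate about real data.

## The pulse-chase replication-completion statistic

**Assay model.** An asynchronous culture is pulsed briefly with EdU, so the
EdU-positive population is exactly the set of cells that were in S phase at
labeling time. Under steady-state cycling, their replication progress
`u` is uniform on [0, 1), so true DNA content at labeling is
`i_2n * (1 + u)` with mean midway between the 2n and 4n DAPI peaks. During
a recovery interval of length `T` each labeled cell advances at rate `r`
(genome fractions per interval); a cell reaching `u = 1` resides at 4n for
`g2_duration` and then divides instantaneously into two EdU-positive 2n
daughters. A full replication block (a hydroxyurea analog) is `r = 0`.

**The statistic.** Divided daughters appear as EdU-positive cells at 2n.
Because each division doubled their number, only half of them are counted,
each at the 4n intensity to represent a completed genome. Writing `W` for
this half-weight-adjusted mean DAPI intensity of the EdU-positive events
of one table,

```
F = (W(t) - W(t0)) / (i_4n - i_2n)
```

`F = 0` for a complete block and `F = 0.5` when the whole initial S-phase
population completed replication (its mean moved from the S midpoint to
4n).

**Divided-cell detection.** A pure DAPI window around 2n cannot separate
post-mitotic daughters from EdU-positive cells that were still early in S
phase: daughters form a peak *at* 2n while early-S cells form a flat shelf
starting *just above* 2n, and both land in any symmetric window. The
adopted rule therefore estimates the number of divided cells as the excess
of EdU-positive events inside the G1 window `i_2n * (1 ± w)` (default
`w = 0.2`) over the count in the adjacent equal-width reference band
`(i_2n (1 + w), i_2n (1 + 2w)]`, which samples the early-S shelf; the
excess is clamped at zero. That many events are remapped from the window's
mean observed intensity at weight 1 to the 4n intensity at weight 0.5,
using the weighted-mean identity (individual events need not be singled
out). The rule is applied identically at both time points, so a blocked
sample — identical DAPI distributions — gives `F = 0` exactly, and full
completion gives `W(t) = i_4n`, hence `F = 0.5`. In the transition regime
where a residual early-S shelf overlaps the reference band, the excess
estimate is conservative (it under-counts daughters); simulations across
the rate range show `F` remains monotone in `r`. The normalization by
`(i_4n - i_2n)` with the t0 reference mean is this package's normative
definition; the alternative normalization by `(i_4n - W(t0))` shares the
0.5-at-completion property under uniform progress.

## Cell-cycle gating

The 2n/4n anchors are the two dominant modes of a Gaussian KDE (Silverman
bandwidth) of log DAPI intensity, each refined off the evaluation grid by
bounded scalar maximization; restricting to EdU-negative events removes
the mid-S smear and sharpens both peaks. Modes below 5% of the dominant
peak height, or closer than a 1.4× intensity ratio to a stronger mode, are
treated as flank artifacts of the KDE — the genuine peaks sit at a ratio
of 2. A single surviving mode raises a degenerate-population error
carrying the mode, and a warning is issued when `i_4n` strays more than
30% from `2 * i_2n`.

EdU positivity is thresholded at the minimum-density valley between the
two dominant modes of log EdU intensity (modes closer than 1 natural-log
unit count as one population). For unimodal input the gate falls back to a
quantile threshold with a strict `>` comparison; at the default quantile
of 1.0 an all-negative sample yields no positive calls, with a warning.

Phase assignment: EdU-positive ⇒ S. EdU-negative events at or below
`1.2 * i_2n` ⇒ G0/G1, at or above `0.8 * i_4n` ⇒ G2/M (the low and high
tails clamp to the nearest window); between the windows ⇒ S under the
imaging context (an unlabeled mid-S nucleus) but flagged `intergate` under
the flow-t0 context, where the pulse should have labeled every S-phase
cell. Events below `0.5 * i_2n` are sub-G1 debris and are excluded from
phase fractions. Window half-width (20%), debris cutoff, and contexts are
configurable; the defaults cover ±4 standard deviations of a 5% CV
measurement.

## Imaging pipeline

**Scene model.** Rendered scenes place non-overlapping elliptical nuclei
whose total DAPI intensity is proportional to true DNA content (1×, 1.5×,
2× the 2n level for G0/G1, S, G2/M); EdU and p-ATM are uniform nuclear
fills; 53BP1 foci are Gaussian spots (σ = 1.4 px) whose kernel is
normalized over its support so the rendered pixel sum equals the requested
integrated intensity exactly; micronuclei are small DAPI disks placed at a
known edge distance from their parent, constrained so the parent remains
the nearest nucleus and micronuclei do not overlap each other (otherwise
the ground truth would be ambiguous). Pixel coordinates are 0-based
(row, column); intensities are arbitrary units.

**Registration.** Cyclic staining rounds are registered translation-only
by phase cross-correlation of the DAPI channel; the shift is applied to
all channels of a round, and a shift beyond a configurable maximum
(default a quarter of the image) raises a registration error.

**Segmentation.** Global threshold with Li's minimum-cross-entropy method
— chosen over Otsu because the dominant background fraction biases Otsu
upward enough to drop the dimmest (largest G0/G1) nuclei — followed by
hole filling and a watershed split seeded on maxima of the smoothed
distance transform (smoothing σ = 2 px, minimum peak distance 10 px).
Objects outside the nucleus size window (default 150–4000 px) are removed
from the nucleus map; DAPI-positive objects below it are candidate
micronuclei.

**Focus detection.** Multiscale Laplacian-of-Gaussian blob detection
(σ ∈ [1, 3], 5 scales) restricted to each nucleus mask, with overlapping
detections merged to the stronger maximum. The detection threshold
defaults to five times a lower-quantile noise estimate (median minus 16th
percentile) of the in-mask intensities — unlike a MAD, this is not
inflated when foci cover much of the nucleus. Each focus's support is the
disk of radius 4σ clipped to the mask, with contested pixels assigned to
the nearest focus; integrated intensity is the support pixel sum minus the
local median background (focus-free mask pixels) times the support size.
Two spots closer than roughly twice the rendered FWHM are optically a
single shoulder-merged blob and are reported as one focus carrying the
combined mass — the reference scenes therefore place foci at least 9 px
apart, and a dedicated test pins the merged behavior.

**Micronuclei.** Candidates inside the size window (default 1–15% of the
median nucleus area) within the association cutoff (default half the
median nucleus equivalent diameter) of a nucleus are assigned to the
nearest nucleus by exact edge-to-edge pixel distance, ties broken toward
the lower nucleus id; farther candidates are discarded with a reported
count. The assignment depends only on the label map, so it is
deterministic and independent of object ordering.

**Histograms.** The 1D focus-intensity histogram uses 16 log-spaced bins
spanning the observed range by default and reports per-bin mean focus
counts per cell, so the bins sum to the mean number of foci per cell. The
2D map arranges cells by increasing DAPI total, splits them into
equal-count position bins (default one per cell), and stores raw counts
with per-bin cell counts so that the marginal over the cell axis
reproduces the 1D histogram exactly (not merely to rounding). Phase
boundaries mark the first S and first G2/M cell in DAPI order.

**Statistics.** Micronucleus phase association reports the fraction of
micronuclei whose parent is in each phase (absent when there are none)
and a two-sided Mann-Whitney test comparing total focus intensity between
micronucleus-bearing and non-bearing G0/G1 nuclei. Condition-level
coupling of G0/G1 damage and micronucleus formation uses the Pearson
product-moment correlation over (mean G0/G1 focus intensity, mean
micronuclei per cell) pairs, requiring at least three conditions and
nonzero variance. Group comparisons elsewhere use the two-sided
Mann-Whitney test and, for dose ladders, Kruskal-Wallis with Dunn's
correction is the intended companion; no further multiple-testing layers
are added.

## Fiber statistics

A fiber is stalled when its CIdU tract length is at or below a threshold
(default 0 — the simulator's exact convention; real digitized data needs
a small positive threshold, exposed as an option). CIdU/IdU ratios are
computed per fiber over elongating fibers only. Stalled fractions carry
95% Wilson intervals. Group comparisons: two-sided Mann-Whitney (exact
for small samples) on IdU lengths and ratios, Fisher's exact test on the
stalled-vs-elongated table; the ratio test is skipped with a notice when
a group has no elongating fibers.

## Dose-response and synergy

The four-parameter logistic is fitted by bounded least squares on log10
dose; the reported IC50 is the relative (midpoint) IC50, robust when the
bottom plateau is above zero. Zero-dose wells are excluded from the
log-domain fit (the free top parameter absorbs the untreated anchor). A
viability trend that *increases* significantly with dose (one-sided
Spearman on per-dose means, α = 0.05) flags the fit; flagged fits carry
no IC50 and are refused by downstream consumers.

The combination index uses the 50%-effect isobole: `D1`, `D2` are the
single-agent IC50s, and for each fixed dose `d2` the re-fitted drug-1
series is inverted at drug 1's own absolute midpoint viability
`(top + bottom) / 2` to give `d1`, contributing
`CI_point = d1/D1 + d2/D2` (symmetrically for fixed `d1`). Inverting at
the absolute midpoint — not at the shifted curve's own relative midpoint —
is the convention under which exactly Loewe-additive data yield CI = 1.
A fixed dose that alone exceeds the midpoint effect cannot intersect the
isobole and is excluded with a notice; fewer than two valid points is an
error. CI is the mean over points, with their standard deviation and,
optionally, a seeded nonparametric bootstrap over wells (199 resamples)
reported as dispersion. With equal unit hill slopes the fixed-dose
combination curve is itself an exact 4PL, so the pipeline is exact there;
with unequal or non-unit slopes the 4PL is an approximation to the
combination curve and contributes a small (sub-percent in the simulated
configurations) model error to each point.

The sensitizing-dose helper returns the dose at which a fitted curve
predicts a viability loss at the midpoint of the screen band (20–45%
loss), mirroring the design of a fixed sub-lethal co-treatment screen.

## Synthetic-data generators: scope and defaults

The generators emulate the *statistical structure* each analysis relies
on, with exact ground truth and byte-identical output under a fixed seed:

- **Pulse chase** (defaults: 20,000 cells; phase fractions 0.50/0.35/0.15
  for G0/G1/S/G2M, a typical asynchronous line; `i_2n` = 100 a.u.; rate
  0.125 genome/interval ≈ an 8-interval S phase; recovery 7 intervals; G2
  residence 3 intervals; DAPI CV 5%; EdU log-intensity components at 7.0
  and 2.5 with spread 0.4). Multiplicative lognormal DAPI noise and a
  two-component lognormal EdU mixture are standard cytometry noise
  shapes. Unlabeled cells are a static snapshot during recovery: the
  completion statistic uses only EdU-positive events, so G1→S entry and
  unlabeled G2 division would not affect any consumer. Mitosis is
  instantaneous; daughters inherit the label.
- **Scenes** (defaults: 600×600 px, 50 nuclei of radius ~16 px, 0–10
  foci per nucleus with log-uniform intensities 200–2000, micronuclei at
  0.3 per nucleus at 3–10 px edge offset, additive Gaussian pixel noise
  0.2). No photobleaching, no illumination field, no 3D; inter-round
  drift is modeled only as integer-pixel translation.
- **Plates**: exact Loewe additivity solved per well by bracketed root
  finding (`brentq`, xtol 1e-13) on the effect level; synergy and
  antagonism are a single dose-potentiation factor α applied to both
  doses before the solve, never to single-agent wells — so the plate
  margins always follow the 4PL truths exactly. Per-replicate Gaussian
  noise, clipped at zero viability. No pharmacokinetics.
- **Fibers**: per-fiber stall Bernoulli, lognormal tract lengths around
  10 μm per labeling window (CV 0.3).
- **Damage populations** (record level, no rendering): Poisson focus
  counts and lognormal intensities growing with dose; micronucleus rates
  5× higher for G0/G1 nuclei and, within G0/G1, proportional to the
  cell's own total focus intensity — encoding the mechanism that damage
  carried through mitosis both brightens G0/G1 foci and sheds
  micronuclei.

Passing calibrations on these generators demonstrates that the estimators
are correct *under the stated models* — uniform S-phase progress,
lognormal noise, Gaussian foci, exact Loewe surfaces. They do not
demonstrate robustness to real-data pathologies: aneuploidy and apoptosis
distorting the DAPI axis, focus clustering beyond the merge scale,
out-of-focus micronuclei, edge effects in plates, or drugs with strongly
asymmetric dose-response shapes.

## Numerical choices and degenerate inputs

- KDE modes are refined by bounded scalar maximization (xatol 1e-10);
  equal-height mode ties resolve toward the lower intensity as `i_2n`.
- Loewe solves and isobole inversions use bracketed methods with
  tolerances several orders below the reported precision.
- Blank images segment to empty label maps (not errors); an empty nucleus
  mask, empty cell list, or zero-variance correlation input raises
  `ValueError`; degenerate DAPI densities raise a dedicated error type.
- Micronucleus association ties break toward the lower nucleus id; exact
  ties are measure-zero but the rule makes the behavior reproducible.
- All simulations consume a single `numpy.random.default_rng(seed)`
  stream; fixed seeds give byte-identical tables and images.

## Problem sizes

The shipped calibrations use 20,000-event cytometry tables, 600×600-px
50-nucleus scenes, 64-well plates, and 500-cell record-level populations
— sizes at which every Monte-Carlo tolerance in the test suite has
several-sigma headroom while the full suite stays fast enough for routine
development.
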