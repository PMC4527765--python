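# Methods

## Region classification and sequence parsing

A cell's pixels at frame *t* are partitioned by membership in the masks at
*t−1* and *t+1*: present in both → stable; absent before, present after →
protrusion; present before, absent after → retraction; absent in both →
short-lived. The verbal definitions of protrusion ("absent in the
previous") and retraction ("absent in the next") overlap on pixels absent
in both neighbours; we resolve this by letting the (prev, next) membership
pair define a strict partition, with short-lived taking that overlap. This
is forced by the bookkeeping: Dynamic Cell Area sums the three non-stable
categories, which must not double-count. Regions are plain pixel sets — no
connected-component labelling or minimum-size filter — and frames are
compared at their actual positions, never re-centred, so translocation
itself produces protrusion/retraction signal. Areas are reported in μm²
(default calibration 0.21 μm/pixel, 5 min/frame) with exact integer pixel
counts retained.

First and last frames of a sequence, and frames adjacent to segmentation
gaps, have undefined protrusions or retractions and are flagged invalid;
they are excluded from all downstream statistics. Speed at frame *t* is
the centroid displacement over the forward pair (t, t+1) — the attachment
convention is not dictated by the measure and the forward pair matches the
two-mask speed primitive. The centroid weights mask pixels uniformly
(masks are binary; no intensity weighting is available or wanted).

## Corrected Membrane Dynamics

One OLS line of Dynamic Cell Area on Cell Speed is fitted over all valid
observations pooled across cells; CMD is its residual. Pooling (rather
than per-cell fits) keeps CMD comparable across the population: a cell's
CMD says how its membrane activity compares with *any* cell moving at that
speed. The OLS identities — zero residual mean and zero residual–speed
correlation — are asserted as invariants, not tuned.

Speed autocorrelation is computed per trajectory: missing values are
replaced by the trace mean, the series is mean-centred, and the lag-ℓ
coefficient is Σₜ x(t)x(t+ℓ) / Σₜ x(t)² — the biased, zero-lag-normalised
autocovariance (the default of the familiar `xcov(..., 'coeff')`-style
routines; an unbiased per-lag rescaling is available via the estimator
argument of `trajectory_autocorrelation` if needed). The persistence score
is the mean over lags 1–12 (1 h at 5 min/frame); lag 0 is excluded since
it is identically 1 and would only shift, not reorder, cells. Traces
shorter than max_lag + 1 frames or with zero variance are excluded with a
warning; the length threshold is exposed because no canonical cut exists.

Conditional-density maps are bivariate histograms whose columns (x bins)
are renormalised to total 1 before log10, so the marginal density of the
conditioning variable is divided out.

## Cohort descriptors

Adhesion-complex (CMAC) features are summarised per cohort — all CMACs of
one cell at one time point — by quartiles q1–q3 and the derived
dispersion, skewness and variation statistics

    QD  = (q3 − q1) / 2          (semi-interquartile range)
    QS  = (q2 − (q1 + q3)/2) / QD   (Bowley-type skewness, QD-standardised)
    CoV = QD / q2

QS is undefined at QD = 0 and CoV at q2 = 0; both are emitted as NaN with
the cohort retained. Quartiles default to linear interpolation between
order statistics; the `method` argument passes through to `numpy.quantile`
for other conventions, and `literal_formulas=True` switches to the
alternative operator placement QD = 2(q3 − q1), QS = q2 − (q3 − q1)/(2·QD)
for sensitivity analysis. Intensity standardisation divides each CMAC
intensity by the per-experiment median intensity of the smallest 3
area-percentiles of CMACs (objects of ~0.15–0.2 μm², near the detection
limit); division rather than subtraction keeps ratio-type descriptors such
as CoV coherent, and makes the operation idempotent after the first pass
in the reference set.

## Archetype testing

Quintiles are assigned by rank with stable tie-breaking, so group sizes
differ by at most one; boundaries are computed on valid observations
pooled across cells. Pairwise quintile contrasts (1v3, 3v5, 1v5) use the
two-sided Wilcoxon rank-sum test: exact enumeration for tie-free samples
of ≤ 10 per group (relevant only in tests), otherwise the tie-corrected
normal approximation with continuity correction. The Bonferroni family is
450 = 3 contrasts × 150 features *per process* — the printed arithmetic
covers one process's regime; a joint 900-family can be requested through
the `family` argument for sensitivity. Significance is adjusted P < 0.001.
The significance triple alone determines the archetype category; direction
signs (sign of the median difference per contrast) are reported separately
because the archetype shapes abstract over sign.

## Two-step selection

Step 1 is a Kruskal–Wallis test per feature between quintiles 1/3/5
(family = number of features, per process, adjusted P < 0.001). Step 2
fits a canonical variate analysis on the full feature matrix restricted to
those three quintiles: with raw between-group scatter B and pooled
within-group scatter W, canonical vectors solve the generalized symmetric
eigenproblem B v = λ W v (at most two informative vectors for three
groups), normalised so canonical variates have unit pooled within-group
variance. Features are standardised to zero mean, unit variance before the
fit: loads are compared across features with wildly different units, which
is meaningless on raw scales. "Load" means the coefficient of the
standardised feature in the canonical vector; a feature's score is the sum
of squared loads over the retained vectors, and the top half (⌈p/2⌉,
inclusive at ties) passes. W is regularised by a ridge of 1e−8·trace(W)/p
when ill-conditioned (possible on synthetic inputs; the experimental
regime of ~1280 observations per quintile vs 150 features keeps W
invertible). Rows with any missing feature are dropped listwise for the
CVA; KW uses available values per feature.

## Synthetic data

The mask generator renders a star-convex cell, r(θ) around a moving
centre, on an integer grid. Per-frame centre displacements are rounded to
whole pixels so that a pure-translation movie is an exact pixel shift
(which makes partition/time-reversal tests exact). Protrusive bumps and
retractive notches are Gaussian wedges in θ whose areas are drawn
Poisson around the nominal rates, added via the exact wedge-area
quadratic so symmetric rates are area-neutral in expectation; a weak
relaxation (5% of the area excess per frame) keeps long runs bounded near
the base area. Consequently realised protrusion/retraction pixel counts
approximate, rather than exactly match, the nominal rates — adequate
because tests assert qualitative monotonicity, exact partitioning and
determinism, not rate calibration.

The table generator draws latent Cell Speed i.i.d. lognormal (median
0.15 μm/min, log-sd 0.7: heavy-tailed, positive, most cells slow) and an
independent Gaussian membrane-activity residual (sd 40 μm²); Dynamic Cell
Area is k·speed + m + residual with defaults k = 300 μm² per (μm/min) and
m = 60 μm², quantised to whole pixels so the pixel/area identity holds
exactly. These values were chosen once as realistic for the imaged system
and give a speed–DCA correlation near 0.74. Dynamic pixels are split into
protrusion/retraction/short-lived fractions with the protrusion share
decreasing in speed (`delta_coupling`, default 0.008, calibrated so the
net-Δarea-vs-speed correlation emulates the reported ≈ −0.3 coupling of
the experimental system: slow cells grow slightly, fast cells shrink).
Feature columns are planted transforms of the percentile rank of a latent
process plus unit Gaussian noise, with effect sizes in noise-sd units:
linear ramps; plateaus implemented as piecewise-linear ramps saturating at
the 40th/60th percentile (the quintile-3 boundaries); weak non-monotone as
a symmetric triangular bump peaking at the median. Cells are grouped into
pseudo-experiments (8 cells each) so per-experiment logic is exercisable.

What the generator does *not* emulate: temporal persistence (speeds are
i.i.d. per observation, so the autocorrelation–speed coupling observed in
real cells has no synthetic analogue and only the white-noise null is
testable); realistic feature–feature correlation structure beyond shared
latents; fluorescence intensities or CMAC sub-objects inside masks.
Passing tests therefore demonstrate correctness of the statistical
machinery under known ground truth, not biological fidelity of any
particular distributional choice — the study's published table carries no
distributional specification for individual features.

## Numerical choices and degenerate inputs

- Quintile assignment on constant vectors raises (quintiles undefined);
  features constant within a quintile are handled by the rank tests, not
  treated as errors.
- Wilcoxon on identical samples returns p = 1 under the exact method.
- Zero-variance speed vectors make the CMD fit unidentifiable and raise.
- Empty conditional-density columns are NaN, not 0 or −inf.
- Adjusted p-values are min(1, raw × family).
- All randomness flows through one `numpy.random.default_rng(seed)` per
  generator call; fixed seed ⇒ bit-identical outputs, and pipeline reports
  serialize with sorted keys so identical runs are byte-identical.

## Problem sizes

Synthetic study conditions use 50 cells × 100 frames = 5,000 observations
with 150 features (matching the order of the experimental 6,419
observations), with planted effects of 5 noise-sd where recovery is
asserted; smaller tables (≈400–3,000 observations) are used for unit-level
checks. These sizes give the nonparametric tests overwhelming power at the
planted effects while keeping the full suite fast.

## Known limitations

- The mask-dynamics stage is validated on synthetic masks only; the raw
  imaging experiments behind the published table are not reproducible from
  masks we can generate.
- XLSB workbooks are not read; convert to XLSX or a CSV triplet.
- The archetype Bonferroni family (450 per process vs 900 joint) and the
  CVA conventions (standardisation, coefficient-vs-structure loads) follow
  the defaults documented above; alternative readings are reachable via
  arguments but not exhaustively cross-tested.
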