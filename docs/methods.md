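# Methods

This note documents the models behind `patternoid`, the parameter choices
that matter, what the synthetic-data generator does and does not emulate,
and the numerical conventions used throughout.

## Coordinate frame and calibration

All morphometrics are computed in micrometres after pixel calibration, so
images acquired at different magnifications (0.569 and 2.27 µm/px are the
two calibrations the assay uses) give compatible results. Pixel grids are
indexed `[y, x]`, origin at the top-left pixel, pixel centres at integer
coordinates. A pixel counts as inside a circle iff its centre is inside
(half-open convention) — unambiguous and testable against analytic areas.
Cavity depth (200 µm) is metadata only; every analysis operates on 2D
z-projections.

## The five invasive parameters

Given a binary mask with cavity centre and radius r = 50 µm:

- **Non-invasive / invasive area**: pixel counts inside / outside the
  cavity circle times the pixel area. The normalized non-invasive area
  divides by the projected cavity area πr² (7854 µm² for d = 100 µm).
  Rasterization can push the measured disk fraction slightly above 1; no
  clipping is applied.
- **Maximum invasive distance** is measured from the cavity *boundary*
  (distance from centre minus radius), the reading that corresponds to
  penetration depth into the matrix. Measurement from the centre is
  available via `from_boundary=False`; the boundary convention is the
  default because "invasion into the matrix" is a depth beyond the wall.
- **Roots** (initial invasion events) are counted as 8-connected
  components of the mask within the annulus (r, r + w] just outside the
  boundary, keeping only components that also reach beyond the annulus.
  Placing the band strictly outside the boundary matters: a cavity filled
  to its wall would otherwise enter the annulus as a ring and connect all
  crossings into one component. The annulus width w defaults to 2 px
  expressed in µm — the thinnest crossing detectable at both supported
  pixel sizes. Two roots emerging closer than the band can resolve merge
  into one; this resolution limit is deliberate and tested.
- **Tips** are skeleton endpoints (exactly one 8-neighbour) outside the
  cavity, on a topology-preserving skeleton whose terminal spurs shorter
  than `min_branch_um` (default 10 µm, well below one cell diameter) are
  pruned as thinning artifacts. Isolated short segments without a junction
  are kept — they are branches, not spurs.
- **Branching factor** = tips/roots. For roots = 0 it is reported as
  missing (NaN) and excluded from cohort means; setting it to 0 would bias
  cohort averages with undefined ratios.

8-connectivity is used everywhere.

## Synthetic-data generator

The assay's microscopy data are not publicly deposited, so the generator
emulates the statistical structure the analysis assumes. It is first-class,
tested code, and every artifact is bit-reproducible given (parameters,
seed).

**Seeding.** Per-cavity starting cell counts are i.i.d. Poisson around the
seeding mean (default 20) — the depositing of singularized cells into
cavities is a classic Poisson thinning. c0 classes {10, 20, 30} ± 10 % are
applied downstream.

**Masks.** One patternoid = a filled central disk (the non-invasive body;
its radius realizes a drawn normalized non-invasive area) plus `roots`
bifurcating branch trees grown outward from evenly spaced, jittered anchor
angles. Each tree runs an unbranched trunk past the root-counting annulus
before its first bifurcation (one tree = one crossing), splits by angle at
each bifurcation toward pre-planned, evenly slotted tip positions (sibling
tips stay resolvable after rasterization), and keeps every branch segment
at or above 25 µm so real tips sit far from the 10 µm pruning threshold.
Strokes are capsules rasterized with sub-pixel accuracy, making branch
width in µm calibration-independent; the stroke's rounded cap is
compensated so the deepest rasterized pixel lands at the drawn maximum
distance. The returned ground truth (roots, tips, distance, pixel-exact
areas) is realized by construction, and the measurement pipeline recovers
it mask-for-mask up to rare rasterization merges (verified against
brute-force oracles over fixtures and 50 random seeds).

Distribution choices per subtype profile:

- roots: rounded normal, clipped at 0 (clipping mass is negligible at the
  configured means);
- branching factor: `1 + Gamma`, with shape/scale matched so mean and SD
  equal the profile values exactly. The support ≥ 1 is inherent (every
  root carries at least one tip); a normal law clipped at 1 would bias the
  mean upward by several percent at the epithelial/hybrid values;
- maximum distance: normal, floored at 75 µm (three minimum segments);
- invasive area (used for dose–response metric scales): log-normal. The
  published mesenchymal numbers have SD ≫ mean (23 971 ± 102 507 µm²),
  i.e. strong right skew; a normal law would produce negative areas. The
  printed SD itself is treated as a heavy-tail indication, not a target.

Profile means printed for the assay's three subtypes are used directly:
branching factors 3.15 ± 0.965 (M-16992), 1.61 ± 0.530 (Mlow-8028),
1.56 ± 0.507 (E-9591); roots 4.8 ± 1.699 (M), 4.15 ± 2.492 (Mlow),
7.5 ± 3.725 (E); maximum distance 379.7 ± 96.1 µm (M). Quantities not
printed for E and Mlow (maximum distance, area scales, non-invasive
fractions) were fixed once at field-plausible values consistent with the
published ordering (E least invasive with the fullest cavity, Mlow
intermediate with thick branches at 12 µm vs 5 µm for the thin fractal M
branches, 6 µm for E): E distance 150 ± 50 µm, Mlow 250 ± 85 µm;
non-invasive fractions 0.90 / 0.70 / 0.55 (E / Mlow / M).

**Time series.** The non-invasive fraction follows a saturating-growth
curve b + (plateau − b)(1 − e^(−t/τ)); invasive area is zero before the
subtype's invasion onset, then grows monotonically. Parameters realize the
published dynamics: Mlow plateaus at 40 % after ~27 h (τ = 8.5 h), E is
steepest and passes ~70 % around 38 h (plateau 0.90, τ = 29 h, onset
38 h), M invades early (onset 8 h) with intermediate cavity filling.
Observations add a replicate-level baseline offset (SD 0.02, what a mixed
model absorbs as its random intercept) plus per-timepoint Gaussian noise.

**Dose–response cohorts.** Expected response follows the decreasing Hill
law; noise is multiplicative log-normal scaled to unit mean, so the
per-dose expectation equals the Hill curve exactly. The Hill coefficient
is a free generator parameter defaulting to 1 (no value is published).

**Overview scans.** Day-0 gels are rendered with per-cavity cell dots and
defect injection (agglomeration, excess surrounding cells, conjoined
neighbours, planar outgrowth, staining failure, collapse) at configurable
per-record rates; flags are recorded as ground truth. Default rates
combined with Poisson-20 seeding and the ± 10 % class bands put the
included fraction in the assay's reported 10–25 % yield window.

**What the generator does not emulate:** collagen mechanics, MMP
biochemistry, cell migration forces, curved/anastomosing branch
morphologies, out-of-focus light, or spatial correlation between
neighbouring cavities. Passing recovery tests therefore demonstrates that
the measurement and fitting pipeline is unbiased for data with the assumed
statistical structure — not that segmentation of real micrographs is
accurate.

## Cohort control and statistics

c0 class boundaries are inclusive after exact multiplication (22 belongs
to class 20; 23 to none); counts are not pre-rounded. QC flags are data
consumed from the ground truth or user annotation — automated defect
detection from overview images is out of scope (the assay's own
acknowledged bottleneck). Multi-batch pooling subsamples every batch to
the per-class minimum across batches (the largest achievable common
distribution), randomly without replacement under a logged seed. Group
comparisons use the unpaired two-tailed pooled-variance t-test at
α = 0.05, matching the assay's stated analysis; its type-I error is
calibration-tested at 10⁴ null simulations.

## Invasion dynamics

Brightfield time-lapse cannot be segmented reliably, so dynamics are
normalized intensity proxies, not areas: inner 100 µm circle (non-invasive),
outer∖inner annulus (invasive; the outer ROI is a circle at 3× the cavity
radius by default — deterministic and comparable across timepoints, with
the radius configurable since no outer-ROI definition is published),
each divided by a collagen-only background ROI per timepoint (making the
pipeline exactly invariant to global per-frame intensity scaling), and the
invasive series baseline-corrected at the timepoint nearest 3 h (1 h
tolerance). Frame drift can be estimated by cross-correlation registration
(`align_frames`), with fixed ROIs as the fallback. Trends are tested with
a linear mixed-effects model (Time, Subtype, Time × Subtype fixed effects;
replicate random intercept), fitted by REML with an optimizer cascade
(L-BFGS, then BFGS, then Powell) because profiled likelihoods of small
cohorts occasionally defeat a single optimizer. The interaction test is
calibration-checked under the null (500 simulations) and for power under a
three-sigma slope difference.

## Dose–response fitting

Hill fits run on per-dose means (replicates weighted equally; no weighting
is published) with the span parameterization bottom + span·occupancy,
span ≥ 0, so a fit cannot silently swap asymptotes when data trend against
the requested direction — such data surface as a poor fit (r² < 0.5,
flagged unconverged, no EC50 reported). EC50 is the half-maximal
concentration between the fitted asymptotes (standard Hill convention),
not a 50 %-absolute-reduction dose. Initialization is multi-start over an
EC50 grid spanning the observed concentrations (×2 Hill-slope starts);
bounds keep EC50 within a 50-fold margin of the tested range.

Two estimates are always reported: the free-h fit and a companion fit
with h pinned at 1. On seven dose means spanning 10–2500 nM the free-h
four-parameter fit is weakly identified when the EC50 approaches the top
of the tested range (its bottom asymptote is unconstrained by the data),
biasing the free-h EC50 low by ~10 % there, while the h = 1 estimate stays
within a few percent. Recovery experiments that generate with h = 1
therefore evaluate the matched-model h = 1 estimate.

Roots/tips (and the normalized non-invasive area) respond non-sigmoidally;
they get ordinary least-squares lines on dose means at concentrations
≤ 500 nM, the published cutoff above which offset effects appear. Data
above the cutoff are ignored entirely, so the fit is bit-identical under
their perturbation.

## Problem sizes and reproducibility

Recovery experiments use 200-mask cohorts per subtype (Monte-Carlo SE
small enough to resolve the configured means), 50 Hill-recovery
simulations at 20 replicates per dose, 10⁴ t-test null simulations and
500 LME null simulations — sizes chosen so the whole suite and the
acceptance script each run in well under half an hour on one CPU. All
generators accept either an integer seed or a shared `numpy` Generator;
the CLI and the acceptance script derive every stream from one root seed
via `SeedSequence` spawning.

## Known limitations

- Root counting saturates when crossings are denser than the annulus can
  resolve; the generator caps root counts at the geometric packing limit
  of the boundary circle.
- Skeleton-based tip counts can differ by ±1 from the constructed truth
  on rare rasterization merges (quantified in tests at ≲ 5 % of masks,
  bias ≪ 1 tip).
- The dynamics quantities are intensity proxies and are labelled as such;
  they are not area fractions.
- The free-h Hill fit's EC50 should not be compared across experiments
  whose top doses differ widely relative to the EC50; prefer the h = 1
  estimate or extend the dose range.
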