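# Methods

## Scope and model

The package implements an empirical in vitro–in vivo relationship
(IVIVR) pipeline: dissolution UV-imaging frames in, plasma
concentration predictions out.  It is *empirical* in the strict sense —
the models interpret dissolution imagery and predict the in vivo
response; they do not explain the physiology behind it.  Two data
routes coexist: a tabular route over extracted surface statistics and
an image route over raw frame stacks, with shared metrics and
experiment designs (10-fold CV, tail extrapolation, unseen-formulation
validation).

## Synthetic study generator

The generator exists so that every stage of the pipeline is testable
with a known ground truth; it emulates the study conditions of a
surface-dissolution experiment on metformin tablets.

**Release kinetics.**  IR tablets release first-order,
`f(t) = 1 − exp(−k·m·t)`; XR tablets follow a Weibull curve,
`f(t) = 1 − exp(−((t/(τ/m))^β))`; `m` is a per-medium rate multiplier.
Defaults: IR500 `k = 0.03 /min`, IR850 `k = 0.026 /min`,
XR750 `τ = 240 min, β = 1.2`; media multipliers pH 1.2 → 0.5,
water → 1.0, pH 6.8 → 1.2.  With these values the IR tablets are >90%
dissolved within the 75-min capture window in water and pH 6.8, while
the acidic medium is the slow, absorption-limiting one.

**Frame rendering.**  Frames default to 112 × 96 px (height × width),
preserving the 28 × 24 mm field of a surface-dissolution imager at a
CPU-trainable scale; all sizes are configurable, with tablet geometry
scaled proportionally and a hard ≥ 4 px margin invariant.  The tablet
is an anti-aliased centred rectangle whose *exact* area tracks
remaining fraction (edge pixels carry fractional coverage, so mass
balance holds to float precision, not to ±1 px); XR tablets grow a gel
annulus (30% of core opacity) whose thickness scales with
`swelling_gain × f` up to one pixel inside the margin.  The
dissolved-drug plume is an exponentially-decaying ridge above the
tablet's top edge, normalised so its pixel sum equals
`drug_absorptivity · dose · f(t)` exactly — the integral, not the plume
shape, carries the quantitative signal, so any smooth nonnegative field
would serve.  Acquisition defaults make the UV channel (255 nm)
drug-sensitive (absorptivity 0.02 AU·px/mg, opacity 1.2 AU) and the
visible channel (520 nm) tablet-dominated (0.002 AU·px/mg, 2.0 AU).
Noise is additive Gaussian, clipped at zero, default sd = 1% of tablet
opacity — visible but non-dominant.

**Pharmacokinetic link.**  Plasma concentrations are the convolution of
the reference-medium release rate with first-order elimination
(`C(t) = (F·D/V)·∫ ṙ(u)e^{−ke(t−u)}du`), evaluated with an exact
exponential-decay recursion on a ≤ 1-min trapezoid grid (default
0.25 min).  This is deliberately mechanistic where the real study is
empirical: it gives a known image → concentration mapping for
parameter-recovery tests.  The pH 1.2 medium drives absorption
(gastric dissolution is rate-limiting for an oral dose), so the IR
effective absorption rate is `ka = 0.5·k`; with `ke = 0.004 /min` the
IR500 Bateman peak lands at 120 min.  Apparent volumes were calibrated
once so Cmax falls in the 1000–1150 ng/mL range typical of published
metformin profiles (IR500 V = 0.147 → Cmax ≈ 1052 ng/mL at 120 min);
units are ng/mL throughout.  Concentration profiles are generated on a
5-min grid to 1440 min.

**What the generator does not model** (hence what passing tests do not
show about real data): flow-cell hydrodynamics and recirculation
background, pH-dependent drug chemistry, inter-subject PK variability,
tablet movement or rotation, detector vignetting, and the jet-colormap
rendering of exported videos (frames are consumed as single-plane
absorbance maps; an RGB mode was considered and rejected as baking a
colormap into the learning problem).

## Imaging and features

Tablet location is automated (tightest box over pixels above a
threshold fraction, default 0.5, of the frame maximum on the visible
channel); an empty box is a valid result after complete dissolution.
ROI geometry is frozen from each medium's t = 0 visible frame and
applied to all frames of both wavelengths; the per-frame tablet area is
re-thresholded each frame.  Surface statistics are deviations from the
region *mean* — no plane levelling — the minimal defensible reading of
roughness parameters on absorbance maps.  `Min` is the minimum
deviation (not the raw minimum), consistent with the other
deviation-based parameters.  `Rq` uses the population (n) denominator,
`StdDev` the sample (n−1) denominator, so the two columns are not
redundant; kurtosis is non-excess (Gaussian → 3), the surface-metrology
convention.  Centre-line ties on even tablet widths break toward the
lower column index; all coordinates are 0-based, half-open, row-major.

The assembled table has 114 columns: 6 captures × 3 ROIs × 6 statistics
plus 6 tablet areas.  Feature names follow
`"<medium> <wavelength><roi> <param>"` with a blank token for the
bottom rectangle.  Statistics that are undefined on constant regions
(skewness/kurtosis) enter the table as 0.0 rather than NaN, and
degenerate ROIs (tablet touching a frame edge) are flagged, never
silently dropped.

## Stacks

Timepoint stacks hold the six co-registered frames of one sampling time
in the fixed channel order (pH 1.2, water, pH 6.8) × (255, 520).
Process stacks hold 108 frame planes — 6 captures × 18 frame-slot times
(t = 0 plus the 17-point XR sampling plan), laid out capture-major —
plus one constant plane encoding the stack's timepoint as t/1440.
Slots beyond a formulation's capture window (75 min IR, 720 min XR) are
zero-filled; zero is the padding value because the detector reports no
signal there.  The 53-point timepoint grid is {0, 5, 10, 15, 30, 45,
60} ∪ {90, 120, …, 1440}.  All stacks of one formulation share the same
frame array by reference, so the only-timepoint-differs invariant holds
bitwise by construction.  Targets are spline-interpolated
concentrations; training scales them by the global training maximum
(the convention that maps a ~54 ng/mL tail record to ≈ 0.047 under a
~1156 ng/mL maximum), and predictions are un-scaled back to ng/mL.

## Tabular models

Eight families: linear, LASSO, ridge, elastic net, random forest, SVR,
MLP, and a deeper MLP standing as the "DNN" family.  Standardisation is
applied inside the CV pipeline for all but the forest.  Grids are small
and documented in `tabular.default_grid`.  Feature engineering produces
all monomials to degree 2 (default), then greedily drops any column
whose |Pearson r| with a retained earlier column exceeds 0.95 (default);
constant columns have undefined correlation and are retained.  Metrics
are pooled out-of-fold (every record predicted exactly once by a model
that never saw it), stated in result metadata.  Attribution is exact
per-record Shapley values for the additive-linear family (satisfying
local accuracy) and permutation importance otherwise; an automated
stacked search was considered out of scope, its role filled by
best-of-grid across the eight families.

## CNN stack

No deep-learning framework is used: the six architectures run on a
compact numpy implementation with manual backpropagation — im2col
convolutions, 2 × 2 max pooling, batch normalisation, dropout (0.25),
dense layers, an identity-shortcut residual block (no post-add
activation, so an all-zero body is an exact identity), and a
four-branch inception module.  All hidden activations are ReLU; every
net ends in one linear output unit.  Filter counts are small (8–32 per
stage) so the nets train in minutes on one CPU; published topology
sketches of the canonical nets fix connectivity, not widths.  Training
is MSE with Adam (lr 1e−3, batch 8 default); "iterations" counts
epochs.  Inputs are min-max normalised with a single *global* min/max
from the training set — per-stack normalisation was rejected because it
discards the absolute absorbance scale that distinguishes timepoints.
Initialisation, shuffling and dropout are all seeded; identical seeds
give bit-identical loss histories.  Architecture plans are serialized
and hashed into run metadata to guard against silent drift.

## Experiments and problem sizes

The CV experiment assigns seeded shuffled folds (sizes differing by at
most one) and pools out-of-fold predictions.  The extrapolation
experiment withholds each formulation's final six records (1290–1440
min), checks for (formulation, time) leakage, fits once on the 94
remaining stacks and reports the 12-row tail table with pooled and
per-formulation metrics — pooled, because a single reported pair for
this design corresponds to metrics over both formulations together;
per-formulation values are always emitted too.  Validation enforces
provenance through the model's training manifest.

Default problem sizes are chosen for desk-scale runs: the CV
parameter-recovery experiment uses the full 112 × 96 resolution
(26 six-channel stacks, 25 epochs, ≈ 2 min); process-stack experiments
use 56 × 48 frames (109-plane stacks, 30 epochs, ≈ 30 s per seed),
where the ResNet-style stem convolution downsamples by 2 immediately.
Reports round to 2 decimal places; negative R² and negative predicted
concentrations are reported as-is.

## Numerical notes and limitations

- The exponential-decay recursion for the PK convolution is exact for
  the kernel and trapezoidal in the release rate; against a 0.01-min
  quadrature oracle the error is well under 0.5%.
- Weibull release with β > 1 has zero initial rate; β < 1 (not used in
  defaults) would diverge at t = 0 and is guarded to 0.
- The XR profile's terminal slope is release-limited (flip-flop
  kinetics: the late Weibull hazard is below ke), so the pure-`ke`
  log-linear tail property is asserted on IR profiles only.
- The feature count of the tabular route is 114 by construction; a
  richer surface-characterisation tool reporting facet orientation and
  gradient statistics would push this into the hundreds, which is out
  of scope here.
- Extrapolated tail predictions carry a systematic seed-dependent
  offset on synthetic data: the timepoint layer extends beyond its
  training range and nothing constrains the network's level there.  The
  extrapolation guarantee is therefore ordinal (formulation
  differentiation and declining tails across seeds), not metric.
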