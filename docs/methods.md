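# Methods

This note records the models, estimators and numerical choices behind
`microhet`, and what the synthetic data do and do not establish.

## Imaging model and detection

A microcolony in bright-field appears as juxtaposed bright and dark
pixels on a flat background. Detection classifies a pixel as cell-like
when its intensity lies outside mean ± k·s.d. of the whole frame
(k = 2.2 by default). The mean and s.d. are computed per frame, globally;
a per-frame statistic is the simplest defensible reading and is exposed
as the place to plug in local statistics if needed. A Sobel gradient
threshold can add edge pixels; it defaults off because on the synthetic
textures every colony pixel already trips the intensity detector, while
the default percentile cutoff would flag a fixed share of background by
construction. On real images with low interior contrast it should be
enabled.

Segmentation drops 8-connected components smaller than `min_size`
(default 30 px) *before* the binary closing (radius 3 px). Ordering
matters: threshold noise on a Gaussian background forms only tiny
diagonal clusters, while a colony's speckle is one large 8-connected
component, so the pre-filter removes noise without touching colony
boundaries; closing then fills the bright/dark speckle into a solid
object. An earlier design that opened the mask first systematically
shaved ragged small-colony boundaries and biased growth rates upward by
~2%; the current ordering leaves rendered-colony areas pixel-exact.

Tracking links components across consecutive retained frames by mutual
nearest centroids (ties to the lowest colony id). A frame whose
component count deviates by more than 30% from the median of its
nearest ≥3 neighbouring frames is discarded as an acquisition anomaly;
requiring at least three neighbours keeps a single anomalous frame from
condemning the first or last frame of the series. When two tracks map
onto one component the colonies have merged: both are flagged
`touched_at` and truncated there, and the merged blob does not seed a
new track at that frame. Debris filters are strict inequalities:
initial area > 50 px and final/initial > 2.

## Growth-rate estimation

ln(area) is regressed on time (hours from frame metadata, so uneven
spacing and discarded frames are handled) over every 3-consecutive-
timepoint window. Windows with R² < 0.9 are dropped; a zero-variance
response (constant area) has undefined R² and is likewise dropped
rather than scored. The colony's rate is the maximum surviving slope
(earliest window on ties), which is invariant to lag prefixes and late
slowdowns. Pointwise rates use the centered 3-point window per interior
timepoint; missing values break the consecutive runs required by the
switching classifier (gaps are never interpolated). Switching calls
need `run_length` consecutive qualifying points on each side and a
switch time outside the first (slow→fast) or last (fast→slow)
`edge_exclusion` frames; with c1 = c2 the rule degenerates to a single
cutoff. The survival cutoff (0.02 h⁻¹) is strict at the boundary.

## Heterogeneity statistics

All distribution statistics live on a 0.01 h⁻¹ grid. The mode is the
argmax of the per-grid-value histogram after a 5-bin moving average;
ties resolve by raw count, then the lowest grid value (so a point mass
reports itself, not the smoothing plateau). The slow/fast fraction
builds the empirical CDF on the grid, finds the steepest 5-point window
by per-window OLS slope (ties toward the window nearest the median),
fits a line through those five points, and walks outward until the CDF
deviates from the line *horizontally* by more than 0.02 h⁻¹ — the
deviation is measured in rate units, matching the threshold's units;
a vertical reading would make the threshold dimensionally arbitrary.
The left and right tail percentages are read off the CDF at those
edges; the larger tail defines the reported fraction and the other is
set to zero, so at most one of slow/fast is nonzero by construction.
Distributions need ≥ 50 values (configurable); the grid CDF is
unstable below that.

The mode-shift calibration moves only the bulk (rates at or above the
left edge) down in 0.01 h⁻¹ steps and records the recomputed slow
fraction. Its expected-change lookup is anchored at the first *nonzero*
shift: the δ = 0 evaluation differs from the δ→0⁺ limit by a one-off
grid-discretisation offset (~0.4 points) because the shifted-bulk
construction re-estimates the edge, and a genuinely mode-shifted strain
corresponds to the shifted branch. Without this anchor the correction
systematically inflates corrected slow fractions and manufactures
spurious slow-up calls. Corrections are only applied for mode
*reductions*.

Penetrance is the percentage of mutant rates at or above the wild-type
bulk's left edge, computed for every mutant-replicate × WT-replicate
pair, with a one-sample Wilcoxon signed-rank test against zero (all-zero
overlap collections return p = 1, where the signed-rank statistic is
undefined).

## Screen analysis

Replicate reproducibility: sample means are aligned (shift ≤ 0.05 h⁻¹,
else the pair is inadmissible) and the two-sample K-S statistic must be
≤ 0.1 for an edge. For a strain's three replicates the kept subset is
the largest clique, ties broken by minimal total edge weight — with
three nodes this reproduces every behaviour described for the original
procedure. The wild-type reference pool, by contrast, uses a
majority-consistency rule (keep replicates admissible with at least half
the pool): a strict clique over a dozen pooled WT days lets a single
outlier day collapse the pool and with it the power of every test in
the screen.

Classification runs two Mann–Whitney U families across strains —
per-replicate modes vs WT modes, and mode-corrected slow fractions vs
WT slow fractions — each BH-corrected separately at FDR 0.1
(replicate-level granularity by default; pooled single-cell rates are
available via `granularity="pooled"`). Categories follow the two FDR
calls and their signs: no-change, mode-only, slow-down-only,
slow-up-only, both-down, mode-down-slow-up, other. Two properties of
this procedure are worth knowing: on an all-null screen the type-I rate
is far below the nominal 0.1 (BH with no real positives is strict),
while in a positives-rich screen BH's adaptive threshold rises to
roughly 0.1 × (fraction rejected), so ~5% of truly-null families are
miscalled. The residual few-percent misclassification seen on planted
screens is this effect, not an implementation artifact.

Enrichment uses the exact upper-tail hypergeometric probability
(log-gamma arithmetic; verified against exhaustive enumeration for all
N ≤ 12).

## Organelle state model

The closed-form low-TMRE prediction treats the sorted HI bin as three
exponentially growing subpopulations — slow-high (0.80 of the bin at
0.20 h⁻¹), fast-high (0.19 at 0.37 h⁻¹) and a low-potential impurity
(0.01, assumed fast-growing, which is the conservative choice) — with a
fraction s = 0.1 per 24 h of the grown low pool removed by low→high
switching and no high→low switching. The 24–48 h evaluation exists in
two term conventions that genuinely disagree: the printed arithmetic
multiplies the fast-high term by 0.20 *without* the 0.653 high-potential
carry-over factor (→ 56.2%), while the displayed symbols include it
(→ ≈64%). Both are implemented (`printed_arithmetic=True/False`); which
was intended cannot be resolved from the text, so the package exposes
the choice instead of hiding it.

The agent-based generator simulates the same three states as a
branching process: per step of length dt each cell leaves a
Geometric(e^(−r·dt)) number of descendants (the Yule offspring law, so
expected growth is e^(r·t) exactly for any dt), then switches state with
the hazard-converted probability p_dt = 1 − (1 − p₂₄)^(dt/24). Because
low and fast-high cells share a growth rate, moving switchers between
those states leaves the total unchanged and the closed form is the
exact expectation of the simulation — the Monte-Carlo convergence test
therefore needs no model-gap allowance, only a sampling band.

Quantile gates (HI/M1/M2/LO) take the top and bottom `bin_fraction`
(default 5%) of ranked intensities plus two equal-size middle gates
(configurable positions; defaults at 1/3 and 2/3 from the top); ties
break by input order via a stable sort. qPCR quantification fits Ct on
log₁₀(quantity) per primer (standard absolute-quantification practice),
excludes primers with standard-curve R² < 0.98, back-computes sample
quantities per technical replicate, averages per primer and per class,
and propagates the ratio's s.d. to first order:
sd_r = r·√((sd_mt/mean_mt)² + (sd_nuc/mean_nuc)²).

## Synthetic data: what it emulates and what it does not

The renderer draws each colony as the N pixels nearest its seed centre,
N = round(A₀·e^(rate·max(0, t − lag))), held constant after an optional
slowdown onset — areas are therefore pixel-exact and nested over time.
Texture is a ±60-intensity checkerboard on a Gaussian background
(s.d. 1 around 1000, 16-bit): the amplitude-to-noise ratio is set so the
colony contribution to frame variance keeps the 2.2-s.d. threshold
clear of the background tail even at the first frame, and the detector
keeps firing at the final frame's ~10% coverage. Contacts are detected
by 8-adjacency of rendered masks and recorded per pair. This is a
geometric stand-in, not a model of real bright-field optics: no
defocus, shading, internal cell structure or debris. Passing end-to-end
tests show the pipeline recovers what the renderer encodes; they do not
certify segmentation accuracy on real micrographs.

Growth-rate mixtures are truncated normals (negative draws redrawn);
the wild-type condition is 90% N(0.407, 0.02) + 10% N(0.15, 0.05) h⁻¹.
Planted screens add day-to-day replicate variation — a common mean
shift (s.d. 0.007 h⁻¹, chosen so replicate modes scatter like the
0.011 h⁻¹ observed across real batches) and a slow-weight wobble
(s.d. 0.5 points, small enough that mean-aligned K-S stays under the
0.1 admissibility cap at realistic rates). Default study conditions:
3 mutant replicates, a 16-replicate WT pool, 2000 colonies per
replicate, effect sizes of −0.08 h⁻¹ on the mode and +20/−8 points on
the slow fraction. The "other" category is planted as mode-up plus
slow-up.

## Problem sizes

The test suite renders small fields (6–16 colonies, ≤ 1600² px) and
classifies screens of 14–70 strains; the acceptance script renders 10
fields × 20 colonies (200 total, mirroring multi-field acquisition) and
completes in under a minute on one CPU. All generators and the pipeline
take explicit integer seeds; there is no global RNG state, and a rerun
with the same configuration reproduces outputs byte-identically.

## Known limitations

- Tracking assumes colonies move little between frames; there is no
  drift correction beyond centroid matching, and merged fields of view
  must be supplied pre-concatenated.
- The slow-fraction edge construction needs a well-defined steep bulk;
  heavily overlapping mixtures (bulk within ~2 s.d. of the slow
  component) blur the edge and the statistic degrades gracefully but
  unavoidably.
- The switching classifier reports the first qualifying fast→slow
  transition and checks slow→fast only if none exists; series containing
  both patterns yield the fast→slow call.
- The qPCR error model propagates only between-primer variation;
  pipetting covariance between technical replicates is not modelled.
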