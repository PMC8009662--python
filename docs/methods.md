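# Methods

## The peak model

Cortical reporter intensity around a cell is modelled as a single unimodal
bump on the circle:

    I(θ) = b + A · g(θ; μ, σ),   g(θ) = Σₖ exp(−(θ − μ + 2πk)² / 2σ²) / (same at μ)

a wrapped Gaussian normalised so g(μ) = 1, plus a constant baseline. The
wrap sum runs over k ∈ [−4, 4]; with σ bounded above by 2π the first
neglected image contributes < 10⁻³ relative. The normalisation makes the
parameters read directly as physical quantities: *b* is the uniform
cortical background (AU), *A* the crescent's height above it (AU), *μ* its
centre (rad) and *σ* its width (rad). Assumptions: one crescent per cell,
additive signal, no systematic intensity gradient along the cortex.
Multimodal profiles are still fit with the single bump; a large residual
RMSE is the flag to inspect them.

## Profiling and the polarity index

Outlines are sub-pixel marching-squares contours of the label region,
smoothed with a 7-vertex circular moving average (the raw staircase
contour biases perimeter ≈ +5%; after smoothing a 20-px disk's perimeter is
within 0.1% and areas within 0.5%). Regions must be simply connected and
away from the image border.

The periphery is split into **63 equal arc-length portions** (configurable;
arc length rather than centroid angle so non-convex cells are handled
sensibly — for a circle the two coincide). Each portion's value is the mean
intensity in a band (default 3 px wide) centred on that stretch of outline,
computed by dense bilinear sampling (16 points along-arc × 9 across-band
per portion). Portions carry both their arc fraction and their centroid
angle; fits are done in angle.

BPI is the fraction of the 63 portions **at or above** half the per-cell
maximum. The inclusive comparison makes a perfectly uniform profile score
exactly 1 (the fully-depolarized limit); attainable values are k/63,
k = 1…63. BPI uses raw reporter intensities — no baseline subtraction and
no membrane normalisation; the membrane channel serves outline tracing and
is retained in the profile for optional ratio analyses.

Cell selection for population snapshots ranks cells by mean reporter
brightness over the 63 portions and keeps the top 10 (ties broken by
ascending cell id) — a proxy for "recently divided, reporter-expressing"
cells that makes genotype comparisons fair.

## Fitting

Bounded trust-region least squares (scipy `least_squares`) with
initialisation μ₀ = argmax portion angle, b₀ = min, A₀ = range, σ₀ from the
circular second moment of (I − b₀)₊; bounds A ≥ 0, 0 ≤ b ≤ max(I),
σ ∈ [2π/63, 2π], μ ∈ μ₀ ± π (wrapped to [0, 2π) afterwards); xtol/ftol
10⁻¹⁴ so noise-free self-consistency holds to 10⁻⁴ relative. A constant
profile short-circuits to A = 0, b = mean, converged, with σ set to a
sentinel (2π) and a `degenerate` flag.

Crescent size is the fitted FWHM over the circumference,
2σ√(2 ln 2)/2π, capped at 1; peak height is *A*.

**Effective amplitude.** At large σ the model is weakly identified: a very
wide wrapped Gaussian is nearly constant, so the optimizer can trade
baseline for amplitude (on pure noise the fit often returns b ≈ 0 with a
large, meaningless A). Wherever a threshold must decide whether a crescent
is *visible* we therefore use the peak-to-trough modulation of the fitted
curve, A_eff = A·(1 − g(μ+π)), and the corresponding effective baseline
b + A·g(μ+π). For narrow crescents A_eff = A to machine precision; for the
degenerate wide fits it correctly collapses to ≈ 0.

## Persistence

A trace starts at cytokinesis (frame 0 is an input annotation, not
inferred) and carries one fit per frame. A frame is *detectable* iff
A_eff ≥ 0.2·b_eff **and** A_eff ≥ 2·RMSE. Persistence is the time of the
first non-detectable frame; if none, the result is censored at the last
frame and reported as such. The thresholds are conventions standing in for
a by-eye call — there is no published threshold to match — and are exposed
as parameters (`detect_contrast`, `detect_snr`). Under the validation
conditions (13 frames at 40 min, amplitude 80 AU over baseline 20, 240-min
half-life, disappearance uniform in 100–460 min, noise 10% of initial
amplitude) measured persistence lands within one frame of truth in
100/100 traces.

Group comparison excludes censored traces (counts reported), returns the
difference of means (B − A, minutes) and a two-sided Mann–Whitney p-value.

## Lineage records and summaries

The state machine: protodermal cells either divide asymmetrically (entry:
meristemoid + SLGC) or become pavement; meristemoids either amplify
(ACD: meristemoid + SLGC) or transition to GMC; GMCs divide symmetrically
into a guard-cell pair; SLGCs either space (ACD: meristemoid + SLGC) or
become pavement. `validate_lineage` reports every violation — orphan or
multiply-parented daughters, ≠ 2 daughters, illegal same-cell transitions,
lone guard cells, daughters not born at the division frame.

Division classification uses parent state, daughter fates and the parent's
polarity call: GMC parents (or depolarized parents with guard daughters)
are SCDs; polarized parents are ACDs subtyped by state (protodermal →
entry, meristemoid → amplifying, SLGC → spacing); contradictory evidence
(e.g. polarized + guard daughters) yields an explicit `unlabeled` call with
a reason rather than a guess. On synthetic records with clean polarity
calls the classifier recovers every true label; corrupting 10% of polarity
calls produces only flagged `unlabeled` calls, never silent mislabels.

Stomatal index counts a guard-cell pair as one stoma and one unit:
SI = stomata / (stomata + pavement + protodermal + SLGC). Cells still
meristemoid or GMC at the window end are "undifferentiated" — included in
cell-number trajectories (where a guard pair counts as 2 cells) but
excluded from SI, which is meant for fully differentiated compositions.
The meristemoid histogram counts amplifying rounds per founder-derived
meristemoid line, binned 0 / 1 / 2 / 3+ (cap configurable).

## The simulator

Per founder, i.i.d. Bernoulli decisions per discrete round: entry with
p_entry, amplification with p_amp, spacing with p_spacing. Two caps bound
the tree (default `max_rounds` = 5, matching the 0–3 amplifying rounds seen
in 48-h windows plus headroom):

* a meristemoid line performs at most `max_rounds` amplifying divisions,
  then differentiates — this makes *n* exactly truncated-geometric and the
  analytic SI oracle `expected_si` exact;
* every spacing division increments a re-entry depth inherited by all
  offspring, and spacing requires depth < `max_rounds`. Without this the
  re-entry loop (SLGC → meristemoid → new SLGCs → …) is supercritical for
  large p_amp·p_spacing and the expected tree is infinite.

All lineages therefore reach absorption; conservation
(cells = founders + divisions) holds exactly at every timepoint. One
top-level seed drives a single `numpy` Generator; the decision sequence is
identical whether or not the full lineage record is materialised, so the
fast counters-only mode used for large sweeps is bit-compatible with the
recorded mode. Scenario presets (wild-type, high-ethylene, high-glucose)
encode only the qualitative orderings — ethylene suppressing and glucose
promoting amplifying ACDs — not calibrated rates, which no desk-scale
source provides.

Time is division rounds, not hours; mapping rounds to days is
presentation-only.

## What the synthetic data does and does not emulate

Emulated: cortical-band fluorescence along closed outlines (ellipse +
smooth low-order radial jitter), a wrapped-Gaussian crescent with known
centre/width/height, additive zero-truncated Gaussian noise on the
reporter, exponential (half-life) post-division amplitude decay with a
hard disappearance time sampled at a fixed 40-min cadence, and lineage
records following the state machine with true division labels. The
rendered band (default 7 px) is wider than the 3-px measurement band so
band means sample band interior rather than anti-aliased edges; ground
truth includes the crescent's true half-max periphery fraction computed
along the actual outline arc.

Not emulated: 3-D geometry and point-spread optics, Poisson photon
statistics, multi-cell packing, cell growth, drift, segmentation errors,
or any spatial signalling. Passing tests therefore validate the
*estimators* (sampling, index, fit, detection, classification, counting)
under the stated measurement model — they do not certify performance on
real microscopy, where segmentation quality and background structure
dominate.

Generator defaults (baseline 20 AU, amplitude 80 AU, σ 0.35 rad, noise
3–8 AU, 160×160 px, 40-min frames) are round numbers chosen once to give
mid-range contrast at the stated cadence; the crescent's true
amplitude-to-background ratio in vivo is not published, so these are free
parameters of the benchmark, not calibrated values.

## Problem sizes

The shipped analyses and tests use 20-cell populations, 200-replicate fit
studies, 100-trace persistence studies, lineages of 400–2,600 founders
(~10⁴ divisions) and simulator runs of 2×10⁴–10⁵ founders per grid point —
sizes at which every stochastic check has standard errors well below its
tolerance while the whole suite runs in well under a minute of compute per
module.

## Known limitations

* Single-bump model: bipolar or patchy cortical signal is fit as one
  crescent and only flagged via RMSE.
* BPI quantisation (1/63 steps) limits resolution for very tight crescents.
* Persistence is quantised to the frame interval and depends on the
  detectability convention; sensitivity to the two thresholds should be
  checked when porting to real data.
* The simulator has no spatial component, so the one-cell-spacing rule and
  cell-size effects on division propensity are out of scope.
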