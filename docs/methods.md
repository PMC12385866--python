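# Methods

## Model

Axon specification is treated as a Bernoulli outcome whose probability is a
smooth function of final neurite length *L* (μm):

    P(L) = ½ [1 + tanh((L − Lc) / σ)]

`Lc` (critical length) is the 50% point; `σ` (dispersion) sets the width of
the transition — roughly, the probability rises from 12% to 88% over
`Lc ± σ`. The curve is symmetric about `Lc`: P(Lc + d) + P(Lc − d) = 1.
The *definitive length* at a near-certainty level `p` inverts the curve in
closed form:

    Lt = Lc + σ · atanh(2p − 1)

The default `p = 0.9995` is the unique round probability level at which
the single-neurite parameters (43.3, 13.7) μm give Lt = 95.4 μm after
0.1 μm rounding; it is configurable and echoed in every fit summary.
Reported lengths are rounded to 0.1 μm; full precision is kept internally.

Model assumptions worth stating: outcomes are independent across neurites
given length (dish-level clustering is ignored — no mixed-effects layer);
length is the only covariate; and in two-neurite settings competition acts
only by shifting `Lc` (see below), not by changing `σ` or the functional
form.

## Differentiation index

Each neurite's two immunofluorescence channels (Tau-1, MAP2) are sampled
along the neurite path; per channel the maximum is the peak signal and the
minimum serves as the background term:

    I_diff = [(Tau_max + 1)/(Tau_min + 1)] / [(MAP2_max + 1)/(MAP2_min + 1)]

The +1 offset keeps the ratio finite at zero intensity. Classification is
strict: axon iff `I_diff > threshold` (default 1.0); the tie at exactly
1.0 is resolved to non-axon, the conservative choice given that observed
axons sit strictly above 1. Swapping the channels maps the index to its
reciprocal, and equal channel extrema give exactly 1 — both are asserted
as invariants.

Whether the "minimum" should be a within-neurite minimum or an off-cell
background measurement is genuinely open; both are supported and the
default is the within-neurite minimum. In image mode the median intensity
of pixels farther than 3 px from the path is subtracted first and negative
values are clipped to 0, so the +1 offset stays well defined.

Records are *excluded* when stray outgrowth inside the soma chamber
exceeds twice the soma diameter (strict; default soma diameter 20 μm,
half the 40 μm chamber width). This reading — confinement failure, not
guided-channel length — is forced by consistency: excluding any guided
neurite longer than 2× the soma diameter would discard every long neurite
in the dataset. Excluded records are flagged, never deleted; all fits
consume only non-excluded rows.

The threshold sweep bins non-excluded neurites by length (default 20 μm
bins from 0; the binning convention is ours) and reports the axon fraction
per bin at thresholds {0.80, 0.90, 1.00, 1.10}, flagging whether the rate
is non-decreasing across non-empty bins.

## Fitting

The sigmoid is fitted to raw binary 0/1 outcomes (not binned rates) by
unweighted nonlinear least squares — `scipy.optimize.curve_fit` from the
start `(median length, IQR/2)`, with a 5×5 coarse restart grid (length
quantiles × dispersion decades) used only if the primary start fails.
A Bernoulli maximum-likelihood objective is available as an option and is
never the default. R² is computed on the binary observations; it can be
negative for a bad fit and is then reported as-is with a warning flag.

The parameter covariance is the heteroscedasticity-consistent sandwich
`(J'J)⁻¹ J' diag(r²) J (J'J)⁻¹`: binary outcomes have Bernoulli variance
`p(1−p)` that varies along the curve, and the usual homoscedastic
least-squares covariance understates the uncertainty by roughly a factor
of two here (checked against a 1000-draw parametric bootstrap). Confidence
bands propagate this covariance through the curve to first order (delta
method), symmetric before clipping to [0, 1]. Whether the original
analysis used a delta-method or bootstrap band is not documented; the
delta method is the default and the bootstrap is the cross-check.

The RMSE landscape evaluates `√mean((P(L) − y)²)` on an (Lc, σ) grid
(default Lc ∈ [10, 120], σ ∈ [1, 50], step 0.5 μm — the grid convention is
ours) and reports the argmin, which brackets the optimizer's solution on a
fine grid.

**Small-sample degeneracy.** Least squares on binary outcomes has a
degenerate optimum whenever some length threshold separates the classes
with few misclassifications: a step (σ → 0) through the gap then beats any
smooth curve. At n ≈ 68 with lengths uniform on [10, 200] μm and a true σ
of ~14 μm, roughly a quarter of random datasets are near-separable, so the
*mean* fitted σ across replicates is biased low by several μm even though
`Lc` is recovered essentially unbiased; by n ≈ 500 the bias is under
1 μm, and at n = 2000 both parameters are recovered to ~0.1 μm on
average. No replicate filtering is applied when means are reported. This
is a property of the estimator itself (a Nelder-Mead search from the same
start finds the same or lower SSE at the collapsed solution), and it is
why the optimizer-versus-grid equivalence check is run at n = 400, where
the surface has a single smooth basin and the comparison is well posed.

## Competition analyses

Pairs are stored as two linked measurement rows. Pooled fits treat the two
neurites of a pair as independent (length, label) observations, matching
the per-neurite scatter convention; a pair-resampling bootstrap is
provided for standard errors that respect within-pair correlation. The
conditional fit restricts to neurites whose partner's final length exceeds
a reference definitive length `Lt_ref` — recomputed from the current
single-neurite fit, never hard-coded — and excludes the conditioning
partner itself unless its own partner also qualifies. Critical-length
shifts between fits carry a delta-method standard error assuming
independent fits.

Stepwise pairs record which channel opened first, the opening days, and
the first neurite's length at second opening; fate patterns
(first_wins / second_wins / dual / none) are assigned from the axon flags,
together with whether the finally-longest neurite carries the axon. The
"none" category is possible in principle though small cohorts may not
contain it. The ~85 μm boundary sometimes quoted for stepwise outcomes is
treated as a descriptive empirical feature, not a model parameter.

Probability maps evaluate a reference fit over a grid of pair lengths;
cells are separable by construction (`p_x` depends only on x). The RGB
rendering maps the longer/first neurite's probability to red and the
shorter/second's to blue.

## Synthetic data generator

The generator emulates the three study designs at their reported scales —
68 single neurites over 9 dishes, 18 simultaneous pairs over 8 dishes, 11
stepwise pairs over 7 dishes — with dish ids assigned round-robin.

* **Lengths**: uniform on [10, 200] μm by default. The source experiments
  do not report a length distribution; uniform maximizes information
  across the sigmoid transition. A rejection-truncated lognormal is
  available.
* **Labels**: Bernoulli draws from the sigmoid at the configured truth,
  default (43.3, 13.7) μm.
* **Competition**: each neurite of a pair feels an effective critical
  length `Lc + 9.9 μm` (the reported single-to-pair shift), plus a further
  `8.8 μm` when its partner's final length exceeds the single-neurite
  `Lt` (the reported conditional shift). This is a phenomenological
  encoding of the two reported shifts, not a mechanistic model of
  inter-neurite inhibition or resource competition.
* **Stepwise**: the first neurite grows to a pre-opening length; the
  second channel opens 1–2 days later; with probability 0.2 the first
  neurite then retracts to a uniform fraction of its pre-opening length,
  otherwise it keeps growing modestly. The retraction probability and the
  first-neurite length range are conventions (the source reports
  retraction anecdotally, not as a rate) and are configurable.
* **Intensity profiles**: per channel, a flat baseline (20 a.u.) plus one
  Gaussian-shaped peak (center 0.6 L, width L/4) sampled every ~1 μm, with
  i.i.d. Gaussian noise truncated at 0. Axons are Tau-dominant (Tau
  amplitude 150, MAP2 at 30% of the dendritic amplitude);
  undifferentiated neurites show mixed expression with MAP2 dominant (Tau
  at 60% of the MAP2 amplitude); setting that ratio to 1 makes the
  channels exactly symmetric and `I_diff` exactly 1 in the noise-free
  case. The default noise (sd 3 a.u.) is a few percent of the peak
  amplitude: because the channel minimum is an extreme order statistic
  over the whole profile, much larger per-sample noise would let the
  minima dominate the contrast ratio and decouple the index from the
  label, which is inconsistent with the clean class separation such
  stainings show. At the defaults the index misclassifies ~0.5% of
  neurites; at noise 0 it reproduces the labels exactly.
* **Exclusion**: stray in-chamber outgrowth is drawn uniform on (0, 44] μm
  against a 20 μm soma, flagging ~9% of records — a convention, since the
  source reports the rule but not the rejection rate.
* **Reproducibility**: a single top-level seed; every record draws from a
  child stream `SeedSequence(entropy=seed, spawn_key=(stream, record))`,
  so subsets are reproducible in isolation and identical config + seed
  give byte-identical serialized output.
* **Image mode** (intentionally minimal): profiles can be rendered as
  16-bit grayscale TIFF pairs (0.5 μm/px, 2 px line on a zero background)
  with a path-coordinates CSV, and re-extracted through the image path.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: dish-level variability (all dishes share one
truth), tip-growth dynamics and towing forces, marker transport or
diffusion, spatially correlated camera noise and PSF blur, neurite-path
curvature, and any mechanistic coupling between competing neurites beyond
the two additive `Lc` shifts.

## Numerical choices and degenerate inputs

Fits require ≥ 4 observations with both classes present; single-class data
raise an error naming the problem, as does a conditional subset emptied by
its condition. Grids must be non-empty with σ > 0. `tanh` arguments are
clipped at ±300 before `cosh` to avoid overflow in gradients. Ties: index
exactly at threshold → non-axon; chamber growth exactly 2× soma → kept.
Landscape argmin ties resolve to the first grid point in row-major order.
CSV floats are written as shortest-round-trip decimal text, so
write→read cycles preserve values exactly; invalid rows are collected into
an error table with reasons rather than aborting the load. In the
pipeline, a conditional fit that fails for data reasons (single-class
subset at small n) is recorded as a diagnostic in the summary instead of
aborting the run.

## Problem sizes used in validation

Recovery simulations use 200 replicates at n = 68 (single-neurite scale)
and n = 500 (pooled-pair scale); the optimizer-versus-grid oracle uses 10
datasets of n = 400 at 0.1 μm grid resolution; calibration checks use
n = 10 000 draws; bootstrap comparisons use 1000 refits at n = 400. These
sizes were chosen so each check's sampling error is small relative to the
tolerance it tests.

## Known limitations

* The dispersion estimate from least squares on binary outcomes is biased
  low at small n (see above); for n ≲ 100 prefer reporting `Lc` (robust)
  and treat `σ` with caution, or use the likelihood objective with a
  penalty of your choosing.
* No mixed-effects treatment of dish clustering; standard errors assume
  independent neurites (pair bootstrap available for pairs).
* Image mode renders straight horizontal paths only; it validates the
  extraction machinery, not realistic morphology, and no tracing or
  skeletonization is attempted.
* Competition shifts are additive phenomenology; the generator cannot
  distinguish competing mechanistic explanations.
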