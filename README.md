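# axonpolar

Quantitative analysis of length-dependent axon specification in cultured
neurons.

During early development one neurite of a multipolar neuron becomes the
axon. In micropatterned cultures where single neurites are guided along
microchannels, axonal fate can be read out from two-channel
immunofluorescence — Tau-1 (axonal marker) versus MAP2 (somatodendritic
marker) — and related to neurite length. `axonpolar` implements that
analysis chain for experimentalists working with such data, plus a
synthetic-data generator so the whole pipeline can be exercised and
validated without microscopy data.

## What it computes

**Axonal differentiation index.** For each neurite, intensity extrema along
the path give

```
I_diff = [(I_Tau^max + 1) / (I_Tau^min + 1)] / [(I_MAP2^max + 1) / (I_MAP2^min + 1)]
```

with the +1 offset guarding against zero intensities. A neurite is
classified as an axon when `I_diff > 1.0` (strict).

**Length–probability sigmoid.** The probability that a neurite of length
*L* (μm) becomes an axon is modeled as

```
P(L) = ½ [1 + tanh((L − Lc) / σ)]
```

where `Lc` is the *critical length* (50% probability) and `σ` the width of
the transition. The model is fitted to binary axon/non-axon outcomes by
nonlinear least squares (`scipy.optimize.curve_fit`), with a
heteroscedasticity-robust parameter covariance. From a fit, the
*definitive length* `Lt = Lc + σ·atanh(2p − 1)` (default p = 0.9995) marks
near-certain axon specification. An exhaustive RMSE landscape over the
(Lc, σ) plane and delta-method confidence bands support the fit.

**Two-neurite competition.** For neuron pairs growing two neurites
(simultaneously, or stepwise with the second path opened later), the
package classifies pair outcomes (none / single / dual axon), fits pooled
and partner-conditional sigmoids, measures critical-length shifts with
standard errors, assigns stepwise fate patterns, and renders the
probability-colored outcome map (red = longer/first neurite, blue =
shorter/second, magenta = both).

## Worked example

Generate a synthetic single-neurite dataset (lengths uniform on 10–200 μm,
labels drawn from the sigmoid at Lc = 43.3 μm, σ = 13.7 μm, noisy
two-channel intensity profiles), then fit and inspect it:

```
$ axonpolar simulate --out demo.csv --seed 0 --n 1000
wrote 1000 records to demo.csv

$ axonpolar fit --input demo.csv --out demo_fit.json
Lc=42.3 μm  sigma=12.0 μm  Lt=87.9 μm  R²=0.7678  n=920

$ axonpolar landscape --input demo.csv --out demo_landscape.csv --lc 10 120 0.5 --sigma 1 50 0.5
argmin: Lc=42.5 μm sigma=12.0 μm (rmse=0.1875)

$ axonpolar sweep --input demo.csv --out demo_sweep.csv
threshold 0.80: monotone=True
threshold 0.90: monotone=True
threshold 1.00: monotone=True
threshold 1.10: monotone=True
```

Reading the output: 920 of 1000 records survive the confinement-failure
exclusion; the fitted critical length (42.3 μm) and dispersion (12.0 μm)
recover the generating truth to within sampling error, slightly attenuated
because labels are re-derived from the noisy intensity channels rather
than taken from the generator. The landscape grid search agrees with the
optimizer to one grid step, and the polarization rate per 20 μm length bin
increases monotonically at every index threshold, supporting `I_diff = 1.0`
as a classification cutoff. `axonpolar run` executes the same stages plus
the pair analyses end to end into a run directory; the same seed
reproduces every CSV byte for byte.

The same operations are available as a library:

```python
from axonpolar import SyntheticConfig, generate_single_dataset, fit_sigmoid

df = generate_single_dataset(SyntheticConfig(n=1000, seed=0))
kept = df[~df.excluded]
fit = fit_sigmoid(kept.length_um, kept.is_axon)
print(fit.summary())
```

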