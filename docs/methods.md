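# Methods

## The anticipation model

`ramancast` treats short-horizon spectral evolution of a fermentation batch
as motion along a low-dimensional manifold in spectrum space. Within a
trailing window of a few hours the observed spectra are well captured by a
2-component mean-centred PCA; anticipation extrapolates the score
trajectory — PC1 as a function of time, PC2 as a function of PC1 — and
back-projects the extrapolated scores:

    s_hat(a + h) = mean + pc1_hat * loading1 + pc2_hat * loading2

The chained PC2~PC1 regression (rather than PC2~time) encodes the
observation that the second component tracks the first along the process
trajectory; both fits see only the window points, never any extrapolated
values. The PCA is refit from scratch at every anchor (fully moving
window, no warm start), so the model adapts to a process deviation as soon
as the window has refreshed.

Assumptions and consequences:

- **Near-monotone dynamics.** Extrapolation presumes the latent trends
  continue; it degrades around turning points (e.g. a metabolite that
  peaks and declines) and recovers on either side of them. This is visible
  in the growing spread of delta_tmin with horizon on the realistic
  synthetic preset.
- **No channel scaling.** PCA is applied to raw (or d2-detrended) spectra
  with mean centring only; variance-scaling channels would distort the
  inverse projection.
- **Window contains enough variation.** A window of identical spectra is
  degenerate (refused); a window whose PC1 scores do not vary cannot
  support the PC2~PC1 fit (refused as a degenerate predictor).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `window_h` | 5 h | trailing accumulation window `(a-W, a]`; 5–10 spectra at 1 h / 30 min acquisition. Shorter reacts faster, longer stabilises the fits |
| `start_h` | 20 h | first anchor; the first anchors need a populated window, and early-batch transients are poor extrapolation bases |
| `n_components` | 2 | retained PCs. Two suffice on windows dominated by one or two latent factors; a third is supported (chained PC3~PC2 fit, evaluated at the predicted PC2) for harder data |
| `pc1_fit`, `pc2_fit` | linear | trend family: linear / quadratic / cubic / ridge. Linear is the most robust extrapolator; higher orders adapt to local fluctuation but destabilise the future domain |
| `ridge_lambda` | 1.0 | L2 penalty on the slope of the ridge fit (intercept unpenalised), applied after standardising the predictor; 0 recovers ordinary least squares |
| `min_window_spectra` | 3 | guards against exact-fit degeneracy (a line through 2 points) |
| detrend `window_points` / `poly_order` | 15 / 3 | Savitzky–Golay second-derivative filter length and local polynomial degree, in channels |

Component orientation is fixed only for reporting determinism (PC1: score
slope over time non-negative; others: largest-magnitude loading element
positive); anticipated spectra are provably invariant under either SVD
sign, and the test suite forces both orientations to confirm it.

The window interval is half-open `(a-W, a]` so each spectrum belongs to
exactly one trailing window end. Horizons are measured from the anchor.
Irregular sampling is permitted; anchors for cohort evaluation are every
acquisition time from `start_h` whose target `a+h` is still inside the
batch.

## Evaluation conventions

- `tmin` is the time of the **most similar** actual spectrum (argmax of
  cosine similarity, equivalently argmin of cosine distance). Ties resolve
  to the candidate closest in time to the target, then to the earlier
  time.
- The comparison set includes every actual spectrum of the batch, the
  fitting window included — required for the baseline's analytic
  `delta_tmin = -h` signature to hold.
- Horizon summaries pool all (batch, anchor) instances directly (no
  per-batch pre-averaging) and report the sample (n−1) standard deviation;
  singleton groups report sd 0 rather than NaN.
- Optional d2 detrending (smoothed second derivative) is applied to both
  the predicted and the actual spectra before comparison. The filter runs
  on the channel index, not on wavenumber units; the axis is near-uniform
  so the two differ only by a constant factor, which cosine similarity
  ignores. Same-length output via the filter's polynomial edge fits keeps
  the vectors axis-aligned.

## The synthetic generator

No public dataset of in-line fed-batch Raman spectra with reference OD
exists at this scale, so the generator stands in for a 23-lot campaign. A
batch is

    spectrum(t) = sum_c latent_c(t) * purespec_c + drift * t + noise

on a 100–3425 cm⁻¹ axis (1 cm⁻¹ step, 3326 channels), sampled for 90 h at
1 h (optionally 30 min or 5 min) intervals. Latent trajectories: logistic
(biomass-like monotone growth, default plateau 30, rate 0.12 h⁻¹, midpoint
40 h), bell (metabolite-like rise and fall, default amplitude 12, peak
45 h, spread 12 h), or linear. Pure-component spectra are sums of 5–15
Gaussian bands with seeded random centres/widths/heights, shared across a
cohort; per-batch parameter jitter (default 5% relative) emulates the
deliberately varied process conditions of a development campaign. The
OD650-like ground truth is a fixed positive multiple of the biomass
latent, hence strictly increasing in it. All randomness flows through
`(seed, batch_index)` substreams, making every batch bit-reproducible.

Presets:

- `linear-exact` — noiseless, both latents linear in time (so the second
  is affine in the first and the spectra lie in a 1-D affine subspace of
  spectrum space): the anticipation model class contains the truth and
  predictions are exact at every horizon. This is the pipeline's
  correctness workhorse.
- `realistic-yeast` — logistic + bell latents, baseline drift
  0.005 h⁻¹, channel noise sd 0.0022, i.e. 1% of the median within-window
  (5 h, hourly) RMS signal variation of the noiseless trajectories,
  measured once on the preset itself.

What the generator does **not** emulate: heteroscedastic shot noise,
cosmic-ray spikes, detector binning, water/fluorescence backgrounds,
spiking experiments, or control-loop feedback. Passing tests therefore
demonstrate the correctness and qualitative behaviour of the pipeline
(exactness inside the model class, the baseline signature, variance
structure, degradation with horizon), not quantitative performance on
instrument data.

## Downstream OD demo

The demo feeds anticipated spectra to a deliberately simple stand-in
chemometrics model: a ridge-regularised linear map from the (optionally
detrended) spectrum to OD, with the penalty selected by leave-one-batch-out
cross-validation over the fixed grid {1e-10, 1e-6, 1e-2, 1, 100}. It is a
transparent demonstration vehicle for the plug-and-play claim — any
spectrum-to-quantity model can consume anticipated spectra — not a
production biomass model. Per-horizon RMSE is reported relative to the OD
predicted from the *actual* spectrum, isolating the anticipation error
from the chemometrics error.

## Numerical choices

- PCA via full SVD (scikit-learn, `svd_solver="full"`): deterministic,
  exact for the tiny windows involved.
- A window is degenerate when its total centred energy is below 1e-18 of
  its total energy.
- Trend fits use `numpy.polynomial` least squares; the ridge fit uses the
  closed-form normal equations on the standardised predictor.
- Cosine similarity clips to [−1, 1] to absorb floating-point overshoot;
  zero-norm vectors are refused rather than returning NaN.
- CSV round-tripping writes shortest-repr floats and reads with pandas'
  `float_precision="round_trip"`, making write-then-read the identity.

## Problem sizes

The test suite and the acceptance script run on desk-scale cohorts chosen
to exercise every code path with comfortable margins: 1–5 batches per
cohort, 90 h at hourly (or 30-min) acquisition, the full 3326-channel
axis, and 20 seeds where seed-averaged trends are asserted. Cohort-size
defaults (23 batches) match a full development campaign and are used where
cost permits.

## Known limitations

- Score extrapolation cannot anticipate a turning point it has not seen;
  horizons beyond ~10–15 h show growing bias and spread on non-monotone
  latents (this mirrors the method's intended use: short-to-medium-horizon
  foresight, with ~20 h judged practically useful).
- No uncertainty bands on anticipated spectra; the spread of delta_tmin
  across anchors is the only dispersion measure provided.
- The PC3 variant's fit family is assumed, not selected by cross-validation.
- Cosine similarity between raw fermentation spectra is compressed near 1
  (a large shared background dominates); tmin discrimination rides on small
  differences, which is why the d2-detrended comparison is offered.
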