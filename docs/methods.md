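# Methods

## Model

Both observed streams are treated as linear images of shared speech-
production sources: `X_A = S A_A + ε_A` (T×25 envelope modulation
subbands) and `X_V = S A_V + ε_V` (T×204 landmark coordinates), with
view-specific noise. Canonical correlation analysis estimates backward
weights `W` mapping observations to source estimates; the forward mixing
is recovered as the canonical loadings `Â = ΣW`, i.e. the covariance
between input features and canonical variates. Because each audio
component is a linear combination of bandpass filter outputs, and
convolution distributes over addition, the component acts on the
envelope as a single filter whose transfer function is the weighted sum
of the bank's transfer functions: the effective MTF is `|H Σ_A W_A|`.

The linear model is deliberate: components can be read directly in the
envelope-frequency and face domains. No time lags are modeled; the
narrowly spaced filterbank can absorb small audio-video asynchronies
within a component's passband.

## Audio front-end

- Resampling: polyphase (`scipy.signal.resample_poly`), anti-aliased.
  Input WAVs are converted to mono and 16 kHz.
- Gammatone bank: 31 4th-order IIR filters, centers equally spaced on
  the ERB-rate scale from 80 to 8000 Hz. The count and range are fixed
  design values; ERB spacing and 4th order are the standard convention
  for this bank. A center at exactly Nyquist is designed a hair below
  it.
- Envelopes: magnitude of the analytic (Hilbert) signal per channel.
- Modulation bank: 25 first-order Butterworth bandpasses, centers 0.5,
  1.0, …, 12.5 Hz (the video-rate Nyquist), band edges at center
  ± 0.375 Hz — for a Butterworth design the −3 dB points, so the
  measured bandwidth is 0.75 Hz by construction (verified within 5%).
  Filters are applied causally (forward only): the components are
  interpreted as transmission filters, and zero-phase filtering would
  hide the lag-absorbing role of the bank.
- For tractability envelopes are decimated to 100 Hz before modulation
  filtering and the filtered averages resampled to 25 Hz; filtering and
  channel-averaging commute (both linear), so the per-channel average is
  filtered once. Linearity and the equivalence of IIR filtering with
  impulse-response convolution are asserted to 1e-6 relative or better
  in the suite.
- Per-video standardization: each of the 25 columns to zero mean, unit
  variance; zero-variance columns (silence) become exact zeros with a
  warning.

## Visual front-end

Landmark tables are read in a long (`frame, landmark, x, y, z`) or wide
(`l00_x … l67_z`) text dialect; columns are landmark-major (column
`3l+d`). Preprocessing: 4th-order causal Butterworth low-pass at 8 Hz
(order unstated in the reference design; 4th gives ≥24 dB/octave),
a one-frame delay of the video stream (edge-padded by default so frame
counts match the audio; a `drop` mode is available), then
standardization pooled within each spatial dimension per video — all x
coordinates jointly, likewise y and z, including the estimated-depth z
on the same footing.

## rCCA

Covariances are pooled sums of per-video Gram matrices. Regularizers
scale with the mean diagonal of each view's covariance, so λ ∈ [1e-5, 1]
is comparable across a 25-dimensional and a 204-dimensional view; the
convention is recorded on every model. The solution is computed on the
symmetric operator `(Σ_A+λ_A s_A I)^{-1/2} Σ_AV (Σ_V+λ_V s_V I)^{-1}
Σ_AVᵀ (Σ_A+λ_A s_A I)^{-1/2}` via `eigh` — mathematically the
generalized eigenproblem of the Lagrangian, numerically better behaved.
Signs follow a fixed convention (largest-|entry| audio loading
positive); components are ordered by decreasing ρ. Unregularized fits on
rank-deficient data raise an error advising λ > 0. Correctness is
checked against an independent whitening-SVD oracle (1e-8) and the
invariance of unregularized correlations under invertible feature
transforms.

MTF composition uses the bank's magnitude responses (H real). Complex
composition was measured to push the peak of a symmetric loading bump
upward by up to half a channel spacing through inter-channel phase
rotation; magnitude composition recovers planted rates without bias.
Phase is retained internally (`ModulationFilterbank.transfer_matrix`).
Component spectra use Welch averaging (2 s segments, 50% overlap, Hann
taper) and are reported as power; spectral peaks take the global
maximum, plateaus resolving to the lowest frequency.

## Evaluation scheme

Splits are grouped by speaker: 10% of videos (by whole speakers) to the
test set, the rest to five balanced folds; no speaker crosses a
boundary (asserted on every split). The match–mismatch objective on a
held-out fold is the sum, over components exceeding the fold null's
95th percentile, of matched correlation minus the null's median.
Matched correlations are computed on variates concatenated across the
fold's videos (per-video averaging is available as an option); each
null sample pairs the audio of one video with the visual stream of a
different video, truncated to the shorter length — a "segment" is a
whole video, since source clips run only seconds. One null pairing
yields all components' null values at once.

The two λ's are optimized over [1e-5, 1] with 5 log-uniform random
evaluations followed by 5 GP-guided ones (Matern-5/2 surrogate, hedged
LCB/EI/PI acquisition). Each candidate is scored by the five-fold *sum*
of objectives in a single search loop; the winner is the highest summed
cross-fold objective. The final model is refit on the full training set
and its components judged on the test set: significant above the 95th
percentile of a 1000-sample test-set null, reported only if the matched
correlation also reaches 1%.

A statistical subtlety: a matched correlation computed on a long
concatenated evaluation set is much more concentrated than single-pair
null samples, so the 95th-percentile rule is conservative rather than
exact in that configuration. The calibration study therefore compares
per-video matched correlations against single-pair nulls of the same
video length, which are exchangeable under audiovisual independence;
measured false-positive rates sit at the nominal 5% (within the
tolerance induced by estimating the percentile from finitely many null
samples). The full pipeline keeps the concatenated statistic, whose
conservatism only strengthens reported components.

## Synthetic corpora

Latent sources are bandlimited Gaussian noise (hard FFT band masks,
re-standardized): the rhythms being emulated are quasi-regular, not
periodic. The flagship study conditions plant two sources —

- 4.0 Hz (bw 1.0 Hz, amplitude 1.3): audio mixing is a Gaussian bump
  over modulation-channel centers at 4 Hz; visual mixing covers the 20
  mouth landmarks (48–67), vertically dominant;
- 1.5 Hz (bw 1.0 Hz, amplitude 0.8): audio bump at 1.5 Hz; visual
  mixing spreads over the 48 non-oral landmarks with small oral
  involvement.

The amplitude hierarchy mirrors natural AV speech, where oral/syllable-
rate coupling is the strongest canonical component and slower head/face
coupling is weaker; it also keeps the decomposition identifiable —
equal source strengths make the two canonical correlations coincide,
and a degenerate pair can be rotated arbitrarily within its subspace,
so no method could match the planted patterns. Noise SDs default to 1.0
per feature ("moderate": per-coordinate SNR ≈ 1 on driven features,
pooled over 25/204 features by the model). No quantitative real-data
SNR was available to calibrate against, so these are design choices.
Speaker variation: mixing vectors jittered multiplicatively (10%) and
source centers additively (SD 0.2 Hz) per speaker.

The waveform-level generator modulates a Gaussian noise carrier with
`max(0, 1 + 0.6·mix)` (rectified fraction recorded, ~6% under flagship
conditions) and drives a schematic static 68-point face with the
source-driven motion plus estimation jitter. It emulates the modulation
content, speaker structure and file formats of a real corpus — not
phonetics, coarticulation, face geometry, or physiological motion
(breathing, heartbeat), so passing tests demonstrate correct machinery
and statistical calibration, not that real speech carries these exact
rates.

## Problem sizes

The flagship corpus is 30 speakers × 5 videos × 60 s at 25 fps
(150 videos, 225k frames), with a 10-evaluation λ search over 5 folds,
a 200-sample null per fold during the search and a 1000-sample null for
the final test — one replicate runs in ~10 s, and the recovery study
repeats it over 10 seeds. Calibration uses 200 independent corpora of
8 speakers × 3 videos × 10 s with 200-sample nulls; the no-survivor
check uses an 18,000-frame independent test set. Speaker identification
uses 20 speakers at noise SD 5 (a deliberately hard regime so the
duration dependence is visible) with 200 trials per duration.

## Known limitations

- Linear, lag-free model; nonlinear AV dependencies and systematic
  audio-video asynchronies are out of scope by design.
- The synthetic generator draws landmark noise i.i.d. per coordinate;
  real face-alignment errors are spatially and temporally correlated.
- The GP search is a light (10-evaluation) optimizer; the objective
  surface is smooth and low-dimensional, but the budget is configurable
  where more exploration is wanted.
- With evaluation sets much longer than individual videos, the
  concatenated matched statistic makes the significance rule
  conservative (see above); interpret absolute significance counts
  accordingly.
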