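# Methods

## Synthetic ECG model

Each cardiac cycle is a sum of five Gaussian bumps — P, Q, R, S, T — each
with an amplitude (mV), a centre offset from the R peak (s) and a width
(Gaussian sigma, s), plus a smooth plateau over the ST window. The template
defaults are package conventions chosen to resemble a plausible limb-lead
trace, not fits to any recording:

| wave | amplitude (mV) | centre (s) | sigma (s) |
|------|---------------|------------|-----------|
| P    | 0.15          | −0.22      | 0.025     |
| Q    | −0.12         | −0.035     | 0.010     |
| R    | 1.00          | 0.0        | 0.013     |
| S    | −0.15         | +0.035     | 0.010     |
| T    | 0.30          | +0.30      | 0.050     |

Class templates modify this base:

- **Sinus rhythm** — the base template; QRS duration measured at 10% of the
  R amplitude is ≈ 85 ms (< 100 ms).
- **QRS widening** — Q/R/S centres and widths scaled by 1.7, giving a QRS
  duration ≈ 140 ms (≥ 120 ms, the conventional widening threshold).
- **ST depression / elevation** — a −0.15 / +0.20 mV plateau over the ST
  window, defined as [R + 0.06 s, R + 0.20 s] at RR = 1 s and scaled
  linearly with the local RR; the plateau has 20 ms half-cosine ramps so it
  adds no broadband splatter.

Beats are placed at programmed R times: mean spacing 60/HR seconds, first
peak half an interval into the record. RR jitter is zero-mean Gaussian (sd a
configurable fraction of RR, default 3% where variation is wanted, truncated
at ±20%); optional per-beat amplitude jitter models gain variation. Defaults
elsewhere emulate the targeted acquisition set-up: 360 Hz sampling, 0.5–40 Hz
band content, resting heart rates of 60–100 bpm. Everything is driven by one
seed; identical arguments give bit-identical output.

What the generator does **not** model: real morphological diversity within a
class, respiratory modulation and heart-rate variability structure, electrode
artefacts, arrhythmic rhythms, or multi-lead geometry. Passing tests on this
data therefore demonstrate that the pipeline's mechanics are correct and that
the four idealised morphologies are separable — not that the classifier
reaches any particular accuracy on clinical recordings.

## Conditioning

Both operations work on the real FFT of the whole record. `bandlimit` zeroes
bins outside [0.5, 40] Hz (DC always included in the cut and excluded from
any maximum search) and inverse-transforms; `fft_threshold_denoise`
additionally zeroes in-band bins whose magnitude is below 0.2 × the maximum
in-band magnitude. The threshold is applied *after* band limiting and to the
*magnitude* (not power); both choices are package conventions, stated here
because other readings exist. Operating on the half-spectrum (rfft/irfft)
guarantees a real output. Since bins are only zeroed, output energy never
exceeds input energy.

The magnitude-threshold step behaves as a lossy spectral compression: it is
near-lossless on quasi-periodic signals with a sparse line spectrum, but on
recordings with RR jitter the beat train's spectrum is not sparse and the
step visibly distorts beat morphology (measured here: up to ~40% of R peaks
missed downstream). The full pipeline therefore conditions with band-limiting
by default and exposes the threshold denoiser as an explicit option
(`conditioning: "threshold"`) and as its own CLI stage.

## R-peak detection and segmentation

The detector is a Pan–Tompkins-style chain: band-pass 5–15 Hz (order-2
Butterworth, zero-phase), differentiate, square, 150 ms moving-window
integral, adaptive threshold = local mean + k·sd over a sliding 2 s window
(k = 1.5), candidate peaks at least 200 ms apart, each snapped to the raw
signal's maximum within ±50 ms. A flat signal yields an empty peak list.
k trades sensitivity against false positives; 1.5 keeps both ≥ 0.95 at a
white-noise sd of 0.05 mV against a 1 mV R wave.

Segments follow the half-RR rule: beat i spans
[R_i − RR(i−1,i)/2, R_i + RR(i,i+1)/2), half-open, half-widths floored to
integer samples. Boundary peaks produce no segment (no half-RR neighbour);
with uniform RR the segments tile the span between the first and last
midpoints exactly. On annotated records, reference beat annotations can
anchor segmentation instead of the detector.

## Beat imaging

Each beat is resampled to the image width and drawn as a connected 1-pixel
black polyline on white, default 256 × 256. Voltage maps through a *fixed*
window ([−1.5, +2.0] mV, clipped) to rows: per-beat min–max normalisation
would erase exactly the ST-level information two of the classes are defined
by. PNG is the default (lossless, so tests can require bit-exact round
trips); JPG is supported. Rendering is a pure function of the beat and the
settings.

## Classifier

A numpy convolutional network: blocks of 3×3 same-padding convolution →
ReLU → 2×2 max pool, then flatten → linear 4-way head, softmax
cross-entropy, Adam (lr 10⁻³), all randomness from one seeded generator so
retraining reproduces the confusion table bit-for-bit on the same machine.
The head flattens rather than global-average-pools deliberately: the four
classes differ by *where* the trace lies in the frame (ST level, QRS
width), and pooling away spatial position leaves the net at chance. The
loader inverts intensities (trace = 1, background = 0) and resamples images
to the configured input resolution (default 64 × 64) so desk-scale training
runs in seconds-to-minutes on one CPU; the standard experiment used
throughout is 4 × 200 images, 50/50 split, 10 epochs.

`small_cnn` (channels 8/16/32) is the default; `resnet_tl`, `alexnet_tl`
and `squeezenet_tl` are deeper presets of the same family standing in for
transfer-learned reference architectures, carrying the published layer
counts of the nets they emulate (177/25/68) as metadata for parity
reporting. Every preset runs from random initialisation; a locally stored
checkpoint can be loaded via `init="checkpoint"`, so no download is ever
required. No augmentation is applied by default.

Balancing downsamples every class without replacement to the smallest class
(or an explicit count). The 50/50 split is per class, ceil(n/2) to
*training* — so an odd class of 5899 gives 2950 train / 2949 test.

## Evaluation metrics

Defined in `ecgpipe.metrics` exactly as in the README. Two conventions are
worth naming:

- **Macro F1** defaults to the harmonic mean of macro precision and macro
  recall; the unweighted mean of per-class F1s is available as
  `f1_mode="mean_of_f1"`. The two differ in the fifth decimal on the bundled
  benchmark tables; the default matches those tables' published aggregates.
- A class with an empty row or column reports the affected metric as
  undefined (`None`, flagged), never silently 0; macro aggregates over an
  undefined class raise.

With balanced row sums, macro recall equals accuracy and the expected
agreement p_e is exactly 1/K, so kappa = (accuracy − 1/K)/(1 − 1/K); the
test suite uses this identity as an internal cross-check.

## RR agreement

Zero differences are dropped before ranking (classic convention; Pratt's
variant is a flag). Ties receive midranks. For n ≤ 25 the two-sided p comes
from the exact null distribution of W+, computed by convolving the
generating polynomial of the observed ranks (midranks doubled to stay on an
integer lattice) — mathematically identical to enumerating all 2ⁿ sign
vectors; beyond 25, a normal approximation with continuity correction and
the standard tie correction Σ(t³−t)/48 on the variance. If every difference
is zero the devices agree exactly and p = 1 by convention. The agreement
band defaults to ±0.1 s; MA coordinates are ((a+b)/2, a−b).

Input series must be pre-aligned pairwise; no beat-matching between devices
is attempted.

## Numerical and degenerate-input choices

- Sample indices 0-based; t = index/fs; half-RR widths floored; half-open
  segment windows prevent one-sample overlaps.
- ADC conversion for serial streams: mV = (code − 512) × 1000 × 3.3 / 1024
  (10-bit, 3.3 V reference) — a fixed affine convention so fixtures are
  deterministic.
- WFDB dialect: format 212 (12-bit two's complement, two samples per 3
  bytes) at gain 200 ADC units/mV; annotation files use 6-bit type codes
  with 10-bit intervals and the 4-byte long-interval escape. Round-trip
  fidelity is tested; quantisation error is bounded by half an ADC step.
- All-zero signals: denoising returns them unchanged; the detector returns
  an empty peak list; an all-zero confusion table raises an
  undefined-metric error.

## Problem sizes

The standard experiment scales used by the test suite and the acceptance
script — 30–60 s recordings, 4 × 200 beat images at 128 px rendered /
64 px trained, 10 epochs — were chosen as the package's desk-scale defaults:
large enough that every stage is exercised with statistically meaningful
counts, small enough to run interactively on a single CPU.

## Known limitations

- The synthetic generator's class templates are idealised; inter-class
  separability is by construction far higher than in clinical data.
- The detector is tuned for resting rhythms (60–100 bpm); arrhythmia and
  tachycardia are out of scope.
- The WFDB writer/reader covers the format-212 single/two-channel dialect
  used here, not the full format family.
- Mapping clinical annotation codes onto the four morphology classes is
  deliberately not shipped; synthetic data is the supported evaluation path.
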