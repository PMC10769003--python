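# Methods

## Scope and intent

`aiirf` is an analysis package plus a phenomenological generator. The
generator is *not* a biophysical model of the AII amacrine cell: it is the
simplest stochastic process we could write down that (a) has the circuit
structure dissected by the pharmacology and genetics it emulates, and (b)
reproduces the published population statistics when pushed through exactly
the same metric pipeline a physiologist would apply to real recordings. Its
purpose is to make every stage of the analysis testable — including the
biases of the estimators themselves — without access to raw recordings.

## Stimulus model

Stimuli are cell-centered discs, annuli, bars or full-field fields at Weber
contrast `c(t)` atop a steady background expressed as a photoisomerization
rate (R*/rod/s; 0.5 / 500 / 25,000 denote the scotopic / mesopic / photopic
regimes). Step epochs use 0.5 s pre-stimulus, 0.5 s stimulus, 1.0 s
post-stimulus (the source figures mark the stimulus window but not absolute
timings; these defaults separate transient from sustained components and are
configurable). Sinusoid epochs hold an integer number of cycles (default 4)
between 0.5 s flanks. The 60 Hz projector frame rate is carried as metadata;
sample-and-hold frame quantization of the sinusoid is available behind a
flag and off by default because metrics at ≤ 20 Hz are insensitive to it.
Presentation order is pseudorandomized by an explicit recorded seed. The rod
collecting area (0.85 µm²) is metadata only.

## Response model

Spatial summation is Gaussian. For a disc of diameter `d`,
`G(d; σ) = 1 − exp(−d²/8σ²)`; annuli are differences of discs and bars are
products of 1-D Gaussian integrals. Center and surround use widths
`σ_c` (AII 16.5 µm fitted, ganglion cell 45 µm) and `σ_s = 300 µm`. `σ_s`
is fixed by hand: it makes the surround grow over the whole 100–1200 µm
range probed, consistent with wide-field amacrine/horizontal-cell spatial
scales; the metrics constrain mainly the product of weight and surround
drive, so `σ_s` and the weights are not separately identifiable from the
calibration targets.

Temporal stages, all derived from the contrast waveform `x(t)`:

* center drive `L(t)`: first-order low-pass, τ_on = 40 ms (rise and fall
  equal by default so the surround-free model is exactly linear — a
  property the rectification analysis relies on);
* sustained surround `S(t)`: first-order low-pass, τ_sus = 60 ms — the
  horizontal-cell (HEPES-sensitive) component, linear in contrast polarity;
* transient surround `T(t)`: an alpha function (τ_tr = 90 ms) driven by
  onsets of the *rectified* contrast `x⁺(t)` with a 60 ms synaptic latency —
  the spiking-amacrine (TTX-sensitive) component. Because it is ON-driven it
  is absent for negative-contrast annuli, as observed.

For a stimulus with spatial drives `(c, s)` and background-specific gains,
the current-clamp response is

```
V(t) = A·g·c·L(t) / (1 + s·[w_tr·T(t) + w_sus·S⁺(t)])  −  s·[W_tr·T(t) + W_sus·S(t)]
```

divisive presynaptic surround (GABA_C on bipolar terminals) and subtractive
direct surround (GABA_A on the AII). `g` is the pathway gate
`f_RBC·[no NBQX] + (1 − f_RBC)·[Cx36 intact]`. Voltage-clamp EPSCs are the
divisive term alone with its own weight (voltage and current clamp see
different effective surround strengths in the data — EPSC charge suppression
is stronger than PSP peak suppression — so the presynaptic weight is
calibrated per recording mode); IPSCs are the direct term plus a
narrow-field glycinergic component present only photopically and suppressed
for spots > ~200 µm (difference of 40/70 µm Gaussians). Ganglion-cell spike
rates are `rate_base + rate_gain · max(drive, 0)` through an inhomogeneous
Poisson sampler; the Cx36 knockout removes the AII-inherited surround from
the ganglion cell while leaving its cone-bipolar excitation, and knockout
recordings use +300% contrast (reduced sensitivity), matching the
experimental design.

Drug/genotype switches are binary component gates: TTX and (at the mesopic
background only) nNOS-1-ablation zero the transient weights; HEPES zeroes
the sustained weights; TPMPA zeroes the presynaptic weights; gabazine zeroes
the direct GABA_A surround and multiplies the presynaptic weight by 1.3
(release of serial inhibition — a single configurable factor, the serial
circuit itself is not modeled); strychnine zeroes the glycinergic IPSC.
Concentrations are metadata.

## Noise and trial structure

Each trial is `noiseless timecourse × cell gain × trial gain + noise`:

* across-cell gain: lognormal, mean 1, CV 0.3, drawn once per cell;
* across-trial gain: lognormal, mean 1, CV 0.05 — ordinary trial-to-trial
  response variability. This term is what produces the small positive
  residual SSI (~0.02–0.04) seen when all surround mechanisms are blocked:
  taking the maximum over a flat, noisy size-tuning curve is upward-biased;
* additive recording noise: Gaussian low-passed at 100 Hz, SD 0.3 mV
  (current clamp) / 2 pA (voltage clamp). The noise floor is absolute, not
  proportional to the response, as in real instrumentation.

None of these are published quantities; they are declared free parameters.
They were chosen so that the extreme-value bias of the peak-depolarization
statistic (a per-trial maximum over the stimulus window) stays within the
published population uncertainties; substantially larger relative noise
would inflate every peak-based metric beyond them.

Randomness uses counter-based substreams keyed on
(master seed, purpose, cell, epoch, trial), so any subset of the population
is bitwise reproducible in isolation.

## Calibration

The packaged target table (`data/reference_targets.csv`) holds the published
population means; `calibrate()` fits the generator to it. Each fit is
one-dimensional and monotone:

| parameter | target | method |
|---|---|---|
| `f_RBC(L)` | NBQX charge-reduction fraction | direct |
| `w_sus` (EPSC) | SSI in TTX | bisection on noiseless charge-SSI |
| `w_tr` (EPSC), `f_transient` | control SSI | bisection given `w_sus` |
| `W_post` | annulus transient peak | linear (annulus center drive ≈ 0) |
| `w_pre` (PSP) | PSP SSI | bisection on noiseless peak-SSI |
| `A(L)` | 88-µm peak ΔV | affine solve (2-step fixed point with `w_pre`) |
| amplitude scales (EPSC/IPSC/glycine) | peak/charge anchors | linear |
| `w_pre` (spikes) | spike-count SSI | bisection on analytic rate integral |
| `σ_c` | RF-center size | expectation match (below) |

`σ_c` is the one exception to noiseless fitting. The "smallest spot
producing maximal response" estimator on a discrete diameter grid is a step
function of `σ_c`, and under measurement noise it is upward-biased (the
95%-of-max threshold is set by a noisy maximum). A noiseless fit therefore
systematically undershoots the population estimate it is supposed to match.
`σ_c` is instead fitted by matching the *mean* estimator output under the
default noise model at the reference n (13 cells, 4 trials, fixed internal
seed), alternated twice with the weight fits since bias and weights
interact. The diameter grid (14 values, 10–1200 µm) spaces points
geometrically with extra resolution at 88–150 µm so the estimator can
resolve centers near 100 µm.

The shipped `data/default_calibration.yaml` is the output of `calibrate()`
on the packaged targets; tests verify that the noiseless round trip
(generator → metrics) reproduces each target SSI to 1e−4. The photopic
88-µm PSP amplitude (12 mV) and the EPSC amplitude scales are assumed
values (marked in the target table): the sources constrain ratios, not
these absolute scales, and no packaged result depends on them beyond units.

## Analysis conventions

* Charge: trapezoidal integral over the stimulus window per trial, averaged
  across trials, reported as magnitude in pC (at 10 kHz the integration-rule
  error is negligible for band-limited signals).
* Peak depolarization: per-trial maximum over the stimulus window, averaged
  across trials (minimum for hyperpolarizing responses, sign kept).
* Cycle analysis: trials averaged, first cycle discarded as onset transient,
  remaining cycles folded; excursions measured from the pre-stimulus
  baseline (a half-wave-rectified response then gives RI = +1 exactly; a
  cycle-mean baseline option exists).
* Annulus decomposition: transient = signed extremum in the first 200 ms of
  the stimulus, sustained = mean over the final third; both windows are our
  conventions. The averaged trace is zero-phase low-passed at 50 Hz before
  the extremum — well above the transient's ~3 Hz bandwidth — because an
  extremum over a noisy window is otherwise biased by the noise bandwidth.
* RF-center criterion ε = 0.05; exposed as a parameter.
* PSTH: 100 ms sliding window on a 1 ms grid, half-open window convention;
  the discrete rate integral times trial count equals the spike count
  exactly.
* Paired-trace subtraction (e.g. control − TTX isolation of a current
  component) is a generic per-timepoint operation on matched trial bundles
  after baseline subtraction.
* Statistics: mean ± SEM (n−1 denominator); two-tailed Student's t tests,
  pooled-variance unpaired by default with a Welch flag; one-way ANOVA. No
  multiple-testing correction is applied, matching the source analyses.

## What the generator does and does not emulate

Passing tests show that the *analysis pipeline* recovers the statistics of a
population whose circuit structure and summary statistics match the
published ones. They do not validate biophysics: there are no conductances,
no gap-junction network dynamics, no dopamine/nitric-oxide neuromodulation
(deliberately minimized in the emulated preparation), no OFF-pathway
responses, and no spike generation in AIIs. Mesopic surround in the
nNOS-ablated retina keeps the wild-type horizontal-cell weight — plausible
but only weakly constrained by the sources. Trial-to-trial and across-cell
variability are single CV parameters, smaller than the spread implied by
some published SEMs; real per-cell heterogeneity (kinetics, RF asymmetry,
electrode quality) is not modeled. Luminance enters only through the three
calibrated backgrounds; there is no continuous luminance model.

## Problem sizes

Packaged experiments run at the reference sample sizes (5–13 cells, 4
trials, 14 spot diameters, 10 kHz traces of 2 s); a full acceptance run
simulates ~3,000 traces and completes in well under a minute on one core,
with the calibration refit (~40 s) needed only when targets change.
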