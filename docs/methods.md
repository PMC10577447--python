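# Methods

This note documents the models, conventions and design choices behind
`rfttag`: what the simulator emulates, how the spectral estimates are
normalized, how the permutation procedures are defined, and where the
design was genuinely open.

## Stimulus model

The tagging drive is a luminance time series

```
s(t) = b + ½ · d · e(t) · sin(2π f t + φ0)
```

with baseline luminance `b = 0.5` (mid-grey, matching the screen
background) and modulation depth `d = 1.0` by default, so the drive spans
the full black-to-white range; both are configurable. The envelope `e(t)`
rises 0 → 1 over the ramp as a half-Hanning window, `sin²(π t / (2 T_ramp))`,
stays at 1 over the plateau, and falls symmetrically. With the default
1.4 s train and 0.2 s ramps, full stimulation lasts exactly 1 s. The
envelope is constructed sample-symmetrically about the train midpoint, so
"plateau" at the sample level is the half-open interval `[0 s, 1 s)`; its
sample count divided by the rate is exactly 1 s. The initial phase `φ0`
defaults to 0.

Time zero is the onset of *full* stimulation (end of ramp-up) everywhere in
the package. An epoch spans −1.4 … +1.4 s: 1.2 s fixation baseline, ramp-up
over −0.2 … 0 s, plateau 0 … 1 s, ramp-down 1 … 1.2 s, 0.2 s post-stimulus.

The spatial taper delivers full amplitude in a central disc covering 60 %
of the patch diameter and falls to zero at the edge across the surrounding
annulus. The falloff profile inside the annulus is a raised cosine — the
plateau/annulus geometry is what matters experimentally; the profile shape
is a package choice.

Session schedules follow the three-session design: a frequency sweep
(12 blocks × 33 tagging trials over 11 frequencies 60–100 Hz step 4, plus
11 response trials → 36 tagging trials per frequency, 25 % response
trials), a size sweep (same counts over 2–12°, 66 Hz), and a position grid
(16 blocks × 45 trials, 30 tagging over 15 positions → 32 per position).
Response (catch) trials are scheduled, labelled, and excluded from
analysis; their epochs are simulated like tagging trials rather than with
the distinct catch-trial timing, since nothing downstream analyses them.
The 100 Hz condition is scheduled but excluded from analysis by default as
a harmonic of the 50 Hz line frequency.

## Synthetic MEG

No public dataset accompanies this experimental design, so the simulator
is the test bed: it produces data whose ground truth is known exactly, and
the tests assert that the analysis chain recovers that ground truth.

**Sensor array.** Positions on the unit head disc, each hosting two
co-located "planar gradiometers" and optionally one "magnetometer"
(Neuromag-style triplet). Twelve posterior positions sit on two occipital
arcs; the rest tile the remaining scalp on a sunflower spiral with a small
seeded jitter. Adjacency connects positions closer than a threshold set
just above the largest nearest-neighbour distance, guaranteeing a connected
neighbourhood structure for cluster formation. This is deliberately *not* a
forward model: sensor weights of the response are imposed directly.

**Response model.** The tagging response in channel *c* on trial *k* is

```
A · g_f(f) · g_s(s) · g_p(x, y) · g_part · w_c · e(t − τ) · sin(2π f (t − τ) + θ_k)
```

* `A` (`amp0`, default 0.15 a.u.) — response amplitude of the best
  posterior sensor at the 60 Hz / 6° / lower-central reference condition.
* `g_f` — linear decline from 1 at 60 Hz to 0 at 88 Hz, zero above. The
  cutoff mirrors the observation that tagging responses reach baseline near
  88 Hz.
* `g_s` — linear growth through the origin, 1 at 6°; responses grow with
  patch size without plateauing over 2–12°.
* `g_p` — separable row × column multipliers over the 3 × 5 grid:
  rows lower 1.0 / middle 0.78 / upper 0.52, columns centre 1.0 / ±6° 0.74 /
  ±12° 0.48, encoding the lower-field and central-field advantages.
* `g_part` — per-participant lognormal gain (σ = 0.35, reproducible per
  participant id), spanning roughly the 2–5× between-participant range seen
  in individual coherence ratios.
* `w_c` — Gaussian falloff (width 0.4) from the occipital pole, multiplied
  by (1 ± 0.35) for the hemisphere contralateral/ipsilateral to a lateral
  patch, and by 1.3 for magnetometers (their higher apparent SNR).
* `τ` = 50 ms fixed response lag (no empirical value is imposed; any small
  fixed lag leaves coherence invariant), `θ_k` ~ N(0, 0.15²) rad per-trial
  phase jitter.
* A second harmonic at `2f` with relative amplitude 0.12 is added to
  magnetometers only, reproducing the sensor-type asymmetry in harmonic
  visibility.

**Noise.** Channel noise is built in the frequency domain from independent
complex-Gaussian bins shaped by an amplitude profile: a `1/f^(α/2)` trend
(α = 1), a Gaussian alpha bump at 10 Hz (width 1.5 Hz), and a flat floor
whose time-domain SD is `white_sd = 1.2`. The photodiode channel carries
the drive itself plus white noise of SD 0.02 — without it the baseline
interval would have zero photodiode variance and baseline coherence would
be undefined; with it, baseline coherence sits at the estimator's 1/N bias
floor.

**Calibration.** `amp0` and `white_sd` were chosen once so that, with the
default noise, the grand-average posterior coherence is ≈ 0.4–0.5 at 60 Hz
and declines to the baseline floor by ≈ 88 Hz, and so the 60 Hz power peak
is visible but modest next to the alpha peak. Tests assert orderings and
sign of slopes, never these absolute values, which in real data depend on
participant physiology and hardware.

**What the simulator does not capture.** Realistic head geometry and
leadfields, eye/cardiac artefacts, line noise and notch-filter dips,
sensor-specific noise floors, non-stationary alpha, and any nonlinear
cortical dynamics beyond a fixed second harmonic. Passing tests therefore
validate the *analysis machinery* (estimators, inference, bookkeeping) and
the qualitative parameter dependencies, not quantitative predictions for
real recordings.

## Spectral estimation

Epochs are cut into a baseline (−1.2 … −0.2 s) and a full-stimulation
(0 … 1 s) segment. All sample windows are half-open `[start, stop)`, so a
1 s window at 1000 Hz is exactly 1000 samples and adjacent windows share no
sample. A single periodic Hanning taper is applied per trial (no
multitapering) before the DFT; with 1 s segments the bin spacing is 1 Hz
and every integer tagging frequency falls exactly on a bin.

DFT normalization: coefficients are scaled by `1/sqrt(n · Σw²)` so the
one-sided sum `Σ c_k |X_k|²` (with `c_k = 2` except at DC and Nyquist)
equals the mean power of the tapered signal. Any consistent convention
leaves coherence unchanged (it is scale-invariant per channel); the choice
is documented, not load-bearing.

Coherence is estimated from per-trial coefficients:
`C_xy = mean_k(X_k conj(Y_k))`, `Coh = |C_xy|²/(C_xx C_yy)`. Bins where
either auto-spectrum is zero are reported as NaN (undefined), never 0.
The estimator needs ≥ 2 trials — a single trial gives identically 1. For
independent signals its expectation is ≈ 1/N over trials, which is why
baseline coherence is non-zero.

Planar gradiometer pairs are combined by summing power and averaging
coherence; magnetometers pass through unchanged. The cross-spectrum has no
meaningful pair combination and is dropped from combined estimates.

Time–frequency maps use 500 ms Hanning windows slid in 50 ms steps over
2–100 Hz in 2 Hz steps (the native resolution of a 0.5 s window). The TFR
baseline window is configurable (default −0.6 … −0.4 s); reported analyses
of this kind have used windows between −0.6 and −0.2 s, and the package
asserts nothing about the specific choice.

Frequency lookup is nearest-bin with an explicit tolerance (at most half a
bin); an off-grid request raises instead of silently rounding.

## Statistics

**Wilcoxon signed-rank.** Zero differences are discarded (≥ 5 non-zero
pairs required); ties get mid-ranks. The standardized statistic is
`z = T / sqrt(Σ r_i²)` with `T = Σ sign(d_i) rank|d_i|`; `Σ r_i²` is the
exact null variance of `T` under sign flips even with ties. `z` is positive
when the first sample tends to exceed the second; swapping inputs negates
it exactly. p-values are exact (n ≤ 25, no ties) or by normal
approximation.

**Cluster-based permutation test.** Input: participants × sensors scalars
for two paired conditions (e.g. coherence at the tag frequency, stimulation
vs baseline). Per sensor a signed-rank z is formed; sensors with two-sided
p < 0.05 (the cluster-forming threshold, configurable) are clustered by
spatial adjacency separately by sign; cluster mass is the signed sum of z.
The null distribution is the maximum |mass| over random participant-wise
condition-label flips (the exchangeable unit in the paired design); with
n participants and `n_perm ≥ 2^n` (n ≤ 16) the flips are enumerated
exactly. Monte-Carlo p-values use the add-one convention
`(1 + #{null ≥ |mass|}) / (1 + n_perm)`, so p ∈ (0, 1]. Mass was chosen
over cluster size as the standard, strictly more informative statistic;
since observed and permuted datasets use the same statistic, validity does
not depend on the choice. Note the rank-based statistic needs ≥ 6
participants for any sensor to pass a 0.05 cluster-forming threshold
(with 5, only a unanimous sign pattern reaches |z| ≈ 2.02).

**Participant-level criterion.** A participant "shows a tagging response"
when their mean stimulation-interval coherence at the tag frequency over a
selected sensor set strictly exceeds the 95th percentile of the statistic
recomputed under shuffles of the baseline/stimulation trial labels
(group sizes preserved, coherence recomputed from pooled per-trial
coefficients). The test is one-sided by design: only a coherence increase
indicates tagging. The "selected posterior sensors" are an explicit
channel-id list in the configuration; the default is the layout's
posterior set of the analysis sensor type, standing in for the
by-inspection selection made when real topographies are available.

**Summaries.** The lateralization index is `(L − R)/(L + R)` at the tag
frequency, in [−1, 1], antisymmetric under hemifield swap, undefined when
both inputs are zero. (The implemented denominator is `L + R`, the only
form that bounds the index; printed renderings of this formula sometimes
duplicate one term.) Condition slopes are ordinary least squares with
their standard error, in coherence per condition unit (the frequency sweep
reports per 4 Hz, the size sweep per degree). Proportion significant is
`100 · #significant / #participants`.

**Design checks.** Two utilities support multi-stimulus designs: the
minimal distinguishable tagging-frequency separation `1/dT` for a
`dT`-second analysis window (5 Hz at 0.2 s, 2 Hz at 0.5 s), and the
intermodulation table `|m f1 ± n f2|` — a quadratic nonlinearity on summed
55 and 60 Hz drives produces its low-frequency component at the 5 Hz
difference frequency.

## Pipeline

`RunConfig` serializes losslessly through YAML and rejects unknown keys.
All stage seeds derive from the master seed via independent seed-sequence
spawns, so a config reproduces its outputs byte-for-byte. Default run
sizes (4 participants, 12 trials per condition, 500 permutations) are
desk-scale choices that keep a full session analysis in the tens of
seconds while leaving every statistic well-defined; the full experimental
counts (11 participants, 36/32 trials, 1000 permutations) are plain
configuration values.

## Known limitations

* The simulator's sensor weights are imposed, not forward-modelled; source
  localization is out of scope.
* Coherence is the only response measure with a participant-level
  criterion; evoked power (averaging before the spectral estimate) is not
  implemented.
* The cluster test assumes exchangeability across the paired conditions
  within participant; it inherits the usual caveat that cluster-level
  significance does not license sensor-level claims.
* Epoch persistence uses NumPy `.npz` containers with JSON/TSV sidecars;
  no native MEG file formats are read or written.
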