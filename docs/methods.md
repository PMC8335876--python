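# Methods

## Feature extraction

Each measurement is an amplitude-frequency sweep |S21|(f) in dB on a fixed
grid (default 1060 points, 1–100 MHz, step ≈ 93.5 kHz). The extraction is
deliberately literal and smoothing-free: the peak is the raw grid maximum
(ties broken toward the lowest frequency, flat curves rejected, a boundary
peak flagged), and the 3 dB band edges are the innermost crossings of
`peak − 3 dB` on either side of the peak. An exact-equality crossing
cannot occur on a discrete grid, so each edge is located by linear
interpolation between the two bracketing samples; the point count N,
used for band means, stays on the raw grid (points with f′ ≤ fₙ ≤ f″).
Interpolation stabilizes the bandwidth against grid quantization; if the
curve re-crosses the level further out (side lobes), the innermost
crossings keep the band the contiguous half-power region around the
characteristic frequency. When a crossing does not exist inside the sweep
span the record fails with an error naming the side; in cohort runs such
records go to a per-record error report instead of aborting.

The five parameters α, β, γ, δ, ρ are fractional changes relative to the
subject's own t₀ baseline (see README for definitions). Two conventions
deserve emphasis:

* Ratios are formed on dB values, whose denominators are negative for
  transmission measurements: an amplitude increase gives negative α/δ/ρ.
  The downstream mapping to [−1, 1] and orientation-corrected AUC make
  classification indifferent to this sign.
* Both ā₀ and āᵢ (the δ numerator) are means over the same N₀ grid points
  inside the baseline band [f₀′, f₀″]; ρ instead follows the current band
  [fᵢ′, fᵢ″]. When both bands cover the same grid points, δ ≡ ρ.

The −3 dB level is the conventional half-power definition; the exact
half-power drop is −10·log10(2) ≈ −3.0103 dB. Extraction uses the literal
−3; on the default grid the induced bandwidth difference is far below one
grid step and tests account for it in tolerance.

At t₀ all five parameters are identically zero by construction, so
baseline records are stored but excluded from every analysis window.

## Classification

The three comparisons label individual (subject, time point) measurements,
not subjects: detection over (0, 24] h (edema vs control), early detection
over (0, 1] h, and phase distinction (0, 6] h vs (6, 24] h within the
edema group. Windows are half-open on the left, so a record at exactly 6 h
is acute; this boundary choice is a package convention, fixed and tested.

For a parameter subset of size ≥ 2, each parameter is divided by the
pooled maximum absolute value over **both** classes before the Euclidean
norm is taken. Normalizing each class by its own maximum (the natural
reading of the scoring formula's symmetric notation) would place the two
classes on different scales, making a single threshold meaningless; the
pooled scale is the choice that lets one threshold T act on all
observations. Consequences: every mapped value lies in [−1, 1], scores in
[0, √k], and removing observations can only weakly increase the remaining
mapped magnitudes. A parameter that is identically zero contributes
nothing (with a warning) rather than dividing by zero.

The ROC is a deterministic threshold sweep: candidate thresholds are the
midpoints between consecutive distinct scores plus ∓∞ sentinels; AUC is
the trapezoid over (FPR, TPR) and equals the tie-aware Mann–Whitney pair
statistic (verified to 1e-12 in tests against both a hand pair-count and
scikit-learn). Score orientation is chosen so AUC ≥ 0.5, with the flip
recorded — the analysis is direction-agnostic because the parameter signs
depend on conventions (see above). The reported operating point maximizes
Youden's J = sensitivity + specificity − 1 (ties toward higher
sensitivity); Youden is the standard single-point criterion and is a
package decision, since operating points can also be chosen by cost
ratios or fixed-specificity rules. Display AUCs are additionally rounded
to two significant digits, mirroring common reporting practice; full
precision is always kept alongside.

## Synthetic cohort

The simulator emulates the measurement protocol the analysis assumes:
49 sweeps per subject (0–24 h every 30 min), 1060-point grids over
1–100 MHz, 10 experimental and 4 control subjects. The sensor–head
coupling is modeled as a single resonance, Lorentzian in linear power over
a flat floor — the simplest shape with the right physics (a resonant
two-port near critical coupling) and closed-form half-power points, which
makes recovery testable analytically. Baseline descriptors vary between
subjects via normal priors: peak −15 ± 1 dB, center 56 ± 1.5 MHz, FWHM
8 ± 0.8 MHz (floor −60 dB), matching a coil resonance in the mid-sweep
range.

Edema is a piecewise-linear drift of the three descriptors: fractional
endpoint changes of +8 % of |A₀| (in dB) for the peak, +1.5 % for the
center frequency and +25 % for the bandwidth, with 70 % of each realized
by 6 h — a fast acute phase followed by a slower chronic phase. Controls
carry no drift. These effect sizes are package defaults chosen to encode
the qualitative fast-then-slow trajectory at magnitudes a coil sensor
plausibly resolves; they are not measured values, and the ground-truth
sidecar (noise-free descriptors per subject and time point) makes every
default auditable. A late (15–18 h) secondary acceleration seen in some
edema time courses is not modeled.

Noise has two components with distinct statistical roles:

* **Physiological jitter** (per time point, i.i.d.): 0.05 dB on the peak,
  300 kHz on the center frequency, 300 kHz on the width. This is the
  dominant variability of control subjects — fluctuation from blood and
  oxygen supply — and because it is independent across time points it
  keeps the observations of different subjects exchangeable under the
  null.
* **Instrument (VNA trace) noise** (per frequency point, i.i.d.):
  0.01 dB, appropriate for a narrow-IF-bandwidth sweep at moderate power.
  This component is kept an order of magnitude below the jitter
  deliberately: noise on the single baseline sweep propagates into every
  one of a subject's 48 parameter vectors as a *shared* offset. If it
  rivaled the per-time-point jitter, a null cohort would cluster by
  subject, and with only 14 subjects the orientation-corrected AUC of a
  zero-effect cohort would drift well above chance. With the default
  composition, all 31 zero-effect combination AUCs average to 0.51–0.56
  over seeds (the tests assert [0.40, 0.60]).

The baseline sweep receives instrument noise but no descriptor jitter: it
defines the reference state, and jittering it would add a second shared
offset per subject.

Seeding: one master `numpy` SeedSequence is spawned into per-subject
children, so cohorts are bit-reproducible and subjects are statistically
independent.

### What passing tests do and do not show

The simulator produces clean single-peak resonances with Gaussian noise
and monotone drift. Real measurements add sensor placement drift,
temperature effects, multi-lobe coupling responses, and non-monotone
physiology. Passing the synthetic detectability tests therefore
demonstrates that the pipeline is *correct* (it recovers configured
changes and ranks combinations sensibly), not that any particular AUC
will be attained on animal or clinical data.

## Numerical and degenerate-input choices

* Linear interpolation only at band edges; means are discrete (no
  resampling), so results are exactly reproducible across platforms.
* Flat sweeps, bands leaving the sweep span, and baselines with a zero
  denominator (A₀, ā₀, f₀ or F₀ equal to 0) raise typed errors;
  cohort-level extraction converts them to per-record reports.
* Degenerate score sets (a single distinct value) yield AUC 0.5 with a
  warning rather than an error.
* Touchstone I/O is v1 only, 2-port, formats RI/MA/DB, any frequency
  unit; amplitudes survive a round trip to ≤ 1e-6 dB. Export writes
  −100 dB placeholders for the three unused S-parameters and phase 0 for
  S21 (phase is not modeled anywhere in the package).
* Cohort CSVs are read with round-trip float parsing so write∘read is the
  identity on the data model.

## Problem sizes

Tests and the acceptance script run the full default geometry (14
subjects × 49 × 1060-point sweeps) throughout; a full pipeline run takes
on the order of a second, and the five-seed null calibration a few
seconds. Structural tests (I/O, CLI wiring) use a 2+2-subject, 200-point
design purely because nothing about wiring depends on scale.

## Known limitations

* Single-peak tracking only: the global maximum is followed; multi-peak
  responses are out of scope.
* Phase information (arg S21) and the reflection/isolation parameters
  S11/S12/S22 are not analyzed.
* No confidence intervals on AUC and no cross-validation: the method as
  specified reports point estimates over the pooled observations.
* Observation-level ROC ignores within-subject correlation; with strong
  per-subject offsets (e.g. instrument noise dominating the baseline) the
  effective sample size is closer to the number of subjects than the
  number of measurements. The simulator's noise composition is chosen so
  this regime does not arise by default, but real data should be checked
  for it.
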