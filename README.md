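# abcpe

Amplitude-based characteristic parameter extraction for
electromagnetic-induction cerebral edema monitoring.

Non-contact electromagnetic induction sensing tracks intracranial change by
sweeping a coil sensor over 1–100 MHz with a vector network analyzer and
recording the two-port transmission amplitude |S21| (dB) versus frequency.
As edema develops, the brain's equivalent impedance Z = R + jωX shifts the
sensor–head coupling resonance: the peak amplitude, the characteristic
frequency and the half-power bandwidth all drift relative to the first
(baseline) sweep. `abcpe` implements the full analysis chain for such
longitudinal monitoring data: feature extraction, multi-parameter
classification, and a synthetic cohort simulator for validation. It is
aimed at researchers developing S-parameter–based physiological monitors
and at anyone who needs a reproducible reference implementation of this
pipeline.

## The algorithm

For each sweep at time *tᵢ*, relative to the subject's own *t₀* baseline:

1. Peak: A(f) = max |S21|, at the characteristic frequency f.
2. 3 dB band: the innermost frequencies f′ < f < f″ with
   |S21|(f′) = |S21|(f″) = A − 3; bandwidth F = f″ − f′; N grid points
   inside; band mean ā.
3. Five characteristic parameters:

   | parameter | definition | meaning |
   |---|---|---|
   | α | (Aᵢ − A₀)/A₀ | peak-amplitude change |
   | β | (fᵢ − f₀)/f₀ | characteristic-frequency shift |
   | γ | (Fᵢ − F₀)/F₀ | 3 dB bandwidth change |
   | δ | (āᵢ − ā₀)/ā₀, āᵢ over the *baseline* band F₀ | mean-amplitude change |
   | ρ | (āᵢ′ − ā₀)/ā₀, āᵢ′ over the *current* band Fᵢ | followed mean-amplitude change |

   Ratios are formed on the dB values directly; since these are negative,
   an amplitude increase yields a negative α/δ/ρ (classification is
   sign-agnostic).

4. Classification: for any subset of {α, β, γ, δ, ρ}, each parameter is
   mapped to [−1, 1] by its pooled maximum absolute value over both classes
   and the observation score is the Euclidean norm of the mapped vector;
   single parameters are thresholded raw. A threshold sweep yields the ROC
   curve, its trapezoidal AUC and the Youden-optimal sensitivity/
   specificity. All 31 non-empty subsets are ranked for three comparisons:
   edema vs control over (0, 24] h, the same within (0, 1] h (early
   detection), and acute (0, 6] h vs chronic (6, 24] h within the edema
   group.

## Worked example

```python
from abcpe import generate_cohort, CombinationModel

cohort = generate_cohort(seed=42)          # 10 Exp + 4 Con, 49 x 1060-pt sweeps
res = CombinationModel.from_cohort(cohort, "detect_24h").fit()
print(res.summary())
```

```
Parameter-combination ROC evaluation — comparison: detect_24h
Observations: 480 positive, 192 negative (one per subject-time point)

Single (5 combinations)
combination                      AUC  AUC(2sig)    sens    spec
alpha                         0.9985        1.0   0.975   1.000
beta                          0.8795       0.88   0.825   0.807
gamma                         0.9738       0.97   0.917   0.984
delta                         0.9943       0.99   0.973   0.984
rho                           0.9981        1.0   0.975   1.000
...
Best combination: alpha (AUC 0.9985, sensitivity 97.5%, specificity 100.0%)
```

The 480/192 split is 10 edema and 4 control subjects with 48 non-baseline
sweeps each. Each AUC is the area under the ROC curve of that parameter
subset's Euclidean score; `sens`/`spec` are read at the threshold
maximizing Youden's J. On this synthetic cohort even single parameters
separate well because the simulated drift is clean; the bandwidth/
band-mean combination scores

```python
roc = res.roc(("gamma", "delta", "rho"))
print(f"AUC={roc.auc:.4f} sens={roc.sensitivity:.3f} spec={roc.specificity:.3f}")
# AUC=0.9895 sens=0.935 spec=1.000
```

The same objects drive the other two comparisons
(`"detect_1h"`, `"phase"`). A `click` CLI wraps the pipeline:

```
abcpe simulate --outdir run/cohort --seed 1
abcpe extract  --input run/cohort/cohort.csv --outdir run/params
abcpe evaluate --input run/cohort/cohort.csv --comparison all --outdir run/eval
abcpe pipeline --seed 1 --outdir run        # all of the above
```

Measured data can be loaded instead of simulated: one Touchstone v1
`.s2p` file per sweep (`abcpe.read_touchstone`, formats RI/MA/DB) or a
long-format CSV (`subject,group,time_h,freq_hz,amp_db`) via
`abcpe.read_cohort_csv`.

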