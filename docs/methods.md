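# Methods

## Scope and intent

`chronocope` implements a complete, seeded re-analysis environment for the
association between coping style and circadian rhythmicity in zebrafish. No
raw behavioural, qPCR or hormone data from live animals are distributed;
instead, a generative model with known ground truth produces cohorts with the
statistical structure the analyses assume, and the analysis chain is
validated against that ground truth plus independent numerical oracles
(enumeration, grid search, direct reimplementation).

## Generative model

### Latent personality

Each fish carries a boldness score `b ~ U(0, 1)` (1 = maximally proactive).
Body weight (normal, mean 150.61 mg, SD 17.99 mg) and sex are drawn
independently of `b`; weight exists solely to verify the null of no
rank–weight correlation.

### Emergence latency

```
latency = s · exp(β(1 − b) + u_i + e),   u_i ~ N(0, σ_u),  e ~ N(0, σ_e)
```

with scale `s = 55 s`, slope `β = 3.0`, stable individual component
`σ_u = 0.3` and fresh per-session residual `σ_e = 0.15`. The calibration was
fixed by Monte-Carlo before the analysis suite was frozen so that the
emulated two-stage experiment (group ranking of 24 batches of 10, 10-min
exclusion, single-test retest) reproduces the published behaviour of the
assay: a pooled rank–latency Spearman correlation of ≈ 0.83 with ≈ 190 of
240 fish emerging within the cutoff. Two structural effects cap this
correlation well below 1 regardless of noise level: the 10-min exclusion
truncates the shy end of the continuum, and within-group ranks are pooled
against absolute latencies across groups whose boldness compositions differ.

### Diurnal channels

Each channel value follows `x(t) = M(b) + A(b)·cos(2π(t − φ)/24)·D(t) + ε`
with `M` and `A` linear in `b` between their shy and bold endpoints,
`ε ~ N(0, (cv·M(b))²)`, and `D(t) = 2^(−t_LL/h)` once light stops cycling
(`h = 20 h`). Concentrations and velocities are floored at 0 after noise.
Defaults:

| channel    | M bold | M shy | A bold | A shy | φ (hCT) | cv | units |
|---|---|---|---|---|---|---|---|
| bmal1a     | 10 | 6   | 4  | 0.4 | 16 | 0.12 | relative |
| clock1a    | 10 | 6   | 4  | 0.4 | 14 | 0.12 | relative |
| per1a      | 10 | 6   | 4  | 0.4 | 1  | 0.12 | relative |
| cry1a      | 10 | 6   | 4  | 0.4 | 3  | 0.12 | relative |
| cipca      | 10 | 6   | 4  | 0.4 | 7  | 0.12 | relative |
| cortisol   | 5  | 12.5 | 4 | 0   | 1  | 0.12 | ng/g |
| melatonin  | 100 | 150 | 80 | 0  | 19 | 0.12 | pg/g |
| activity   | 6  | 4   | 5  | 0.5 | 1  | 0.25 | mm/s |

Rationale: gene expression falls in level and loses rhythm towards the shy
end (amplitude at 10 % of the bold value); shy fish hold a high flat cortisol
level (2.5× the bold mesor, a standard proactive/reactive endocrine
signature) and an intermediate flat melatonin level placed between the bold
trough (20) and peak (180) such that net output rises with rank; activity
peaks in the first hour of the light phase. The cosine parameterisation with
acrophase = time of peak is the standard cosinor convention.

Two activity-specific mechanisms:

* a per-individual lognormal activity scale (log-SD 0.3), a personality-
  independent trait multiplying the whole trace. It makes AUC and amplitude
  noisy, mutually collinear proxies of boldness while rhythm strength — a
  variance ratio, invariant under scaling — remains the clean predictor;
  this is what gives the model-selection experiment its intended structure.
* one burst bin per 24-h day at a shared locomotor ceiling (25 mm/s, CV 8 %,
  random bin within the day): a startle/feeding bout whose height does not
  depend on boldness. The daily maximum velocity (Vmax) is therefore
  rank-independent by construction — reactive fish are not slower, they are
  arrhythmic — while the sustained rhythm differs. Bursts occur at a random
  time each day so they contribute essentially nothing to the 24-h harmonic.

Sampling designs: gene/hormone series use the six timepoints 1, 7, 13, 15,
19, 23 hCT under 14:10 LD; activity is recorded for six days in 30-min bins
starting at 7 hCT (days 1–3 LD, days 4–6 LL; the LD analysis window is
recording hours [7, 79), LL is [79, 151)).

qPCR plumbing: target Ct values encode expression as
`Ct = 24 − log2(E)` with the housekeeping gene *ippA* at Ct 15, plus
technical-triplicate noise (SD 0.05). The ΔCt subtraction removes the
housekeeping level, so a global Ct shift changes nothing downstream.

### Randomness

Every draw comes from a counter-based substream keyed by
`(cohort seed, individual id, purpose, session)` (CRC32-hashed labels feeding
a numpy `SeedSequence`). Adding a fish or a channel never perturbs the draws
of any other fish, and identical configurations are byte-identical.
`CohortConfig.noise_free()` silences every noise source (latency noise,
channel noise, the activity scale, the bursts, the qPCR technical noise),
under which channels trace the generative cosinor exactly and emergence rank
is a deterministic function of boldness.

## Analysis choices

* **LOWESS**: tricube-weighted local *linear* regression over the 5 nearest
  neighbours, zero robustness iterations, evaluated at the input times
  (delegated to statsmodels; tests compare it point-by-point against a direct
  implementation). Straight-line data pass through unchanged.
* **24-h cosinor**: closed-form OLS on `{1, cos, sin}` — no iterative
  optimiser, no free period. Period estimation (Lomb–Scargle, chi-square
  periodogram) and multi-harmonic fits are out of scope. Constant input
  yields amplitude 0 and, by convention, R² 0. A design in which all times
  coincide modulo 24 h raises a singular-design error.
* **AUC** integrates the LOWESS curve over the observed window rather than
  the fitted sine over a full period (whose integral would collapse to
  24·mesor and discard the curve's shape). This preserves the "net output"
  semantics for the unevenly sampled six-point design.
* **Rhythm strength** is defined as the harmonic-regression R² at 24 h on
  the unsmoothed series: dimensionless, bounded in [0, 1] and comparable
  across individuals. A chi-square-periodogram statistic (Qp) was considered
  and rejected because it is unbounded and sample-size dependent. Under pure
  white noise its expectation is 2/(n − 1) (two model degrees of freedom).
* **Relative expression** for time-course analysis is `2^(−ΔCt)` per sample,
  normalised by the gene's grand mean across fish and timepoints: genes
  become comparable while between-fish level differences — which the
  rank-correlation analyses need — are preserved. The per-(gene, rank) mean
  series averages ΔCt within (rank, timepoint) cells before exponentiation.
* **Spearman**: mid-ranks for ties; exact permutation p (full enumeration)
  below n = 10, t approximation otherwise.
* **Emergence ranking**: ties broken by input order (fish emerge one at a
  time through a single hatch, so exact ties are a numerical artefact);
  non-emergers (≥ 10 min) carry no rank and drop out of correlations
  pairwise. The single-test cutoff is a parameter because assay variants run
  either to completion or to a 1-h cap.
* **Mirror test**: AGR frequency = AGR/(duration − FRZ − LFA); fish freezing
  for the whole 10-min trial are non-responders and are excluded.
* **Model selection**: VIF threshold 5 and Cook's-distance threshold 4/n are
  the common textbook defaults and are exposed as parameters; influential
  points are flagged, never auto-removed. Backward elimination drops, at each
  step, the least significant predictor whose removal either improves AIC or
  has a likelihood-ratio p ≥ 0.05 — both criteria jointly determine the
  optimal model. An AIC-only rule would retain a pure-noise predictor at the
  P(χ²₁ > 2) ≈ 16 % rate and could never reach the ≥ 90 % selection
  consistency the design aims for. Emergence rank is treated as numeric in
  the linear model. The candidate set is {AUC, amplitude, rhythm strength,
  Vmax}.
* **Two-way ANOVA** uses type-II sums of squares (statsmodels) with
  Bonferroni (α/m) and Šidák (1 − (1 − α)^(1/m)) post-hoc helpers.

## Problem sizes

The default study is 9 groups × 10 fish with 2 random eliminations per group
(72 analysed), the latency validation runs 24 groups × 10, and repeated-
cohort experiments (selection consistency, Vmax null, type-I error of the
strain chi-square) use 100 seeded cohorts; headline correlations are averaged
over 20 seeds. These sizes keep every Monte-Carlo estimate's standard error
well below the margins being asserted.

## What the synthetic cohorts do and do not show

The generator reproduces the *correlation structure* the analyses assume:
monotone amplitude/mesor gradients along the continuum, a personality-
independent locomotor ceiling, damping under constant light, session-stable
individual differences. It does not emulate tank or social effects, sex or
weight effects on behaviour (weight is a null covariate only), non-sinusoidal
waveform shapes, ultradian components, or assay-specific measurement error
beyond multiplicative Gaussian noise. Passing tests therefore demonstrate
that the pipeline recovers known structure at realistic noise levels — not
that real populations carry that structure.

Known limitations: under constant light the generator damps only the rhythm,
not the activity-level contrast, so the LL AUC–rank correlation stays
stronger than in real recordings, where proactive fish converge on the
reactive activity pattern. Noise-free cohorts make rhythm strength exactly 1
for every rhythmic fish (a constant), so strength monotonicity in boldness is
a property of the noisy regime. Pooled within-group ranks tie across groups;
correlations of −1 in the noise-free limit hold exactly only for a single
fully ranked group.
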