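# chronocope

Circadian rhythmicity and animal-personality analysis for zebrafish cohorts.

Laboratory zebrafish populations contain consistent behavioural types
("coping styles") spanning a proactive–reactive continuum: proactive fish
leave a familiar shelter quickly (early emergers, EE), are aggressive towards
a mirror image and keep robust diurnal rhythms; reactive fish (late emergers,
LE) are shy, risk-averse and can lack rhythmicity almost entirely.
`chronocope` is a tested, reusable pipeline for studying this coupling. It

1. **simulates** seeded cohorts whose circadian channels (clock-gene
   expression by qPCR, whole-body cortisol and melatonin, 30-min binned
   swimming velocity under 14:10 LD and constant light) co-vary with a latent
   boldness trait,
2. **scores** the behavioural assays (group/single emergence ranking with the
   10-min exclusion rule, mirror-test aggression frequency),
3. **quantifies** rhythmicity per fish and channel, and
4. **correlates** each rhythm metric with emergence rank, including the
   multicollinearity-aware model selection that identifies which activity
   metric predicts rank.

It is aimed at chronobiologists and behavioural ecologists who want the full
analysis chain — and its statistical behaviour under a known ground truth —
without access to raw animal data.

## The model

Every diurnal channel is a fixed-period cosinor

```
x(t) = M + A·cos(2π(t − φ)/24)·D(t) + ε,    ε ~ N(0, (cv·M)²)
```

with mesor `M`, amplitude `A`, acrophase `φ` (hours circadian time, 0 =
lights-on) and a damping factor `D(t) = 2^(−t_LL/h)` that halves the rhythm
every `h` hours of constant light. Analysis follows the standard chain for
short, unevenly sampled time courses:

- **LOWESS** (5-point window, tricube weights, locally linear, no robustness
  iterations) smooths the series;
- a **24-h sinusoid** is fitted to the smoothed curve by closed-form OLS on
  the harmonic basis `{1, cos ωt, sin ωt}`, giving mesor, amplitude
  `√(a²+b²)` and acrophase;
- **AUC** is the trapezoidal integral of the LOWESS curve over the observed
  window (net transcriptional/secretory/locomotor output);
- **rhythm strength** is the fraction of raw-series variance carried by the
  24-h harmonic (R² ∈ [0,1]);
- **Vmax** is the mean of the daily velocity maxima over the first three LD
  days (locomotor capacity).

qPCR tables are quantified by ΔΔCt: technical triplicates are averaged on the
Ct scale, ΔCt = Ct(target) − Ct(*ippA*), relative expression is `2^(−ΔCt)`,
and the EE-vs-LE contrast is `2^(ΔCt_LE − ΔCt_EE)`. Associations are Spearman
rank correlations (exact permutation p below n = 10, t approximation
otherwise); the activity metrics additionally pass through VIF screening
(threshold 5), Cook's-distance influence flags (4/n) and backward elimination
under AIC with likelihood-ratio confirmation.

## Worked example

```python
from chronocope import CohortConfig, RunConfig, run_full_study

result = run_full_study(RunConfig(cohort=CohortConfig(seed=1)))
print(result.correlations.set_index(["channel", "metric", "regime"])
      .loc[[("cortisol", "auc", "LD"),
            ("activity", "rhythm_strength", "LD"),
            ("activity", "vmax", "LD")]])
print(result.selection.retained_predictors)
```

prints (72 analysed fish: 9 groups of 10 ranked by group emergence, two
random eliminations per group):

```
                                     rho       p_value   n
channel  metric          regime
cortisol auc             LD     0.815084  2.945366e-18  72
activity rhythm_strength LD    -0.717980  1.263679e-12  72
activity vmax            LD     0.152880  1.998160e-01  72
('rhythm_strength',)
```

Read: whole-body cortisol output (AUC) rises steeply towards the reactive end
of the continuum (ρ = 0.82 — shy fish sit at a high, flat cortisol level),
the 24-h rhythm strength of swimming activity falls with emergence rank
(ρ = −0.72), and maximal swimming speed is rank-independent (ρ = 0.15, n.s.),
i.e. reactive fish are not simply poorer swimmers. The model selection
retains rhythm strength as the sole predictor of emergence rank after AUC and
amplitude are removed as collinear. The same run also reports the mirror-test
aggression frequency (ρ = −0.66, n = 66 responders) and the body-weight null
(ρ = −0.12, n.s.).

The same analysis is available from the shell:

```bash
chronocope run-all --seed 1 --out results/run1
chronocope simulate --seed 1 --out results/tables   # cohort CSVs only
chronocope score-emergence --latencies results/tables/latency_group.csv --out ranked.csv
```

## Layout

```
src/chronocope/
  synthetic.py    seeded cohort generator (the ground-truth model)
  behavior.py     emergence ranking, mirror-test scoring
  expression.py   ΔΔCt quantification, expression time series
  rhythm.py       LOWESS, 24-h cosinor, AUC, rhythm strength, Vmax
  stats.py        Spearman, chi-square, two-way ANOVA, model selection
  pipeline.py     run_full_study / make_report
  cli.py          chronocope command-line interface
docs/methods.md   modelling and calibration notes
```
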