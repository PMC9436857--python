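# bisectlab

Statistical tooling for studies that relate the **spontaneous eyeblink
rate (EBR)** — a non-invasive proxy of striatal dopamine D2-receptor
availability — to individual differences in **temporal and color
bisection** performance.  The package covers the complete analysis
chain: blink detection in resting-state pupil streams, maximum-likelihood
logistic psychometric fitting with a deviance goodness-of-fit exclusion,
rank-based correlational inference with BCa bootstrap intervals, and
default-prior Bayes factors — plus a synthetic-data generator so the
whole pipeline can be exercised and validated without any recordings.

## The science in brief

In a bisection task an observer learns two anchor stimuli (intervals of
300 and 967 ms, or mostly-red 22 %-blue vs mostly-blue 78 %-blue discs)
and then classifies intermediate stimuli (6 levels, 3 blocks × 76
trials) as closer to one anchor or the other.  The per-level proportion
of "long" (or "red") responses is fitted with a two-parameter logistic

```
psi(x; alpha, beta) = 1 / (1 + exp(-beta (x - alpha)))
```

by maximum likelihood (guess and lapse rates fixed at 0).  Derived
indices:

* **BP** (bisection point) = `alpha` — the subjectively equidistant
  level; lower BP = relative overestimation;
* **DL** (difference limen) = `ln(3)/beta` — half the 25–75 % spread;
* **WF** (Weber fraction) = `DL/BP` — dimensionless precision, lower =
  finer discrimination.

Fit quality is checked with **pDev**: the observed deviance is compared
against deviances of datasets parametrically bootstrapped from the
fitted function; participants with pDev < .05 are excluded task-wise.

EBR is the number of blinks per minute in the last 5 minutes of an
8-minute 500 Hz resting recording (first 3 minutes discarded), where a
blink is ≥ 3 consecutive samples without a detected pupil.  EBR is then
related to WFs and BPs through Spearman correlations with 95 % BCa
bootstrap intervals, dependent-correlation comparisons (Fisher z +
bootstrap difference CI), semi-partial rank correlations, a paired
t-test on WFs across tasks, and default Bayes factors (stretched-beta
prior for correlations, JZS Cauchy prior for t-tests).

## Worked example

Simulate a 75-participant cohort in which EBR and the true temporal WF
are copula-coupled at Spearman ρ = .28 (the color task independent of
EBR), run the full analysis, and print the headline rows:

```python
import bisectlab as bl

config = bl.StudyConfig(n_participants=75, target_rho=0.28,
                        master_seed=1, n_boot=2000, n_sim_pdev=500)
report = bl.run_study(config)
cols = ["analysis", "estimate", "n", "p_value", "ci_low", "ci_high", "bf"]
print(report.analyses.set_index("analysis").loc[
    ["ebr_x_wf_time", "ebr_x_wf_color", "wf_time_vs_wf_color_paired_t"], cols[1:]])
```

Output (seed 1):

```
                              estimate   n  p_value  ci_low  ci_high    bf
analysis
ebr_x_wf_time                    0.128  71    0.287  -0.108    0.343 0.441
ebr_x_wf_color                   0.041  71    0.733  -0.178    0.288 0.198
wf_time_vs_wf_color_paired_t     0.642  75    0.523     NaN      NaN 0.155
```

Reading: the `estimate` column is the Spearman ρ (or t for the paired
row), each row carries its own N after exclusions (pDev < .05 per task),
and `bf` is the one-sided correlation Bayes factor (BF₁₀ for the t-test
row).  This particular cohort illustrates the realities the pipeline is
built to expose: the population coupling of ρ = .28 is attenuated by
WF-estimation noise at design-scale trial counts and then blurred by
cohort-level sampling error (SE ≈ 1/√(n−3) ≈ .12 at n = 71), so a
single n = 75 study can land at ρ̂ = .13 with an ambiguous Bayes factor
— which is why the a-priori power computation below matters.  The test
suite verifies the machinery at population scale (n = 2,000), where the
estimate matches the attenuated truth to within .05.  The control task
shows no association and the tasks' Weber fractions do not differ
(paired t, BF₁₀ ≪ 1/3).

The same pipeline runs from the shell:

```bash
bisectlab simulate --n 75 --rho 0.28 --seed 1 --out data/
bisectlab ebr --in data/streams --out ebr.csv
bisectlab fit --trials data/trials.csv --nsim 1000 --seed 7 --out fits.csv
bisectlab correlate --fits fits.csv --ebr ebr.csv --nboot 10000 --seed 11 --out results.csv
bisectlab bf --t 1.21 --n 75
bisectlab run-all --config study.yaml --out report/
```

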