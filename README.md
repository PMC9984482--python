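# ppvstroke

Pulse-pressure variability (PPV) analysis of functional outcome after
acute ischemic stroke.

In stroke units, blood pressure is charted roughly every 4 h for the
first 72 h after admission. The pulse pressure of each reading,
PP = SBP − DBP (mmHg), fluctuates, and the magnitude of that fluctuation
is itself a candidate predictor of how the patient fares. `ppvstroke` is
a tested pipeline for that question, aimed at clinical researchers
working with stroke-unit registries: it computes the standard PPV
indices from raw reading series, labels functional outcomes on the
modified Rankin Scale (mRS), and runs the full association battery.
Because registries of this kind are rarely shared, the package also
ships a synthetic-cohort generator with the same statistical structure,
so every stage is reproducible and testable without patient data.

## The indices and the statistics

For a patient's PP readings $x_1,\dots,x_n$ with mean $\bar x$:

- $SD = \sqrt{\frac{1}{n-1}\sum_{i=1}^{n}(x_i-\bar x)^2}$, and
  $CV = 100\,SD/\bar x$;
- $SV = \sqrt{\frac{1}{n-1}\sum_{i=1}^{n-1}(x_{i+1}-x_i)^2}$
  (successive variation);
- $ARV = \frac{1}{n-1}\sum_{i=1}^{n-1}|x_{i+1}-x_i|$
  (average real variability);
- $DMM = \max_i x_i - \min_i x_i$ (range);
- $MSC = \max_i |x_{i+1}-x_i|$ (maximal successive change).

Outcomes at 30 and 90 days are labelled unfavorable when mRS ≥ 3, or by
a severity-adjusted rule that also reads the admission NIHSS score. The
inference suite comprises Spearman rank correlations with the mRS
score, Mann–Whitney U group comparisons, four nested logistic
regressions (M1 unadjusted; M2 + thrombolysis + mean PP; M3 as M2 with
the severity-adjusted outcome; M4 as M2 + age + sex + myocardial
infarction) reporting odds ratios per 10 mmHg with Wald 95 % CIs, and
ROC analysis with AUC, DeLong confidence intervals, Youden's index and
the optimal cut-off.

## Worked example

```sh
ppvstroke simulate --seed 42 --n 60 --out demo/data
# wrote 60 patients to demo/data
cat > demo/config.json <<'EOF'
{"cohort_csv": "demo/data/cohort.csv",
 "readings_csv": "demo/data/bp_readings.csv",
 "output_dir": "demo/report"}
EOF
ppvstroke analyze --config demo/config.json
```

`demo/report/` then contains the four report tables (full-precision and
display-rounded CSVs), an exclusion-count file and a run log. A few rows
of the display tables:

```
table3_models_display.csv
horizon,index,model,or_per_10mmHg,ci_low,ci_high,p_value,n_used,converged,error
30d,dmm,M1,1.334,1.062,1.677,0.013,60,True,
30d,dmm,M2,1.321,1.046,1.670,0.020,60,True,

table4_roc_display.csv
horizon,index,auc,auc_ci_low,auc_ci_high,cutoff,youden_index,p_value
30d,sd,0.703,0.559,0.846,18,0.40,0.006
```

Read: in this 60-patient synthetic cohort, a 10 mmHg increase in the
72-h PP range (DMM) carries 1.33-fold odds of an unfavorable 30-day
outcome (95 % CI 1.06–1.68) before adjustment, essentially unchanged
after adjusting for thrombolysis and mean PP; PP SD discriminates
unfavorable outcome with AUC 0.70, best dichotomized at 18 mmHg. The
generator's default outcome model loads on PP SD with a true OR of 4.8
per 10 mmHg, so positive associations like these are expected.

The same computations are available as library calls
(`ppvstroke.summarize_ppv`, `run_model_suite`, `roc_analysis`, ...) on
pandas inputs.

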