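# promediate

Bayesian mediation analysis of patient-reported outcomes (PROs) collected
through a chatbot, evaluated end to end on synthetic dialogues with known
ground truth.

Clinical trials increasingly gather PROs — fatigue, stress, side-effect
severity — through conversational agents rather than questionnaires. This
package asks the statistical question behind that design: if treatment
assignment X influences an outcome Y (fatigue) partly through a mediator M
(adverse-event severity), with a covariate Z (stress) also predicting Y, can
the causal decomposition be recovered reliably from values extracted out of
chatbot transcripts? It is written for biostatisticians who want a tested,
reproducible simulation pipeline rather than a one-off notebook.

## The model

Two linear-Gaussian equations:

```
M_i ~ Normal(i_m + a·X_i,                    σ_m)
Y_i ~ Normal(i_y + c′·X_i + d·Z_i + b·M_i,   σ_y)
```

The treatment effect decomposes into the **direct effect** c′, the
**indirect effect** a·b transmitted through the mediator, and the **total
effect** c = c′ + a·b. With Normal(0, 10²) priors on all coefficients and
InverseGamma(0.001, 0.001) priors on both residual variances, every full
conditional is exact, so the model is fitted by a from-scratch blocked Gibbs
sampler (coefficient vector jointly, then variance, per equation). Equal-
tailed 95% credible intervals, split-chain R-hat and effective sample size
are reported for the eight parameters and the three derived effects.

The pipeline has four stages, each usable alone:

1. **dialogue synthesis** — simulate a 1:1 randomized cohort from the model
   above and render each subject as a multi-turn transcript following the
   chatbot's branching router (fatigue yes/no → stress → side effects);
2. **transcript extraction** — parse (X, Z, M, Y) back out of the
   transcripts, fail-fast on malformed dialogues;
3. **mediation model** — the Gibbs sampler and posterior summaries;
4. **simulation study** — replicate simulate→extract→fit and score Bias,
   RMSE, Coverage and Interval_Width per estimand against the known truth.

## Worked example

```
$ python analysis/01_simulate_dialogues.py
simulated 75 subjects: 38 active, 37 placebo; 66 took the fatigue branch
...
  [agent] Please rate your fatigue on a zero-to-ten scale, where zero means none at all.
  [user ] I'd say about 3.95 right now.

$ python analysis/02_extract_transcripts.py
extracted 75 subjects (66 on the fatigue branch); max |extracted - rounded truth| = 0

$ python analysis/03_fit_mediation.py
effect decomposition (posterior mean [95% CI]):
  direct    +0.324  [+0.068, +0.581]
  indirect  +0.184  [+0.057, +0.347]
  total     +0.507  [+0.252, +0.761]
```

The cohort was generated with true a=0.4, b=0.5, c′=0.3, d=0.2, so the true
direct, indirect and total effects are 0.30, 0.20 and 0.50; each credible
interval above contains its target. `analysis/04_simulation_study.py`
repeats this over 100 fresh cohorts and prints the study-level table
(excerpt from `results/study/metrics.csv`):

```
                   bias    rmse  coverage  interval_width
a                0.0065  0.1157      0.95          0.4566
cprime           0.0083  0.1059      0.99          0.5006
d                0.0022  0.0271      0.97          0.1174
indirect effect -0.0001  0.0759      0.95          0.3022
```

Bias is the mean deviation of the posterior mean from the truth, Coverage
the fraction of replications whose 95% interval contains it, Interval_Width
the mean interval length.

The same stages are available as a CLI (`promediate simulate | extract |
fit | study | report`, see `--help`), driven by a YAML config and emitting
a manifest of seeds and file digests per run.

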