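# seamsim

Simulation of **two-stage adaptive seamless phase II/III clinical trial
designs** with interim treatment selection or subgroup selection
(adaptive enrichment), for statisticians planning such trials and
needing their operating characteristics — power, selection
probabilities, futility rates, expected sample size — under realistic
effect assumptions.

A seamless design runs a selection stage and a confirmatory stage in
one protocol, with data from both stages entering the final analysis.
Because the interim adaptation (dropping arms, restricting recruitment
to a biomarker subgroup) depends on the accumulating data, naive final
tests inflate the type I error. `seamsim` implements the standard
remedy: stage-wise p-values combined by the **inverse-normal
combination test**

    C_K = w1 * Phi^-1(1 - p_K1) + w2 * Phi^-1(1 - p_K2),   w1^2 + w2^2 = 1

(or Fisher's product test), applied to every intersection hypothesis
H_K inside a **closed testing procedure**: an elementary hypothesis
H_k: theta_k = 0 is rejected at familywise level alpha iff every H_K
with k in K is rejected. Intersections are tested with **Dunnett's**
many-to-one test (K arms vs a shared control, correlation
1/(1+lambda)) or, for the subgroup/full-population pair, the
**Spiessens–Debois**, Simes or Bonferroni tests. This controls the
familywise error rate in the strong sense for *any* data-driven
selection rule — including rules informed by an **early outcome**
(e.g. a 15-day lung-function measure, or progression-free survival)
while the primary outcome drives the hypothesis tests.

Trials are simulated at the level of standardized score statistics
`S = theta_hat * sqrt(I)` drawn from their exact joint normal law, so
runtime is independent of patient-level sample sizes. Supported
outcomes: normal, binary (log odds ratios), time-to-event (exponential
expected-event model). See `docs/methods.md` for the model and all
conventions.

## Worked example

A five-arm COPD dose-selection trial: four indacaterol doses against
placebo, interim selection of the best two doses on trough FEV1 at 15
days (standardized effects 0.68–0.95), confirmatory testing on
percentage of days of poor control (standardized effects 0.13–0.23),
100 patients/arm in stage 1 and 300/arm in stage 2, early–final
correlation 0.4:

```sh
seamsim treatsel --fixture copd-setting1 --seed 7 --nsim 10000
```

```
simulation of test statistics:
expectation early = 4.8 5.8 6.7 6.4
expectation final stage 1 = 0.9 1.2 1.6 1.4 and stage 2 = 1.6 2.1 2.8 2.4
weights: stage 1 = 0.5 and stage 2 = 0.87

number of treatments selected at stage 1:
      n      %
  1      0   0.00
  2  10000 100.00
  3      0   0.00
  4      0   0.00
  Total  10000 100.00

treatment selection at stage 1:
      n      %
  1    421   4.21
  2   3341  33.41
  3   8675  86.75
  4   7563  75.63

hypothesis rejection at study endpoint:
      n      %
  H1    184   1.84
  H2   2156  21.56
  H3   7312  73.12
  H4   5670  56.70

reject H3 and/or H4 = 8576 : 85.76%
```

The header lines are deterministic: the expected z statistics
(`sqrt(n/2) * theta`, e.g. `sqrt(50) * 0.95 = 6.7` for the 300 ug
dose) and the combination weights (`sqrt(100/400) = 0.5`,
`sqrt(300/400) = 0.87`). The tables are Monte Carlo estimates over
10,000 replicates: the two highest doses are selected in 87% and 76%
of trials, their null hypotheses rejected in 73% and 57%, and at least
one of them rejected in 85.8% of trials — the design's power for
demonstrating efficacy of a high dose.

The same interface drives an oncology enrichment design
(`seamsim subpop --fixture oncology-subgroup`): hazard ratio 0.6 in a
30%-prevalence biomarker subgroup vs 0.9 overall, a four-branch
futility rule at the interim, stage-2 enrichment to 200 patients/arm
when only the subgroup continues, and Spiessens–Debois closed testing.
Python access, custom YAML configs (`--config`), JSON/CSV output
(`--format`) and parameter sweeps (`--grid thresh=0:6:0.5`, or
`seamsim.run_grid` for list-valued sweeps such as futility-limit
pairs) are available; see `seamsim.FIXTURES` for the shipped designs.

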