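# Methods

`seamsim` simulates two-stage adaptive seamless phase II/III designs in
which the first stage ends with a data-driven selection — of treatment
arms in a multi-arm study with a shared control, or of the patient
population (subgroup versus full population) in an enrichment design —
and the second stage contributes confirmatory evidence. The final
analysis combines independent stage-wise p-values with a pre-specified
combination function inside a closed testing procedure, which controls
the familywise error rate (FWER) in the strong sense for *any*
selection rule, including rules informed by an early outcome rather
than the primary one.

## Statistical model

### Statistics, not patients

All simulation happens on the scale of standardized score statistics
`S = theta_hat * sqrt(I)`, where `theta_hat` estimates the treatment
effect and `I` is its Fisher information. These are asymptotically
normal with unit variance and mean `theta * sqrt(I)`, so one replicate
of a whole trial is a single draw from a multivariate normal
distribution. Runtime is therefore linear in the number of replicates
and independent of the patient-level sample sizes. Patient-level data
generation exists only as an oracle inside the test suite, where the
model covariance is checked against the empirical covariance of
statistics computed from simulated bivariate-normal patient records.

### Expected statistics per outcome type

With `n` patients per arm and effects expressed versus control:

* **Normal** (`N`): `sqrt(n/2) * theta`, `theta` a standardized mean
  difference, information `n/2`.
* **Time-to-event** (`T`): `sqrt(o/4) * delta`, where `o` is the
  expected total number of events in the two arms under an exponential
  model, information `o/4`. Two dialects exist and are explicit,
  validated fields, never inferred:
  * the treatment-selection driver reads effects as *minus log hazard
    rates* (control default 0), per-arm event probability
    `1 - exp(-exp(-mu))`, and `delta = mu_k - mu_0` (positive good);
  * the subgroup driver reads effects as *hazard ratios* against a
    baseline hazard (default 1) with unit follow-up, per-arm event
    probabilities `1 - exp(-h0)` and `1 - exp(-h0*HR)`, and
    `delta = log(HR)` (negative good).
* **Binary** (`B`): effects are event rates, converted internally to
  minus log odds `mu = log((1-r)/r)`; the statistic is the log odds
  ratio over the standard 2x2 error with cell counts replaced by their
  expectations (`o = n*r`), so lower event rates give positive
  statistics.

Orientation is canonicalized internally so that larger = better: only
the subgroup driver's hazard-ratio statistics need a sign flip before
testing, and reports flip back for display. The futility selection rule
deliberately operates on the *natural* scale because its inequalities
are stated there (for time-to-event outcomes "continue" means the
statistic is *below* its limit).

### Joint covariance

**Treatment selection.** Slots are `E_1..E_K` (early outcome, stage-1
patients), `F1_1..F1_K` (final outcome, stage-1 patients) and
`F2_1..F2_K` (final outcome, the stage-2 increment on fresh patients).
The covariance is the Kronecker product

```
[[1, rho, 0], [rho, 1, 0], [0, 0, 1]]  (x)  CS_K(1/(1+lambda))
```

with `CS_K(r)` the compound-symmetric matrix with unit diagonal and
off-diagonal `r`. For shared-control normal data this is exact, not an
approximation: within one cohort `cov(E_k, F1_k) = rho` (same
patients), `cov(E_k, F1_m) = rho/(1+lambda)` for `k != m` (shared
control patients only), and the stage-2 increment is independent of
everything in stage 1 (disjoint patients). With 1:1 allocation the
between-arm correlation is 1/2. Cumulative final statistics, when
needed, are the information-weighted combination
`(sqrt(I1)*F1 + sqrt(I2)*F2)/sqrt(I1+I2)`, which reproduces the
group-sequential correlation `corr(F1, Fcum) = sqrt(I1/(I1+I2))`.
The printed "stage 2" expectations are the incremental means at `n2`;
the combination test below only ever consumes incremental stage-wise
p-values, which keeps the stage-wise p-values independent by
construction.

**Subgroup selection.** Slots are `(E_S, E_F, F1_S, F1_F, F2_S, F2_F)`
for the subgroup (prevalence `tau`) nested in the full population.
Within one stage/endpoint block the nesting induces
`corr(S_S, S_F) = sqrt(I_S/I_F)` (equal to `sqrt(tau)` when per-patient
information is equal; for time-to-event outcomes the ratio is the event
ratio, which also reflects unequal hazards). The covariance is built
constructively: the full-population residual is
`sqrt(I_S/I_F) * (subgroup part) + sqrt(1 - I_S/I_F) * (complement
part)`, with the early--final correlation `rho` inside each part. This
construction is positive semi-definite by design, coincides with the
Kronecker form whenever the early and final information ratios agree
(as in the shipped examples), and extends replicate-by-replicate to
varying prevalence. When the early and final ratios differ, it implies
`corr(E_F, F1_F)` slightly below `rho` — the price of an explicit
patient-cohort decomposition.

Under varying prevalence, one binomial draw of subgroup membership out
of the planned stage-1 total (both arms) per replicate yields a
realized fraction that replaces `tau` in all information terms of that
replicate, for both stages.

### Stage-2 information by branch

For subgroup designs the continuation branch fixes the stage-2
subgroup information: `n2 * tau` per arm under co-primary continuation,
the enrichment sample size (or `n2 * tau` when no enrichment is
planned) under subgroup-only continuation, and `n2` for the full
population. Combination weights are fixed at design time from the
planned full-population sample sizes and are *never* recomputed after
enrichment — the combination test requires weights specified in
advance. Under complete follow-up in treatment designs, dropped arms
contribute a stage-2 statistic at stage-1 information (their stage-1
patients followed to the final outcome); this convention is a design
choice where the exact information content of followed-up dropped arms
is not uniquely determined.

## Testing procedure

Each intersection hypothesis `H_K` is tested at one-sided level
`alpha` (default 0.025) by the inverse-normal combination

```
C_K = w1 * Phi^-1(1 - p_K1) + w2 * Phi^-1(1 - p_K2) >= Phi^-1(1 - alpha)
```

with `w_j^2 = n_j/(n1+n2)` by default, or by Fisher's product criterion
`p_K1 * p_K2 <= c_alpha`, `c_alpha = exp(-chi2_{4,1-alpha}/2)`.
An elementary hypothesis is rejected iff every intersection containing
it is rejected (closed testing). There is no interim efficacy stop: the
only stage-1 exits are selection and futility, so the final critical
value is simply `Phi^-1(1 - alpha)`.

Intersection p-values:

* treatment selection — Dunnett's many-to-one test,
  `p = 1 - P(max of m equicorrelated normals <= z_max)` with common
  correlation `1/(1+lambda)`;
* subgroup selection — Spiessens--Debois (the same tail probability
  with correlation `sqrt(I_S/I_F)`), Simes, or Bonferroni.

Stage 1 always uses the full intersection (every arm has stage-1
data). After the interim, the stage-2 p-value for `H_K` is the p-value
of `H_(K ∩ selected)` — multiplicity `|K ∩ selected|` — and equals 1
when that set is empty; dropped hypotheses can never be rejected. This
reduced-dimension convention was validated against the published
operating characteristics: keeping the full dimension with dropped
statistics at -inf depresses the best-2 COPD design's power by about
five percentage points relative to the published value, while the
reduced dimension reproduces it within Monte Carlo tolerance.

### Numerics

Both correlation structures are equicorrelated, so
`P(max_i Z_i <= z) = E_W[Phi((z - sqrt(r) W)/sqrt(1-r))^m]` is computed
by 96-node Gauss--Hermite quadrature — deterministic, vectorized over
replicates, and accurate to machine precision for `m <= 8` (verified
against adaptive quadrature and scipy's generic MVN CDF; the latter is
randomized quasi-Monte Carlo with errors around 1e-6 and serves only as
the independent oracle in tests). Normal quantiles of p-values 0 and 1
are capped at +-8.2 so the "-inf for dropped arms" convention stays
finite; the cap changes no decision at any `alpha >= 1e-15`. Drivers
enforce at most 7 experimental arms (the closed test enumerates `2^K - 1`
intersections). Singular covariances (`corr = 1`, `tau -> 1`) fall back
from Cholesky to a symmetric eigenvalue factor.

## Selection rules

Treatment designs: select all; best 1/2/3 (ties broken uniformly at
random from a dedicated, seeded substream — measure-zero for continuous
statistics but well-defined for crafted inputs); the epsilon-rule
(all arms within `epsilon` of the best; `epsilon = 0` is best-1, large
`epsilon` selects all); one arm uniformly at random; and a threshold
rule (all arms at or above a fixed early-statistic threshold, with an
empty selection stopping the trial for futility).

Subgroup designs: a threshold rule on `delta = z_F - z_S` (canonical
scale: subgroup-only if `delta <= l1`, full-only if `delta > l2`, else
both, with ties at `l1` going to the subgroup exactly as the
inequalities read), and a four-branch futility rule on the natural
scale (each population continues while its statistic is below its
limit; both at or above their limits stops the trial).

## Operating characteristics

The treatment driver reports the distribution of the number of arms
selected, per-arm selection counts, per-hypothesis rejection counts,
the combined rejection count over a pre-specified set of arms
(`ptest`), and the expected total sample size
`(K+1)*n1 + E[(m+1)*n2; m >= 1]` (futility stops contribute stage 1
only; the control arm continues whenever at least one arm does). The
subgroup driver reports the selection-by-rejection table (subgroup /
full / both continuation against `Hs`, `Hf`, both, either), the
futility rate, and the expected sample size with `2*n2` per continuing
replicate in the full population or both and `2*enrich` (or
`2*n2*tau`) under subgroup-only continuation.

## Reproducibility and problem sizes

One root seed spawns independent substreams for statistic draws,
tie-breaks and prevalence draws, so identical configurations and seeds
give byte-identical JSON reports. Published seeds from other
implementations cannot reproduce bit-identical draws here; agreement is
assessed at Monte Carlo tolerance. The shipped fixtures run 10,000
replicates (a few seconds each); FWER audits in the test suite use
100,000 replicates per null configuration, giving a Monte Carlo
standard error of about 0.0005 on a level of 0.025. The patient-level
covariance oracles use cohorts of a few patients per arm and 150,000 to
200,000 replicates, which bounds each covariance entry's standard error
near 0.002.

## What the generator does and does not emulate

The simulation model reproduces exactly the joint normal law of the
standardized statistics implied by the design — which is also the
asymptotic law of the statistics computed from patient-level data — so
passing tests demonstrate correctness of selection, combination and
closed testing logic, and calibration of the operating characteristics
under that law. It does not model finite-sample non-normality,
estimated variances (t rather than z statistics), censoring processes
or calendar-time event accrual for survival outcomes, overrunning
patients recruited between the interim data cut and the decision, or
drift in patient characteristics between stages. For time-to-event
outcomes the p-clud assumption behind the combination test can fail if
interim information leaks beyond censored observation times; the model
assumes it holds.

## Known limitations

* Two stages only; no alpha-spending boundary solver for J > 2 or
  interim efficacy stopping.
* One subgroup nested in the full population; no treatment-by-subgroup
  co-selection.
* No treatment-effect estimation or selection-bias correction; output
  is hypothesis-testing operating characteristics.
* The conditional-error-function subgroup method is out of scope; the
  combination-test methods (CT-SD, CT-Simes, CT-Bonferroni) are
  implemented.
* Expected-sample-size accounting assumes the control arm is enriched
  identically to the experimental arm; this convention reproduces the
  published expected sample sizes.
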