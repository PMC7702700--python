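# tsakit — trial sequential analysis for cumulative meta-analysis

Meta-analyses are updated every time a new randomised trial is published,
and every update is another significance test: naive repeated testing at
|z| ≥ 1.96 inflates the type-I error well beyond 5%, and a non-significant
pooled result says nothing about whether the evidence is merely
insufficient.  Trial sequential analysis (TSA) treats the growing
meta-analysis like an interim-monitored trial: it fixes a *required
information size* (RIS) — the meta-analytic analogue of a sample size —
and tests each update against error-spending monitoring boundaries instead
of a fixed critical value.

`tsakit` implements this machinery for two-arm binary-outcome trials, and
in particular the planning use-case: estimating, from completed feasibility
and pilot trials, how many participants one or more **future** trials must
recruit for the cumulative meta-analysis to give a decisive answer.

Who it is for: trialists and evidence-synthesis statisticians sizing a
follow-up randomised trial from pilot data, and methodologists studying
sequential meta-analysis error rates.

## The model

* Per-trial effects from 2×2 tables (odds ratio by default; risk ratio and
  risk difference supported), with a 0.5 continuity correction on zero
  cells.  Pooling is inverse-variance, fixed-effect or DerSimonian–Laird
  random-effects with Cochran's Q, τ², I², and the *diversity*
  D² = 1 − v_F/v_R (always ≥ I²).
* Required information size for anticipated event proportions p_C, p_E at
  two-sided α and power 1 − β, with p̄ = (p_C + p_E)/2:

  IS = 4 (z₁₋α/₂ + z₁₋β)² p̄(1 − p̄) / (p_E − p_C)²,  RIS = ⌈IS / (1 − D²)⌉.

* Lan–DeMets O'Brien–Fleming-type α-spending efficacy boundaries (and a
  Pocock-type option), solved on the realised look schedule by the
  classical sub-density recursion (Simpson-grid convolution plus
  root-finding); β-spending futility boundaries (the inner wedge) under the
  design drift θ* = z₁₋α/₂ + z₁₋β; repeated ("TSA-adjusted") confidence
  intervals that replace 1.96 with the current boundary.
* Planning: additional participants = max(0, RIS − accrued), with a
  conservative variant that excludes the trial whose data informed the
  design effect, and projection of hypothetical future trials.
* A Monte-Carlo harness demonstrating type-I inflation of naive repeated
  testing and the error control of boundary monitoring.

## Worked example

The packaged data are the two completed MiQuit trials — a text-message
smoking-cessation intervention for pregnant women — as 2×2 tables
reconstructed from the published percentages (per-arm counts were never
printed; see `tsakit/datasets.py`).  The design anticipates quit rates of
2.0% vs 5.4% with 90% power at two-sided 5% significance.

```python
from tsakit import report, run_sequential
from tsakit.datasets import MIQUIT_ANALYSED, miquit_design, miquit_trials

result = run_sequential(miquit_trials(), miquit_design(),
                        accrued_override=MIQUIT_ANALYSED)
print(report(result))
```

prints

```
Trial sequential analysis
=========================
Pooled OR (random_DL, k=2): 2.080
  naive 95% CI:    1.008 to 4.291
  adjusted CI:     0.721 to 6.003
  tau2=0.0000  I2=0.0%  D2=0.0%

Look  trial            t      z     eff_z  fut_z  classification
   1  feasibility     0.160  1.118   4.904      -  continue
   2  pilot           0.467  1.982   2.869  0.072  conventional_only

Verdict: continue
Required information size: 1296 participants
Accrued: 605 participants (fraction 0.467)
```

Reading the numbers: the pooled odds ratio 2.08 is conventionally
significant (z = 1.98 ≥ 1.96, naive CI excludes 1) but falls well short of
the monitoring boundary 2.87 at 47% of the required information, so the
adjusted CI still includes 1 — the finding could be a false positive, and
the verdict is to continue trialling.  The remaining requirement is
1296 − 605 = 691 participants (346 per arm):

```
$ tsa plan src/tsakit/data/miquit_reconstructed.csv \
      --p-ctl 0.020 --p-exp 0.054 --accrued 605
RIS 1296, accrued 605 -> additional 691 participants (346 per arm, 1:1)
```

The `examples/` directory has one short script per capability (analysis,
planning, scenario projection, boundary tables, error-rate simulation); the
same workflow is scriptable through the `tsa` CLI (`analyze`, `plan`,
`project`, `boundaries`, `simulate`).

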