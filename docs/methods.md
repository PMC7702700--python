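# Methods

## Model and procedure

`tsakit` performs cumulative meta-analysis of two-arm binary-outcome trials
under group-sequential monitoring.

**Effects and pooling.** Each trial is a 2×2 table (a, b; c, d) =
(events, non-events) in the experimental and control arms.  The default
measure is the log odds ratio, point = ln(ad/bc), se² = 1/a + 1/b + 1/c +
1/d; risk ratio and risk difference use the standard large-sample formulas.
When any cell is zero, 0.5 is added to all four cells of that trial (the
usual constant continuity correction; toggleable — a double-zero table with
the correction disabled is inestimable and rejected).  Pooling is
inverse-variance.  The random-effects model is DerSimonian–Laird:
Q = Σw(θᵢ − θ_F)², τ² = max(0, (Q − (k−1)) / (Σw − Σw²/Σw)), random
weights 1/(se² + τ²).  Heterogeneity is summarised by
I² = max(0, (Q − (k−1))/Q) and by the diversity D² = 1 − v_F/v_R, the
fraction of the random-effects model variance attributable to between-trial
variation.  D² ≥ I² always; both are defined as 0 for a single trial so the
sequential machinery runs from the first look.  The implementation was
cross-checked against R `metafor` (method="DL") to 1e-10 on the packaged
data.

**Information.** Information is measured in randomised participants — all
planning arithmetic in this setting is participant counts.  The
fixed-model information size for anticipated proportions p_C, p_E at
two-sided α and power 1 − β is IS = 4(z₁₋α/₂ + z₁₋β)² p̄(1−p̄)/(p_E−p_C)²
(p̄ the mean proportion), and RIS = ⌈IS/(1 − D²)⌉.  This is the variance
model of the two-proportion *risk-difference* test; it agrees with the
conventional two-trial-arm sample size to within rounding (≤ 6
participants on the shipped design).  Participant numbers are always
ceiled, never rounded, so designs are not under-powered by truncation.
Accrued information is the running sum of randomised participants; an
explicit analysed-participant override replaces the final total when the
two differ (the shipped example analyses 605 of 614 randomised).

**Boundaries.** Two-sided symmetric efficacy boundaries are solved from an
error-spending function on the realised look schedule t₁ < … ≤ 1 (each
trial is one look; t > 1 is clamped, and looks past full information use
the fixed-sample 1.96).  The default O'Brien–Fleming-type Lan–DeMets spend
is α*(t) = 2(1 − Φ(z₁₋α/₂/√t)), halved per tail; a Pocock-type function is
available.  Under the null the cumulative z-statistics are multivariate
normal with corr(Zᵢ, Zⱼ) = √(tᵢ/tⱼ); boundaries are solved look-by-look
with the classical sub-density recursion on the score scale S = Z√t
(independent normal increments), propagated by Simpson-rule convolution on
a ≥ 2001-point grid spanning the continuation region, with Brent
root-finding (tolerance 1e-6 on z) on each look's incremental crossing
probability.  The recursion was validated three ways: against an
independent multivariate-normal rectangle oracle (agreement < 1e-3),
against published two-sided Lan–DeMets O'Brien–Fleming tables under the
per-tail convention (below), and by closing the loop — the attained null
crossing probability of a solved boundary set recomputes to α within 1e-7.
Doubling the grid moves no boundary by more than 1e-4.

*Spending conventions.* Two conventions exist for two-sided symmetric
designs.  The default evaluates the spending function once at the total
two-sided α and splits the spend between the tails; `SpendingSpec(per_side=
True)` instead lets each tail spend its own function at level α/2, which is
what the familiar published tables use (4.877, 3.357, 2.680, 2.290, 2.031
at five equal looks, α = 0.05) and is slightly more conservative early.
On the worked example's two-look schedule the conventions give second-look
boundaries 2.87 and 3.08 respectively; the per-tail figure reproduces the
adjusted confidence interval printed by the reference TSA software for
that example, suggesting that software spends per tail.

**Futility.** The inner wedge spends the type-II error β under the design
alternative, represented by the drift θ* = z₁₋α/₂ + z₁₋β (the expected z at
full information).  The same spending family is applied to β — the
reference software's β-spending choice is not documented, so this is a
package assumption — and the wedge value at each look is solved with the
same recursion, continuing between the wedge and the efficacy boundary.
Efficacy boundaries are solved ignoring the wedge (non-binding futility),
so type-I control never depends on stopping for futility.  A wedge is
displayed (and can be crossed) only where f > 0.  The wedge meets the
efficacy boundary exactly only in a single-look design; see Limitations.

**Sequential analysis.** At look j the first j trials are pooled, D² of
that cumulative meta-analysis (or a user override; or a design-time frozen
value with `freeze_d2=True`) sets the current RIS, earlier accrual totals
are re-expressed on that single information scale, and boundaries are
solved on the realised schedule — spending functions need one scale per
analysis, so a D² change rescales all fractions rather than mixing scales.
Looks are classified exhaustively and exclusively: `efficacy_crossed` iff
|z| ≥ boundary; otherwise `information_reached` at t ≥ 1;
`futility_crossed` when |z| falls inside a displayed wedge;
`conventional_only` when 1.96 ≤ |z| < boundary; else `continue`.  As a
result-level verdict, `conventional_only` maps to `continue` — crossing
only the fixed-sample threshold is not a sequential decision.

**Adjusted confidence interval.** The repeated confidence interval
exp(θ ± b_J·se) (natural scale for risk differences), where b_J is the
final look's efficacy boundary: width is exactly b_J/1.96 times the naive
interval, equal at full information.  The reference software's internal
algorithm for its adjusted CI is not published; the repeated-CI
construction is this package's documented choice and is validated by
containment and the width ratio, not by reproducing printed endpoints.

**Planning.** additional = max(0, RIS − accrued), per-arm = ⌈additional/2⌉
(1:1 only; doubling the per-arm count can exceed the total by one — both
are reported).  Conservative mode removes the design-informing trial from
both the meta-analysis and the accrual, widening the gap by exactly that
trial's size when D² is unchanged.  Multi-trial division of the total is
left to the user.  Projection appends a hypothetical trial, reruns the
analysis (its data may raise D² and hence the RIS), and reports the new
verdict; when the efficacy boundary is crossed the remaining requirement
is zero.

## Synthetic data and experiments

`SimSpec` draws each trial's log odds ratio from N(ln OR_true, τ²),
converts to an experimental-arm probability through the logistic link
anchored at the control rate, and draws binomial event counts, 1:1 split;
everything is reproducible from the seed.  Defaults: control rate 0.10,
ten trials of 202 participants, 10,000 replicates (Monte-Carlo standard
error ≈ 0.002 at α = 0.05).  The default control rate and trial size are
chosen so expected cell counts (~10+ events per arm) support the normal
approximation the z-machinery assumes: the experiments probe the
*sequential procedure*, not small-sample bias of the log odds ratio.  The
companion design (p_C = 0.10, p_E = 0.1475, α = 0.05, power 0.90) has
RIS = 2020, so ten equal trials place looks at t = 0.1, …, 1.0.

The type-I experiment runs under OR = 1 and reports the fraction of
replicates declared significant at any look — naively (|z| ≥ 1.96 every
look; ≈ 0.15 at ten looks) or against the solved boundaries (held at or
below α).  The power experiment runs under the design alternative with
total n = RIS and pools *risk differences* with fixed effects, because the
information-size formula is the risk-difference test's variance model;
measuring power on the log-OR z-test at an RD-derived information size
would conflate two scales (the OR test's analytic power at this design is
≈ 0.88 for that reason, an expected property, not a defect).

What the generator does not emulate: publication bias, small-study
effects, non-1:1 allocation, within-trial interim looks, time-to-event
outcomes, and correlated trial designs.  Passing simulations therefore
show that the sequential machinery controls the errors it models, not that
real-world meta-analyses are free of other biases.

## The packaged worked example

The MiQuit feasibility (207 women, 12.5% vs 7.8% cessation) and pilot
(407 women, 5.4% vs 2.0%) trials are shipped as reconstructed 2×2 tables —
13/104 vs 8/103 and 11/203 vs 4/204 — the integer counts consistent with
the published percentages under a near-1:1 split; per-arm counts were
never printed, so the tables and everything downstream of them are
approximate.  The reconstruction reproduces the published feasibility OR
(1.68) exactly and the pilot OR approximately (2.86 vs printed 2.70); the
two-trial DerSimonian–Laird pooled OR is 2.08 against a published 2.26
that is not recoverable from any counts matching the printed percentages.
Hypothetical scenario trials C (16/315 vs 6/315, +3.17%) and D (4/315 vs
6/315, −0.63%) are reconstructed the same way; scenario D yields
D² = 30.9% where the reference analysis printed 33%, so its raised RIS is
1876 here versus 1941 there.  The closed-form design arithmetic —
conventional sample size 1292, RIS 1296, 1296 − 605 = 691,
1941 − 1235 = 706 — is exact and independent of the reconstruction.

## Numerical choices and degenerate inputs

- z-quantiles from the standard normal inverse CDF at full floating
  precision; no table lookups (the "1.96" in prose is Φ⁻¹(0.975)).
- Boundary solver: Simpson grid ≥ 2001 points per look over the exact
  continuation region; bisection-backed Brent to 1e-6; boundaries capped at
  z = 15 where the incremental spend is numerically zero.
- Spending boundaries on *clustered* looks (spacing → 0) can locally rise:
  the incremental spend is O(Δt) while the crossing probability at an
  unchanged threshold is O(√Δt).  Monotone decrease is an invariant of
  separated schedules only.
- k = 1 pooling defines τ² = I² = D² = 0; Q = 0 gives I² = 0; τ² and I²
  are truncated at zero.
- Degenerate schedules (duplicate fractions after clamping at 1) are
  rejected; a schedule ending short of t = 1 spends only α*(t_last).

## Known limitations

- Attained power at exactly n = RIS under boundary monitoring is ~1–2
  percentage points below the design power (≈ 0.886 for the ten-look
  simulation design, dual-validated by recursion and Monte Carlo): the
  information-size formula is the fixed-sample one and omits the
  group-sequential inflation factor.  Equivalently, the futility wedge
  meets the efficacy boundary at t = 1 only for single-look designs.
  This mirrors the reference software's own convention; treat the RIS as
  a floor, not a guarantee of full design power under monitoring.
- Only two-sided symmetric designs, binary outcomes, and 1:1 allocation;
  no Peto/Mantel–Haenszel pooling, meta-regression, stage-wise p-values,
  or conditional power.
- The adjusted CI and β-spending family are documented package choices
  where the reference software's algorithms are unpublished.
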