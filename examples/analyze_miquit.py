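"""Sequential analysis of the two completed MiQuit smoking-cessation trials.

Pools the feasibility and pilot trials chronologically, compares the
cumulative z-score with Lan-DeMets O'Brien-Fleming monitoring boundaries,
and prints the per-look report.  The pooled odds ratio crosses the
conventional 1.96 threshold but not the monitoring boundary, so the
evidence is not yet decisive and the adjusted confidence interval is wider
than the naive one.
"""

from tsakit import report, run_sequential
from tsakit.datasets import MIQUIT_ANALYSED, miquit_design, miquit_trials

result = run_sequential(
    miquit_trials(), miquit_design(), accrued_override=MIQUIT_ANALYSED
)
print(report(result))
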