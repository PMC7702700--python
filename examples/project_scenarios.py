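"""Project how a hypothetical third trial would change the verdict.

Scenario C (630 women, +3.17% absolute difference in favour of the
intervention) pushes the cumulative z-curve across the monitoring boundary:
a firm conclusion without reaching the full information size.  Scenario D
(same size, -0.63% against) drops the z-curve below conventional
significance without touching the futility wedge, and the heterogeneity it
introduces raises the required information size, so even more participants
are needed.
"""

from tsakit import project_scenario
from tsakit.datasets import MIQUIT_ANALYSED, miquit_design, miquit_trials, scenario_trial

design = miquit_design()
trials = miquit_trials()

for name in ("C", "D"):
    result, plan = project_scenario(
        trials, scenario_trial(name), design, accrued_override=MIQUIT_ANALYSED
    )
    final = result.final_look
    print(
        f"scenario {name}: z={final.z:+.2f} vs boundary {final.efficacy_z:.2f}  "
        f"D2={result.final_pooled.D2:.1%}  RIS={result.ris}  "
        f"verdict={result.verdict}  additional={plan.additional_total}"
    )
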