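"""Sample size for one or more future trials from the completed ones.

The requirement is the gap between the heterogeneity-adjusted required
information size and the participants already recruited.  The standard plan
counts both completed trials; the conservative plan excludes the pilot
trial, whose data informed the anticipated effect, and therefore asks for
more participants — yet still fewer than a stand-alone conventionally
powered trial (1292).
"""

from tsakit import conventional_sample_size, plan_next_trials
from tsakit.datasets import MIQUIT_ANALYSED, miquit_design, miquit_trials

design = miquit_design()
trials = miquit_trials()

print(f"conventional stand-alone trial: {conventional_sample_size(design)} participants")

std = plan_next_trials(design, trials, accrued_override=MIQUIT_ANALYSED)
print(
    f"standard plan:     RIS {std.ris}, accrued {std.accrued} -> "
    f"{std.additional_total} more participants ({std.per_arm} per arm)"
)

con = plan_next_trials(design, trials, mode="conservative", exclude="pilot")
print(
    f"conservative plan: RIS {con.ris}, accrued {con.accrued} -> "
    f"{con.additional_total} more participants ({con.per_arm} per arm)"
)
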