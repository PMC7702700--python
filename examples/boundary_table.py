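"""Monitoring and futility boundaries for a five-look schedule.

Solves the Lan-DeMets O'Brien-Fleming alpha-spending efficacy boundaries
and the beta-spending futility wedge at five equally spaced information
fractions.  Early looks demand very large z-scores (almost no error is
spent); the final threshold sits just above the fixed-sample 1.96.  The
wedge exists (f > 0) only once enough information has accrued.
"""

from tsakit import SpendingSpec, futility_boundaries

bset = futility_boundaries(
    [0.2, 0.4, 0.6, 0.8, 1.0], SpendingSpec(total_error=0.05), beta=0.10
)
print("t      efficacy_z  futility_z  alpha_spent  beta_spent")
for i, t in enumerate(bset.fractions):
    fut = bset.displayed_futility()[i]
    fut_s = f"{fut:10.3f}" if fut is not None else "         -"
    print(
        f"{t:4.2f} {bset.efficacy_z[i]:11.3f} {fut_s} "
        f"{bset.alpha_spent[i]:12.6f} {bset.beta_spent[i]:11.6f}"
    )
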