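"""Why repeated significance testing needs monitoring boundaries.

Simulates many replicate sequences of ten null trials (odds ratio 1) and
counts how often a cumulative meta-analysis is declared significant when
every update is tested naively at |z| >= 1.96, versus when it is tested
against alpha-spending boundaries.  Naive repeated testing inflates the
type-I error well above the nominal 5%; boundary monitoring holds it.

2000 replicates keep this demo quick; the packaged experiments default to
10,000.
"""

from tsakit import DesignSpec, SimSpec, error_rate_experiment

design = DesignSpec(p_ctl=0.10, p_exp=0.1475, alpha=0.05, power=0.90)
spec = SimSpec(
    true_or=1.0, p_ctl=0.10, n_trials=10, n_per_trial=202, replicates=2000, seed=7
)

naive = error_rate_experiment(spec, design, monitor="naive")
monitored = error_rate_experiment(spec, design, monitor="boundaries")
print(f"type-I error, naive repeated testing (10 looks): {naive:.3f}")
print(f"type-I error, boundary monitoring  (10 looks): {monitored:.3f}")
print("nominal level: 0.050")
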