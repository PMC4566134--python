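"""Anomalous-signal quality as a function of pattern count.

Computes the half-set CC_ano, the model-referenced CC_anoref, and the
anomalous-Patterson peak height at the true Harker vector for growing
nested subsets of derivative patterns.
"""

import sirasfx as sx
from sirasfx.experiments import run_signal_curves
from sirasfx.simulate import SimulationConfig, simulate_patterns

truth = sx.default_ground_truth(seed=1)
derivative = simulate_patterns(truth, "derivative",
                               SimulationConfig(seed=4, n_patterns=800))
tab = run_signal_curves(truth, derivative, [100, 200, 400, 800], seed=1)
print(tab.round(3).to_string(index=False))
print("CC_ano (two random halves against each other) stays low long after")
print("CC_anoref (observed vs model-calculated Bijvoet differences) shows the")
print("signal emerging — the reason the model-referenced statistic exists.")
print("The Patterson sigma-height at the Hg self-vector grows alongside it.")
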