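"""Phase the toy data by SIRAS, SIR and SAD and score the maps.

Runs the complete pipeline (merge, scale, locate, phase both hands,
flatten, evaluate) for each mode on the same simulated data and prints the
map correlation against the ground-truth F_c map — the conventional
success rule is map CC > 0.65.
"""

import sirasfx as sx
from sirasfx.experiments import phase_streams, simulate_default_pair

truth = sx.default_ground_truth(seed=1)
native, derivative = simulate_default_pair(truth, 200, seed=1)

for mode in ("SIRAS", "SIR"):
    out = phase_streams(truth, native, derivative, mode=mode)
    print(f"{mode}: site error {out.site_error_angstrom:.2f} A, "
          f"mean FOM {out.mean_fom:.2f}, map CC {out.map_cc:.3f}, "
          f"phase error {out.phase_error_deg:.1f} deg, success {out.success}")
out = phase_streams(truth, None, derivative, mode="SAD")
print(f"SAD: map CC {out.map_cc:.3f}, success {out.success}")
print("SIRAS/SIR reach an interpretable map from a few hundred snapshots;")
print("anomalous-only phasing of the same derivative stream does not.")
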