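"""Cross-check the cohort recursion against a patient-level simulation.

Simulates 50,000 individual trajectories with the same transition and reward
rules and compares mean outcomes with the deterministic cohort model; they
should agree within Monte-Carlo error.
"""

import numpy as np

from osteocea import TREATMENT, microsim_summary, default_parameters, \
    run_cohort, summarize
from osteocea.engine import ShadowEvents

params = default_parameters()
n = 50_000

ms = microsim_summary(params, TREATMENT, n, seed=7)
trace = run_cohort(params, TREATMENT)
zero = ShadowEvents(np.zeros_like(trace.incident), np.zeros(trace.n_cycles),
                    np.zeros(trace.n_cycles), np.zeros(trace.n_cycles))
cohort = summarize(trace, trace, zero, zero, params).treatment

print(f"{'outcome':<14} {'cohort':>10} {'microsim':>10} {'z-score':>8}")
for field in ("qalys", "life_years", "fracture_cost", "total_cost"):
    c = getattr(cohort, field)
    m = getattr(ms, field)
    z = (m - c) / ms.se[field]
    print(f"{field:<14} {c:10.3f} {m:10.3f} {z:8.2f}")

print(f"\n|z| < 3 for every outcome means the deterministic cohort "
      f"recursion and {n:,} sampled patient histories tell the same story "
      "(comparison excludes the out-of-chain correction factor, which the "
      "microsimulation does not model).")
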