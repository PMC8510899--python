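"""Shared helpers for the test suite."""

import numpy as np

from osteocea import TREATMENT, run_cohort, summarize
from osteocea.engine import ShadowEvents


def markov_visible_arm(params, arm):
    """Cohort arm summary excluding the out-of-chain correction factor.

    Used when comparing against the patient-level oracle, which simulates
    only Markov-visible events.
    """
    tr = run_cohort(params, arm)
    zero = ShadowEvents(np.zeros_like(tr.incident), np.zeros(tr.n_cycles),
                        np.zeros(tr.n_cycles), np.zeros(tr.n_cycles))
    res = summarize(tr, tr, zero, zero, params)
    return res.treatment if arm == TREATMENT else res.off_treatment
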