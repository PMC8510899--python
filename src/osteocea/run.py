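"""One-call evaluation of the two-strategy comparison."""

from __future__ import annotations

from .economics import EconomicSummary, summarize
from .engine import correction_factor, run_cohort
from .parameters import OFF_TREATMENT, TREATMENT, ModelParameters

__all__ = ["evaluate"]


def evaluate(params: ModelParameters,
             age_rate_multiplier: dict[int, float] | None = None
             ) -> EconomicSummary:
    """Run both arms, apply the correction factor, and summarize.

    This is the base-case pipeline: treatment and off-treatment cohort
    traces, out-of-chain accounting of hierarchy-hidden fractures, then
    discounted costs, QALYs, life-years, 10-year fracture counts and the
    ICER.
    """
    trace_t = run_cohort(params, TREATMENT, age_rate_multiplier)
    trace_o = run_cohort(params, OFF_TREATMENT, age_rate_multiplier)
    shadow_t = correction_factor(trace_t, params)
    shadow_o = correction_factor(trace_o, params)
    return summarize(trace_t, trace_o, shadow_t, shadow_o, params)
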