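"""Discounted costs, QALYs, life-years and the incremental comparison.

Rewards accrue on state occupancy at cycle start; a cycle's whole reward is
discounted by that cycle's factor.  Annual inputs are prorated by the cycle
length.  First-year fracture costs use the age band at the *event* (the age a
year-1 tunnel occupant had on entering the track); subsequent-year costs and
utility multipliers persist for the remainder of life in the post-hip /
post-vertebral states.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, NamedTuple

import numpy as np

from .parameters import (
    FRACTURE_TYPES,
    OFF_TREATMENT,
    TREATMENT,
    ModelParameters,
    age_band_lookup,
)

if TYPE_CHECKING:  # pragma: no cover
    from .engine import CohortTrace, ShadowEvents, StateSpace

__all__ = [
    "discount_factor",
    "cycle_fracture_cost",
    "cycle_treatment_cost",
    "cycle_qaly",
    "fracture_cost_vector",
    "qaly_vector",
    "ArmSummary",
    "EconomicSummary",
    "summarize",
]

#: Cycles counted towards the "10-year fracture incidence" block.
TEN_YEARS = 10.0


def discount_factor(cycle: int, annual_rate: float, cycle_length: float) -> float:
    """Present-value factor for a reward accruing at ``cycle``."""
    return float((1.0 + annual_rate) ** (-(cycle * cycle_length)))


class TreatmentCost(NamedTuple):
    """Per-cycle treatment spend for one fully alive, persistent patient."""

    drug: float
    management: float

    @property
    def total(self) -> float:
        return self.drug + self.management


def cycle_treatment_cost(cycle: int, arm: str,
                         params: ModelParameters) -> TreatmentCost:
    """Drug and management cost per persistent patient in ``cycle``.

    Treatment arm (while on the 5-year course): one dose per cycle, a nurse
    visit each cycle, a routine visit every second cycle and a DXA scan every
    fourth.  Off-treatment arm: the single dose, nurse visit and routine visit
    in cycle 0 only.
    """
    c = params.costs
    s = params.settings
    dose = c.drug_annual * s.cycle_length
    if arm == OFF_TREATMENT:
        if cycle == 0:
            return TreatmentCost(dose, c.visit_nurse + c.visit_routine)
        return TreatmentCost(0.0, 0.0)
    if arm != TREATMENT:
        raise ValueError(f"unknown arm: {arm!r}")
    if cycle >= s.treatment_cycles:
        return TreatmentCost(0.0, 0.0)
    per_year = s.cycles_per_year
    mgmt = c.visit_nurse
    if cycle % per_year == 0:
        mgmt += c.visit_routine
    if cycle % (2 * per_year) == 0:
        mgmt += c.dxa_scan
    return TreatmentCost(dose, mgmt)


def cycle_fracture_cost(space: "StateSpace", state: int | str,
                        age: float) -> float:
    """Fracture-care cost accrued by one occupant of ``state`` this cycle."""
    from . import engine as eng

    if isinstance(state, str):
        state = space.index[state]
    params = space.params
    dt = space.cycle_length
    k = int(space.kind[state])
    t = int(space.tunnel[state])
    if k in (eng.HIP, eng.VERT, eng.OTHER) and t <= space.per_year:
        f = {eng.HIP: "hip", eng.VERT: "vertebral", eng.OTHER: "other"}[k]
        event_age = age - (t - 1) * dt
        return age_band_lookup(event_age, params.costs.fracture_first_year[f]) * dt
    if k in (eng.HIP, eng.POST_HIP):
        return params.costs.fracture_subsequent_annual["hip"] * dt
    if k in (eng.VERT, eng.POST_VERT):
        return params.costs.fracture_subsequent_annual["vertebral"] * dt
    return 0.0


def cycle_qaly(space: "StateSpace", state: int | str, age: float) -> float:
    """QALYs accrued by one occupant of ``state`` this cycle."""
    from . import engine as eng

    if isinstance(state, str):
        state = space.index[state]
    params = space.params
    dt = space.cycle_length
    k = int(space.kind[state])
    t = int(space.tunnel[state])
    if k == eng.DEAD:
        return 0.0
    u = age_band_lookup(age, params.utilities.well_by_age)
    if k in (eng.HIP, eng.VERT, eng.OTHER) and t <= space.per_year:
        f = {eng.HIP: "hip", eng.VERT: "vertebral", eng.OTHER: "other"}[k]
        return u * params.utilities.multiplier_first_year[f].value * dt
    if k in (eng.HIP, eng.POST_HIP):
        return u * params.utilities.multiplier_subsequent["hip"].value * dt
    if k in (eng.VERT, eng.POST_VERT):
        return u * params.utilities.multiplier_subsequent["vertebral"].value * dt
    return u * dt


def fracture_cost_vector(space: "StateSpace", age: float) -> np.ndarray:
    """Per-state fracture cost for one cycle at cohort age ``age``."""
    return np.array([cycle_fracture_cost(space, i, age)
                     for i in range(space.n_states)])


def qaly_vector(space: "StateSpace", age: float) -> np.ndarray:
    """Per-state QALY accrual for one cycle at cohort age ``age``."""
    return np.array([cycle_qaly(space, i, age) for i in range(space.n_states)])


def _banded(values: dict[int, float], ages: np.ndarray) -> np.ndarray:
    """Vectorized closed-open age-band lookup."""
    bounds = sorted(values)
    vals = np.array([values[b] for b in bounds])
    idx = np.digitize(ages, bounds[1:], right=False)
    return vals[idx]


def reward_matrices(space: "StateSpace",
                    ages: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Undiscounted per-cycle, per-state cost and QALY matrices.

    Row ``c`` holds what one occupant of each state accrues during cycle
    ``c``; equivalent to stacking :func:`fracture_cost_vector` /
    :func:`qaly_vector` over cycles, but built column-wise for speed.
    """
    from . import engine as eng

    params = space.params
    dt = space.cycle_length
    n = len(ages)
    S = space.n_states
    cost = np.zeros((n, S))
    qaly = np.zeros((n, S))
    u_well = _banded(params.utilities.well_by_age, ages)
    kind_to_type = {eng.HIP: "hip", eng.VERT: "vertebral", eng.OTHER: "other"}
    for i in range(S):
        k = int(space.kind[i])
        t = int(space.tunnel[i])
        if k == eng.DEAD:
            continue
        if k == eng.WELL:
            qaly[:, i] = u_well * dt
        elif k in kind_to_type and t <= space.per_year:
            f = kind_to_type[k]
            event_age = ages - (t - 1) * dt
            cost[:, i] = _banded(params.costs.fracture_first_year[f],
                                 event_age) * dt
            qaly[:, i] = u_well * params.utilities.multiplier_first_year[f].value * dt
        elif k in (eng.HIP, eng.POST_HIP):
            cost[:, i] = params.costs.fracture_subsequent_annual["hip"] * dt
            qaly[:, i] = u_well * params.utilities.multiplier_subsequent["hip"].value * dt
        elif k in (eng.VERT, eng.POST_VERT):
            cost[:, i] = params.costs.fracture_subsequent_annual["vertebral"] * dt
            qaly[:, i] = (u_well *
                          params.utilities.multiplier_subsequent["vertebral"].value * dt)
    return cost, qaly


@dataclass(frozen=True)
class ArmSummary:
    """Discounted lifetime outcomes for one strategy."""

    arm: str
    fracture_cost: float
    drug_cost: float
    management_cost: float
    life_years: float
    qalys: float
    fractures_10yr_per_1000: dict[str, float]

    @property
    def total_cost(self) -> float:
        return self.fracture_cost + self.drug_cost + self.management_cost

    def as_dict(self) -> dict:
        return {
            "arm": self.arm,
            "fracture_cost": self.fracture_cost,
            "drug_cost": self.drug_cost,
            "management_cost": self.management_cost,
            "total_cost": self.total_cost,
            "life_years": self.life_years,
            "qalys": self.qalys,
            "fractures_10yr_per_1000": dict(self.fractures_10yr_per_1000),
        }


@dataclass(frozen=True)
class EconomicSummary:
    """Both arms, their increments (treatment minus off-treatment) and ICER."""

    treatment: ArmSummary
    off_treatment: ArmSummary

    @property
    def incremental_cost(self) -> float:
        return self.treatment.total_cost - self.off_treatment.total_cost

    @property
    def incremental_qalys(self) -> float:
        return self.treatment.qalys - self.off_treatment.qalys

    @property
    def incremental_life_years(self) -> float:
        return self.treatment.life_years - self.off_treatment.life_years

    @property
    def fractures_avoided_per_1000(self) -> dict[str, float]:
        """Off-treatment minus treatment 10-year counts (positive = avoided)."""
        return {f: self.off_treatment.fractures_10yr_per_1000[f]
                - self.treatment.fractures_10yr_per_1000[f]
                for f in (*FRACTURE_TYPES, "total")}

    @property
    def icer(self) -> float | None:
        """Δcost / ΔQALY; ``None`` when ΔQALY is zero (see ``icer_label``)."""
        dq = self.incremental_qalys
        if dq == 0.0:
            return None
        return self.incremental_cost / dq

    @property
    def icer_label(self) -> str:
        dq, dc = self.incremental_qalys, self.incremental_cost
        if dq == 0.0:
            return "undefined" if dc == 0.0 else (
                "dominated" if dc > 0 else "dominant")
        if dq > 0 and dc <= 0:
            return "dominant"
        if dq < 0 and dc >= 0:
            return "dominated"
        return f"{self.incremental_cost / dq:.0f}"

    def as_dict(self) -> dict:
        return {
            "treatment": self.treatment.as_dict(),
            "off_treatment": self.off_treatment.as_dict(),
            "incremental_cost": self.incremental_cost,
            "incremental_qalys": self.incremental_qalys,
            "incremental_life_years": self.incremental_life_years,
            "fractures_avoided_per_1000": self.fractures_avoided_per_1000,
            "icer": self.icer,
            "icer_label": self.icer_label,
        }


def _summarize_arm(trace: "CohortTrace", shadow: "ShadowEvents",
                   params: ModelParameters) -> ArmSummary:
    s = params.settings
    dt = s.cycle_length
    n = trace.n_cycles
    space = trace.space
    disc_c = np.array([discount_factor(c, s.discount_rate_costs, dt)
                       for c in range(n)])
    disc_q = np.array([discount_factor(c, s.discount_rate_qalys, dt)
                       for c in range(n)])
    alive = trace.alive[:n]

    cost_mat, qaly_mat = reward_matrices(space, trace.ages)
    occ = trace.occupancy[:n]
    frac_cost = float(disc_c @ (occ * cost_mat).sum(axis=1)) + shadow.total_cost
    qalys = float(disc_q @ (occ * qaly_mat).sum(axis=1)) - shadow.total_qaly_loss
    life_years = float((alive * dt * disc_q).sum())

    # treatment delivery: persistent, alive patients only
    drug = 0.0
    mgmt = 0.0
    if trace.arm == TREATMENT:
        w_p = trace.persistence.persistent
        for c in range(s.treatment_cycles):
            tc = cycle_treatment_cost(c, TREATMENT, params)
            drug += disc_c[c] * alive[c] * w_p[c] * tc.drug
            mgmt += disc_c[c] * alive[c] * w_p[c] * tc.management
    else:
        tc = cycle_treatment_cost(0, OFF_TREATMENT, params)
        drug = tc.drug * alive[0]
        mgmt = tc.management * alive[0]

    n10 = min(int(round(TEN_YEARS / dt)), n)
    counts = {}
    for j, f in enumerate(FRACTURE_TYPES):
        counts[f] = 1000.0 * float(trace.incident[:n10, j].sum()
                                   + shadow.events[:n10, j].sum())
    counts["total"] = sum(counts[f] for f in FRACTURE_TYPES)
    return ArmSummary(trace.arm, frac_cost, drug, mgmt, life_years, qalys, counts)


def summarize(trace_treatment: "CohortTrace", trace_off: "CohortTrace",
              shadow_treatment: "ShadowEvents", shadow_off: "ShadowEvents",
              params: ModelParameters) -> EconomicSummary:
    """Fold two traces and their correction factors into the Table-2 surface."""
    return EconomicSummary(
        _summarize_arm(trace_treatment, shadow_treatment, params),
        _summarize_arm(trace_off, shadow_off, params),
    )
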