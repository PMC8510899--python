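"""Patient-level Monte-Carlo microsimulation: an independent oracle.

Individual trajectories are sampled with the same per-cycle transition
probabilities, persistence mechanics and reward rules as the cohort engine,
but with discontinuation, fractures and death drawn per patient.  Expected
state occupancy and mean discounted outcomes converge to the cohort model's
values, which makes the microsimulation a cross-check on the deterministic
recursion (within Monte-Carlo error).

The comparison covers Markov-visible quantities: the out-of-chain correction
factor is a cohort-level construct (it uses cohort survival tails) and is not
re-derived per patient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import engine as eng
from .economics import cycle_treatment_cost, discount_factor, reward_matrices
from .parameters import (
    ARMS,
    FRACTURE_TYPES,
    OFF_TREATMENT,
    TREATMENT,
    ModelParameters,
    default_parameters,
)

__all__ = [
    "PatientPath",
    "MicrosimResult",
    "simulate_patient",
    "microsim_summary",
    "random_parameters",
]

_OFF_STATUS_BASE = 0  # status codes: 0 persistent, 1..n_offset offset, n_offset+1 off


def _status_multipliers(hr: float, n_offset: int) -> np.ndarray:
    """Hazard multiplier per persistence status code (0..n_offset+1)."""
    m = np.empty(n_offset + 2)
    m[0] = hr
    for k in range(1, n_offset + 1):
        m[k] = eng.effect_multiplier(hr, k, n_offset)
    m[n_offset + 1] = 1.0
    return m


def _advance_status(status: np.ndarray, cycle: int, n_treat: int,
                    n_offset: int, p_disc: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Evolve persistence status codes at the start of ``cycle``.

    Matches the cohort profile: offsets advance one stratum per cycle;
    persistent patients may discontinue from cycle 2 through the end of the
    course, and all remaining persistent patients enter the offset when the
    course completes.
    """
    off_code = n_offset + 1
    out = status.copy()
    in_offset = (status >= 1) & (status <= n_offset)
    out[in_offset] = np.minimum(status[in_offset] + 1, off_code)
    persistent = status == 0
    if 2 <= cycle < n_treat and p_disc > 0.0:
        leave = persistent & (rng.random(status.shape) < p_disc)
        out[leave] = 1
    elif cycle == n_treat:
        out[persistent] = 1
    return out


@dataclass
class PatientPath:
    """One sampled trajectory."""

    arm: str
    states: list[str]                       # state label at each cycle start
    fractures: list[tuple[int, str]]        # (cycle, fracture type)
    discontinuation_cycle: int | None       # first cycle off treatment, if any
    death_cycle: int | None


def simulate_patient(params: ModelParameters, arm: str,
                     rng: np.random.Generator) -> PatientPath:
    """Sample a single trajectory from the well state at the start age."""
    res = _simulate(params, arm, 1, rng, record_paths=True)
    return res.paths[0]


@dataclass
class MicrosimResult:
    """Monte-Carlo means (and standard errors) over ``n`` patients.

    Costs and QALYs are Markov-visible (no out-of-chain correction), so they
    compare against a cohort summary computed without shadow events.
    """

    arm: str
    n: int
    seed: int | None
    occupancy: np.ndarray                  # (n_cycles + 1, n_states) fractions
    fracture_cost: float
    drug_cost: float
    management_cost: float
    life_years: float
    qalys: float
    se: dict[str, float]
    paths: list[PatientPath] = field(default_factory=list)

    @property
    def total_cost(self) -> float:
        return self.fracture_cost + self.drug_cost + self.management_cost


def microsim_summary(params: ModelParameters, arm: str, n: int,
                     seed: int | None = None) -> MicrosimResult:
    """Mean discounted outcomes over ``n`` simulated patients."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(params.settings.rng_seed if seed is None else seed)
    res = _simulate(params, arm, n, rng)
    res_seed = params.settings.rng_seed if seed is None else seed
    return MicrosimResult(res.arm, n, res_seed, res.occupancy,
                          res.fracture_cost, res.drug_cost,
                          res.management_cost, res.life_years, res.qalys,
                          res.se)


def _simulate(params: ModelParameters, arm: str, n: int,
              rng: np.random.Generator,
              record_paths: bool = False) -> MicrosimResult:
    if arm not in ARMS:
        raise ValueError(f"arm must be one of {ARMS}")
    space = eng.StateSpace(params)
    s = params.settings
    dt = s.cycle_length
    n_cycles = s.n_cycles
    n_treat = s.treatment_cycles
    n_offset = s.offset_cycles
    off_code = n_offset + 1
    p_disc = eng.rate_to_probability(s.annual_discontinuation_rate, dt)

    ages = s.start_age + dt * np.arange(n_cycles)
    cost_mat, qaly_mat = reward_matrices(space, ages)
    disc_c = np.array([discount_factor(c, s.discount_rate_costs, dt)
                       for c in range(n_cycles)])
    disc_q = np.array([discount_factor(c, s.discount_rate_qalys, dt)
                       for c in range(n_cycles)])
    mult_by_status = {f: _status_multipliers(params.effect.hazard_ratio(f),
                                             n_offset)
                      for f in FRACTURE_TYPES}
    rates = {f: params.rates.rate(f) for f in FRACTURE_TYPES}

    state = np.full(n, space.well, dtype=np.int64)
    status = np.zeros(n, dtype=np.int64)
    frac_cost = np.zeros(n)
    drug = np.zeros(n)
    mgmt = np.zeros(n)
    qalys = np.zeros(n)
    lys = np.zeros(n)
    occupancy = np.zeros((n_cycles + 1, space.n_states))
    occupancy[0] = np.bincount(state, minlength=space.n_states) / n

    paths_states: list[list[str]] = (
        [[space.labels[space.well]] for _ in range(n)] if record_paths else [])
    fractures: list[list[tuple[int, str]]] = [[] for _ in range(n)] if record_paths else []
    disc_cycle: list[int | None] = [None] * n if record_paths else []

    for c in range(n_cycles):
        age = ages[c]
        if arm == TREATMENT and c >= 1:
            prev = status.copy()
            status = _advance_status(status, c, n_treat, n_offset, p_disc, rng)
            if record_paths:
                for i in range(n):
                    if disc_cycle[i] is None and prev[i] == 0 and status[i] != 0:
                        disc_cycle[i] = c

        # per-patient fracture entry probabilities
        if arm == TREATMENT:
            p_by_f = {f: (1.0 - np.exp(-rates[f] * mult_by_status[f][status] * dt))
                      for f in FRACTURE_TYPES}
        else:
            mult = {f: (params.effect.hazard_ratio(f) if c == 0 else 1.0)
                    for f in FRACTURE_TYPES}
            p_by_f = {f: np.full(n, 1.0 - np.exp(-rates[f] * mult[f] * dt))
                      for f in FRACTURE_TYPES}

        band = space.mortality_band_index(age)
        p_well = eng.probability_to_rate(
            eng.age_band_lookup(age, params.mortality.well_annual))
        q_states = 1.0 - np.exp(-p_well * space.rr_by_band[:, band] * dt)
        q_states[space.dead] = 0.0
        q = q_states[state]

        in_well = state == space.well
        hip_at_risk = space.can_hip[state]
        p_h = np.where(in_well | hip_at_risk, p_by_f["hip"], 0.0)
        p_v = np.where(in_well, p_by_f["vertebral"], 0.0)
        p_o = np.where(in_well, p_by_f["other"], 0.0)
        total = q + p_h + p_v + p_o
        over = total > 1.0
        if np.any(over):
            scale = np.where(over, 1.0 / total, 1.0)
            q, p_h, p_v, p_o = q * scale, p_h * scale, p_v * scale, p_o * scale

        alive = state != space.dead
        # rewards on the state at cycle start
        frac_cost += disc_c[c] * cost_mat[c, state]
        qalys += disc_q[c] * qaly_mat[c, state]
        lys += disc_q[c] * dt * alive
        if arm == TREATMENT:
            on_rx = alive & (status == 0) & (c < n_treat)
            tc = cycle_treatment_cost(c, TREATMENT, params)
            drug += disc_c[c] * tc.drug * on_rx
            mgmt += disc_c[c] * tc.management * on_rx
        elif c == 0:
            tc = cycle_treatment_cost(0, OFF_TREATMENT, params)
            drug += disc_c[c] * tc.drug * alive
            mgmt += disc_c[c] * tc.management * alive

        u = rng.random(n)
        new_state = space.advance[state]
        hit_death = u < q
        hit_hip = (~hit_death) & (u < q + p_h)
        hit_vert = (~hit_death) & (~hit_hip) & (u < q + p_h + p_v)
        hit_other = (~hit_death) & (~hit_hip) & (~hit_vert) & (u < q + p_h + p_v + p_o)
        new_state[hit_death] = space.dead
        new_state[hit_hip] = space.hip_entry
        new_state[hit_vert] = space.vert_entry
        new_state[hit_other] = space.other_entry
        new_state[~alive] = space.dead
        if record_paths:
            for i in range(n):
                if hit_hip[i]:
                    fractures[i].append((c, "hip"))
                elif hit_vert[i]:
                    fractures[i].append((c, "vertebral"))
                elif hit_other[i]:
                    fractures[i].append((c, "other"))
        state = new_state
        occupancy[c + 1] = np.bincount(state, minlength=space.n_states) / n
        if record_paths:
            for i in range(n):
                paths_states[i].append(space.labels[state[i]])

    total = frac_cost + drug + mgmt
    se = {
        "fracture_cost": float(frac_cost.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        "total_cost": float(total.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        "qalys": float(qalys.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        "life_years": float(lys.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
    }
    result = MicrosimResult(arm, n, None, occupancy,
                            float(frac_cost.mean()), float(drug.mean()),
                            float(mgmt.mean()), float(lys.mean()),
                            float(qalys.mean()), se)
    if record_paths:
        for i in range(n):
            labels = paths_states[i]
            death = next((c for c, lab in enumerate(labels) if lab == "dead"), None)
            end = death + 1 if death is not None else len(labels)
            result.paths.append(PatientPath(arm, labels[:end], fractures[i],
                                            disc_cycle[i], death))
    return result


def random_parameters(seed: int,
                      rng: np.random.Generator | None = None) -> ModelParameters:
    """A valid randomized parameter set bracketing the published values.

    Used for fuzz/property testing of the engine: fracture rates ×[0.25, 4],
    hazard ratios in [0.3, 1.0], mortality and relative risks ×[0.5, 2]
    (probabilities clipped below 1), costs ×[0.25, 4], well utilities in
    [0.3, 0.9], utility multipliers in [0.4, 1.0].  Settings are unchanged.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    base = default_parameters()
    d = base.to_dict()

    def scale(x, lo, hi):
        return float(x) * rng.uniform(lo, hi)

    for f in FRACTURE_TYPES:
        d["rates"][f] = scale(getattr(base.rates, f).value, 0.25, 4.0)
    for name in ("hr_hip", "hr_vertebral", "hr_nonvertebral"):
        d["effect"][name] = float(rng.uniform(0.3, 1.0))
    for band in d["mortality"]["well_annual"]:
        d["mortality"]["well_annual"][band] = min(
            scale(d["mortality"]["well_annual"][band], 0.5, 2.0), 0.95)
    for key in ("rr_first_year", "rr_subsequent"):
        for f in d["mortality"][key]:
            for band in d["mortality"][key][f]:
                d["mortality"][key][f][band] = scale(
                    d["mortality"][key][f][band], 0.5, 2.0)
    for f in d["costs"]["fracture_first_year"]:
        for band in d["costs"]["fracture_first_year"][f]:
            d["costs"]["fracture_first_year"][f][band] = scale(
                d["costs"]["fracture_first_year"][f][band], 0.25, 4.0)
    for f in d["costs"]["fracture_subsequent_annual"]:
        d["costs"]["fracture_subsequent_annual"][f] = scale(
            d["costs"]["fracture_subsequent_annual"][f], 0.25, 4.0)
    for name in ("drug_annual", "visit_routine", "visit_nurse", "dxa_scan"):
        d["costs"][name] = scale(d["costs"][name], 0.25, 4.0)
    for band in d["utilities"]["well_by_age"]:
        d["utilities"]["well_by_age"][band] = float(rng.uniform(0.3, 0.9))
    for key in ("multiplier_first_year", "multiplier_subsequent"):
        for f in d["utilities"][key]:
            d["utilities"][key][f] = float(rng.uniform(0.4, 1.0))
    return ModelParameters.from_dict(d)
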