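"""Discrete-time Markov cohort engine.

State space (6-month cycles): a single ``well`` state; hip and vertebral
fracture tracks made of one tunnel state per cycle since the event for the
duration of the excess-mortality window (16 tunnels for 8 years), followed by
a terminal post-fracture state with background mortality; an "other" (wrist /
distal forearm) fracture track of two tunnels that returns to ``well``; and an
absorbing ``dead`` state.  The first two tunnels of each track are the first
year after the event (first-year mortality, cost and utility inputs apply);
later tunnels carry the subsequent-year inputs.

Severity hierarchy: occupants of a fracture state sustain only fractures of
the same or higher severity — hip-state occupants can re-fracture a hip but
sustain no vertebral or "other" fracture, vertebral-state occupants can
sustain a hip fracture but no "other" fracture (vertebral re-fracture is not
modelled), and "other" states simply clock their year.  The vertebral and
"other" fractures the hierarchy hides are restored by
:func:`correction_factor`, which prices them outside the chain.

Treatment effect: hazard ratios apply to the treatment arm's persistent
patients through the 5-year course and, linearly waning over 2 years, after
discontinuation; the off-treatment arm's single dose covers only cycle 0.
Persistence is carried as population stratum weights (persistent, four offset
strata, off) and enters the chain as a weighted-mean hazard multiplier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .parameters import (
    ARMS,
    FRACTURE_TYPES,
    OFF_TREATMENT,
    TREATMENT,
    ModelParameters,
    SimulationSettings,
    age_band_lookup,
)

__all__ = [
    "StateSpace",
    "PersistenceProfile",
    "CohortTrace",
    "ShadowEvents",
    "rate_to_probability",
    "effect_multiplier",
    "arm_multiplier",
    "persistence_profile",
    "cycle_mortality",
    "build_transition_matrix",
    "build_transition_row",
    "run_cohort",
    "correction_factor",
]

# state kind codes
WELL, HIP, POST_HIP, VERT, POST_VERT, OTHER, DEAD = range(7)
_KIND_NAMES = {WELL: "well", HIP: "hip", POST_HIP: "post_hip", VERT: "vertebral",
               POST_VERT: "post_vertebral", OTHER: "other", DEAD: "dead"}


def rate_to_probability(rate: float, duration: float) -> float:
    """Convert a constant event rate to a probability over ``duration`` years."""
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if duration <= 0:
        raise ValueError("duration must be > 0")
    return 1.0 - math.exp(-rate * duration)


def probability_to_rate(p: float, duration: float = 1.0) -> float:
    """Inverse of :func:`rate_to_probability` (rates compose multiplicatively)."""
    return -math.log(1.0 - p) / duration


class StateSpace:
    """Enumerated model states with precomputed structural arrays."""

    def __init__(self, params: ModelParameters):
        s = params.settings
        dt = s.cycle_length
        per_year = s.cycles_per_year
        n_hip = int(round(params.mortality.excess_duration_years["hip"] / dt))
        n_vert = int(round(params.mortality.excess_duration_years["vertebral"] / dt))
        n_other = per_year  # the "other" state lasts one year, then back to well

        labels: list[str] = ["well"]
        kind = [WELL]
        tunnel = [0]
        for t in range(1, n_hip + 1):
            labels.append(f"hip_{t}")
            kind.append(HIP)
            tunnel.append(t)
        labels.append("post_hip")
        kind.append(POST_HIP)
        tunnel.append(n_hip + 1)
        for t in range(1, n_vert + 1):
            labels.append(f"vertebral_{t}")
            kind.append(VERT)
            tunnel.append(t)
        labels.append("post_vertebral")
        kind.append(POST_VERT)
        tunnel.append(n_vert + 1)
        for t in range(1, n_other + 1):
            labels.append(f"other_{t}")
            kind.append(OTHER)
            tunnel.append(t)
        labels.append("dead")
        kind.append(DEAD)
        tunnel.append(0)

        self.params = params
        self.labels = labels
        self.n_states = len(labels)
        self.kind = np.array(kind)
        self.tunnel = np.array(tunnel)
        self.index = {lab: i for i, lab in enumerate(labels)}
        self.well = 0
        self.dead = self.n_states - 1
        self.hip_entry = self.index["hip_1"]
        self.vert_entry = self.index["vertebral_1"]
        self.other_entry = self.index["other_1"]
        self.per_year = per_year
        self.cycle_length = dt

        # where each state's survivors advance to (well and terminals self-loop)
        adv = np.arange(self.n_states)
        for i, lab in enumerate(labels):
            k, t = kind[i], tunnel[i]
            if k == HIP:
                adv[i] = i + 1  # next tunnel, or post_hip after the last
            elif k == VERT:
                adv[i] = i + 1
            elif k == OTHER:
                adv[i] = i + 1 if t < n_other else self.well
        self.advance = adv

        # severity hierarchy: a state's occupants may sustain fractures of the
        # same or higher severity only; "other" states just clock their year
        self.hip_group = (self.kind == HIP) | (self.kind == POST_HIP)
        self.vert_group = (self.kind == VERT) | (self.kind == POST_VERT)
        self.can_hip = self.vert_group | self.hip_group

        # mortality relative risk per state per age band (bands from the table)
        mort = params.mortality
        self.mort_bands = sorted(mort.well_annual)
        rr = np.ones((self.n_states, len(self.mort_bands)))
        for i in range(self.n_states):
            k, t = kind[i], tunnel[i]
            if k in (HIP, VERT, OTHER):
                f = {HIP: "hip", VERT: "vertebral", OTHER: "other"}[k]
                years_since = (t - 1) * dt  # window start of this tunnel
                if years_since < mort.excess_duration_years[f]:
                    table = (mort.rr_first_year[f] if t <= per_year
                             else mort.rr_subsequent[f])
                    for j, band in enumerate(self.mort_bands):
                        rr[i, j] = table[band]
        self.rr_by_band = rr

    def mortality_band_index(self, age: float) -> int:
        idx = 0
        for j, band in enumerate(self.mort_bands):
            if age >= band:
                idx = j
        return idx

    def describe(self) -> list[tuple[str, str, int]]:
        return [(lab, _KIND_NAMES[int(k)], int(t))
                for lab, k, t in zip(self.labels, self.kind, self.tunnel)]


@dataclass(frozen=True)
class PersistenceProfile:
    """Treatment-arm stratum weights per cycle.

    ``persistent[c]`` is the fraction still on treatment, ``offset[c, k-1]``
    the fraction ``k`` cycles into the post-discontinuation effect-waning
    period, and ``off[c]`` the fraction with no residual effect.  Weights are
    fractions of the (alive) cohort and sum to one every cycle.
    """

    persistent: np.ndarray
    offset: np.ndarray  # shape (n_cycles, offset_cycles)
    off: np.ndarray

    @property
    def n_offset(self) -> int:
        return self.offset.shape[1]


def persistence_profile(settings: SimulationSettings,
                        n_cycles: int | None = None) -> PersistenceProfile:
    """Stratum weights for the treatment arm.

    Everyone is persistent through cycles 0–1 (the cohort received at least
    two doses by construction).  From cycle 2, the persistent fraction decays
    by the per-cycle discontinuation probability through the end of the 5-year
    course; discontinuers — and completers, at the end of the course — pass
    through the offset strata in consecutive cycles and then contribute no
    effect.
    """
    if n_cycles is None:
        n_cycles = settings.n_cycles
    p_disc = rate_to_probability(settings.annual_discontinuation_rate,
                                 settings.cycle_length)
    n_treat = settings.treatment_cycles
    n_off = settings.offset_cycles

    w_p = np.zeros(n_cycles)
    for c in range(n_cycles):
        if c < min(2, n_treat):
            w_p[c] = 1.0
        elif c < n_treat:
            w_p[c] = w_p[c - 1] * (1.0 - p_disc)
        else:
            w_p[c] = 0.0

    leavers = np.zeros(n_cycles + 1)
    prev = 1.0
    for c in range(1, n_cycles):
        leavers[c] = max(prev - w_p[c], 0.0)
        prev = w_p[c]

    offset = np.zeros((n_cycles, n_off))
    for c in range(n_cycles):
        for k in range(1, n_off + 1):
            j = c - (k - 1)
            if 0 < j < n_cycles:
                offset[c, k - 1] = leavers[j]
    off = 1.0 - w_p - offset.sum(axis=1)
    off = np.where(np.abs(off) < 1e-12, 0.0, off)
    return PersistenceProfile(w_p, offset, off)


def effect_multiplier(hazard_ratio: float, stratum: str | int,
                      n_offset: int = 4) -> float:
    """Hazard multiplier for one persistence stratum.

    ``stratum`` is ``"persistent"``, ``"off"``, or an integer ``k`` in
    ``1..n_offset`` indexing the offset cycles after the last covered dose.
    The residual benefit declines linearly from full at the moment coverage
    ends to none two years later: stratum ``k`` spans the interval
    ``[(k-1), k)`` cycles since coverage ended and carries the benefit
    remaining at its start, so the multiplier first reaches 1 in the ``off``
    stratum, exactly ``n_offset`` cycles (2 years) after the last dose.
    """
    if stratum == "persistent":
        return hazard_ratio
    if stratum == "off":
        return 1.0
    if isinstance(stratum, int) and 1 <= stratum <= n_offset:
        return hazard_ratio + (1.0 - hazard_ratio) * (stratum - 1) / n_offset
    raise ValueError(f"unknown persistence stratum: {stratum!r}")


def arm_multiplier(fracture_type: str, cycle: int, arm: str,
                   persistence: PersistenceProfile | None,
                   params: ModelParameters) -> float:
    """Cycle-level hazard multiplier on the baseline fracture rate.

    Off-treatment: the single dose grants the full hazard ratio in cycle 0
    only.  Treatment: the weighted mean of the stratum multipliers under the
    cycle's persistence weights.
    """
    hr = params.effect.hazard_ratio(fracture_type)
    if arm == OFF_TREATMENT:
        return hr if cycle == 0 else 1.0
    if arm != TREATMENT:
        raise ValueError(f"unknown arm: {arm!r}")
    if persistence is None:
        raise ValueError("treatment arm needs a persistence profile")
    n_off = persistence.n_offset
    m = persistence.persistent[cycle] * hr
    for k in range(1, n_off + 1):
        m += persistence.offset[cycle, k - 1] * effect_multiplier(hr, k, n_off)
    m += persistence.off[cycle] * 1.0
    return m


def cycle_mortality(space: StateSpace, state: int | str, age: float) -> float:
    """Per-cycle probability of death in ``state`` at ``age``.

    The annual well-state probability is converted to a rate, scaled by the
    state's age-banded relative risk (1 outside the excess window), and
    converted back over one cycle.
    """
    if isinstance(state, str):
        state = space.index[state]
    p_annual = age_band_lookup(age, space.params.mortality.well_annual)
    band = space.mortality_band_index(age)
    rate = probability_to_rate(p_annual) * space.rr_by_band[state, band]
    return rate_to_probability(rate, space.cycle_length)


def _cycle_inputs(space: StateSpace, cycle: int, age: float, arm: str,
                  persistence: PersistenceProfile | None,
                  rate_scale: float = 1.0):
    """Per-cycle death vector and fracture entry probabilities."""
    params = space.params
    dt = space.cycle_length
    p_annual = age_band_lookup(age, params.mortality.well_annual)
    band = space.mortality_band_index(age)
    base_rate = probability_to_rate(p_annual)
    q = 1.0 - np.exp(-base_rate * space.rr_by_band[:, band] * dt)
    q[space.dead] = 0.0
    p_frac = {}
    for f in FRACTURE_TYPES:
        m = arm_multiplier(f, cycle, arm, persistence, params)
        rate = params.rates.rate(f)
        p_frac[f] = rate_to_probability(rate * rate_scale * m, dt)
    return q, p_frac


def build_transition_matrix(space: StateSpace, q: np.ndarray,
                            p_frac: dict[str, float]) -> np.ndarray:
    """One cycle's row-stochastic transition matrix.

    Competing risks are converted to per-cycle probabilities independently;
    the outflow is rescaled only in the (never reached at published
    magnitudes) case where it would exceed one.
    """
    S = space.n_states
    T = np.zeros((S, S))
    out = q.copy()
    extra = np.zeros(S)
    extra[space.well] = p_frac["hip"] + p_frac["vertebral"] + p_frac["other"]
    extra[space.can_hip] = p_frac["hip"]
    out = out + extra
    scale = np.where(out > 1.0, 1.0 / np.maximum(out, 1e-300), 1.0)
    qs = q * scale

    T[np.arange(S), space.dead] += qs
    # fracture entries: hip from well and every hip/vertebral state (severity
    # hierarchy), vertebral and "other" from well only
    T[space.well, space.vert_entry] += p_frac["vertebral"] * scale[space.well]
    T[space.well, space.other_entry] += p_frac["other"] * scale[space.well]
    idx = np.concatenate(([space.well], np.where(space.can_hip)[0]))
    T[idx, space.hip_entry] += p_frac["hip"] * scale[idx]
    # survivors advance along their track (well and terminals self-loop)
    stay = 1.0 - (q + extra) * scale
    T[np.arange(S), space.advance] += stay
    T[space.dead, :] = 0.0
    T[space.dead, space.dead] = 1.0
    return T


def build_transition_row(space: StateSpace, state: int | str, cycle: int,
                         age: float, arm: str,
                         persistence: PersistenceProfile | None = None
                         ) -> dict[str, float]:
    """A single state's transition probabilities as a label → probability map."""
    if isinstance(state, str):
        state = space.index[state]
    if arm == TREATMENT and persistence is None:
        persistence = persistence_profile(space.params.settings)
    q, p_frac = _cycle_inputs(space, cycle, age, arm, persistence)
    T = build_transition_matrix(space, q, p_frac)
    row = T[state]
    return {space.labels[j]: float(row[j]) for j in np.nonzero(row)[0]}


@dataclass
class CohortTrace:
    """A completed cohort run: occupancy, flows and effect modulation."""

    arm: str
    occupancy: np.ndarray          # (n_cycles + 1, n_states), cycle-start shares
    ages: np.ndarray               # (n_cycles,) age at each cycle start
    incident: np.ndarray           # (n_cycles, 3) entries into hip/vert/other year 1
    multipliers: np.ndarray        # (n_cycles, 3) effective hazard multipliers
    fracture_prob: np.ndarray      # (n_cycles, 3) per-cycle entry probabilities
    persistence: PersistenceProfile | None
    space: StateSpace

    @property
    def n_cycles(self) -> int:
        return self.incident.shape[0]

    @property
    def alive(self) -> np.ndarray:
        """Alive fraction at each cycle start (length n_cycles + 1)."""
        return 1.0 - self.occupancy[:, self.space.dead]


def run_cohort(params: ModelParameters, arm: str,
               age_rate_multiplier: dict[int, float] | None = None
               ) -> CohortTrace:
    """Run the cohort recursion from 100% well at the start age to the horizon.

    ``age_rate_multiplier`` optionally maps age-band lower bounds to relative
    fracture incidence (normalised to 1 at the start-age band), for the
    age-adjusted-rates scenario.
    """
    if arm not in ARMS:
        raise ValueError(f"arm must be one of {ARMS}")
    space = StateSpace(params)
    s = params.settings
    n = s.n_cycles
    pers = persistence_profile(s, n) if arm == TREATMENT else None

    start_scale = 1.0
    if age_rate_multiplier is not None:
        start_scale = age_band_lookup(s.start_age, age_rate_multiplier)

    occ = np.zeros((n + 1, space.n_states))
    occ[0, space.well] = 1.0
    ages = s.start_age + s.cycle_length * np.arange(n)
    incident = np.zeros((n, 3))
    mults = np.ones((n, 3))
    probs = np.zeros((n, 3))

    entries = (space.hip_entry, space.vert_entry, space.other_entry)
    for c in range(n):
        age = ages[c]
        rate_scale = 1.0
        if age_rate_multiplier is not None:
            rate_scale = age_band_lookup(age, age_rate_multiplier) / start_scale
        q, p_frac = _cycle_inputs(space, c, age, arm, pers, rate_scale)
        T = build_transition_matrix(space, q, p_frac)
        v = occ[c]
        occ[c + 1] = v @ T
        for j, f in enumerate(FRACTURE_TYPES):
            incident[c, j] = v @ T[:, entries[j]]
            mults[c, j] = arm_multiplier(f, c, arm, pers, params)
            probs[c, j] = p_frac[f]
    return CohortTrace(arm, occ, ages, incident, mults, probs, pers, space)


@dataclass
class ShadowEvents:
    """Correction-factor fractures hidden by the severity hierarchy.

    Occupants of hip states would, absent the hierarchy, still sustain
    vertebral and "other" fractures (and vertebral-state occupants "other"
    fractures).  These expected events are counted here, outside the chain,
    with their discounted cost, QALY decrement (including the QALY loss of
    the events' excess mortality) attributed to the cycle of occurrence.
    """

    events: np.ndarray            # (n_cycles, 3); hip column always zero
    cost: np.ndarray              # (n_cycles,) discounted USD
    qaly_loss: np.ndarray         # (n_cycles,) discounted QALYs
    excess_deaths: np.ndarray     # (n_cycles,) expected extra deaths

    @property
    def total_cost(self) -> float:
        return float(self.cost.sum())

    @property
    def total_qaly_loss(self) -> float:
        return float(self.qaly_loss.sum())


def correction_factor(trace: CohortTrace, params: ModelParameters) -> ShadowEvents:
    """Price the fractures the hierarchy overlooks.

    Per cycle: overlooked vertebral events arise from hip-state occupancy at
    the cycle's vertebral entry probability; overlooked "other" events from
    hip- plus vertebral-state occupancy at the "other" entry probability.
    Each event carries its first-year cost and utility decrement over the
    first year (two cycles), and, for vertebral events, subsequent-year cost
    and utility decrements over the occupants' remaining expected lifetime,
    using cohort survival from the trace; excess deaths (first-year mortality
    relative risk above one, floored at zero) are converted to a QALY loss via
    the discounted remaining QALY expectation of a well-state survivor.
    """
    from .economics import discount_factor  # deferred: avoids a cycle at import

    s = params.settings
    dt = s.cycle_length
    n = trace.n_cycles
    space = trace.space
    occ = trace.occupancy
    alive = trace.alive

    disc_c = np.array([discount_factor(c, s.discount_rate_costs, dt)
                       for c in range(n + 1)])
    disc_q = np.array([discount_factor(c, s.discount_rate_qalys, dt)
                       for c in range(n + 1)])
    ages_ext = s.start_age + dt * np.arange(n + 1)
    u_well = np.array([age_band_lookup(a, params.utilities.well_by_age)
                       for a in ages_ext])

    # reverse-cumulative discounted alive mass, for lifetime tails
    A_c = alive * disc_c                   # costs
    B_q = alive * disc_q * u_well          # utility-weighted
    revA = np.concatenate([np.cumsum(A_c[::-1])[::-1], [0.0, 0.0]])
    revB = np.concatenate([np.cumsum(B_q[::-1])[::-1], [0.0, 0.0]])

    hip_occ = occ[:n, space.hip_group].sum(axis=1)
    vert_occ = occ[:n, space.vert_group].sum(axis=1)

    events = np.zeros((n, 3))
    events[:, 1] = hip_occ * trace.fracture_prob[:, 1]               # vertebral
    events[:, 2] = (hip_occ + vert_occ) * trace.fracture_prob[:, 2]  # other

    cost = np.zeros(n)
    qaly_loss = np.zeros(n)
    excess_deaths = np.zeros(n)
    mult_first = {f: params.utilities.multiplier_first_year[f].value
                  for f in FRACTURE_TYPES}
    mult_sub_vert = params.utilities.multiplier_subsequent["vertebral"].value
    cost_sub_vert = params.costs.fracture_subsequent_annual["vertebral"]

    for c in range(n):
        age = ages_ext[c]
        a0 = alive[c]
        if a0 <= 0:
            continue
        # conditional survival to cycles c and c+1 given alive at c
        s0, s1 = 1.0, alive[c + 1] / a0
        for j, f in ((1, "vertebral"), (2, "other")):
            e = events[c, j]
            if e == 0.0:
                continue
            c_first = age_band_lookup(age, params.costs.fracture_first_year[f])
            first_cost = c_first * dt * (disc_c[c] * s0 + disc_c[c + 1] * s1)
            first_q = (1.0 - mult_first[f]) * dt * (
                u_well[c] * disc_q[c] * s0 + u_well[c + 1] * disc_q[c + 1] * s1)
            cost[c] += e * first_cost
            qaly_loss[c] += e * first_q
            if f == "vertebral":
                tail_cost = cost_sub_vert * dt * revA[c + 2] / a0
                tail_q = (1.0 - mult_sub_vert) * dt * revB[c + 2] / a0
                cost[c] += e * tail_cost
                qaly_loss[c] += e * tail_q
            # excess mortality of the overlooked event, floored at zero
            rr = age_band_lookup(age, params.mortality.rr_first_year[f])
            p_well = age_band_lookup(age, params.mortality.well_annual)
            ed = e * max(rr - 1.0, 0.0) * p_well
            excess_deaths[c] += ed
            qaly_loss[c] += ed * dt * revB[c + 1] / a0
    return ShadowEvents(events, cost, qaly_loss, excess_deaths)
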