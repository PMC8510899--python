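"""Probabilistic sensitivity analysis and the printed scenario analyses.

Every uncertain input is assigned a distribution family matched to its domain:
lognormal for ratios (hazard ratios, mortality relative risks), beta for
probabilities and utilities, gamma for costs and event rates.  Standard errors
come from printed 95% confidence intervals where available and are otherwise
assumed to be 10% of the mean.  Draws are independent across parameters; each
iteration re-runs the full two-arm model and records the incremental
cost/QALY pair, from which the cost-effectiveness acceptability curve (CEAC)
is built.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .economics import EconomicSummary
from .parameters import (
    ModelParameters,
    ParameterError,
    age_band_lookup,
    set_path,
)
from .run import evaluate

__all__ = [
    "ParameterDistribution",
    "PSAResult",
    "CEAC",
    "assign_distributions",
    "sample_parameters",
    "run_psa",
    "ceac",
    "net_monetary_benefit",
    "scenario_perfect_persistence",
    "scenario_age_adjusted_rates",
]

#: Width of a 95% CI in standard errors.
_Z95 = 2.0 * 1.959963984540054


@dataclass(frozen=True)
class ParameterDistribution:
    """A sampling distribution for one scalar model input.

    ``path`` addresses the input in the parameter dictionary (dotted);
    ``family`` is one of ``lognormal``, ``beta``, ``gamma``; ``mean``/``se``
    are on the natural scale except that lognormal distributions built from a
    CI carry ``sigma_log`` and are centred (median) on the point estimate.
    """

    path: str
    family: str
    mean: float
    se: float
    sigma_log: float | None = None

    def sample(self, rng: np.random.Generator) -> float:
        if self.se == 0.0:
            return self.mean
        if self.family == "lognormal":
            if self.sigma_log is not None:
                mu, sigma = math.log(self.mean), self.sigma_log
            else:
                # moment-matched on the natural scale
                sigma2 = math.log(1.0 + (self.se / self.mean) ** 2)
                mu = math.log(self.mean) - sigma2 / 2.0
                sigma = math.sqrt(sigma2)
            return float(rng.lognormal(mu, sigma))
        if self.family == "gamma":
            shape = (self.mean / self.se) ** 2
            scale = self.se ** 2 / self.mean
            return float(rng.gamma(shape, scale))
        if self.family == "beta":
            m, v = self.mean, self.se ** 2
            if v >= m * (1.0 - m):
                raise ParameterError(self.path,
                                     "beta SE too large for mean")
            nu = m * (1.0 - m) / v - 1.0
            return float(rng.beta(m * nu, (1.0 - m) * nu))
        raise ParameterError(self.path, f"unknown family '{self.family}'")


def _ci_se(low: float, high: float) -> float:
    return (high - low) / _Z95


def _ci_sigma_log(low: float, high: float) -> float:
    return (math.log(high) - math.log(low)) / _Z95


def assign_distributions(params: ModelParameters,
                         default_cv: float = 0.1) -> list[ParameterDistribution]:
    """Distributions for every uncertain input in the parameter set.

    CI-derived standard errors where the input prints one (hazard ratios,
    baseline rates, utility multipliers); ``default_cv`` × mean otherwise
    (well-state mortality, mortality relative risks, all costs, well-state
    utilities).  Structural settings (discontinuation, discounting, offset)
    are not sampled.
    """
    dists: list[ParameterDistribution] = []
    eff = params.effect
    for name, est in (("hr_hip", eff.hr_hip),
                      ("hr_vertebral", eff.hr_vertebral),
                      ("hr_nonvertebral", eff.hr_nonvertebral)):
        dists.append(ParameterDistribution(
            f"effect.{name}", "lognormal", est.value,
            se=1.0,  # unused when sigma_log given
            sigma_log=_ci_sigma_log(est.ci_low, est.ci_high)))
    for name in ("hip", "vertebral", "other"):
        est = getattr(params.rates, name)
        dists.append(ParameterDistribution(
            f"rates.{name}", "gamma", est.value,
            se=_ci_se(est.ci_low, est.ci_high)))
    for band, p in params.mortality.well_annual.items():
        dists.append(ParameterDistribution(
            f"mortality.well_annual.{band}", "beta", p, se=default_cv * p))
    for f, tab in params.mortality.rr_first_year.items():
        for band, rr in tab.items():
            dists.append(ParameterDistribution(
                f"mortality.rr_first_year.{f}.{band}", "lognormal", rr,
                se=default_cv * rr))
    for f, tab in params.mortality.rr_subsequent.items():
        for band, rr in tab.items():
            dists.append(ParameterDistribution(
                f"mortality.rr_subsequent.{f}.{band}", "lognormal", rr,
                se=default_cv * rr))
    for f, tab in params.costs.fracture_first_year.items():
        for band, c in tab.items():
            dists.append(ParameterDistribution(
                f"costs.fracture_first_year.{f}.{band}", "gamma", c,
                se=default_cv * c))
    for f, c in params.costs.fracture_subsequent_annual.items():
        dists.append(ParameterDistribution(
            f"costs.fracture_subsequent_annual.{f}", "gamma", c,
            se=default_cv * c))
    for name in ("drug_annual", "visit_routine", "visit_nurse", "dxa_scan"):
        c = getattr(params.costs, name)
        dists.append(ParameterDistribution(
            f"costs.{name}", "gamma", c, se=default_cv * c))
    for band, u in params.utilities.well_by_age.items():
        dists.append(ParameterDistribution(
            f"utilities.well_by_age.{band}", "beta", u, se=default_cv * u))
    for f, est in params.utilities.multiplier_first_year.items():
        dists.append(ParameterDistribution(
            f"utilities.multiplier_first_year.{f}", "beta", est.value,
            se=_ci_se(est.ci_low, est.ci_high)))
    for f, est in params.utilities.multiplier_subsequent.items():
        dists.append(ParameterDistribution(
            f"utilities.multiplier_subsequent.{f}", "beta", est.value,
            se=_ci_se(est.ci_low, est.ci_high)))
    return dists


def sample_parameters(distributions: list[ParameterDistribution],
                      rng: np.random.Generator,
                      base: ModelParameters) -> ModelParameters:
    """One coherent joint draw, validated, CIs dropped on sampled leaves."""
    d = base.to_dict()
    for dist in distributions:
        set_path(d, dist.path, dist.sample(rng))
    return ModelParameters.from_dict(d)


@dataclass(frozen=True)
class PSAResult:
    """Per-iteration incremental cost/QALY pairs from the PSA."""

    incremental_cost: np.ndarray
    incremental_qalys: np.ndarray
    seed: int
    n_iterations: int

    def probability_cost_effective(self, wtp: float) -> float:
        """Fraction of iterations with positive net monetary benefit at ``wtp``."""
        nmb = wtp * self.incremental_qalys - self.incremental_cost
        return float(np.mean(nmb > 0.0))


def run_psa(params: ModelParameters, n: int | None = None,
            seed: int | None = None) -> PSAResult:
    """``n`` full two-arm evaluations on jointly sampled parameter sets."""
    if n is None:
        n = params.settings.psa_iterations
    if seed is None:
        seed = params.settings.rng_seed
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    dists = assign_distributions(params)
    dc = np.empty(n)
    dq = np.empty(n)
    for i in range(n):
        drawn = sample_parameters(dists, rng, params)
        res = evaluate(drawn)
        dc[i] = res.incremental_cost
        dq[i] = res.incremental_qalys
    return PSAResult(dc, dq, seed, n)


@dataclass(frozen=True)
class CEAC:
    """Probability that continued treatment is cost-effective, by threshold."""

    thresholds: np.ndarray
    probability: np.ndarray


def net_monetary_benefit(dcost: float, dqaly: float, wtp: float) -> float:
    return wtp * dqaly - dcost


def ceac(psa: PSAResult, thresholds: np.ndarray | None = None) -> CEAC:
    """CEAC over a willingness-to-pay grid (default 0–60,000 USD by 1,000)."""
    if thresholds is None:
        thresholds = np.arange(0.0, 60001.0, 1000.0)
    thresholds = np.asarray(thresholds, dtype=float)
    if psa.n_iterations < 1:
        raise ValueError("empty PSA result")
    nmb = (thresholds[:, None] * psa.incremental_qalys[None, :]
           - psa.incremental_cost[None, :])
    prob = (nmb > 0.0).mean(axis=1)
    return CEAC(thresholds, prob)


def scenario_perfect_persistence(params: ModelParameters) -> EconomicSummary:
    """Full persistence: no discontinuation during the 5-year course.

    All treatment-arm patients complete the course and then pass through the
    2-year effect-offset period.
    """
    d = params.replace_value("settings.annual_discontinuation_rate", 0.0)
    return evaluate(ModelParameters.from_dict(d))


def scenario_age_adjusted_rates(params: ModelParameters,
                                multipliers: dict[int, float]
                                ) -> EconomicSummary:
    """Fracture rates scaled by age-band relative incidence as the cohort ages.

    ``multipliers`` maps age-band lower bounds to relative fracture incidence;
    they are renormalised so that the start-age band equals one, which keeps
    the starting rates at their base-case values.
    """
    for band, m in multipliers.items():
        if m <= 0:
            raise ParameterError(f"age_rate_multiplier.{band}", "must be > 0")
    # will raise if the start age has no band
    age_band_lookup(params.settings.start_age, multipliers)
    return evaluate(params, age_rate_multiplier=multipliers)
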