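"""Second-order probabilistic sensitivity analysis.

Each iteration draws one parameter set from the uncertainty distributions
(gamma for costs, beta for probabilities and utilities, Dirichlet for
transition-matrix rows, log-normal for relative risks), simulates the full
cohort through both arms under common random numbers, and records the
cohort-level incremental cost and QALYs.  Parameter uncertainty — not
patient-level noise — is the only thing that varies between iterations:
the patient-level random streams are held fixed, so the scatter of the
cost-utility plane isolates second-order uncertainty.

Distribution constructors work from exactly the moments a published table
provides: mean/SD for gamma, point estimate with 95% CI for log-normal and
beta, row probabilities with an effective sample size for Dirichlet, and a
maximum-likelihood negative-binomial fit for raw utilization counts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .cohort import Cohort
from .economics import net_monetary_benefit
from .engine import _param_arrays, _patient_arrays, _simulate_paths, \
    cohort_draws
from .parameters import ModelParameters

__all__ = [
    "DistributionSpec",
    "PsaIteration",
    "PsaResult",
    "gamma_from_moments",
    "lognormal_from_ci",
    "beta_from_point_range",
    "dirichlet_row",
    "fit_negbin_mle",
    "build_default_specs",
    "sample_parameters",
    "run_psa",
    "ceac",
]

_Z95 = 1.959964  # two-sided 95% normal quantile


@dataclass
class DistributionSpec:
    """One parameter's sampling distribution."""

    family: str  # gamma | beta | dirichlet | lognormal | negbin | fixed
    parameters: dict = field(default_factory=dict)
    provenance: str = ""

    def sample(self, rng: np.random.Generator, size=None):
        p = self.parameters
        if self.family == "fixed":
            value = p["value"]
            if size is None:
                return value
            return np.full(size, value, dtype=float)
        if self.family == "gamma":
            return rng.gamma(p["shape"], p["scale"], size=size)
        if self.family == "beta":
            return rng.beta(p["alpha"], p["beta"], size=size)
        if self.family == "lognormal":
            return rng.lognormal(p["mu"], p["sigma"], size=size)
        if self.family == "dirichlet":
            conc = np.asarray(p["concentrations"], dtype=float)
            return rng.dirichlet(conc, size=size)
        if self.family == "negbin":
            size_p, mean = p["size"], p["mean"]
            prob = size_p / (size_p + mean)
            return rng.negative_binomial(size_p, prob, size=size)
        raise ValueError(f"unknown family: {self.family}")

    def mean(self) -> float | np.ndarray:
        p = self.parameters
        if self.family == "fixed":
            return p["value"]
        if self.family == "gamma":
            return p["shape"] * p["scale"]
        if self.family == "beta":
            return p["alpha"] / (p["alpha"] + p["beta"])
        if self.family == "lognormal":
            return math.exp(p["mu"] + p["sigma"] ** 2 / 2)
        if self.family == "dirichlet":
            c = np.asarray(p["concentrations"], dtype=float)
            return c / c.sum()
        if self.family == "negbin":
            return p["mean"]
        raise ValueError(f"unknown family: {self.family}")


def gamma_from_moments(mean: float, sd: float,
                       provenance: str = "") -> DistributionSpec:
    """Method-of-moments gamma: shape = mean^2/sd^2, scale = sd^2/mean."""
    if mean <= 0 or sd <= 0:
        raise ValueError("gamma moments must be positive")
    return DistributionSpec(
        family="gamma",
        parameters={"shape": mean ** 2 / sd ** 2, "scale": sd ** 2 / mean},
        provenance=provenance or f"gamma from mean={mean}, sd={sd}")


def lognormal_from_ci(point: float, lower: float, upper: float,
                      provenance: str = "") -> DistributionSpec:
    """Log-normal with median at the point estimate and sigma from the
    width of the 95% CI on the log scale."""
    if not (0 < lower <= point <= upper):
        raise ValueError("need 0 < lower <= point <= upper")
    sigma = (math.log(upper) - math.log(lower)) / (2 * _Z95)
    return DistributionSpec(
        family="lognormal",
        parameters={"mu": math.log(point), "sigma": sigma},
        provenance=provenance or f"lognormal from {point} ({lower}-{upper})")


def beta_from_point_range(point: float, lower: float, upper: float,
                          provenance: str = "") -> DistributionSpec:
    """Beta with mean at the point estimate and SD from the printed range
    treated as a 95% interval width.

    Printed ranges sometimes pin one endpoint at the point estimate; the
    width is used as-is.  A zero-width range degenerates to a fixed value.
    """
    if not (0.0 <= point <= 1.0):
        raise ValueError("point must be in [0, 1]")
    lo, hi = min(lower, upper), max(lower, upper)
    if not (0.0 <= lo and hi <= 1.0):
        raise ValueError("range must lie in [0, 1]")
    sd = (hi - lo) / (2 * _Z95)
    if sd == 0.0 or point in (0.0, 1.0):
        return DistributionSpec(family="fixed",
                                parameters={"value": point},
                                provenance=provenance or "degenerate range")
    var = sd ** 2
    max_var = point * (1 - point)
    if var >= max_var:
        var = 0.999 * max_var
    nu = point * (1 - point) / var - 1.0
    return DistributionSpec(
        family="beta",
        parameters={"alpha": point * nu, "beta": (1 - point) * nu},
        provenance=provenance or f"beta from {point} ({lower}-{upper})")


def dirichlet_row(row, concentration_n: float,
                  provenance: str = "") -> DistributionSpec:
    """Dirichlet over a transition-matrix row with the given effective
    sample size; zero cells are floored at a small epsilon."""
    row = np.asarray(row, dtype=float)
    if concentration_n <= 0:
        raise ValueError("concentration must be positive")
    if np.any(row < 0) or abs(row.sum() - 1.0) > 1e-9:
        raise ValueError("row must be a probability vector summing to 1")
    conc = np.maximum(row * concentration_n, 1e-6)
    return DistributionSpec(
        family="dirichlet", parameters={"concentrations": conc.tolist()},
        provenance=provenance or f"dirichlet n={concentration_n}")


def fit_negbin_mle(counts) -> DistributionSpec:
    """Maximum-likelihood negative binomial (size/mean parameterization)
    for overdispersed utilization counts.

    The mean MLE equals the sample mean; the dispersion (size) is profiled
    by 1-D likelihood maximization.  Equal counts (no overdispersion signal)
    fall back to Poisson with a warning.
    """
    x = np.asarray(counts)
    if x.size < 2:
        raise ValueError("need at least two observations")
    if np.any(x < 0) or not np.all(np.equal(np.mod(x, 1), 0)):
        raise ValueError("counts must be nonnegative integers")
    if not np.any(x > 0):
        raise ValueError("all-zero counts are degenerate")
    mean = float(x.mean())
    if np.all(x == x[0]) or float(x.var()) <= mean:
        warnings.warn("no overdispersion; falling back to a Poisson "
                      "(infinite size)", stacklevel=2)
        return DistributionSpec(
            family="negbin",
            parameters={"mean": mean, "size": float("inf"),
                        "loglik": float(np.sum(stats.poisson.logpmf(x, mean)))},
            provenance="poisson fallback (equidispersed counts)")

    def nll(log_size: float) -> float:
        size = math.exp(log_size)
        prob = size / (size + mean)
        return -float(np.sum(stats.nbinom.logpmf(x, size, prob)))

    res = minimize_scalar(nll, bounds=(-10.0, 10.0), method="bounded")
    size = math.exp(res.x)
    return DistributionSpec(
        family="negbin",
        parameters={"mean": mean, "size": size, "loglik": -float(res.fun)},
        provenance=f"negbin MLE on n={x.size} counts")


# ----------------------------------------------------------------------
# parameter-set sampling

def build_default_specs(params: ModelParameters) -> dict[str, DistributionSpec]:
    """Distribution specs for every non-fixed model parameter.

    State-cost components are varied through unit-cost uncertainty
    (multiplicative gamma factors), keeping the reference component means
    canonical while utilization stays at its observed medians.
    """
    specs: dict[str, DistributionSpec] = {}
    specs["hosp_cost_mean"] = gamma_from_moments(
        params.hosp_cost_mean, params.hosp_cost_sd, "hospitalization cost")
    for i in range(4):
        lo, hi = params.utility_ranges[i]
        specs[f"utility_{i}"] = beta_from_point_range(
            params.utilities_by_class[i], lo, hi, f"utility class {i + 1}")
        plo, phi = params.hosp_prob_ranges[i]
        specs[f"hosp_prob_{i}"] = beta_from_point_range(
            params.hosp_prob_monthly[i], plo, phi,
            f"hospitalization probability class {i + 1}")
        specs[f"transition_row_{i}"] = dirichlet_row(
            params.nyha_transition_matrix[i], params.dirichlet_concentration,
            f"transition row class {i + 1}")
    specs["readmit_prob_30d"] = beta_from_point_range(
        params.readmit_prob_30d, *params.readmit_prob_ci,
        provenance="30-day readmission")
    specs["hosp_disutility"] = beta_from_point_range(
        params.hosp_disutility, *params.hosp_disutility_ci,
        provenance="hospitalization disutility")
    specs["rr_mortality"] = lognormal_from_ci(
        params.rr_mortality, *params.rr_mortality_ci,
        provenance="mortality relative risk")
    specs["rr_hospitalization"] = lognormal_from_ci(
        params.rr_hospitalization, *params.rr_hospitalization_ci,
        provenance="hospitalization relative risk")
    # multiplicative unit-cost factors (mean 1) for the cost components
    for svc in ("ed", "outpatient"):
        uc = params.unit_costs[svc]
        if uc["sd"] > 0:
            specs[f"unit_cost_factor_{svc}"] = gamma_from_moments(
                1.0, uc["sd"] / uc["mean"], f"{svc} unit cost factor")
    drug = params.unit_costs["drug_6mo"]
    specs["unit_cost_factor_drug"] = gamma_from_moments(
        1.0, drug["sd"] / drug["mean"], "drug cost factor")
    return specs


def sample_parameters(params: ModelParameters,
                      specs: dict[str, DistributionSpec],
                      rng: np.random.Generator) -> ModelParameters:
    """Draw one complete parameter set; unknown-field specs raise."""
    known_dynamic = {"hosp_cost_mean", "readmit_prob_30d", "hosp_disutility",
                     "rr_mortality", "rr_hospitalization"}
    for name in specs:
        if (name not in known_dynamic
                and not name.startswith(("utility_", "hosp_prob_",
                                         "transition_row_",
                                         "unit_cost_factor_"))
                and not hasattr(params, name)):
            raise KeyError(f"spec does not match any parameter field: {name}")

    out = params.copy()

    def clamp01(x):
        return float(np.clip(x, 0.0, 1.0))

    for name in ("hosp_cost_mean", "readmit_prob_30d", "hosp_disutility",
                 "rr_mortality", "rr_hospitalization"):
        if name in specs:
            value = float(specs[name].sample(rng))
            if name in ("readmit_prob_30d", "hosp_disutility"):
                value = clamp01(value)
            setattr(out, name, value)

    for i in range(4):
        if f"utility_{i}" in specs:
            out.utilities_by_class[i] = clamp01(
                specs[f"utility_{i}"].sample(rng))
        if f"hosp_prob_{i}" in specs:
            out.hosp_prob_monthly[i] = clamp01(
                specs[f"hosp_prob_{i}"].sample(rng))
        if f"transition_row_{i}" in specs:
            row = np.asarray(specs[f"transition_row_{i}"].sample(rng))
            out.nyha_transition_matrix[i] = (row / row.sum()).tolist()

    factors = {}
    for svc in ("ed", "outpatient", "drug"):
        key = f"unit_cost_factor_{svc}"
        factors[svc] = (float(specs[key].sample(rng))
                        if key in specs else 1.0)
    for svc in ("ed", "outpatient", "drug"):
        out.state_cost_components[svc] = [
            c * factors[svc] for c in out.state_cost_components[svc]]
    return out


# ----------------------------------------------------------------------
# running the PSA

@dataclass
class PsaIteration:
    """Cohort-level increments for one sampled parameter set."""

    index: int
    delta_cost: float
    delta_qaly: float

    @property
    def quadrant(self) -> str:
        if self.delta_qaly > 0:
            return ("costlier_more_effective" if self.delta_cost >= 0
                    else "cheaper_more_effective")
        if self.delta_qaly < 0:
            return ("costlier_less_effective" if self.delta_cost > 0
                    else "cheaper_less_effective")
        return "equal_effectiveness"


@dataclass
class PsaResult:
    iterations: list = field(default_factory=list)
    seed: int | None = None
    wtp_grid: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.iterations)

    @property
    def delta_cost(self) -> np.ndarray:
        return np.array([it.delta_cost for it in self.iterations])

    @property
    def delta_qaly(self) -> np.ndarray:
        return np.array([it.delta_qaly for it in self.iterations])

    def quadrant_proportions(self) -> dict[str, float]:
        n = len(self.iterations)
        tally: dict[str, float] = {}
        for it in self.iterations:
            tally[it.quadrant] = tally.get(it.quadrant, 0) + 1
        return {k: v / n for k, v in tally.items()}

    def ceac(self, wtp_grid=None) -> pd.DataFrame:
        grid = wtp_grid if wtp_grid is not None else self.wtp_grid
        return ceac(self.iterations, grid)

    def acceptance_at(self, wtp: float) -> float:
        nmb = wtp * self.delta_qaly - self.delta_cost
        return float(np.mean(nmb > 0))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "iteration": [it.index for it in self.iterations],
            "delta_cost": self.delta_cost,
            "delta_qaly": self.delta_qaly,
            "quadrant": [it.quadrant for it in self.iterations],
        })


def run_psa(cohort: Cohort, params: ModelParameters,
            n_iterations: int | None = None, seed: int = 0,
            specs: dict[str, DistributionSpec] | None = None) -> PsaResult:
    """Sample ``n_iterations`` parameter sets and simulate the full cohort
    under each, with patient-level random streams held fixed.

    The paired-arm simulation for all iterations runs through the
    vectorized engine in one pass.
    """
    if n_iterations is None:
        n_iterations = params.psa_iterations
    if n_iterations < 1:
        raise ValueError("need at least one iteration")
    if specs is None:
        specs = build_default_specs(params)

    rng = np.random.default_rng(seed)
    sampled = [sample_parameters(params, specs, rng)
               for _ in range(n_iterations)]

    cohort = _ensure_kits(cohort, params, seed)
    draws = cohort_draws(len(cohort), params.horizon_months, seed)
    pat = _patient_arrays(cohort, params)
    par = _param_arrays(sampled)

    cost_s, qaly_s, _, _ = _simulate_paths(pat, par, draws, medly=False,
                                           base=params)
    cost_m, qaly_m, _, _ = _simulate_paths(pat, par, draws, medly=True,
                                           base=params)
    dc = cost_m.mean(axis=1) - cost_s.mean(axis=1)
    dq = qaly_m.mean(axis=1) - qaly_s.mean(axis=1)
    iterations = [PsaIteration(index=i, delta_cost=float(dc[i]),
                               delta_qaly=float(dq[i]))
                  for i in range(n_iterations)]
    return PsaResult(iterations=iterations, seed=seed,
                     wtp_grid=list(params.wtp_grid))


def _ensure_kits(cohort: Cohort, params: ModelParameters,
                 seed: int) -> Cohort:
    if cohort.data["kit_type"].isna().any():
        from .scenarios import assign_deployment
        return assign_deployment(cohort, params.deployment_ratio, seed)
    return cohort


def ceac(iterations, wtp_grid) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve: at each willingness-to-pay,
    the fraction of iterations with positive net monetary benefit."""
    if len(iterations) == 0:
        raise ValueError("no iterations")
    dc = np.array([it.delta_cost for it in iterations])
    dq = np.array([it.delta_qaly for it in iterations])
    grid = np.asarray(list(wtp_grid), dtype=float)
    if np.any(grid < 0):
        raise ValueError("willingness-to-pay must be nonnegative")
    probs = [float(np.mean([net_monetary_benefit(c, q, w) > 0
                            for c, q in zip(dc, dq)]))
             for w in grid]
    return pd.DataFrame({"wtp": grid, "probability": probs})
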