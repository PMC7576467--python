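"""Seven-state monthly microsimulation of heart-failure progression.

States: four community states (NYHA I-IV), two hospital states (index
admission and readmission), and absorbing death.  Cycles are one month with
no half-cycle correction.  Within a cycle events resolve in a fixed order:

1. death — survival-score monthly probability in community states (scaled
   by the mortality relative risk in the telemonitoring arm), a fixed
   monthly in-hospital probability in hospital states;
2. discharge — a surviving hospitalized patient returns to the NYHA class
   held at admission;
3. (re)admission — patients with a hospitalization history face the 30-day
   readmission probability (persistently, by default: hospitalization marks
   a lasting change in disease trajectory and hospital-to-hospital chains
   are allowed); never-hospitalized patients face their class-specific
   monthly admission probability, scaled by the hospitalization relative
   risk in the telemonitoring arm;
4. NYHA transition — community patients who were not hospitalized in the
   previous cycle and were not admitted move by the monthly transition
   matrix;
5. accrual — class utility (minus the hospitalization disutility for
   hospital cycles) and state or admission costs, discounted to baseline.

Both arms of one patient share a common random-number stream, so a null
intervention reproduces the comparator trajectory exactly.  A per-patient
reference implementation (``step_patient``/``simulate_patient``) and a
vectorized cohort engine (``simulate_cohort``) implement identical
semantics; tests cross-validate them path by path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort, PatientProfile
from .economics import (amortized_fixed_cost, medly_monthly_cost,
                        monthly_state_cost)
from .parameters import ModelParameters
from .survival import (SurvivalModel, annual_hazard, cohort_hazards,
                       linear_predictor, monthly_death_probability)

__all__ = [
    "HealthState",
    "SimState",
    "ArmResult",
    "CohortResults",
    "discount_factor",
    "step_patient",
    "simulate_patient",
    "simulate_cohort",
    "N_DRAWS_PER_CYCLE",
]

#: uniform draws consumed per cycle: death, (re)admission, NYHA transition
N_DRAWS_PER_CYCLE = 3

ARMS = ("standard", "medly")


class HealthState(Enum):
    NYHA1 = 1
    NYHA2 = 2
    NYHA3 = 3
    NYHA4 = 4
    HOSP_INDEX = 5
    HOSP_READMIT = 6
    DEAD = 7

    @property
    def is_hospital(self) -> bool:
        return self in (HealthState.HOSP_INDEX, HealthState.HOSP_READMIT)


_COMMUNITY = {1: HealthState.NYHA1, 2: HealthState.NYHA2,
              3: HealthState.NYHA3, 4: HealthState.NYHA4}


@dataclass
class SimState:
    """Mutable per-patient state between cycles."""

    current: HealthState
    resident_nyha: int
    current_age: float
    alive: bool = True
    months_since_discharge: int | None = None
    ever_hospitalized: bool = False


@dataclass
class ArmResult:
    """Discounted accumulators for one patient in one arm."""

    arm: str
    discounted_cost: float = 0.0
    discounted_qaly: float = 0.0
    life_months: int = 0
    admissions: int = 0


def discount_factor(month: int, annual_rate: float) -> float:
    """(1 + r)^(-month/12), evaluated at cycle start (no half-cycle
    correction)."""
    if month < 0:
        raise ValueError("month must be nonnegative")
    if annual_rate < 0:
        raise ValueError("rate must be nonnegative")
    return float((1.0 + annual_rate) ** (-month / 12.0))


def _clamped(p: float | np.ndarray, label: str):
    over = np.any(np.asarray(p) > 1.0)
    if over:
        warnings.warn(f"{label} exceeded 1 after relative-risk scaling; "
                      "clamped", stacklevel=3)
    return np.minimum(p, 1.0)


# ----------------------------------------------------------------------
# per-patient reference implementation

def step_patient(state: SimState, profile: PatientProfile,
                 params: ModelParameters, arm: str,
                 draws: Sequence[float],
                 hazard_annual: float | None = None,
                 ) -> tuple[SimState, float, float]:
    """Advance one patient one cycle; returns (next state, undiscounted
    cycle cost, undiscounted cycle utility).

    ``draws`` must supply ``N_DRAWS_PER_CYCLE`` uniforms; all are consumed
    every cycle so that paired arms stay on a common random-number stream.
    """
    if not state.alive or state.current is HealthState.DEAD:
        raise ValueError("dead patients are not stepped")
    if len(draws) < N_DRAWS_PER_CYCLE:
        raise ValueError("insufficient random draws for this cycle")
    if arm not in ARMS:
        raise ValueError(f"unknown arm: {arm}")
    medly = arm == "medly"

    if hazard_annual is None:
        model = SurvivalModel.from_params(params)
        hazard_annual = annual_hazard(linear_predictor(profile, model), model)

    in_hosp = state.current.is_hospital
    rr_m = params.rr_mortality if medly else 1.0
    p_death = (params.inhospital_mortality_monthly if in_hosp
               else monthly_death_probability(hazard_annual, rr_m))
    if draws[0] < p_death:
        return (SimState(current=HealthState.DEAD,
                         resident_nyha=state.resident_nyha,
                         current_age=state.current_age, alive=False,
                         months_since_discharge=None,
                         ever_hospitalized=state.ever_hospitalized),
                0.0, 0.0)

    was_hosp = in_hosp
    cls = state.resident_nyha
    rr_h = params.rr_hospitalization if medly else 1.0
    persistent = params.readmission_scope == "persistent"

    if persistent:
        eligible = True
        at_risk_readmit = state.ever_hospitalized
    else:
        eligible = not was_hosp
        at_risk_readmit = (state.months_since_discharge == 0
                           and not was_hosp)

    if at_risk_readmit:
        rr_re = rr_h if params.rr_applies_to_readmission else 1.0
        p_adm = _clamped(params.readmit_prob_30d * rr_re,
                         "readmission probability")
    else:
        p_adm = _clamped(params.hosp_prob_monthly[cls - 1] * rr_h,
                         "hospitalization probability")
    admitted = eligible and draws[1] < p_adm

    if admitted:
        next_state = (HealthState.HOSP_READMIT if state.ever_hospitalized
                      else HealthState.HOSP_INDEX)
    else:
        if not was_hosp:
            cum = np.cumsum(params.nyha_transition_matrix[cls - 1])
            cls = 1 + int(np.sum(draws[2] > cum[:3]))
        next_state = _COMMUNITY[cls]

    in_hosp_now = admitted
    util = params.utilities_by_class[cls - 1]
    if in_hosp_now:
        cost = params.hosp_cost_mean
        util -= params.hosp_disutility
    else:
        cost = monthly_state_cost(cls, state.current_age, params).total
    if medly:
        kit = profile.kit_type or "FK"
        cost += medly_monthly_cost(kit, params)

    if in_hosp_now:
        msd = None
    elif was_hosp:
        msd = 0
    elif state.months_since_discharge is not None:
        msd = state.months_since_discharge + 1
    else:
        msd = None

    return (SimState(current=next_state, resident_nyha=cls,
                     current_age=state.current_age + 1.0 / 12.0,
                     alive=True, months_since_discharge=msd,
                     ever_hospitalized=state.ever_hospitalized or admitted),
            float(cost), float(util))


def simulate_patient(profile: PatientProfile, params: ModelParameters,
                     arm: str, seed: int | None = None,
                     draws: np.ndarray | None = None) -> ArmResult:
    """Run one patient through the model until death or the horizon.

    ``draws`` (shape ``(horizon_months, 3)``) may be supplied directly to
    share a common random-number stream between arms; otherwise they are
    generated from ``seed``.
    """
    if params.horizon_months < 1:
        raise ValueError("horizon must be at least one cycle")
    if draws is None:
        rng = np.random.default_rng(seed)
        draws = rng.random((params.horizon_months, N_DRAWS_PER_CYCLE))
    if draws.shape[0] < params.horizon_months:
        raise ValueError("insufficient random draws for the horizon")

    model = SurvivalModel.from_params(params)
    hazard = annual_hazard(linear_predictor(profile, model), model)

    result = ArmResult(arm=arm)
    if arm == "medly":
        result.discounted_cost += amortized_fixed_cost(params)

    state = SimState(current=_COMMUNITY[profile.nyha_class],
                     resident_nyha=profile.nyha_class,
                     current_age=profile.age)
    for t in range(params.horizon_months):
        prev_hosp = state.current.is_hospital
        state, cost, util = step_patient(state, profile, params, arm,
                                         draws[t], hazard_annual=hazard)
        if not state.alive:
            break
        df = discount_factor(t, params.discount_rate_annual)
        result.discounted_cost += df * cost
        result.discounted_qaly += df * util / 12.0
        result.life_months += 1
        # every hospital cycle is entered through an admission event
        if state.current.is_hospital:
            result.admissions += 1
    return result


# ----------------------------------------------------------------------
# vectorized cohort engine

def _patient_arrays(cohort: Cohort, params: ModelParameters):
    df = cohort.data
    model = SurvivalModel.from_params(params)
    hazards = cohort_hazards(cohort, model)
    kit_cost = np.zeros(len(df))
    kits = df["kit_type"] if "kit_type" in df.columns else None
    for i, kit in enumerate(kits if kits is not None else []):
        kit_cost[i] = medly_monthly_cost(
            kit if isinstance(kit, str) else "FK", params)
    return {
        "hazard": hazards,
        "age0": df["age"].to_numpy(dtype=float),
        "cls0": df["nyha_class"].to_numpy(dtype=np.int64),
        "medly_monthly": kit_cost,
    }


def _param_arrays(param_list: Sequence[ModelParameters]):
    """Stack per-iteration parameters into lookup tables."""
    util = np.array([p.utilities_by_class for p in param_list])
    comp = [p.state_cost_components for p in param_list]
    nondrug = np.array([[c["ed"][i] + c["gp"][i] + c["outpatient"][i]
                         for i in range(4)] for c in comp])
    drug = np.array([[c["drug"][i] for i in range(4)] for c in comp])
    hosp_p = np.array([p.hosp_prob_monthly for p in param_list])
    trans_cum = np.array([np.cumsum(p.nyha_transition_matrix, axis=1)
                          for p in param_list])[:, :, :3]
    return {
        "util": util, "nondrug": nondrug, "drug": drug, "hosp_p": hosp_p,
        "trans_cum": trans_cum,
        "readmit": np.array([p.readmit_prob_30d for p in param_list]),
        "disutil": np.array([p.hosp_disutility for p in param_list]),
        "hosp_cost": np.array([p.hosp_cost_mean for p in param_list]),
        "rr_m": np.array([p.rr_mortality for p in param_list]),
        "rr_h": np.array([p.rr_hospitalization for p in param_list]),
        "p_ih": np.array([p.inhospital_mortality_monthly
                          for p in param_list]),
        "op_monthly": np.array([p.medly_operational_monthly
                                for p in param_list]),
    }


def _simulate_paths(pat: dict, par: dict, draws: np.ndarray, medly: bool,
                    base: ModelParameters):
    """Vectorized core over (iterations x patients).

    ``draws`` has shape ``(n_pat, horizon, 3)`` and is shared across arms
    and iterations (common random numbers).  Returns arrays of shape
    ``(n_iter, n_pat)``: discounted cost, discounted QALY, life months and
    admission counts.
    """
    n_iter = par["util"].shape[0]
    n_pat = pat["hazard"].size
    horizon = int(base.horizon_months)
    persistent = base.readmission_scope == "persistent"
    rr_on_re = bool(base.rr_applies_to_readmission)
    rate = float(base.discount_rate_annual)
    age_thr = float(base.drug_age_threshold)

    rr_m = par["rr_m"][:, None] if medly else 1.0
    rr_h = par["rr_h"][:, None] if medly else 1.0
    p_die_comm = 1.0 - np.exp(-pat["hazard"][None, :] * rr_m / 12.0)
    p_ih = np.broadcast_to(par["p_ih"][:, None], (n_iter, n_pat))
    p_re = par["readmit"][:, None] * (rr_h if (rr_on_re and medly) else 1.0)
    p_re = _clamped(np.broadcast_to(p_re, (n_iter, n_pat)),
                    "readmission probability")

    it4 = (np.arange(n_iter) * 4)[:, None]
    hosp_p_flat = par["hosp_p"].reshape(-1)
    util_flat = par["util"].reshape(-1)
    nondrug_flat = par["nondrug"].reshape(-1)
    drug_flat = par["drug"].reshape(-1)
    tc_flat = [np.ascontiguousarray(par["trans_cum"][:, :, k]).reshape(-1)
               for k in range(3)]
    hosp_cost = par["hosp_cost"][:, None]
    disutil = par["disutil"][:, None]

    # per-patient program cost already includes the operational component
    medly_monthly = pat["medly_monthly"][None, :] if medly else 0.0

    alive = np.ones((n_iter, n_pat), dtype=bool)
    in_hosp = np.zeros((n_iter, n_pat), dtype=bool)
    post = np.zeros((n_iter, n_pat), dtype=bool)
    msd0 = np.zeros((n_iter, n_pat), dtype=bool)
    cls = np.broadcast_to(pat["cls0"][None, :], (n_iter, n_pat)).copy()

    cost = np.zeros((n_iter, n_pat))
    qaly = np.zeros((n_iter, n_pat))
    life = np.zeros((n_iter, n_pat), dtype=np.int64)
    adm = np.zeros((n_iter, n_pat), dtype=np.int64)
    if medly:
        cost += amortized_fixed_cost(base)

    for t in range(horizon):
        if not alive.any():
            break
        df = (1.0 + rate) ** (-t / 12.0)
        u_death = draws[:, t, 0][None, :]
        u_adm = draws[:, t, 1][None, :]
        u_tr = draws[:, t, 2][None, :]

        p_death = np.where(in_hosp, p_ih, p_die_comm)
        die = alive & (u_death < p_death)
        alive = alive & ~die
        a = alive

        was_hosp = a & in_hosp
        in_hosp = in_hosp & ~was_hosp  # provisional discharge

        flat = (it4 + (cls - 1)).reshape(-1)
        p_cls = _clamped(hosp_p_flat[flat].reshape(n_iter, n_pat) * rr_h,
                         "hospitalization probability")
        if persistent:
            eligible = a
            at_risk_re = a & post
        else:
            eligible = a & ~was_hosp
            at_risk_re = a & msd0 & ~was_hosp
        p_adm = np.where(at_risk_re, p_re, p_cls)
        admit = eligible & (u_adm < p_adm)
        in_hosp = in_hosp | admit
        adm += admit
        post = post | admit

        move = a & ~was_hosp & ~admit
        c0 = tc_flat[0][flat].reshape(n_iter, n_pat)
        c1 = tc_flat[1][flat].reshape(n_iter, n_pat)
        c2 = tc_flat[2][flat].reshape(n_iter, n_pat)
        newcls = 1 + ((u_tr > c0).astype(np.int64) + (u_tr > c1) + (u_tr > c2))
        cls = np.where(move, newcls, cls)

        flat = (it4 + (cls - 1)).reshape(-1)
        util = util_flat[flat].reshape(n_iter, n_pat) - disutil * in_hosp
        drug_ok = (pat["age0"] + t / 12.0) >= age_thr
        comm_cost = (nondrug_flat[flat].reshape(n_iter, n_pat)
                     + drug_flat[flat].reshape(n_iter, n_pat)
                     * drug_ok[None, :])
        cyc_cost = np.where(in_hosp, hosp_cost, comm_cost)
        if medly:
            cyc_cost = cyc_cost + medly_monthly

        cost += df * cyc_cost * a
        qaly += df * (util / 12.0) * a
        life += a

        msd0 = was_hosp & ~in_hosp

    return cost, qaly, life, adm


@dataclass
class CohortResults:
    """Paired per-patient arm results for one cohort simulation."""

    cost: dict = field(default_factory=dict)
    qaly: dict = field(default_factory=dict)
    life_months: dict = field(default_factory=dict)
    admissions: dict = field(default_factory=dict)
    seed: int | None = None

    @property
    def n_patients(self) -> int:
        return len(next(iter(self.cost.values())))

    @property
    def mean_cost(self) -> dict:
        return {arm: float(np.mean(v)) for arm, v in self.cost.items()}

    @property
    def mean_qaly(self) -> dict:
        return {arm: float(np.mean(v)) for arm, v in self.qaly.items()}

    def mcse(self, field_name: str = "cost") -> dict:
        data = getattr(self, field_name)
        out = {}
        for arm, v in data.items():
            v = np.asarray(v, dtype=float)
            out[arm] = (float(np.std(v, ddof=1) / np.sqrt(v.size))
                        if v.size > 1 else 0.0)
        return out

    def arm_result(self, i: int, arm: str) -> ArmResult:
        return ArmResult(arm=arm,
                         discounted_cost=float(self.cost[arm][i]),
                         discounted_qaly=float(self.qaly[arm][i]),
                         life_months=int(self.life_months[arm][i]),
                         admissions=int(self.admissions[arm][i]))

    def to_dataframe(self) -> pd.DataFrame:
        frames = []
        for arm in self.cost:
            frames.append(pd.DataFrame({
                "patient_id": np.arange(self.n_patients),
                "arm": arm,
                "discounted_cost": self.cost[arm],
                "discounted_qaly": self.qaly[arm],
                "life_months": self.life_months[arm],
                "admissions": self.admissions[arm],
            }))
        return pd.concat(frames, ignore_index=True)


def cohort_draws(n_patients: int, horizon_months: int,
                 seed: int) -> np.ndarray:
    """The common random-number block shared by both arms."""
    rng = np.random.default_rng(seed)
    return rng.random((n_patients, horizon_months, N_DRAWS_PER_CYCLE))


def simulate_cohort(cohort: Cohort, params: ModelParameters, seed: int = 0,
                    arms: Iterable[str] = ARMS,
                    draws: np.ndarray | None = None) -> CohortResults:
    """Simulate every patient through the requested arms under common
    random numbers; returns paired per-patient results."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    arms = tuple(arms)
    for arm in arms:
        if arm not in ARMS:
            raise ValueError(f"unknown arm: {arm}")
    if "medly" in arms and cohort.data["kit_type"].isna().any():
        from .scenarios import assign_deployment
        cohort = assign_deployment(cohort, params.deployment_ratio, seed)

    if draws is None:
        draws = cohort_draws(len(cohort), params.horizon_months, seed)
    pat = _patient_arrays(cohort, params)
    par = _param_arrays([params])

    results = CohortResults(seed=seed)
    for arm in arms:
        cost, qaly, life, adm = _simulate_paths(
            pat, par, draws, medly=(arm == "medly"), base=params)
        results.cost[arm] = cost[0]
        results.qaly[arm] = qaly[0]
        results.life_months[arm] = life[0]
        results.admissions[arm] = adm[0]
    return results
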