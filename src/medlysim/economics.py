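"""Cost assembly and cost-effectiveness summary measures.

Monthly ambulatory ("living with heart failure") costs are built per NYHA
class from four components — emergency department, general practitioner,
outpatient and drug — with the drug component payable only for patients at
or above the public drug-benefit age threshold (65 years).  Program costs
for the telemonitoring arm combine a per-patient share of the fixed site
cost, a monthly operational cost and a kit-dependent monthly equipment cost.

Cost-effectiveness outputs follow standard cost-utility practice: paired
arm means, Monte Carlo standard errors, incremental cost and QALYs, the
ICER with an explicit dominance classification, and net monetary benefit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .parameters import KIT_TYPES, ModelParameters

__all__ = [
    "CostBreakdown",
    "CEResult",
    "monthly_state_cost",
    "monthly_cost_from_utilization",
    "medly_monthly_cost",
    "amortized_fixed_cost",
    "compute_icer",
    "net_monetary_benefit",
]


@dataclass
class CostBreakdown:
    """Monthly ambulatory cost split by component (CAD/month)."""

    ed: float
    gp: float
    outpatient: float
    drug: float

    @property
    def total(self) -> float:
        return self.ed + self.gp + self.outpatient + self.drug


def monthly_state_cost(nyha_class: int, age: float,
                       params: ModelParameters) -> CostBreakdown:
    """Component costs for one community cycle in the given class.

    The drug component applies only when ``age >= drug_age_threshold``.
    """
    if nyha_class not in (1, 2, 3, 4):
        raise ValueError(f"unknown NYHA class: {nyha_class}")
    if age < 0:
        raise ValueError("age must be nonnegative")
    i = nyha_class - 1
    c = params.state_cost_components
    drug = c["drug"][i] if age >= params.drug_age_threshold else 0.0
    return CostBreakdown(ed=float(c["ed"][i]), gp=float(c["gp"][i]),
                         outpatient=float(c["outpatient"][i]),
                         drug=float(drug))


def monthly_cost_from_utilization(visits_per_6mo: dict[str, float],
                                  unit_costs: dict[str, float],
                                  drug_monthly: float = 0.0) -> CostBreakdown:
    """Rebuild monthly component costs from 6-month utilization counts.

    ``component = count * unit_cost / 6``; the drug component is passed
    through directly as a monthly amount.  This is the costing route the
    probabilistic analysis uses to propagate unit-cost uncertainty.
    """
    comp = {}
    for svc in ("ed", "gp", "outpatient"):
        count = float(visits_per_6mo.get(svc, 0.0))
        if count < 0:
            raise ValueError(f"negative utilization for {svc}")
        comp[svc] = count * float(unit_costs.get(svc, 0.0)) / 6.0
    return CostBreakdown(ed=comp["ed"], gp=comp["gp"],
                         outpatient=comp["outpatient"],
                         drug=float(drug_monthly))


def medly_monthly_cost(kit_type: str, params: ModelParameters) -> float:
    """Monthly program cost for one enrolled patient (kit + operations)."""
    if kit_type not in KIT_TYPES:
        raise ValueError(f"unknown kit type: {kit_type}")
    return float(params.kit_monthly_cost[kit_type]
                 + params.medly_operational_monthly)


def amortized_fixed_cost(params: ModelParameters) -> float:
    """One-time per-patient share of the fixed site-implementation cost."""
    if params.medly_site_capacity <= 0:
        raise ValueError("site capacity must be positive")
    return float(params.medly_fixed_site_cost / params.medly_site_capacity)


# ----------------------------------------------------------------------

@dataclass
class CEResult:
    """Cost-effectiveness comparison of the telemonitoring arm vs standard
    care, with Monte Carlo standard errors of each mean."""

    mean_cost: dict = field(default_factory=dict)
    mean_qaly: dict = field(default_factory=dict)
    mcse_cost: dict = field(default_factory=dict)
    mcse_qaly: dict = field(default_factory=dict)
    delta_cost: float = 0.0
    delta_qaly: float = 0.0
    mcse_delta_cost: float = 0.0
    mcse_delta_qaly: float = 0.0
    icer: float | None = None
    classification: str = "undefined"
    n_patients: int = 0

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "n_patients": self.n_patients,
            "mean_cost": self.mean_cost, "mean_qaly": self.mean_qaly,
            "mcse_cost": self.mcse_cost, "mcse_qaly": self.mcse_qaly,
            "delta_cost": self.delta_cost, "delta_qaly": self.delta_qaly,
            "mcse_delta_cost": self.mcse_delta_cost,
            "mcse_delta_qaly": self.mcse_delta_qaly,
            "icer": self.icer, "classification": self.classification,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    def summary_row(self) -> dict:
        """Flat row mirroring the deterministic results table layout."""
        return {
            "cost_medly": self.mean_cost.get("medly"),
            "mcse_cost_medly": self.mcse_cost.get("medly"),
            "cost_standard": self.mean_cost.get("standard"),
            "mcse_cost_standard": self.mcse_cost.get("standard"),
            "qaly_medly": self.mean_qaly.get("medly"),
            "mcse_qaly_medly": self.mcse_qaly.get("medly"),
            "qaly_standard": self.mean_qaly.get("standard"),
            "mcse_qaly_standard": self.mcse_qaly.get("standard"),
            "delta_cost": self.delta_cost,
            "mcse_delta_cost": self.mcse_delta_cost,
            "delta_qaly": self.delta_qaly,
            "mcse_delta_qaly": self.mcse_delta_qaly,
            "icer": self.icer,
            "classification": self.classification,
        }


def _mcse(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    if x.size <= 1:
        return 0.0
    return float(np.std(x, ddof=1) / np.sqrt(x.size))


def classify(delta_cost: float, delta_qaly: float) -> str:
    if delta_qaly > 0 and delta_cost >= 0:
        return "cost_effective_quadrant"
    if delta_qaly > 0 and delta_cost < 0:
        return "dominant"
    if delta_qaly < 0 and delta_cost > 0:
        return "dominated"
    if delta_qaly < 0 and delta_cost <= 0:
        return "cheaper_less_effective"
    return "undefined"


def compute_icer(results) -> CEResult:
    """Summarize paired per-patient arm results into a CEResult.

    ``results`` must expose per-patient arrays ``cost[arm]`` and
    ``qaly[arm]`` for arms ``"medly"`` and ``"standard"`` over the same
    patients (see :class:`medlysim.engine.CohortResults`).  Negative ICERs
    are always reported together with their dominance classification.
    """
    cost_m = np.asarray(results.cost["medly"], dtype=float)
    cost_s = np.asarray(results.cost["standard"], dtype=float)
    qaly_m = np.asarray(results.qaly["medly"], dtype=float)
    qaly_s = np.asarray(results.qaly["standard"], dtype=float)
    if cost_m.shape != cost_s.shape or qaly_m.shape != qaly_s.shape:
        raise ValueError("arms must cover the same patients")
    n = cost_m.size
    if n == 0:
        raise ValueError("empty cohort")

    dc = float(cost_m.mean() - cost_s.mean())
    dq = float(qaly_m.mean() - qaly_s.mean())
    icer = dc / dq if dq != 0.0 else None
    return CEResult(
        mean_cost={"medly": float(cost_m.mean()),
                   "standard": float(cost_s.mean())},
        mean_qaly={"medly": float(qaly_m.mean()),
                   "standard": float(qaly_s.mean())},
        mcse_cost={"medly": _mcse(cost_m), "standard": _mcse(cost_s)},
        mcse_qaly={"medly": _mcse(qaly_m), "standard": _mcse(qaly_s)},
        delta_cost=dc, delta_qaly=dq,
        mcse_delta_cost=_mcse(cost_m - cost_s),
        mcse_delta_qaly=_mcse(qaly_m - qaly_s),
        icer=icer,
        classification=("undefined" if dq == 0.0 else classify(dc, dq)),
        n_patients=n,
    )


def net_monetary_benefit(delta_cost: float, delta_qaly: float,
                         wtp: float) -> float:
    """NMB = wtp * dQALY - dCost; positive iff cost-effective at ``wtp``."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be nonnegative")
    return wtp * delta_qaly - delta_cost
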