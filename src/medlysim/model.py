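"""Model/Results objects wrapping the microsimulation pipeline.

:class:`CostUtilityModel` is built from a cohort (observed or synthetic)
plus a parameter set; ``fit()`` calibrates the survival layer, runs the
paired deterministic microsimulation and returns a
:class:`CostUtilityResults` carrying arm means, Monte Carlo standard
errors, the incremental results and a ``summary()`` table.  Probabilistic
sensitivity analysis and the standard plots (cost-utility plane, CEAC)
hang off the results object.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort, generate_cohort
from .economics import CEResult, compute_icer
from .engine import CohortResults, simulate_cohort
from .parameters import ModelParameters
from .psa import PsaResult, run_psa
from .scenarios import assign_deployment
from .survival import calibrate_baseline_hazard

__all__ = ["CostUtilityModel", "CostUtilityResults"]


class CostUtilityModel:
    """Cost-utility microsimulation of telemonitoring vs standard care.

    Parameters
    ----------
    cohort : the patient population to simulate.
    params : model inputs; packaged defaults when omitted.

    Examples
    --------
    >>> model = CostUtilityModel.from_moments(n=200, seed=1)
    >>> res = model.fit(seed=1)
    >>> print(res.summary())            # doctest: +SKIP
    """

    def __init__(self, cohort: Cohort,
                 params: ModelParameters | None = None):
        if len(cohort) == 0:
            raise ValueError("empty cohort")
        self.params = params or ModelParameters()
        if cohort.data["kit_type"].isna().any():
            cohort = assign_deployment(cohort, self.params.deployment_ratio,
                                       cohort.seed or 0)
        self.cohort = cohort

    @classmethod
    def from_moments(cls, n: int | None = None,
                     params: ModelParameters | None = None,
                     seed: int = 0,
                     nyha_class: int | None = None) -> "CostUtilityModel":
        """Build the model on a synthetic cohort generated from the
        configured marginal moments and correlation structure."""
        params = params or ModelParameters()
        cohort = generate_cohort(n if n is not None else params.cohort_size,
                                 params=params, seed=seed,
                                 nyha_class=nyha_class)
        return cls(cohort, params)

    def fit(self, seed: int = 0, calibrate: bool = True
            ) -> "CostUtilityResults":
        """Calibrate the survival baseline hazard (optional) and run the
        paired deterministic simulation."""
        params = self.params
        if calibrate:
            params = calibrate_baseline_hazard(self.cohort, params,
                                               seed=seed)
        raw = simulate_cohort(self.cohort, params, seed=seed)
        ce = compute_icer(raw)
        return CostUtilityResults(model=self, params=params, raw=raw,
                                  ce=ce, seed=seed)


@dataclass
class CostUtilityResults:
    """Fitted results: arm-level and incremental cost-effectiveness."""

    model: CostUtilityModel
    params: ModelParameters
    raw: CohortResults
    ce: CEResult
    seed: int

    # -- convenience accessors -------------------------------------------
    @property
    def icer(self) -> float | None:
        return self.ce.icer

    @property
    def delta_cost(self) -> float:
        return self.ce.delta_cost

    @property
    def delta_qaly(self) -> float:
        return self.ce.delta_qaly

    def summary(self) -> str:
        """Plain-text table in the usual deterministic-results layout."""
        ce = self.ce
        lines = [
            "Cost-utility microsimulation results",
            "=" * 70,
            f"patients: {ce.n_patients}    horizon: "
            f"{self.params.horizon_months} months    discount rate: "
            f"{self.params.discount_rate_annual:.1%}/yr",
            f"baseline annual hazard: "
            f"{self.params.shfm['baseline_annual_hazard']:.4f}",
            "-" * 70,
            f"{'arm':<12}{'cost (CAD)':>14}{'MCSE':>10}"
            f"{'QALYs':>10}{'MCSE':>8}",
        ]
        for arm in ("standard", "medly"):
            lines.append(
                f"{arm:<12}{ce.mean_cost[arm]:>14,.0f}"
                f"{ce.mcse_cost[arm]:>10,.0f}"
                f"{ce.mean_qaly[arm]:>10.2f}{ce.mcse_qaly[arm]:>8.2f}")
        lines += [
            "-" * 70,
            f"incremental cost:  {ce.delta_cost:>12,.0f}  "
            f"(MCSE {ce.mcse_delta_cost:,.0f})",
            f"incremental QALYs: {ce.delta_qaly:>12.3f}  "
            f"(MCSE {ce.mcse_delta_qaly:.3f})",
            f"ICER: "
            + (f"{ce.icer:,.0f} CAD/QALY" if ce.icer is not None
               else "undefined (zero QALY difference)")
            + f"   [{ce.classification}]",
            "=" * 70,
        ]
        return "\n".join(lines)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.ce.summary_row()])

    # -- uncertainty ------------------------------------------------------
    def run_psa(self, n_iterations: int | None = None,
                seed: int | None = None) -> PsaResult:
        """Probabilistic sensitivity analysis on the fitted configuration."""
        return run_psa(self.model.cohort, self.params,
                       n_iterations=n_iterations,
                       seed=self.seed if seed is None else seed)

    # -- plots ------------------------------------------------------------
    def plot_ce_plane(self, psa_result: PsaResult, ax=None, wtp=50000.0):
        """Cost-utility plane of PSA iterations with the WTP ray."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        dq, dc = psa_result.delta_qaly, psa_result.delta_cost
        ax.scatter(dq, dc, s=8, alpha=0.5)
        ax.axhline(0.0, color="grey", lw=0.8)
        ax.axvline(0.0, color="grey", lw=0.8)
        span = np.linspace(min(dq.min(), 0), max(dq.max(), 0), 50)
        ax.plot(span, wtp * span, "--", color="darkred", lw=1,
                label=f"WTP {wtp:,.0f}/QALY")
        ax.set_xlabel("incremental QALYs")
        ax.set_ylabel("incremental cost (CAD)")
        ax.legend()
        return ax

    def plot_ceac(self, psa_result: PsaResult, ax=None):
        """Cost-effectiveness acceptability curve."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        curve = psa_result.ceac()
        ax.plot(curve["wtp"], curve["probability"])
        ax.set_ylim(0, 1)
        ax.set_xlabel("willingness to pay (CAD/QALY)")
        ax.set_ylabel("probability cost-effective")
        return ax
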