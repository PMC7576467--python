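"""Typed parameter store for the heart-failure telemonitoring cost-utility model.

All monetary values are 2019 Canadian dollars. The packaged defaults carry the
reference inputs of the model: monthly NYHA transition probabilities,
per-class hospitalization probabilities and utilities, per-class monthly
ambulatory cost components (emergency department, general practitioner,
outpatient, drug), hospitalization cost moments, telemonitoring program costs
for the three deployment kits (Full Kit, Bring Your Own Phone, Bring Your Own
Everything), treatment-effect relative risks, the survival-score coefficient
block, and the virtual-cohort moments with a configurable correlation matrix.

Configuration files are YAML (JSON accepted); any subset of fields may be
overridden and the remainder are filled from the defaults.
"""

from __future__ import annotations

import copy
import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

__all__ = [
    "ModelParameters",
    "Violation",
    "ValidationError",
    "default_parameters",
    "load_config",
    "write_config",
    "validate",
    "KIT_TYPES",
    "ALT_RR_HOSPITALIZATION",
]

KIT_TYPES = ("FK", "BYOP", "BYOE")

#: Alternative hospitalization relative-risk preset (point, lower, upper).
#: The reference default below (0.753) comes from the program-evaluation
#: effectiveness estimate; this preset is the unadjusted estimate reported
#: alongside the program cost table. Neither is privileged by the model;
#: select via ``rr_hospitalization`` / ``rr_hospitalization_ci``.
ALT_RR_HOSPITALIZATION = (0.857, 0.703, 1.014)

# Ordered characteristic names for the virtual cohort.  The correlation
# matrix and the moment table are indexed in this order.
CHARACTERISTICS = (
    "age",
    "sex_female",
    "ischemic_etiology",
    "on_beta_blocker",
    "on_aldosterone_blocker",
    "on_arb",
    "on_ace_inhibitor",
    "on_allopurinol",
    "lvef_pct",
    "nyha_latent",
    "sbp_mmHg",
    "lymphocytes_pct",
    "sodium_mEq_L",
    "cholesterol_mg_dL",
    "hemoglobin_g_dL",
    "urate_mg_dL",
    "weight_kg",
    "furosemide_equiv_mg_day",
    "has_icd",
)

BINARY_CHARACTERISTICS = (
    "sex_female",
    "ischemic_etiology",
    "on_beta_blocker",
    "on_aldosterone_blocker",
    "on_arb",
    "on_ace_inhibitor",
    "on_allopurinol",
    "has_icd",
)

# Cohort marginal moments: continuous -> (mean, sd), binary -> proportion.
_DEFAULT_MOMENTS: dict[str, Any] = {
    "age": {"mean": 58.23, "sd": 15.43},
    "sex_female": {"proportion": 0.22},
    "ischemic_etiology": {"proportion": 0.285},
    "on_beta_blocker": {"proportion": 0.894},
    "on_aldosterone_blocker": {"proportion": 0.712},
    "on_arb": {"proportion": 0.272},
    "on_ace_inhibitor": {"proportion": 0.455},
    "on_allopurinol": {"proportion": 0.136},
    "lvef_pct": {"mean": 32.07, "sd": 13.62},
    "nyha_latent": {"mean": 0.0, "sd": 1.0},
    "sbp_mmHg": {"mean": 110.36, "sd": 17.91},
    "lymphocytes_pct": {"mean": 22.18, "sd": 9.07},
    "sodium_mEq_L": {"mean": 137.73, "sd": 3.06},
    "cholesterol_mg_dL": {"mean": 154.77, "sd": 52.71},
    "hemoglobin_g_dL": {"mean": 13.33, "sd": 1.99},
    "urate_mg_dL": {"mean": 7.97, "sd": 2.70},
    "weight_kg": {"mean": 83.39, "sd": 20.04},
    "furosemide_equiv_mg_day": {"mean": 99.57, "sd": 123.93},
    "has_icd": {"proportion": 0.565},
}

# Physiological clip bounds applied after sampling.
_DEFAULT_BOUNDS: dict[str, list[float]] = {
    "age": [18.0, 100.0],
    "lvef_pct": [1.0, 100.0],
    "sbp_mmHg": [60.0, 250.0],
    "sodium_mEq_L": [110.0, 160.0],
    "hemoglobin_g_dL": [4.0, 22.0],
    "lymphocytes_pct": [1.0, 60.0],
    "cholesterol_mg_dL": [50.0, 500.0],
    "urate_mg_dL": [1.0, 20.0],
    "weight_kg": [30.0, 250.0],
    "furosemide_equiv_mg_day": [0.0, 2000.0],
}


def _default_correlation() -> list[list[float]]:
    """Modest, clinically plausible inter-characteristic correlations.

    The source cohort's own matrix is not distributed; this stand-in keeps
    the generation mechanism intact and is fully replaceable via config.
    Entries are on the latent-normal scale.
    """
    n = len(CHARACTERISTICS)
    idx = {name: i for i, name in enumerate(CHARACTERISTICS)}
    m = np.eye(n)
    pairs = {
        ("age", "sbp_mmHg"): 0.20,
        ("age", "ischemic_etiology"): 0.20,
        ("age", "cholesterol_mg_dL"): -0.10,
        ("lvef_pct", "nyha_latent"): -0.30,
        ("lvef_pct", "has_icd"): -0.20,
        ("nyha_latent", "furosemide_equiv_mg_day"): 0.20,
        ("nyha_latent", "sbp_mmHg"): -0.15,
        ("urate_mg_dL", "furosemide_equiv_mg_day"): 0.25,
        ("urate_mg_dL", "on_allopurinol"): 0.30,
        ("weight_kg", "furosemide_equiv_mg_day"): 0.15,
        ("hemoglobin_g_dL", "sex_female"): -0.20,
        ("sodium_mEq_L", "furosemide_equiv_mg_day"): -0.15,
    }
    for (a, b), r in pairs.items():
        m[idx[a], idx[b]] = m[idx[b], idx[a]] = r
    return m.tolist()


def _default_shfm_block() -> dict[str, Any]:
    """Proportional-hazards survival-score block.

    Log hazard ratios mirror the published multivariate Cox model for
    ambulatory heart-failure survival (coefficient magnitudes follow the
    commonly cited hazard ratios for each covariate).  Covariates are
    centered at the cohort means so a cohort-average patient scores ~0 and
    ``baseline_annual_hazard`` is the cohort-average annual mortality
    hazard.  The baseline hazard is re-estimated by
    :func:`medlysim.survival.calibrate_baseline_hazard` so that comparator
    lifetime QALYs match the calibration anchor.
    """
    return {
        "baseline_annual_hazard": 0.105,
        "coefficients": {
            "age": 0.0086,
            "sex_female": -0.10,
            "ischemic_etiology": 0.30,
            "nyha_class": 0.47,
            "lvef_pct": -0.030,
            "sbp_mmHg": -0.008,
            "on_beta_blocker": -0.42,
            "on_ace_inhibitor": -0.26,
            "on_arb": -0.16,
            "on_aldosterone_blocker": -0.30,
            "on_allopurinol": 0.45,
            "lymphocytes_pct": -0.022,
            "sodium_mEq_L": -0.0163,
            "cholesterol_mg_dL": -0.003,
            "hemoglobin_g_dL": -0.034,
            "urate_mg_dL": 0.077,
            "weight_kg": -0.002,
            "furosemide_equiv_mg_day": 0.002,
            "has_icd": -0.27,
        },
        "centers": {
            "age": 58.23,
            "sex_female": 0.22,
            "ischemic_etiology": 0.285,
            "nyha_class": 2.36,
            "lvef_pct": 32.07,
            "sbp_mmHg": 110.36,
            "on_beta_blocker": 0.894,
            "on_ace_inhibitor": 0.455,
            "on_arb": 0.272,
            "on_aldosterone_blocker": 0.712,
            "on_allopurinol": 0.136,
            "lymphocytes_pct": 22.18,
            "sodium_mEq_L": 137.73,
            "cholesterol_mg_dL": 154.77,
            "hemoglobin_g_dL": 13.33,
            "urate_mg_dL": 7.97,
            "weight_kg": 83.39,
            "furosemide_equiv_mg_day": 99.57,
            "has_icd": 0.565,
        },
    }


def _nyha_cutpoints_from_counts(counts=(44, 166, 93, 1)) -> list[float]:
    # Latent-normal thresholds reproducing the observed class distribution.
    from scipy.stats import norm

    total = sum(counts)
    cum = np.cumsum(counts)[:-1] / total
    return [float(norm.ppf(c)) for c in cum]


@dataclass
class Violation:
    field: str
    value: Any
    rule: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.field}={self.value!r}: {self.rule}"


class ValidationError(ValueError):
    """Raised when a configuration violates a model invariant."""

    def __init__(self, violations: list[Violation]):
        self.violations = violations
        super().__init__("; ".join(str(v) for v in violations))


@dataclass
class ModelParameters:
    """Complete input set for the cost-utility microsimulation."""

    # --- horizon, discounting, run sizes ---
    discount_rate_annual: float = 0.015
    horizon_months: int = 300
    cohort_size: int = 1000
    psa_iterations: int = 1000

    # --- disease dynamics ---
    nyha_transition_matrix: list = field(default_factory=lambda: [
        [0.977, 0.019, 0.004, 0.0],
        [0.008, 0.981, 0.010, 0.001],
        [0.0, 0.034, 0.960, 0.006],
        [0.0, 0.0, 0.055, 0.945],
    ])
    hosp_prob_monthly: list = field(
        default_factory=lambda: [0.0152, 0.024, 0.024, 0.154])
    hosp_prob_ranges: list = field(default_factory=lambda: [
        [0.008, 0.023], [0.012, 0.036], [0.012, 0.036], [0.077, 0.231]])
    readmit_prob_30d: float = 0.159
    readmit_prob_ci: list = field(default_factory=lambda: [0.089, 0.159])
    # Monthly all-cause death probability while hospitalized (replaces the
    # survival-score probability for hospital cycles).  No point estimate is
    # printed with the cited source; default chosen so hospitalization-
    # mortality coupling stays weak, and fully configurable.
    inhospital_mortality_monthly: float = 0.02
    # "persistent": the 30-day readmission probability applies to every cycle
    # after the first hospitalization (hospitalization as a progression
    # marker), with hospital-to-hospital chains allowed.
    # "first_cycle": it applies only in the first community cycle after
    # discharge.
    readmission_scope: str = "persistent"
    # Whether the hospitalization relative risk also scales the readmission
    # probability (False: index admissions only).
    rr_applies_to_readmission: bool = False

    # --- utilities ---
    utilities_by_class: list = field(
        default_factory=lambda: [0.81, 0.72, 0.59, 0.508])
    utility_ranges: list = field(default_factory=lambda: [
        [0.81, 0.90], [0.72, 0.83], [0.59, 0.74], [0.508, 0.59]])
    hosp_disutility: float = 0.059
    hosp_disutility_ci: list = field(default_factory=lambda: [0.0, 0.11])

    # --- ambulatory state costs (per class, per month, CAD) ---
    state_cost_components: dict = field(default_factory=lambda: {
        "ed": [0.0, 0.0, 62.83, 62.83],
        "gp": [0.0, 0.0, 12.87, 12.87],
        "outpatient": [97.00, 97.00, 97.00, 97.00],
        "drug": [52.00, 52.00, 79.43, 208.16],
    })
    drug_age_threshold: float = 65.0

    # --- hospitalization costs ---
    hosp_cost_mean: float = 8908.0
    hosp_cost_sd: float = 16867.0
    los_mean_days: float = 5.9
    los_sd_days: float = 11.2

    # --- unit costs and utilization (for the utilization costing route) ---
    unit_costs: dict = field(default_factory=lambda: {
        "ed": {"mean": 377.00, "sd": 374.00},
        "outpatient": {"mean": 291.33, "sd": 161.11},
        "gp": {"mean": 77.20, "sd": 0.0},
        "drug_6mo": {"mean": 1248.96, "sd": 2233.52},
    })
    utilization_median_6mo: dict = field(default_factory=lambda: {
        "ed": [0, 0, 1, 1],
        "outpatient": [2, 1, 2, 2],
        "gp": [0, 1, 2, 2],
    })

    # --- telemonitoring program costs ---
    medly_fixed_site_cost: float = 102500.0
    medly_site_capacity: int = 1000
    medly_operational_monthly: float = 44.67
    kit_monthly_cost: dict = field(default_factory=lambda: {
        "FK": 67.56, "BYOP": 18.87, "BYOE": 3.80})
    deployment_ratio: list = field(default_factory=lambda: [2, 1, 2])

    # --- treatment effects ---
    rr_mortality: float = 0.81
    rr_mortality_ci: list = field(default_factory=lambda: [0.70, 0.94])
    rr_hospitalization: float = 0.753
    rr_hospitalization_ci: list = field(default_factory=lambda: [0.634, 0.879])

    # --- decision rule ---
    wtp_grid: list = field(
        default_factory=lambda: [float(w) for w in range(0, 100001, 1000)])

    # --- survival score ---
    shfm: dict = field(default_factory=_default_shfm_block)
    calibration_target_qaly: float = 4.95

    # --- cohort synthesis ---
    cohort_moments: dict = field(
        default_factory=lambda: copy.deepcopy(_DEFAULT_MOMENTS))
    correlation_matrix: list = field(default_factory=_default_correlation)
    nyha_cutpoints: list = field(default_factory=_nyha_cutpoints_from_counts)
    truncation_bounds: dict = field(
        default_factory=lambda: copy.deepcopy(_DEFAULT_BOUNDS))

    # --- uncertainty analysis ---
    dirichlet_concentration: float = 500.0

    # Names of fields overridden by the user (vs packaged defaults).
    provenance: dict = field(default_factory=dict, compare=False)

    # ------------------------------------------------------------------
    def copy(self) -> "ModelParameters":
        return copy.deepcopy(self)

    def replace(self, **overrides: Any) -> "ModelParameters":
        """Copy with named fields replaced (validated)."""
        new = self.copy()
        for key, value in overrides.items():
            if not hasattr(new, key):
                raise AttributeError(f"unknown parameter field: {key}")
            setattr(new, key, value)
        _raise_if_invalid(new)
        return new

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("provenance", None)
        return _plain(d)

    @classmethod
    def from_dict(cls, data: dict) -> "ModelParameters":
        params = cls()
        unknown = [k for k in data if not hasattr(params, k)]
        if unknown:
            raise ValidationError(
                [Violation(k, data[k], "unknown parameter field")
                 for k in unknown])
        for key, value in data.items():
            if key == "provenance":
                continue
            setattr(params, key, value)
            params.provenance[key] = "user"
        _raise_if_invalid(params)
        return params


def _plain(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _plain(obj.tolist())
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def default_parameters() -> ModelParameters:
    """The packaged reference parameter set."""
    return ModelParameters()


# ----------------------------------------------------------------------
# validation

def validate(params: ModelParameters) -> list[Violation]:
    """Check every type invariant; returns findings (empty list = valid)."""
    v: list[Violation] = []

    def prob(name: str, x: float) -> None:
        if not (0.0 <= float(x) <= 1.0):
            v.append(Violation(name, x, "probability must be in [0, 1]"))

    tm = np.asarray(params.nyha_transition_matrix, dtype=float)
    if tm.shape != (4, 4):
        v.append(Violation("nyha_transition_matrix", tm.shape,
                           "must be a 4x4 matrix"))
    else:
        for i, row in enumerate(tm):
            if np.any(row < 0) or np.any(row > 1):
                v.append(Violation(f"nyha_transition_matrix[{i}]",
                                   row.tolist(),
                                   "entries must be probabilities"))
            if abs(row.sum() - 1.0) > 1e-9:
                v.append(Violation(f"nyha_transition_matrix[{i}]",
                                   float(row.sum()),
                                   "row must sum to 1 within 1e-9"))

    for i, p in enumerate(params.hosp_prob_monthly):
        prob(f"hosp_prob_monthly[{i}]", p)
    prob("readmit_prob_30d", params.readmit_prob_30d)
    prob("inhospital_mortality_monthly", params.inhospital_mortality_monthly)
    for i, u in enumerate(params.utilities_by_class):
        if not (0.0 <= float(u) <= 1.0):
            v.append(Violation(f"utilities_by_class[{i}]", u,
                               "utility must be in [0, 1]"))
    prob("hosp_disutility", params.hosp_disutility)

    for comp, values in params.state_cost_components.items():
        if len(values) != 4:
            v.append(Violation(f"state_cost_components[{comp}]", values,
                               "needs one value per NYHA class"))
        elif any(float(c) < 0 for c in values):
            v.append(Violation(f"state_cost_components[{comp}]", values,
                               "costs must be nonnegative"))
    for name, val in [("hosp_cost_mean", params.hosp_cost_mean),
                      ("hosp_cost_sd", params.hosp_cost_sd),
                      ("medly_fixed_site_cost", params.medly_fixed_site_cost),
                      ("medly_operational_monthly",
                       params.medly_operational_monthly)]:
        if float(val) < 0:
            v.append(Violation(name, val, "cost must be nonnegative"))
    for kit, c in params.kit_monthly_cost.items():
        if kit not in KIT_TYPES:
            v.append(Violation("kit_monthly_cost", kit, "unknown kit type"))
        elif float(c) < 0:
            v.append(Violation(f"kit_monthly_cost[{kit}]", c,
                               "cost must be nonnegative"))
    if params.medly_site_capacity <= 0:
        v.append(Violation("medly_site_capacity", params.medly_site_capacity,
                           "site capacity must be positive"))

    ratio = list(params.deployment_ratio)
    if len(ratio) != 3 or any(r < 0 for r in ratio) or sum(ratio) <= 0:
        v.append(Violation("deployment_ratio", ratio,
                           "needs 3 nonnegative entries with positive sum"))

    for name, rr in [("rr_mortality", params.rr_mortality),
                     ("rr_hospitalization", params.rr_hospitalization)]:
        if float(rr) <= 0:
            v.append(Violation(name, rr, "relative risk must be positive"))

    cm = np.asarray(params.correlation_matrix, dtype=float)
    k = len(CHARACTERISTICS)
    if cm.shape != (k, k):
        v.append(Violation("correlation_matrix", cm.shape,
                           f"must be {k}x{k} over the characteristics"))
    else:
        if not np.allclose(cm, cm.T, atol=1e-10):
            v.append(Violation("correlation_matrix", "asymmetric",
                               "matrix must be symmetric"))
        if not np.allclose(np.diag(cm), 1.0, atol=1e-10):
            v.append(Violation("correlation_matrix", np.diag(cm).tolist(),
                               "diagonal must be 1"))

    cuts = list(params.nyha_cutpoints)
    if len(cuts) != 3 or not all(a < b for a, b in zip(cuts, cuts[1:])):
        v.append(Violation("nyha_cutpoints", cuts,
                           "needs 3 strictly increasing thresholds"))

    if params.shfm.get("baseline_annual_hazard", 0.0) <= 0:
        v.append(Violation("shfm.baseline_annual_hazard",
                           params.shfm.get("baseline_annual_hazard"),
                           "baseline hazard must be positive"))

    if params.readmission_scope not in ("persistent", "first_cycle"):
        v.append(Violation("readmission_scope", params.readmission_scope,
                           "must be 'persistent' or 'first_cycle'"))
    if params.horizon_months < 1:
        v.append(Violation("horizon_months", params.horizon_months,
                           "horizon must be at least one cycle"))
    if params.discount_rate_annual < 0:
        v.append(Violation("discount_rate_annual",
                           params.discount_rate_annual,
                           "discount rate must be nonnegative"))
    return v


def _raise_if_invalid(params: ModelParameters) -> None:
    violations = validate(params)
    if violations:
        raise ValidationError(violations)


# ----------------------------------------------------------------------
# config i/o

def load_config(path: str | Path | None = None) -> ModelParameters:
    """Read a YAML/JSON config, filling unset fields from the defaults.

    An empty or missing override set yields the packaged reference
    parameters.  Unknown fields and invariant violations raise
    :class:`ValidationError`; malformed files raise a parse error.
    """
    if path is None:
        return default_parameters()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text) if text.strip() else {}
    else:
        data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data)}")
    return ModelParameters.from_dict(data)


def write_config(params: ModelParameters, path: str | Path) -> None:
    """Serialize the full parameter set (YAML or JSON by extension)."""
    path = Path(path)
    data = params.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))


def nearest_correlation(matrix: np.ndarray) -> tuple[np.ndarray, float]:
    """Project a symmetric matrix to the nearest PSD correlation matrix.

    Clips negative eigenvalues and rescales to unit diagonal; returns the
    repaired matrix and the Frobenius norm of the adjustment.
    """
    sym = (matrix + matrix.T) / 2.0
    w, q = np.linalg.eigh(sym)
    w_clipped = np.clip(w, 1e-10, None)
    repaired = (q * w_clipped) @ q.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    delta = float(np.linalg.norm(repaired - matrix, "fro"))
    if delta > 0:
        warnings.warn(
            f"correlation matrix repaired to nearest PSD "
            f"(adjustment norm {delta:.3g})", stacklevel=2)
    return repaired, delta
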