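"""Synthetic virtual-patient cohorts with a configurable correlation structure.

Patients are drawn from a latent multivariate standard normal whose
correlation matrix is factored by Cholesky decomposition (NORTA-style mixed
generation).  Each latent coordinate is back-transformed to its
characteristic's marginal:

* continuous  -> ``mean + sd * z`` then clipped to physiological bounds,
* binary      -> ``1`` if ``z < Phi^-1(proportion)``,
* NYHA class  -> ordinal 1-4 by thresholding against three latent cutpoints
  placed at the normal quantiles of the observed cumulative class
  proportions.

The same seed always reproduces the same cohort.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from scipy.linalg import LinAlgError, cholesky
from scipy.stats import norm

from .parameters import (
    BINARY_CHARACTERISTICS,
    CHARACTERISTICS,
    ModelParameters,
    nearest_correlation,
)

__all__ = [
    "PatientProfile",
    "Cohort",
    "CorrelatedSampler",
    "build_correlated_sampler",
    "generate_cohort",
    "assign_nyha_class",
    "truncate_profile",
]


@dataclass
class PatientProfile:
    """One virtual patient: survival-score covariates, NYHA class, kit."""

    patient_id: int
    age: float
    sex_female: int
    ischemic_etiology: int
    on_beta_blocker: int
    on_aldosterone_blocker: int
    on_arb: int
    on_ace_inhibitor: int
    on_allopurinol: int
    lvef_pct: float
    nyha_class: int
    sbp_mmHg: float
    lymphocytes_pct: float
    sodium_mEq_L: float
    cholesterol_mg_dL: float
    hemoglobin_g_dL: float
    urate_mg_dL: float
    weight_kg: float
    furosemide_equiv_mg_day: float
    has_icd: int
    kit_type: str | None = None

    def as_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


@dataclass
class Cohort:
    """Ordered collection of patients plus its generation provenance."""

    data: pd.DataFrame
    seed: int | None = None
    moments: dict | None = None
    clip_log: dict | None = None

    def __len__(self) -> int:
        return len(self.data)

    def __getitem__(self, i: int) -> PatientProfile:
        row = self.data.iloc[i]
        return PatientProfile(**{
            f.name: (row[f.name] if f.name in row else None)
            for f in dataclasses.fields(PatientProfile)})

    def profiles(self) -> list[PatientProfile]:
        return [self[i] for i in range(len(self))]

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Cohort":
        return cls(data=pd.read_csv(path))


def assign_nyha_class(latent: float | np.ndarray,
                      cutpoints) -> int | np.ndarray:
    """Map a latent standard-normal value to an ordinal NYHA class 1-4."""
    cuts = np.asarray(cutpoints, dtype=float)
    if cuts.shape != (3,) or not np.all(np.diff(cuts) > 0):
        raise ValueError(
            f"cutpoints must be 3 strictly increasing values, got {cutpoints}")
    cls = 1 + np.searchsorted(cuts, np.asarray(latent, dtype=float),
                              side="right")
    if np.isscalar(latent) or np.ndim(latent) == 0:
        return int(cls)
    return cls.astype(np.int64)


class CorrelatedSampler:
    """Seed-deterministic sampler of correlated mixed-type profiles."""

    def __init__(self, moments: dict, correlation: np.ndarray,
                 nyha_cutpoints, bounds: dict | None = None,
                 repair: bool = False):
        missing = [c for c in CHARACTERISTICS if c not in moments]
        if missing:
            raise ValueError(f"moments missing characteristics: {missing}")
        corr = np.asarray(correlation, dtype=float)
        k = len(CHARACTERISTICS)
        if corr.shape != (k, k):
            raise ValueError(f"correlation must be {k}x{k}")
        if not np.allclose(corr, corr.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(corr), 1.0, atol=1e-10):
            raise ValueError("correlation matrix must have unit diagonal")
        self.adjustment_norm = 0.0
        try:
            self._chol = cholesky(corr, lower=True)
        except LinAlgError:
            if not repair:
                raise ValueError(
                    "correlation matrix is not positive semidefinite "
                    "(pass repair=True to project to the nearest PSD)")
            corr, self.adjustment_norm = nearest_correlation(corr)
            self._chol = cholesky(
                corr + 1e-10 * np.eye(k), lower=True)
        self.correlation = corr
        self.moments = moments
        self.cutpoints = np.asarray(nyha_cutpoints, dtype=float)
        if not np.all(np.diff(self.cutpoints) > 0):
            raise ValueError("nyha cutpoints must be strictly increasing")
        self.bounds = bounds or {}
        self.clip_log: dict[str, int] = {}

    def latent(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Correlated latent standard-normal draws, shape (n, k)."""
        z = rng.standard_normal((n, len(CHARACTERISTICS)))
        return z @ self._chol.T

    def sample(self, n: int, rng: np.random.Generator) -> pd.DataFrame:
        z = self.latent(n, rng)
        cols: dict[str, np.ndarray] = {}
        self.clip_log = {}
        for j, name in enumerate(CHARACTERISTICS):
            zj = z[:, j]
            if name == "nyha_latent":
                cols["nyha_class"] = assign_nyha_class(zj, self.cutpoints)
            elif name in BINARY_CHARACTERISTICS:
                p = float(self.moments[name]["proportion"])
                cols[name] = (zj < norm.ppf(p)).astype(np.int64)
            else:
                m = float(self.moments[name]["mean"])
                s = float(self.moments[name]["sd"])
                x = m + s * zj
                if name in self.bounds:
                    lo, hi = self.bounds[name]
                    clipped = int(np.sum((x < lo) | (x > hi)))
                    if clipped:
                        self.clip_log[name] = clipped
                    x = np.clip(x, lo, hi)
                cols[name] = x
        return pd.DataFrame(cols)


def build_correlated_sampler(moments: dict, correlation,
                             nyha_cutpoints=None, bounds: dict | None = None,
                             repair: bool = False) -> CorrelatedSampler:
    """Construct the mixed-type sampler from marginal moments and a
    latent correlation matrix (Cholesky-factored)."""
    if nyha_cutpoints is None:
        nyha_cutpoints = ModelParameters().nyha_cutpoints
    return CorrelatedSampler(moments, correlation, nyha_cutpoints,
                             bounds=bounds, repair=repair)


def generate_cohort(n: int, sampler: CorrelatedSampler | None = None,
                    seed: int = 0,
                    params: ModelParameters | None = None,
                    nyha_class: int | None = None) -> Cohort:
    """Generate ``n`` virtual patients.

    Parameters
    ----------
    n : cohort size (0 allowed).
    sampler : a prebuilt :class:`CorrelatedSampler`; built from ``params``
        (or the defaults) when omitted.
    seed : RNG seed; identical seeds give identical cohorts.
    nyha_class : when given, every patient is pinned to this class (the
        latent class assignment is overridden; all other covariates keep
        their correlated heterogeneity).
    """
    if n < 0:
        raise ValueError("cohort size must be nonnegative")
    if sampler is None:
        p = params or ModelParameters()
        sampler = build_correlated_sampler(
            p.cohort_moments, p.correlation_matrix, p.nyha_cutpoints,
            bounds=p.truncation_bounds)
    rng = np.random.default_rng(seed)
    df = sampler.sample(n, rng)
    if nyha_class is not None:
        if nyha_class not in (1, 2, 3, 4):
            raise ValueError("nyha_class must be 1-4")
        df["nyha_class"] = nyha_class
    df.insert(0, "patient_id", np.arange(n, dtype=np.int64))
    df["kit_type"] = pd.Series([None] * n, dtype=object)
    return Cohort(data=df, seed=seed, moments=sampler.moments,
                  clip_log=dict(sampler.clip_log))


def truncate_profile(profile: PatientProfile,
                     bounds: dict[str, tuple[float, float]]) -> PatientProfile:
    """Clip a single profile's continuous fields to the given ranges."""
    updated = dataclasses.asdict(profile)
    for name, (lo, hi) in bounds.items():
        if name in updated and updated[name] is not None:
            updated[name] = float(min(max(updated[name], lo), hi))
    return PatientProfile(**updated)
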