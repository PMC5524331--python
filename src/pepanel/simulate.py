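"""Synthetic longitudinal cohort generator with known ground truth.

The generator emulates the statistical structure the analysis assumes: for
patient ``i``, protein ``p`` at gestational age ``g`` (weeks),

    abundance = 2 ** ( f_p(g) + b_ip + delta_p(g) * [case] + eps )

with a smooth per-protein mean log2 trajectory ``f_p``, a patient random
intercept ``b_ip ~ N(0, sigma_patient^2)``, residual noise
``eps ~ N(0, sigma_resid^2)``, and case effects ``delta_p(g)`` equal to a
configured log2 effect size inside a gestational-age window and zero outside
it.  Occasional extreme outliers (a multiplicative factor of 4-10) exercise
the downstream thresholding step.

Defaults mirror the study conditions the pipeline was built for: 90 control
and 76 case patients, 2-6 samples per patient across 8-40 weeks, 1,125
proteins.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import CONTROL, LATE_PE, CohortTable, CovariateTable, ProteinPanel


class ConfigError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class Effect:
    """A multiplicative case effect on one protein inside a GA window."""

    protein: int  # column index into the panel
    log2_effect: float  # additive on the log2 scale
    ga_window: tuple[float, float]  # effect active for lo <= GA <= hi


@dataclasses.dataclass
class SyntheticConfig:
    n_controls: int = 90
    n_cases: int = 76
    n_proteins: int = 1125
    samples_per_patient: tuple[int, int] = (2, 6)
    ga_range: tuple[float, float] = (8.0, 40.0)
    #: fraction of proteins given a (random cubic) GA trend; the rest are flat
    trend_fraction: float = 0.5
    #: SD of the patient random intercept, log2 units
    sigma_patient: float = 0.35
    #: residual SD, log2 units
    sigma_resid: float = 0.25
    effects: Sequence[Effect] = ()
    outlier_rate: float = 0.0
    #: 'uniform' draws GAs uniformly in ga_range; 'grid' mimics 4-week visits
    schedule: str = "uniform"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_patient < 0 or self.sigma_resid < 0:
            raise ConfigError("noise SDs must be non-negative")
        lo, hi = self.samples_per_patient
        if not (1 <= lo <= hi):
            raise ConfigError("samples_per_patient range invalid")
        for e in self.effects:
            if not 0 <= e.protein < self.n_proteins:
                raise ConfigError(f"effect on protein index {e.protein} out of range")
            if not (self.ga_range[0] <= e.ga_window[0] <= e.ga_window[1] <= self.ga_range[1]):
                raise ConfigError(f"effect window {e.ga_window} outside ga_range")
        if not 0 <= self.outlier_rate < 1:
            raise ConfigError("outlier_rate must be in [0, 1)")
        if self.schedule not in ("uniform", "grid"):
            raise ConfigError("schedule must be 'uniform' or 'grid'")


def _trajectories(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-protein polynomial coefficients of the mean log2 curve.

    Baselines span the dynamic range typical of relative fluorescence data
    (log2 ~ 8-14); trended proteins get a random cubic in standardised GA.
    """
    coef = np.zeros((cfg.n_proteins, 4))
    coef[:, 0] = rng.uniform(8.0, 14.0, size=cfg.n_proteins)
    has_trend = rng.random(cfg.n_proteins) < cfg.trend_fraction
    coef[has_trend, 1:] = rng.normal(0.0, 0.3, size=(int(has_trend.sum()), 3))
    return coef


def _mean_log2(coef: np.ndarray, ga: np.ndarray) -> np.ndarray:
    """Evaluate the mean curves: (n_samples, n_proteins)."""
    z = (ga - 24.0) / 16.0  # standardise to roughly [-1, 1]
    basis = np.stack([np.ones_like(z), z, z**2, z**3], axis=1)
    return basis @ coef.T


def _sample_gas(cfg: SyntheticConfig, k: int, rng: np.random.Generator) -> np.ndarray:
    lo, hi = cfg.ga_range
    if cfg.schedule == "uniform":
        ga = np.sort(rng.uniform(lo, hi, size=k))
    else:
        # visits every 4 weeks from a random start, with ~2 days of jitter
        start = rng.uniform(lo, lo + 4.0)
        grid = np.arange(start, hi, 4.0)
        if len(grid) < k:
            k = len(grid)
        first = rng.integers(0, len(grid) - k + 1)
        ga = grid[first : first + k] + rng.normal(0.0, 0.3, size=k)
        ga = np.sort(np.clip(ga, lo, hi))
    # enforce strictly increasing GAs (duplicate draws are measure-zero but
    # clipping in grid mode can collide)
    while len(np.unique(ga)) < len(ga):
        ga = np.sort(ga + rng.normal(0.0, 1e-3, size=len(ga)))
    return ga


def generate_cohort(
    cfg: SyntheticConfig,
) -> tuple[CohortTable, CovariateTable, dict]:
    """Draw a full synthetic cohort; the seed fully determines the output.

    Returns the cohort, plausible per-patient covariates (BMI lognormal
    around the group medians, ~20% smokers, mild:severe cases 48:28), and a
    ground-truth record of every injected effect.
    """
    rng = np.random.default_rng(cfg.seed)
    coef = _trajectories(cfg, rng)

    patient_ids = [f"C{i:03d}" for i in range(cfg.n_controls)] + [
        f"P{i:03d}" for i in range(cfg.n_cases)
    ]
    groups = [CONTROL] * cfg.n_controls + [LATE_PE] * cfg.n_cases

    rows_meta = []
    rows_ab = []
    lo_k, hi_k = cfg.samples_per_patient
    for pid, grp in zip(patient_ids, groups):
        k = int(rng.integers(lo_k, hi_k + 1))
        ga = _sample_gas(cfg, k, rng)
        b = rng.normal(0.0, cfg.sigma_patient, size=cfg.n_proteins)
        mean = _mean_log2(coef, ga)  # (k, P)
        log2v = mean + b[None, :] + rng.normal(0.0, cfg.sigma_resid, size=mean.shape)
        if grp == LATE_PE:
            for e in cfg.effects:
                in_win = (ga >= e.ga_window[0]) & (ga <= e.ga_window[1])
                log2v[in_win, e.protein] += e.log2_effect
        values = np.exp2(log2v)
        for j in range(k):
            rows_meta.append((pid, float(ga[j]), grp))
            rows_ab.append(values[j])

    panel = ProteinPanel(columns=tuple(f"PROT{p:04d}" for p in range(cfg.n_proteins)))
    meta = pd.DataFrame(rows_meta, columns=["patient_id", "ga_weeks", "group"])
    values_all = np.asarray(rows_ab)
    if cfg.outlier_rate > 0:
        # separate stream so the base values are identical across outlier_rate
        rng_out = np.random.default_rng([cfg.seed, 0xA11])
        hit = rng_out.random(values_all.shape) < cfg.outlier_rate
        factors = rng_out.uniform(4.0, 10.0, size=values_all.shape)
        values_all = np.where(hit, values_all * factors, values_all)
    abundance = pd.DataFrame(values_all, columns=list(panel.columns))
    cohort = CohortTable(meta=meta, abundance=abundance, panel=panel)

    covariates = _draw_covariates(patient_ids, groups, rng)
    truth = {
        "seed": cfg.seed,
        "sigma_patient": cfg.sigma_patient,
        "sigma_resid": cfg.sigma_resid,
        "effects": [
            {
                "protein": panel.columns[e.protein],
                "protein_index": e.protein,
                "log2_effect": e.log2_effect,
                "ga_window": list(e.ga_window),
            }
            for e in cfg.effects
        ],
    }
    return cohort, covariates, truth


def _draw_covariates(patient_ids, groups, rng: np.random.Generator) -> CovariateTable:
    n = len(patient_ids)
    is_case = np.array([g == LATE_PE for g in groups])
    # BMI lognormal around median 26.5 (controls) / 30.0 (cases)
    bmi = np.exp(rng.normal(np.where(is_case, np.log(30.0), np.log(26.5)), 0.2, size=n))
    age = np.clip(np.round(rng.normal(24.0, 5.0, size=n)), 16, 45)
    parity = rng.poisson(1.2, size=n).astype(float)
    smoking = (rng.random(n) < 0.20).astype(float)
    severity = np.where(
        is_case, np.where(rng.random(n) < 48.0 / 76.0, "mild", "severe"), "none"
    )
    data = pd.DataFrame(
        {
            "bmi": bmi,
            "maternal_age": age,
            "parity": parity,
            "smoking": smoking,
            "severity": severity,
        },
        index=pd.Index(patient_ids, name="patient_id"),
    )
    return CovariateTable(data=data)


def write_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2)


def write_covariates(covariates: CovariateTable, path) -> None:
    df = covariates.data
    out = pd.DataFrame(
        {
            "ID": df.index,
            "BMI": df["bmi"].to_numpy(),
            "AGE": df["maternal_age"].to_numpy(),
            "PARITY": df["parity"].to_numpy(),
            "SMOKING": df["smoking"].astype(int).to_numpy(),
            "SEVERITY": df["severity"].to_numpy(),
        }
    )
    out.to_csv(path, index=False)
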